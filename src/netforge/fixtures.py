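"""Deterministic synthetic worlds with planted co-functional structure.

A world partitions part of its gene universe into functional modules and
makes module-mates look co-functional in every evidence channel the
toolkit consumes: correlated expression, similar phylogenetic profiles,
a shared rare protein domain, conserved chromosomal adjacency, and a
shared annotation term.  A second, paralog-duplicated proteome supports
orthology-transfer tests.  Everything is reproducible from (seed,
parameters): each evidence channel draws from its own sub-seeded stream
so adding one channel never perturbs another.

The generator emulates the *statistical* signatures of real evidence
(module-level correlation, profile similarity, synteny), not platform
artifacts or real similarity-score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    AnnotationSet,
    DataError,
    ExpressionMatrix,
    GenePair,
    gene_pair,
)
from .evidence import GeneOrderTable, OrderRow, ProfileMatrix
from .orthology import SimilarityTable, SimRow
from . import io as nfio


@dataclass
class WorldParams:
    """Synthetic-world generation parameters.

    ``noise`` in [0, 1] controls how cleanly module structure shows in
    each channel (0 = noiseless planted signal, 1 = no signal).
    """

    n_genes: int = 300
    n_modules: int = 6
    module_size: int = 20
    noise: float = 0.2
    n_samples: int = 24
    n_profile_cols: int = 30
    n_genomes: int = 8
    n_contigs: int = 4
    n_decoy_terms: int = 6
    dup_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise DataError("modules do not fit in the gene universe")
        if not 0.0 <= self.noise <= 1.0:
            raise DataError("noise must lie in [0, 1]")
        if self.n_samples < 12:
            raise DataError("n_samples must be >= 12 (co-expression minimum)")
        if not 0.0 <= self.dup_rate <= 1.0:
            raise DataError("dup_rate must lie in [0, 1]")


@dataclass
class SyntheticWorld:
    params: WorldParams
    seed: int
    genes: list[str]
    modules: list[list[str]]
    annotations: AnnotationSet
    expression: ExpressionMatrix
    phylo_profiles: ProfileMatrix
    domain_ann: AnnotationSet
    gene_orders: GeneOrderTable
    sim_table: SimilarityTable
    target_namesakes: dict[str, str]
    truth: set[GenePair] = field(default_factory=set)

    def target_annotations(self) -> AnnotationSet:
        """Module terms mapped onto the duplicated target proteome."""
        terms = {
            term: frozenset(self.target_namesakes[g] for g in genes)
            for term, genes in self.annotations.terms.items()
            if term.startswith("MOD_")
        }
        return AnnotationSet(terms=terms)

    def module_terms(self) -> list[str]:
        return sorted(t for t in self.annotations.terms if t.startswith("MOD_"))


def _module_annotations(
    modules: list[list[str]], genes: list[str], params: WorldParams,
    rng: np.random.Generator,
) -> AnnotationSet:
    terms: dict[str, frozenset[str]] = {}
    meta: dict[str, dict] = {}
    for m, members in enumerate(modules):
        term = f"MOD_{m:02d}"
        terms[term] = frozenset(members)
        meta[term] = {"level": 5, "name": f"planted module {m}"}
    for d in range(params.n_decoy_terms):
        members = rng.choice(genes, size=params.module_size, replace=False)
        term = f"DECOY_{d:02d}"
        terms[term] = frozenset(members)
        meta[term] = {"level": 5, "name": f"decoy term {d}"}
    return AnnotationSet(terms=terms, term_meta=meta)


def _expression(
    genes: list[str], modules: list[list[str]], params: WorldParams,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    member_of = {g: m for m, mem in enumerate(modules) for g in mem}
    factors = rng.standard_normal((params.n_modules, params.n_samples))
    values = rng.standard_normal((params.n_genes, params.n_samples))
    for i, g in enumerate(genes):
        m = member_of.get(g)
        if m is not None:
            values[i] = (1.0 - params.noise) * factors[m] + params.noise * values[i]
    samples = [f"S{j:03d}" for j in range(params.n_samples)]
    return ExpressionMatrix(genes=list(genes), samples=samples, values=values)


def _phylo_profiles(
    genes: list[str], modules: list[list[str]], params: WorldParams,
    rng: np.random.Generator,
) -> ProfileMatrix:
    member_of = {g: m for m, mem in enumerate(modules) for g in mem}
    patterns = rng.integers(0, 2, size=(params.n_modules, params.n_profile_cols))
    values = rng.integers(0, 2, size=(params.n_genes, params.n_profile_cols)).astype(float)
    for i, g in enumerate(genes):
        m = member_of.get(g)
        if m is not None:
            resample = rng.random(params.n_profile_cols) < params.noise
            row = np.where(resample, values[i], patterns[m])
            values[i] = row
    cols = [f"SP{j:03d}" for j in range(params.n_profile_cols)]
    return ProfileMatrix(genes=list(genes), columns=cols, values=values)


def _domain_annotations(
    genes: list[str], modules: list[list[str]], params: WorldParams,
    rng: np.random.Generator,
) -> AnnotationSet:
    terms: dict[str, frozenset[str]] = {}
    for m, members in enumerate(modules):
        keep = rng.random(len(members)) >= params.noise
        carriers = [g for g, k in zip(members, keep) if k]
        if len(carriers) < 2:
            carriers = list(members[:2])
        terms[f"DOM_MOD_{m:02d}"] = frozenset(carriers)
    for c in range(5):
        carriers = rng.choice(genes, size=max(2, params.n_genes // 3), replace=False)
        terms[f"DOM_COMMON_{c}"] = frozenset(carriers)
    return AnnotationSet(terms=terms)


def _gene_orders(
    genes: list[str], modules: list[list[str]], params: WorldParams,
    rng: np.random.Generator,
) -> GeneOrderTable:
    module_genes = {g for mem in modules for g in mem}
    background = [g for g in genes if g not in module_genes]
    rows: list[OrderRow] = []
    for gi in range(params.n_genomes):
        order = list(background)
        rng.shuffle(order)
        for members in modules:
            block = list(members)
            rng.shuffle(block)
            if rng.random() >= params.noise:  # keep module syntenic
                at = rng.integers(0, len(order) + 1)
                order[at:at] = block
            else:
                for g in block:
                    at = rng.integers(0, len(order) + 1)
                    order.insert(at, g)
        contig_len = (len(order) + params.n_contigs - 1) // params.n_contigs
        genome = f"GEN{gi:02d}"
        for idx, g in enumerate(order):
            contig = f"{genome}_c{idx // contig_len}"
            rows.append(OrderRow(genome=genome, gene=g, contig=contig,
                                 position=idx % contig_len))
    return GeneOrderTable(rows=rows)


def _similarity(
    genes: list[str], params: WorldParams, rng: np.random.Generator
) -> tuple[SimilarityTable, dict[str, str]]:
    """Duplicated target proteome: namesake orthologs plus paralogs.

    The world's genes act as the source species (direction code B); the
    duplicated proteome is the target species (code A) queried against
    it.  Each target namesake is a mutual best hit of its source gene;
    a ``dup_rate`` fraction of target genes carry a paralog whose
    within-target similarity to the namesake is a random fraction of
    the seed score.
    """
    rows: list[SimRow] = []
    namesakes: dict[str, str] = {}
    for g in genes:
        tg = f"t_{g}"
        namesakes[g] = tg
        s = float(rng.uniform(200.0, 400.0))
        rows.append(SimRow(query=tg, subject=g, direction="AB", score=s))
        rows.append(SimRow(query=g, subject=tg, direction="BA", score=s))
        if rng.random() < params.dup_rate:
            ratio = float(rng.uniform(0.5, 0.95))
            rows.append(SimRow(query=f"{tg}_p", subject=tg, direction="AA",
                               score=ratio * s))
    return SimilarityTable(rows=rows), namesakes


def generate_world(seed: int, params: WorldParams | None = None, **overrides) -> SyntheticWorld:
    """Build a fully reproducible synthetic world.

    Parameters may be given as a :class:`WorldParams` or as keyword
    overrides of its defaults.
    """
    if params is None:
        params = WorldParams(**overrides)
    elif overrides:
        raise DataError("pass either params or keyword overrides, not both")
    streams = np.random.SeedSequence(seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]
    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    modules = [
        genes[m * params.module_size : (m + 1) * params.module_size]
        for m in range(params.n_modules)
    ]
    truth = {
        gene_pair(a, b)
        for members in modules
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    }
    annotations = _module_annotations(modules, genes, params, rngs[0])
    expression = _expression(genes, modules, params, rngs[1])
    phylo = _phylo_profiles(genes, modules, params, rngs[2])
    domains = _domain_annotations(genes, modules, params, rngs[3])
    orders = _gene_orders(genes, modules, params, rngs[4])
    sim, namesakes = _similarity(genes, params, rngs[5])
    return SyntheticWorld(
        params=params,
        seed=seed,
        genes=genes,
        modules=modules,
        annotations=annotations,
        expression=expression,
        phylo_profiles=phylo,
        domain_ann=domains,
        gene_orders=orders,
        sim_table=sim,
        target_namesakes=namesakes,
        truth=truth,
    )


def world_to_files(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Emit every input format the toolkit consumes; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "annotations": out / "annotations.gmt",
        "term_levels": out / "term_levels.tsv",
        "expression": out / "expression.tsv",
        "phylo_profiles": out / "phylo_profiles.tsv",
        "domains": out / "domains.gmt",
        "gene_orders": out / "gene_orders.tsv",
        "similarity": out / "similarity.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
    }
    nfio.write_annotation_gmt(world.annotations, manifest["annotations"])
    with open(manifest["term_levels"], "w") as fh:
        for term in sorted(world.annotations.terms):
            level = world.annotations.term_meta.get(term, {}).get("level", 1)
            fh.write(f"{term}\t{level}\n")
    nfio.write_expression_matrix(world.expression, manifest["expression"])
    nfio.write_profile_matrix(world.phylo_profiles, manifest["phylo_profiles"])
    nfio.write_annotation_gmt(world.domain_ann, manifest["domains"])
    nfio.write_gene_order_table(world.gene_orders, manifest["gene_orders"])
    nfio.write_similarity_table(world.sim_table, manifest["similarity"])
    nfio.write_pair_set(world.truth, manifest["truth_pairs"])
    return manifest
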