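"""Readers and writers for every text format the toolkit touches.

All pair-based files are half-matrix: each unordered pair appears exactly
once, stored with the lexicographically smaller gene first.  Weights are
serialized with 6 significant digits for stable diffs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datamodel import (
    AnnotationSet,
    ComponentNetwork,
    DataError,
    ExpressionMatrix,
    GenePair,
    IntegratedNetwork,
    gene_pair,
    validate_gene_id,
)

logger = logging.getLogger("netforge")

_WFMT = "{:.6g}"


def read_annotation_set(path: str | Path, format: str = "gmt") -> AnnotationSet:
    """Read an annotation set from a GMT or two-column gene/term TSV file.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; the
    two-column format is ``gene<TAB>term`` per line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise DataError(f"{path}: empty annotation file")
    terms: dict[str, set[str]] = {}
    meta: dict[str, dict] = {}
    if format == "gmt":
        for lineno, ln in content:
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term, desc = fields[0], fields[1]
            genes = {validate_gene_id(g) for g in fields[2:] if g}
            if not genes:
                raise DataError(f"{path}:{lineno}: GMT line has no genes")
            terms.setdefault(term, set()).update(genes)
            if desc:
                meta.setdefault(term, {})["name"] = desc
    elif format == "two-column":
        for lineno, ln in content:
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected gene<TAB>term")
            gene, term = fields
            terms.setdefault(term, set()).add(validate_gene_id(gene))
    else:
        raise DataError(f"unknown annotation format {format!r}")
    return AnnotationSet(terms={t: frozenset(g) for t, g in terms.items()}, term_meta=meta)


def write_annotation_gmt(ann: AnnotationSet, path: str | Path) -> None:
    """Write an annotation set in GMT format (deterministic ordering)."""
    with open(path, "w") as fh:
        for term in sorted(ann.terms):
            desc = ann.term_meta.get(term, {}).get("name", "na")
            genes = "\t".join(sorted(ann.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_term_levels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``term<TAB>level`` TSV of ontology depths."""
    out: dict[str, int] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise DataError(f"{path}:{lineno}: expected term<TAB>level")
        try:
            out[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-integer level {fields[1]!r}") from exc
    return out


def _parse_edge_rows(
    path: Path, tolerate_symmetric: bool
) -> dict[GenePair, float]:
    edges: dict[GenePair, float] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise DataError(f"{path}:{lineno}: expected geneA<TAB>geneB<TAB>weight")
        a, b, w_str = fields
        if a == b:
            raise DataError(f"{path}:{lineno}: self-loop on {a!r}")
        try:
            w = float(w_str)
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-numeric weight {w_str!r}") from exc
        pair = gene_pair(validate_gene_id(a), validate_gene_id(b))
        if pair in edges:
            if tolerate_symmetric and abs(edges[pair] - w) <= 1e-9 * max(1.0, abs(w)):
                continue
            raise DataError(f"{path}:{lineno}: duplicate unordered pair {pair}")
        edges[pair] = w
    return edges


def read_edge_list(
    path: str | Path, tolerate_symmetric: bool = False
) -> IntegratedNetwork:
    """Read a ``geneA geneB weight`` TSV into a network.

    With ``tolerate_symmetric`` a symmetric duplicate row carrying the
    identical weight is collapsed instead of rejected.
    """
    edges = _parse_edge_rows(Path(path), tolerate_symmetric)
    return IntegratedNetwork(edges=edges)


def read_component(path: str | Path, dataset_id: str | None = None) -> ComponentNetwork:
    """Read an edge-list TSV as a component (LLS-weighted) network."""
    edges = _parse_edge_rows(Path(path), tolerate_symmetric=False)
    return ComponentNetwork(dataset_id=dataset_id or Path(path).stem, edges=edges)


def write_edge_list(network: IntegratedNetwork | ComponentNetwork, path: str | Path) -> None:
    """Write a network as a half-matrix ``geneA geneB weight`` TSV."""
    with open(path, "w") as fh:
        for (a, b), w in sorted(network.edges.items()):
            fh.write(f"{a}\t{b}\t{_WFMT.format(w)}\n")


def write_sif(
    network: IntegratedNetwork | ComponentNetwork,
    path: str | Path,
    relation: str = "cofunction",
) -> None:
    """Write a network in Cytoscape SIF format, one line per unordered edge."""
    if not network.edges:
        logger.warning("writing empty network to %s", path)
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def read_sif(path: str | Path, weight: float = 1.0) -> IntegratedNetwork:
    """Read a SIF file back into a network (uniform edge weight)."""
    edges: dict[GenePair, float] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 3:
            raise DataError(f"{path}:{lineno}: expected node<TAB>relation<TAB>node")
        edges[gene_pair(fields[0], fields[2])] = weight
    return IntegratedNetwork(edges=edges)


def read_scored_pairs(path: str | Path, dataset_id: str | None = None):
    """Read a scored-pair TSV (geneA, geneB, score) as a ScoredPairTable."""
    from .datamodel import ScoredPairTable

    rows = _parse_edge_rows(Path(path), tolerate_symmetric=False)
    return ScoredPairTable(dataset_id=dataset_id or Path(path).stem, rows=rows)


def write_scored_pairs(table, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (a, b), s in sorted(table.rows.items()):
            fh.write(f"{a}\t{b}\t{_WFMT.format(s)}\n")


def read_pair_set(path: str | Path) -> set[GenePair]:
    """Read a two-column pair file (gold-standard positives/negatives)."""
    pairs: set[GenePair] = set()
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise DataError(f"{path}:{lineno}: expected geneA<TAB>geneB")
        pairs.add(gene_pair(fields[0], fields[1]))
    return pairs


def write_pair_set(pairs: Iterable[GenePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line list (guide genes, DEGs)."""
    return {
        validate_gene_id(ln.strip())
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    }


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample ids, col 0 = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"{path}: empty expression matrix")
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate gene rows")
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.genes, columns=em.samples)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_profile_matrix(path: str | Path):
    """Read a genes x columns profile TSV as a ProfileMatrix."""
    from .evidence import ProfileMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"{path}: empty profile matrix")
    return ProfileMatrix(
        genes=[str(g) for g in df.index],
        columns=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_profile_matrix(pm, path: str | Path) -> None:
    df = pd.DataFrame(pm.values, index=pm.genes, columns=pm.columns)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_gene_order_table(path: str | Path):
    """Read a ``genome gene contig position`` TSV as a GeneOrderTable."""
    from .evidence import GeneOrderTable, OrderRow

    rows = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 4:
            raise DataError(f"{path}:{lineno}: expected genome<TAB>gene<TAB>contig<TAB>index")
        try:
            pos = int(fields[3])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-integer position {fields[3]!r}") from exc
        rows.append(OrderRow(genome=fields[0], gene=fields[1], contig=fields[2], position=pos))
    return GeneOrderTable(rows=rows)


def write_gene_order_table(table, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table.rows:
            fh.write(f"{r.genome}\t{r.gene}\t{r.contig}\t{r.position}\n")


def read_similarity_table(path: str | Path):
    """Read a ``query subject direction score`` TSV as a SimilarityTable."""
    from .orthology import SimilarityTable, SimRow

    rows = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 4:
            raise DataError(
                f"{path}:{lineno}: expected query<TAB>subject<TAB>direction<TAB>score"
            )
        try:
            score = float(fields[3])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-numeric score {fields[3]!r}") from exc
        rows.append(SimRow(query=fields[0], subject=fields[1], direction=fields[2], score=score))
    return SimilarityTable(rows=rows)


def write_similarity_table(table, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table.rows:
            fh.write(f"{r.query}\t{r.subject}\t{r.direction}\t{_WFMT.format(r.score)}\n")
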