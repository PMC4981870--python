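"""Orthology mapping and cross-species network transfer.

Functional linkages conserved between species ("associalogs") let a
well-annotated source network seed a network for a new proteome.  Two
mapping schemes are provided: bidirectional best hits (BBH) and a
reduced InParanoid-style clustering in which same-species inparalogs
join a BBH seed pair with a confidence score equal to their similarity
to the seed gene relative to the seed pair's cross-species similarity.
Transferred edges are scored by the InParanoid-weighted LLS:

    IWLLS(A-B) = LLS(A'-B') * s(A, A') * s(B, B')

where (A', B') is the source edge and s are the inparalog confidence
scores in [0, 1] (1 for seed orthologs), so transfer never inflates an
edge weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .datamodel import ComponentNetwork, DataError, GenePair, gene_pair

logger = logging.getLogger("netforge")

# direction codes: cross-species AB / BA, within-species AA / BB
_CROSS = {"AB", "BA"}
_WITHIN = {"AA", "BB"}


@dataclass(frozen=True)
class SimRow:
    query: str
    subject: str
    direction: str
    score: float


@dataclass
class SimilarityTable:
    """Pairwise sequence-similarity scores between (and within) species.

    ``direction`` is AB (species-A query vs species-B subject), BA, or
    the within-species codes AA / BB used for inparalog detection.
    """

    rows: list[SimRow]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for r in self.rows:
            if r.direction not in _CROSS | _WITHIN:
                raise DataError(f"unknown direction {r.direction!r}")
            if r.score < 0:
                raise DataError(f"negative similarity score for {r.query}->{r.subject}")
            key = (r.query, r.subject, r.direction)
            if key in seen:
                raise DataError(f"duplicate similarity row {key}")
            seen.add(key)

    def best_hits(self, direction: str) -> dict[str, tuple[str, float]]:
        """Per-query best hit in one direction (ties: higher score, then
        lexicographically smaller subject; resolution is logged)."""
        best: dict[str, tuple[str, float]] = {}
        tied: set[str] = set()
        for r in self.rows:
            if r.direction != direction:
                continue
            cur = best.get(r.query)
            if cur is None or r.score > cur[1] or (r.score == cur[1] and r.subject < cur[0]):
                if cur is not None and r.score == cur[1]:
                    tied.add(r.query)
                best[r.query] = (r.subject, r.score)
            elif r.score == cur[1]:
                tied.add(r.query)
        for q in tied:
            logger.info("tie for best %s hit of %s resolved deterministically", direction, q)
        return best

    def within_scores(self, direction: str) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for r in self.rows:
            if r.direction == direction:
                out[(r.query, r.subject)] = r.score
        return out


@dataclass(frozen=True)
class OrthoLink:
    gene_src: str
    gene_tgt: str
    inparalog_score: float
    cluster_id: str


@dataclass
class OrthologyMap:
    """Cross-species gene correspondences with inparalog confidences.

    Each cluster holds exactly one seed (mutual-best) pair with score 1;
    additional links are inparalogs with scores in [0, 1].
    """

    links: list[OrthoLink]

    def __post_init__(self) -> None:
        for link in self.links:
            if not 0.0 <= link.inparalog_score <= 1.0:
                raise DataError("inparalog scores must lie in [0, 1]")

    def src_to_tgt(self) -> dict[str, list[tuple[str, float]]]:
        """source gene -> [(target gene, inparalog-pair product score)]."""
        out: dict[str, list[tuple[str, float]]] = {}
        for link in self.links:
            out.setdefault(link.gene_src, []).append((link.gene_tgt, link.inparalog_score))
        return out

    @classmethod
    def identity(cls, genes) -> "OrthologyMap":
        return cls(
            links=[OrthoLink(g, g, 1.0, f"cluster_{g}") for g in sorted(genes)]
        )


def bbh(sim: SimilarityTable) -> OrthologyMap:
    """Bidirectional-best-hit orthology: (a, b) linked iff b is a's best
    forward hit and a is b's best reverse hit; all scores are 1."""
    fwd = sim.best_hits("AB")
    rev = sim.best_hits("BA")
    if not fwd or not rev:
        raise DataError("similarity table must contain both AB and BA directions")
    links = []
    for a in sorted(fwd):
        b, _ = fwd[a]
        back = rev.get(b)
        if back is not None and back[0] == a:
            links.append(OrthoLink(gene_src=b, gene_tgt=a, inparalog_score=1.0,
                                   cluster_id=f"seed_{a}_{b}"))
    return OrthologyMap(links=links)


def inparanoid_clusters(sim: SimilarityTable, overlap_cut: float = 0.0) -> OrthologyMap:
    """InParanoid-style clustering reduced to seed + similarity-ratio rule.

    BBH pairs seed the clusters with confidence 1.  A same-species gene
    joins a cluster when its within-species similarity to the seed gene
    reaches ``overlap_cut`` times the seed pair's cross-species score,
    with inparalog confidence = that ratio clipped to [0, 1]; a gene
    qualifying for several clusters goes to the one with the higher
    seed score.
    """
    seeds = bbh(sim)
    fwd = sim.best_hits("AB")
    within_a = sim.within_scores("AA")
    within_b = sim.within_scores("BB")
    seed_pairs: list[tuple[str, str, float]] = []  # (a, b, cross score)
    for link in seeds.links:
        a, b = link.gene_tgt, link.gene_src
        seed_pairs.append((a, b, fwd[a][1]))
    links = list(seeds.links)
    seed_genes_a = {a for a, _, _ in seed_pairs}
    seed_genes_b = {b for _, b, _ in seed_pairs}
    # candidate inparalogs: gene -> (score, cluster, partner-side seed, seed score)
    best_assign: dict[tuple[str, str], tuple[float, float, OrthoLink]] = {}
    for a, b, s_cross in seed_pairs:
        if s_cross <= 0:
            continue
        cluster = f"seed_{a}_{b}"
        for (q, subj), s_within in within_a.items():
            if subj != a or q == a or q in seed_genes_a:
                continue
            ratio = s_within / s_cross
            if ratio < overlap_cut:
                continue
            link = OrthoLink(gene_src=b, gene_tgt=q,
                             inparalog_score=min(ratio, 1.0), cluster_id=cluster)
            _assign(best_assign, ("A", q), s_cross, link)
        for (q, subj), s_within in within_b.items():
            if subj != b or q == b or q in seed_genes_b:
                continue
            ratio = s_within / s_cross
            if ratio < overlap_cut:
                continue
            link = OrthoLink(gene_src=q, gene_tgt=a,
                             inparalog_score=min(ratio, 1.0), cluster_id=cluster)
            _assign(best_assign, ("B", q), s_cross, link)
    links.extend(link for _, _, link in best_assign.values())
    return OrthologyMap(links=links)


def _assign(best_assign, key, seed_score, link) -> None:
    cur = best_assign.get(key)
    if cur is None or seed_score > cur[0]:
        best_assign[key] = (seed_score, link.inparalog_score, link)


def transfer(
    network_src: ComponentNetwork, omap: OrthologyMap, dataset_id: str | None = None
) -> ComponentNetwork:
    """Map a source network onto the target proteome, scoring by IWLLS.

    For every source edge (A', B') and every target pair (A, B) reachable
    through the orthology links, the candidate weight is the source LLS
    times the two inparalog scores; multiple routes to the same target
    pair keep the maximum, and self-pairs are discarded.
    """
    mapping = omap.src_to_tgt()
    if not any(a in mapping or b in mapping for a, b in network_src.edges):
        raise DataError("orthology map shares no genes with the source network")
    edges: dict[GenePair, float] = {}
    for (a_src, b_src), w in network_src.edges.items():
        for a_tgt, s_a in mapping.get(a_src, ()):
            for b_tgt, s_b in mapping.get(b_src, ()):
                if a_tgt == b_tgt:
                    continue
                pair = gene_pair(a_tgt, b_tgt)
                iwlls = w * s_a * s_b
                if iwlls > edges.get(pair, float("-inf")):
                    edges[pair] = iwlls
    src_id = dataset_id or (
        f"{getattr(network_src, 'dataset_id', 'network')}_transferred"
    )
    return ComponentNetwork(dataset_id=src_id, edges=edges)


def term_recovery_auc(network, ann, min_term: int = 5) -> list[tuple[str, float]]:
    """Leave-one-out guilt-by-association AUC per annotation term.

    Each term with at least ``min_term`` member genes present in the
    network is scored by the neighborhood leave-one-out ROC analysis;
    terms whose members are absent from the network are skipped.
    """
    from .prioritize import loo_auc

    if not ann.terms:
        raise DataError("annotation set is empty")
    net_genes = network.genes()
    out: list[tuple[str, float]] = []
    for term in sorted(ann.terms):
        members = ann.terms[term] & net_genes
        if len(members) < min_term:
            if ann.terms[term] and not members:
                logger.info("term %s members absent from network; skipped", term)
            continue
        out.append((term, loo_auc(network, members)))
    return out
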