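"""Network-assisted gene prioritization and function prediction.

Two complementary strategies:

* neighborhood-based — candidates are ranked by the sum of edge weights
  connecting them to user-supplied guide genes, with leave-one-out ROC
  analysis reporting how well the network retrieves the guides
  themselves (AUC 0.5 = random, 1 = perfect, > 0.7 = good);
* context-based — network hubs (degree >= 50 by default) are tested for
  enrichment of their direct neighborhoods in a set of differentially
  expressed genes by a one-tailed Fisher's exact test.

Direct neighbors also drive function prediction: candidate annotation
terms for a query gene are ranked by the summed weight of annotated
neighbors carrying each term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import AnnotationSet, DataError
from .gold import GoldStandard  # noqa: F401  (re-exported for CLI convenience)

logger = logging.getLogger("netforge")

GOOD_AUC = 0.7


@dataclass
class PrioritizationResult:
    """Ranked candidates from neighborhood-based prioritization."""

    candidates: list[tuple[str, float]]
    guide_genes_used: frozenset[str]
    auc: float | None = None

    @property
    def good_predictive_power(self) -> bool | None:
        return None if self.auc is None else self.auc > GOOD_AUC

    def top(self, k: int = 100) -> list[tuple[str, float]]:
        return self.candidates[:k]


def _guide_sums(adj, guides, exclude: str | None = None) -> dict[str, float]:
    scores: dict[str, float] = {}
    for u in guides:
        if u == exclude:
            continue
        for nbr, w in adj.get(u, {}).items():
            scores[nbr] = scores.get(nbr, 0.0) + w
    return scores


def neighborhood_scores(net, guides, compute_auc: bool = True) -> PrioritizationResult:
    """Rank non-guide genes by summed edge weight to the guide genes.

    Guides absent from the network are logged and dropped; at least one
    must remain.  Candidates are all non-guide genes with positive
    score, ranked by descending score with lexicographic tie-breaks.
    """
    guides = set(guides)
    net_genes = net.genes()
    present = guides & net_genes
    missing = guides - net_genes
    if missing:
        logger.info("%d guide genes absent from network dropped", len(missing))
    if not present:
        raise DataError("no guide genes present in the network")
    adj = net.adjacency()
    scores = _guide_sums(adj, present)
    candidates = sorted(
        ((g, s) for g, s in scores.items() if g not in present and s > 0),
        key=lambda kv: (-kv[1], kv[0]),
    )
    auc = loo_auc(net, present) if compute_auc and len(present) >= 2 else None
    return PrioritizationResult(
        candidates=candidates, guide_genes_used=frozenset(present), auc=auc
    )


def loo_auc(net, guides) -> float:
    """Leave-one-out ROC AUC of guide retrieval by neighborhood scoring.

    Each guide g is scored against the remaining guides and compared
    with all non-guide network genes scored in the same fold; the AUC is
    the Mann-Whitney statistic over all (held-out guide, non-guide)
    comparisons, with ties credited 0.5.
    """
    guides = set(guides)
    net_genes = net.genes()
    present = sorted(guides & net_genes)
    if len(present) < 2:
        raise DataError("leave-one-out AUC needs >= 2 guide genes in the network")
    adj = net.adjacency()
    nonguides = sorted(net_genes - guides)
    if not nonguides:
        raise DataError("no non-guide genes in the network")
    base = _guide_sums(adj, present)
    ng_base = np.array([base.get(g, 0.0) for g in nonguides])
    wins = 0.0
    total = 0
    for h in present:
        h_adj = adj.get(h, {})
        # non-guide scores in this fold: remove h's contribution
        fold = ng_base - np.array([h_adj.get(g, 0.0) for g in nonguides])
        s_h = sum(w for u, w in h_adj.items() if u in guides and u != h)
        fold_sorted = np.sort(fold)
        lo = np.searchsorted(fold_sorted, s_h, side="left")
        hi = np.searchsorted(fold_sorted, s_h, side="right")
        wins += lo + 0.5 * (hi - lo)
        total += len(nonguides)
    return wins / total


@dataclass
class ContextHubResult:
    """Hubs enriched for DEG neighborhoods, ranked by Fisher p-value."""

    hubs: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (gene, degree, overlap with DEGs, p_value)


def fisher_enrichment_p(overlap: int, n_neighbors: int, n_degs: int, universe: int) -> float:
    """One-tailed (enrichment) Fisher's exact p for a 2x2 neighborhood table.

    Probability of drawing >= ``overlap`` DEGs when ``n_neighbors`` genes
    are sampled without replacement from a universe containing
    ``n_degs`` DEGs: the hypergeometric upper tail.
    """
    if overlap > min(n_neighbors, n_degs) or universe < max(n_neighbors, n_degs):
        raise DataError("inconsistent contingency counts")
    return float(stats.hypergeom.sf(overlap - 1, universe, n_degs, n_neighbors))


def context_hubs(
    net,
    degs,
    min_degree: int = 50,
    p_cut: float = 0.01,
    bh_correct: bool = False,
) -> ContextHubResult:
    """Context-based prioritization of network hubs against a DEG set.

    For each hub (degree >= ``min_degree``) the 2x2 table of (neighbor
    of hub) x (DEG membership) over the network's gene universe minus
    the hub is tested for enrichment; hubs passing ``p_cut`` are
    returned ranked by ascending p-value.  ``bh_correct`` optionally
    applies a Benjamini-Hochberg correction across hubs before the cut
    (off by default).
    """
    degs = set(degs)
    net_genes = net.genes()
    deg_in_net = degs & net_genes
    if not deg_in_net:
        raise DataError("no DEGs present in the network")
    adj = net.adjacency()
    hubs = sorted(g for g in net_genes if len(adj.get(g, {})) >= min_degree)
    if not hubs:
        logger.warning("no gene reaches hub degree threshold %d", min_degree)
        return ContextHubResult(hubs=[])
    records = []
    n_universe = len(net_genes) - 1  # hub itself excluded
    for h in hubs:
        neighbors = set(adj[h])
        overlap = len(neighbors & deg_in_net)
        n_degs_bg = len(deg_in_net - {h})
        p = fisher_enrichment_p(overlap, len(neighbors), n_degs_bg, n_universe)
        records.append((h, len(neighbors), overlap, p))
    if bh_correct:
        order = np.argsort([r[3] for r in records], kind="stable")
        m = len(records)
        adj_p = {}
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            i = m - rank_from_last
            running = min(running, records[idx][3] * m / i)
            adj_p[idx] = running
        records = [
            (h, d, o, adj_p[i]) for i, (h, d, o, _p) in enumerate(records)
        ]
    passing = [r for r in records if r[3] <= p_cut]
    passing.sort(key=lambda r: (r[3], r[0]))
    return ContextHubResult(hubs=passing)


def predict_function(
    net, query: str, ann: AnnotationSet, k: int = 10
) -> list[tuple[str, float]]:
    """Candidate annotation terms for a gene from its direct neighbors.

    Each term carried by an annotated neighbor scores the summed weight
    of the edges to the neighbors carrying it; the top ``k`` terms are
    returned (ties broken lexicographically).
    """
    adj = net.adjacency()
    if query not in net.genes():
        raise DataError(f"query gene {query!r} absent from the network")
    gene_terms = ann.gene_to_terms()
    term_scores: dict[str, float] = {}
    for nbr, w in adj[query].items():
        for term in gene_terms.get(nbr, ()):
            term_scores[term] = term_scores.get(term, 0.0) + w
    if not term_scores:
        logger.info("query %s has no annotated neighbors", query)
        return []
    ranked = sorted(term_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


@dataclass
class GBABenchmark:
    """Per-term guilt-by-association AUCs plus summary statistics."""

    term_aucs: list[tuple[str, float]]
    median_auc: float
    wilcoxon_p: float  # one-sided signed-rank test of AUCs vs 0.5


def gba_benchmark(net, ann: AnnotationSet, min_term: int = 5) -> GBABenchmark:
    """Leave-one-out AUC for every qualifying annotation term.

    Terms with at least ``min_term`` member genes in the network each
    contribute one AUC; the summary reports the median and a one-sided
    Wilcoxon signed-rank test of the AUC distribution against 0.5.
    """
    from .orthology import term_recovery_auc

    aucs = term_recovery_auc(net, ann, min_term=min_term)
    if not aucs:
        raise DataError(f"no term has >= {min_term} member genes in the network")
    values = np.array([a for _, a in aucs])
    nonzero = values[values != 0.5]
    if nonzero.size:
        wp = float(stats.wilcoxon(values - 0.5, alternative="greater").pvalue)
    else:
        wp = 1.0
    return GBABenchmark(
        term_aucs=aucs, median_auc=float(np.median(values)), wilcoxon_p=wp
    )
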