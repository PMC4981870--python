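"""Evidence scoring: raw data -> continuous pairwise scores.

Four families of functional-linkage evidence are scored here, each
producing a :class:`~netforge.datamodel.ScoredPairTable` that is later
calibrated to log-likelihood scores:

* phylogenetic profiling — mutual information between genes' presence
  profiles across reference genomes;
* protein-domain co-occurrence — mutual information between
  inverse-frequency-weighted domain profiles, so rare domains carry more
  weight than common ones;
* gene neighborhood — two complementary statistics of chromosomal
  proximity conserved across genomes (a physical-distance score and a
  probability-of-proximity score);
* co-expression — Pearson correlation between expression profiles,
  retained only when significant at a configurable confidence level.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    AnnotationSet,
    DataError,
    ExpressionMatrix,
    GenePair,
    ScoredPairTable,
    gene_pair,
)

logger = logging.getLogger("netforge")


@dataclass
class ProfileMatrix:
    """Genes x columns profile values (species presence or domain weights)."""

    genes: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise DataError("profile matrix shape mismatch")
        if np.any(self.values < 0):
            raise DataError("profile values must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene rows in profile matrix")


@dataclass(frozen=True)
class OrderRow:
    genome: str
    gene: str
    contig: str
    position: int


@dataclass
class GeneOrderTable:
    """Per-genome gene order: (genome, gene, contig, position index)."""

    rows: list[OrderRow]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for r in self.rows:
            key = (r.genome, r.contig, r.position)
            if key in seen:
                raise DataError(
                    f"duplicate position {r.position} on contig {r.contig!r} "
                    f"of genome {r.genome!r}"
                )
            seen.add(key)

    def by_genome(self) -> dict[str, dict[str, tuple[str, int]]]:
        """genome -> {gene -> (contig, position)}."""
        out: dict[str, dict[str, tuple[str, int]]] = {}
        for r in self.rows:
            out.setdefault(r.genome, {})[r.gene] = (r.contig, r.position)
        return out

    def contig_sizes(self) -> dict[tuple[str, str], int]:
        """(genome, contig) -> number of genes placed on that contig."""
        sizes: dict[tuple[str, str], int] = {}
        for r in self.rows:
            key = (r.genome, r.contig)
            sizes[key] = sizes.get(key, 0) + 1
        return sizes


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def _discretize(v: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-width discretization; <=2 distinct values are used directly.

    Returns integer codes and the number of levels.  A constant vector
    collapses to a single level (MI against anything is then 0).
    """
    v = np.asarray(v, dtype=float)
    uniq = np.unique(v)
    if uniq.size <= 2:
        return np.searchsorted(uniq, v), uniq.size
    lo, hi = float(uniq[0]), float(uniq[-1])
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    return np.digitize(v, edges), n_bins


def _mi_from_codes(ix: np.ndarray, nx: int, iy: np.ndarray, ny: int) -> float:
    joint = np.bincount(ix * ny + iy, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    outer = np.outer(px, py)
    mi = float(np.sum(p[mask] * np.log(p[mask] / outer[mask])))
    return max(mi, 0.0)


def mutual_information(x, y, n_bins: int = 4) -> float:
    """Mutual information (nats) of two real vectors after discretization.

    Each vector is independently discretized into ``n_bins`` equal-width
    bins; binary vectors bypass discretization and are used as categories
    directly.  A constant vector yields MI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise DataError("mutual_information requires equal-length vectors of size >= 2")
    if n_bins < 2:
        raise DataError("n_bins must be >= 2")
    ix, nx = _discretize(x, n_bins)
    iy, ny = _discretize(y, n_bins)
    if nx == 1 or ny == 1:
        return 0.0
    return _mi_from_codes(ix, nx, iy, ny)


def _pairwise_binary_mi(X: np.ndarray) -> np.ndarray:
    """All-pairs MI for a 0/1 matrix via joint-count matrix products."""
    X = X.astype(float)
    n = X.shape[1]
    n11 = X @ X.T
    rs = X.sum(axis=1)
    n10 = rs[:, None] - n11
    n01 = rs[None, :] - n11
    n00 = n - n11 - n10 - n01
    mi = np.zeros_like(n11)
    p1 = rs / n
    p0 = 1.0 - p1
    for cnt, pa, pb in (
        (n11, p1[:, None], p1[None, :]),
        (n10, p1[:, None], p0[None, :]),
        (n01, p0[:, None], p1[None, :]),
        (n00, p0[:, None], p0[None, :]),
    ):
        p = cnt / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * np.log(p / (pa * pb))
        mi += np.where(p > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def profile_scores(pm: ProfileMatrix, n_bins: int = 4, dataset_id: str | None = None) -> ScoredPairTable:
    """Score every gene pair by the MI of their profile rows.

    Pairs with zero MI (including genes with constant, e.g. all-zero,
    profiles) are dropped: they carry no co-occurrence signal.
    """
    if len(pm.genes) < 2:
        raise DataError("profile scoring needs >= 2 genes")
    if len(pm.columns) < 2:
        raise DataError("profile scoring needs >= 2 columns (MI degenerate otherwise)")
    rows: dict[GenePair, float] = {}
    is_binary = np.isin(pm.values, (0.0, 1.0)).all()
    if is_binary:
        mi = _pairwise_binary_mi(pm.values)
        idx = np.triu_indices(len(pm.genes), k=1)
        for i, j in zip(*idx):
            if mi[i, j] > 0:
                rows[gene_pair(pm.genes[i], pm.genes[j])] = float(mi[i, j])
    else:
        codes = [_discretize(pm.values[i], n_bins) for i in range(len(pm.genes))]
        for i, j in itertools.combinations(range(len(pm.genes)), 2):
            (ix, nx), (iy, ny) = codes[i], codes[j]
            if nx == 1 or ny == 1:
                continue
            s = _mi_from_codes(ix, nx, iy, ny)
            if s > 0:
                rows[gene_pair(pm.genes[i], pm.genes[j])] = s
    return ScoredPairTable(dataset_id=dataset_id or "profile_mi", rows=rows)


def phylo_profile_scores(pm: ProfileMatrix, n_bins: int = 4) -> ScoredPairTable:
    """MI scores on a phylogenetic profile matrix (entries in [0, 1])."""
    if np.any(pm.values > 1.0):
        raise DataError("phylogenetic profile entries must lie in [0, 1]")
    return profile_scores(pm, n_bins=n_bins, dataset_id="phylo_profile")


def domain_profiles(domain_ann: AnnotationSet, universe_size: int) -> ProfileMatrix:
    """Inverse-frequency-weighted domain occurrence profiles.

    Entry (gene, domain) is ``1 / freq(domain)`` when the gene carries
    the domain and 0 otherwise, with ``freq = n_carriers /
    universe_size``; rare domains thus receive large weights.
    """
    if universe_size < 1:
        raise DataError("universe_size must be >= 1")
    domains = sorted(d for d, genes in domain_ann.terms.items() if genes)
    genes = sorted(domain_ann.universe)
    values = np.zeros((len(genes), len(domains)))
    gidx = {g: i for i, g in enumerate(genes)}
    for j, d in enumerate(domains):
        carriers = domain_ann.terms[d]
        if len(carriers) > universe_size:
            raise DataError(f"domain {d!r} annotates more genes than the universe")
        weight = universe_size / len(carriers)
        for g in carriers:
            values[gidx[g], j] = weight
    return ProfileMatrix(genes=genes, columns=domains, values=values)


def domain_cooccurrence_scores(
    domain_ann: AnnotationSet, universe_size: int, n_bins: int = 4
) -> ScoredPairTable:
    """Weighted domain profiles followed by pairwise MI scoring."""
    pm = domain_profiles(domain_ann, universe_size)
    spt = profile_scores(pm, n_bins=n_bins, dataset_id="domain_cooccurrence")
    return spt


# ---------------------------------------------------------------------------
# gene neighborhood
# ---------------------------------------------------------------------------


def neighborhood_distance_scores(
    orders: GeneOrderTable, min_genomes: int = 2
) -> ScoredPairTable:
    """Physical-distance neighborhood score averaged over genomes.

    For each genome containing both genes, the contribution is
    ``1 / (1 + |delta|)`` when they share a contig (delta = position
    difference) and 0 otherwise; the score is the mean over those
    genomes.  Pairs co-occurring in fewer than ``min_genomes`` genomes
    are omitted.
    """
    genomes = orders.by_genome()
    if len(genomes) < 2:
        raise DataError("neighborhood scoring needs >= 2 genomes")
    contrib: dict[GenePair, list[float]] = {}
    for placement in genomes.values():
        genes = sorted(placement)
        for a, b in itertools.combinations(genes, 2):
            ca, pa = placement[a]
            cb, pb = placement[b]
            val = 1.0 / (1.0 + abs(pa - pb)) if ca == cb else 0.0
            contrib.setdefault(gene_pair(a, b), []).append(val)
    rows = {
        pair: float(np.mean(vals))
        for pair, vals in contrib.items()
        if len(vals) >= min_genomes and sum(vals) > 0
    }
    return ScoredPairTable(dataset_id="neighborhood_distance", rows=rows)


def _tail_at_least(qs: list[float], k: int) -> float:
    """P(X >= k) for X a sum of independent Bernoulli(q_g) variables."""
    probs = np.zeros(len(qs) + 1)
    probs[0] = 1.0
    for q in qs:
        probs[1:] = probs[1:] * (1 - q) + probs[:-1] * q
        probs[0] *= 1 - q
    return float(probs[k:].sum())


def neighborhood_probability_scores(
    orders: GeneOrderTable, window: int = 1
) -> ScoredPairTable:
    """Probability-based neighborhood score.

    For a pair observed within ``window`` positions on a shared contig in
    k of the m genomes containing both genes, the score is ``-ln P`` with
    P the tail probability of seeing >= k proximities under independent
    uniform placement.  The per-genome proximity chance is
    ``q = min(1, 2*window / (L - 1))`` for a contig of L genes; the tail
    over genomes with unequal contig sizes is the exact Poisson-binomial
    tail (which reduces to the binomial tail when all q are equal).
    Pairs never observed in proximity score 0 and are dropped.
    """
    if window < 1:
        raise DataError("window must be >= 1")
    genomes = orders.by_genome()
    sizes = orders.contig_sizes()
    obs: dict[GenePair, tuple[int, list[float]]] = {}
    for genome, placement in genomes.items():
        genes = sorted(placement)
        for a, b in itertools.combinations(genes, 2):
            ca, pa = placement[a]
            cb, pb = placement[b]
            L = sizes[(genome, ca)]
            q = min(1.0, 2.0 * window / max(L - 1, 1))
            within = ca == cb and abs(pa - pb) <= window
            k, qs = obs.get(gene_pair(a, b), (0, []))
            obs[gene_pair(a, b)] = (k + int(within), qs + [q])
    rows: dict[GenePair, float] = {}
    for pair, (k, qs) in obs.items():
        if k == 0:
            continue
        p = _tail_at_least(qs, k)
        score = -math.log(max(p, 1e-300))
        if score > 0:
            rows[pair] = score
    return ScoredPairTable(dataset_id="neighborhood_probability", rows=rows)


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------


def coexpression_scores(
    em: ExpressionMatrix, min_samples: int = 12, conf: float = 0.99
) -> ScoredPairTable:
    """Pearson correlations filtered at the given confidence level.

    Datasets with fewer than ``min_samples`` samples are rejected
    outright (correlations from few samples are promiscuous).  For each
    gene pair the two-sided t-test ``t = r * sqrt((n-2) / (1-r^2))`` with
    ``n - 2`` degrees of freedom must reach ``p < 1 - conf`` for the pair
    to be retained; genes with constant expression are skipped.
    """
    n = em.n_samples
    if n < min_samples:
        raise DataError(
            f"dataset rejected: {n} samples < required minimum of {min_samples}"
        )
    if not 0 < conf < 1:
        raise DataError("conf must be in (0, 1)")
    std = em.values.std(axis=1)
    keep = std > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("skipping %d constant-expression genes", n_dropped)
    genes = [g for g, k in zip(em.genes, keep) if k]
    if len(genes) < 2:
        raise DataError("fewer than 2 non-constant genes in expression matrix")
    vals = em.values[keep]
    r = np.corrcoef(vals)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    alpha = 1.0 - conf
    rows: dict[GenePair, float] = {}
    iu = np.triu_indices(len(genes), k=1)
    for i, j in zip(*iu):
        if pvals[i, j] < alpha:
            rows[gene_pair(genes[i], genes[j])] = float(r[i, j])
    return ScoredPairTable(dataset_id="coexpression", rows=rows)
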