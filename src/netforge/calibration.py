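"""Bayesian log-likelihood score (LLS) calibration of evidence datasets.

Each evidence dataset ranks gene pairs by its own intrinsic score
(mutual information, correlation, proximity...).  Calibration converts
those heterogeneous scores to a common currency: the log-likelihood
score

    LLS = ln[ (P(I|D) / P(~I|D)) / (P(I) / P(~I)) ]

where P(I|D) and P(~I|D) are the frequencies of gold-standard positive
and negative pairs observed in a score bin of dataset D, and P(I)/P(~I)
is the prior odds over the whole gold standard.  Ranked gold-overlapping
pairs are split into equal-count bins, per-bin LLS values are computed
(optionally with 0.632 bootstrap smoothing), and a monotone regression
of LLS on the bin mean scores maps every pair's intrinsic score to a
continuous LLS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .datamodel import ComponentNetwork, DataError, GenePair, ScoredPairTable
from .gold import GoldStandard

logger = logging.getLogger("netforge")


def lls(n_pos_D: int, n_neg_D: int, n_pos_all: int, n_neg_all: int) -> float:
    """Log-likelihood score of a dataset cell against the gold prior.

    A Haldane pseudocount of 0.5 is added to the dataset cell counts so
    degenerate bins (zero positives or zero negatives) stay finite.
    """
    if n_pos_all <= 0 or n_neg_all <= 0:
        raise DataError("gold standard must contain positives and negatives")
    if n_pos_D < 0 or n_neg_D < 0:
        raise DataError("negative counts")
    if n_pos_D == 0 and n_neg_D == 0:
        raise DataError("empty bin: no gold pairs observed in dataset cell")
    return math.log(
        ((n_pos_D + 0.5) / (n_neg_D + 0.5)) / (n_pos_all / n_neg_all)
    )


@dataclass
class BinStat:
    mean_score: float
    lls: float
    n_pos: int
    n_neg: int


@dataclass
class LLSModel:
    """Binned LLS estimates plus a monotone score -> LLS mapping."""

    dataset_id: str
    bins: list[BinStat]
    prior_odds: float
    _kind: str = field(default="isotonic", repr=False)
    _iso: IsotonicRegression | None = field(default=None, repr=False)
    _coeffs: tuple[float, float] | None = field(default=None, repr=False)

    def predict(self, scores) -> np.ndarray:
        """Map intrinsic scores to LLS through the fitted regression."""
        scores = np.asarray(scores, dtype=float)
        if self._kind == "isotonic":
            assert self._iso is not None
            return self._iso.predict(scores)
        if self._kind == "linear":
            a, b = self._coeffs  # type: ignore[misc]
            return a * scores + b
        return np.full(scores.shape, self.bins[0].lls)


def _overlap_records(
    spt: ScoredPairTable, gold: GoldStandard
) -> list[tuple[GenePair, float, bool]]:
    """Gold-overlapping (pair, score, is_positive), ranked by descending
    score with ties broken by canonical pair order."""
    recs = []
    for pair, score in spt.rows.items():
        if pair in gold.positives:
            recs.append((pair, score, True))
        elif pair in gold.negatives:
            recs.append((pair, score, False))
    recs.sort(key=lambda r: (-r[1], r[0]))
    return recs


def _bin_slices(n: int, bin_size: int) -> list[slice]:
    slices = [slice(i, min(i + bin_size, n)) for i in range(0, n, bin_size)]
    return slices


def _fit_mapping(model: LLSModel) -> LLSModel:
    """Fit the monotone score->LLS regression on the bin summaries.

    Isotonic regression is used with >= 5 bins; with fewer bins an
    ordinary linear fit of LLS on mean score is more stable.
    """
    xs = np.array([b.mean_score for b in model.bins])
    ys = np.array([b.lls for b in model.bins])
    if len(model.bins) >= 5:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        iso.fit(xs, ys)
        model._kind = "isotonic"
        model._iso = iso
    elif len(model.bins) >= 2:
        a, b = np.polyfit(xs, ys, 1)
        model._kind = "linear"
        model._coeffs = (float(a), float(b))
    else:
        model._kind = "constant"
    return model


def _build_bins(
    recs: list[tuple[GenePair, float, bool]],
    gold: GoldStandard,
    bin_size: int,
    dataset_id: str,
) -> tuple[LLSModel, list[slice]]:
    n_pos_all = len(gold.positives)
    n_neg_all = len(gold.negatives)
    slices = _bin_slices(len(recs), bin_size)
    bins: list[BinStat] = []
    for sl in slices:
        chunk = recs[sl]
        n_pos = sum(1 for r in chunk if r[2])
        n_neg = len(chunk) - n_pos
        bins.append(
            BinStat(
                mean_score=float(np.mean([r[1] for r in chunk])),
                lls=lls(n_pos, n_neg, n_pos_all, n_neg_all),
                n_pos=n_pos,
                n_neg=n_neg,
            )
        )
    # ranked descending -> reverse so bins are ascending in mean score
    bins.reverse()
    slices.reverse()
    model = LLSModel(
        dataset_id=dataset_id,
        bins=bins,
        prior_odds=n_pos_all / n_neg_all,
    )
    return model, slices


def fit_lls_model(
    spt: ScoredPairTable, gold: GoldStandard, bin_size: int = 1000
) -> LLSModel:
    """Equal-count binning of ranked gold-overlapping pairs, then per-bin
    LLS and the monotone regression mapping."""
    if bin_size < 1:
        raise DataError("bin_size must be >= 1")
    recs = _overlap_records(spt, gold)
    if len(recs) < 2 * bin_size:
        raise DataError(
            f"insufficient gold overlap: {len(recs)} overlapping pairs "
            f"< 2 x bin_size ({2 * bin_size})"
        )
    model, _ = _build_bins(recs, gold, bin_size, spt.dataset_id)
    return _fit_mapping(model)


def bootstrap_lls_model(
    spt: ScoredPairTable,
    gold: GoldStandard,
    bin_size: int = 1000,
    B: int = 100,
    seed: int = 0,
) -> LLSModel:
    """0.632-bootstrap-smoothed LLS model.

    Bins are fixed on the full-sample ranking.  For each of B bootstrap
    resamples of the gold-overlapping pairs, per-bin LLS is estimated on
    the out-of-bag pairs of that bin; the final per-bin LLS combines the
    in-sample estimate and the mean out-of-bag estimate with weights
    0.368 / 0.632.  Resamples leaving a bin without out-of-bag gold
    pairs are skipped for that bin.
    """
    if B < 10:
        raise DataError("B must be >= 10")
    recs = _overlap_records(spt, gold)
    if len(recs) < 2 * bin_size:
        raise DataError(
            f"insufficient gold overlap: {len(recs)} overlapping pairs "
            f"< 2 x bin_size ({2 * bin_size})"
        )
    model, slices = _build_bins(recs, gold, bin_size, spt.dataset_id)
    n = len(recs)
    n_pos_all = len(gold.positives)
    n_neg_all = len(gold.negatives)
    labels = np.array([r[2] for r in recs])
    bin_of = np.empty(n, dtype=int)
    for b_idx, sl in enumerate(slices):
        bin_of[sl] = b_idx
    rng = np.random.default_rng(seed)
    sums = np.zeros(len(slices))
    counts = np.zeros(len(slices), dtype=int)
    n_bins = len(slices)
    for _ in range(B):
        sampled = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[sampled] = True
        oob = ~in_bag
        pos_oob = np.bincount(bin_of[oob & labels], minlength=n_bins)
        neg_oob = np.bincount(bin_of[oob & ~labels], minlength=n_bins)
        for b_idx in range(n_bins):
            p, q = int(pos_oob[b_idx]), int(neg_oob[b_idx])
            if p == 0 and q == 0:
                logger.debug("bin %d has no out-of-bag pairs; resample skipped", b_idx)
                continue
            sums[b_idx] += lls(p, q, n_pos_all, n_neg_all)
            counts[b_idx] += 1
    for b_idx, bstat in enumerate(model.bins):
        if counts[b_idx] > 0:
            oob_mean = sums[b_idx] / counts[b_idx]
            bstat.lls = 0.368 * bstat.lls + 0.632 * oob_mean
        else:
            logger.warning("bin %d never had out-of-bag pairs; in-sample LLS kept", b_idx)
    return _fit_mapping(model)


def apply_lls_model(
    model: LLSModel, spt: ScoredPairTable, min_lls: float = 0.0
) -> ComponentNetwork:
    """Map every scored pair through the model; keep edges with LLS >= min_lls."""
    pairs = sorted(spt.rows)
    scores = np.array([spt.rows[p] for p in pairs])
    mapped = model.predict(scores)
    edges = {p: float(v) for p, v in zip(pairs, mapped) if v >= min_lls}
    return ComponentNetwork(dataset_id=model.dataset_id, edges=edges)


@dataclass
class PRCurve:
    """Cumulative precision/recall at successive bins of ranked pairs."""

    points: list[tuple[float, float, int]]  # (recall, precision, cum_pairs)


def precision_recall(
    network, benchmark: GoldStandard, bin: int = 1000
) -> PRCurve:
    """Cumulative precision and recall over benchmark-overlapping edges.

    Edges are ranked by descending weight; after each successive bin of
    ``bin`` benchmark-overlapping edges (and at exhaustion), cumulative
    precision TP/(TP+FP) and recall TP/|positives| are recorded.
    """
    if not benchmark.positives:
        raise DataError("benchmark has no positive pairs")
    if hasattr(network, "ranked_edges"):
        ranked = network.ranked_edges()
    else:
        ranked = sorted(network, key=lambda kv: (-kv[1], kv[0]))
    tp = 0
    seen = 0
    points: list[tuple[float, float, int]] = []
    n_pos = len(benchmark.positives)
    for pair, _w in ranked:
        if pair in benchmark.positives:
            tp += 1
        elif pair in benchmark.negatives:
            pass
        else:
            continue
        seen += 1
        if seen % bin == 0:
            points.append((tp / n_pos, tp / seen, seen))
    if seen == 0:
        raise DataError("network has no overlap with the benchmark")
    if seen % bin != 0:
        points.append((tp / n_pos, tp / seen, seen))
    return PRCurve(points=points)


def lls_vs_pairs_area(network, gold: GoldStandard, bin: int = 1000) -> float:
    """Area under the cumulative-LLS versus cumulative-pairs curve.

    Edges are ranked by weight; after each bin of gold-overlapping
    edges the LLS of the cumulative gold counts is computed, and the
    trapezoidal area under (cum_pairs, cum_LLS) summarizes how much
    high-scoring, high-likelihood linkage the network exposes.
    """
    if hasattr(network, "ranked_edges"):
        ranked = network.ranked_edges()
    else:
        ranked = sorted(network, key=lambda kv: (-kv[1], kv[0]))
    n_pos_all = len(gold.positives)
    n_neg_all = len(gold.negatives)
    if n_pos_all == 0 or n_neg_all == 0:
        raise DataError("gold standard must contain positives and negatives")
    tp = 0
    fp = 0
    xs: list[float] = []
    ys: list[float] = []
    seen = 0
    for pair, _w in ranked:
        if pair in gold.positives:
            tp += 1
        elif pair in gold.negatives:
            fp += 1
        else:
            continue
        seen += 1
        if seen % bin == 0:
            xs.append(seen)
            ys.append(lls(tp, fp, n_pos_all, n_neg_all))
    if seen == 0:
        raise DataError("network has no overlap with the gold standard")
    if seen % bin != 0:
        xs.append(seen)
        ys.append(lls(tp, fp, n_pos_all, n_neg_all))
    if len(xs) == 1:
        return float(xs[0] * ys[0])
    return float(np.trapezoid(ys, xs))
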