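"""LLS formula, binning/regression calibration, bootstrap, PR curves."""

import math

import numpy as np
import pytest

from netforge import (
    DataError,
    GoldStandard,
    ScoredPairTable,
    apply_lls_model,
    bootstrap_lls_model,
    fit_lls_model,
    lls,
    precision_recall,
)
from netforge.calibration import lls_vs_pairs_area


def _gold_and_scores(n_pos, n_neg, seed, score_fn):
    """Synthetic gold standard plus a scored table over the same pairs."""
    rng = np.random.default_rng(seed)
    positives = {(f"p{i:05d}a", f"p{i:05d}b") for i in range(n_pos)}
    negatives = {(f"n{i:05d}a", f"n{i:05d}b") for i in range(n_neg)}
    rows = {}
    for pair in positives:
        rows[pair] = score_fn(True, rng)
    for pair in negatives:
        rows[pair] = score_fn(False, rng)
    return GoldStandard(positives=positives, negatives=negatives), ScoredPairTable(
        dataset_id="synthetic", rows=rows
    )


class TestLLSFormula:
    def test_enriched_cell_example(self):
        # pseudocounts cancel in the balanced cell: ln(20.5/20.5 * 900/100)
        assert lls(20, 20, 100, 900) == pytest.approx(math.log(9), abs=1e-12)

    def test_cell_matching_prior_scores_zero_without_pseudocount_shift(self):
        # dataset odds equal to the prior 1:9 up to the pseudocount
        value = lls(10, 90, 100, 900)
        expected = math.log((10.5 / 90.5) * 9)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_zero_positive_cell_is_finite_negative(self):
        value = lls(0, 40, 100, 900)
        assert math.isfinite(value) and value < 0

    def test_empty_cell_is_an_error(self):
        with pytest.raises(DataError):
            lls(0, 0, 100, 900)

    def test_pseudocount_perturbation_bound(self):
        """With all counts >= 5 the value stays within ln((n+0.5)/n) per
        cell of the pseudocount-free closed form."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b = rng.integers(5, 200, size=2)
            A, B = rng.integers(500, 2000, size=2)
            exact = math.log((a / b) / (A / B))
            bound = math.log((a + 0.5) / a) + math.log((b + 0.5) / b)
            assert abs(lls(a, b, A, B) - exact) <= bound + 1e-12


class TestFitModel:
    def test_separating_scores_give_strictly_decreasing_bin_lls(self):
        # perfect separation, 3 bins: pure-pos / mixed / pure-neg
        gold, spt = _gold_and_scores(
            1500, 1500, seed=0,
            score_fn=lambda pos, rng: rng.uniform(10, 20) if pos else rng.uniform(0, 9),
        )
        model = fit_lls_model(spt, gold, bin_size=1000)
        values = [b.lls for b in model.bins]  # ascending mean score
        assert values == sorted(values)
        assert len(set(values)) == len(values)

    def test_label_free_scores_give_near_zero_bins(self):
        gold, spt = _gold_and_scores(
            2000, 2000, seed=1, score_fn=lambda pos, rng: rng.uniform()
        )
        model = fit_lls_model(spt, gold, bin_size=1000)
        assert max(abs(b.lls) for b in model.bins) < 0.3

    def test_bins_match_brute_force_binning_oracle(self):
        gold, spt = _gold_and_scores(
            2500, 2500, seed=2, score_fn=lambda pos, rng: rng.normal(1 if pos else 0)
        )
        bin_size = 500
        model = fit_lls_model(spt, gold, bin_size=bin_size)
        # independent re-implementation: sort, chunk, count
        recs = sorted(
            ((p, s, p in gold.positives) for p, s in spt.rows.items()),
            key=lambda r: (-r[1], r[0]),
        )
        chunks = [recs[i : i + bin_size] for i in range(0, len(recs), bin_size)]
        chunks.reverse()
        assert len(model.bins) == len(chunks)
        for b, chunk in zip(model.bins, chunks):
            n_pos = sum(1 for r in chunk if r[2])
            assert (b.n_pos, b.n_neg) == (n_pos, len(chunk) - n_pos)
            assert b.mean_score == pytest.approx(np.mean([r[1] for r in chunk]))
            expected = math.log(
                ((n_pos + 0.5) / (len(chunk) - n_pos + 0.5))
                / (len(gold.positives) / len(gold.negatives))
            )
            assert b.lls == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_of_scores_preserves_bin_lls(self):
        gold, spt = _gold_and_scores(
            1500, 1500, seed=3, score_fn=lambda pos, rng: rng.normal(1 if pos else 0)
        )
        model_a = fit_lls_model(spt, gold, bin_size=500)
        transformed = ScoredPairTable(
            dataset_id=spt.dataset_id,
            rows={p: math.exp(s) for p, s in spt.rows.items()},
        )
        model_b = fit_lls_model(transformed, gold, bin_size=500)
        assert [b.lls for b in model_a.bins] == pytest.approx(
            [b.lls for b in model_b.bins], abs=1e-12
        )

    def test_insufficient_overlap_error_names_counts(self):
        gold, spt = _gold_and_scores(10, 10, seed=4, score_fn=lambda pos, rng: rng.uniform())
        with pytest.raises(DataError, match="20 overlapping"):
            fit_lls_model(spt, gold, bin_size=1000)


class TestBootstrap:
    def test_same_seed_gives_identical_model(self):
        gold, spt = _gold_and_scores(
            1000, 1000, seed=5, score_fn=lambda pos, rng: rng.normal(1 if pos else 0)
        )
        m1 = bootstrap_lls_model(spt, gold, bin_size=400, B=25, seed=9)
        m2 = bootstrap_lls_model(spt, gold, bin_size=400, B=25, seed=9)
        assert [b.lls for b in m1.bins] == [b.lls for b in m2.bins]

    def test_bootstrap_close_to_in_sample_on_informative_fixture(self):
        gold, spt = _gold_and_scores(
            2000, 2000, seed=6, score_fn=lambda pos, rng: rng.normal(2 if pos else 0)
        )
        plain = fit_lls_model(spt, gold, bin_size=1000)
        boot = bootstrap_lls_model(spt, gold, bin_size=1000, B=50, seed=1)
        for b_plain, b_boot in zip(plain.bins, boot.bins):
            assert b_boot.lls == pytest.approx(b_plain.lls, abs=0.1 * max(1.0, abs(b_plain.lls)))

    def test_label_free_bootstrap_is_near_zero_for_small_and_large_B(self):
        gold, spt = _gold_and_scores(
            1500, 1500, seed=7, score_fn=lambda pos, rng: rng.uniform()
        )
        for B in (10, 100):
            model = bootstrap_lls_model(spt, gold, bin_size=1500, B=B, seed=2)
            assert max(abs(b.lls) for b in model.bins) < 0.15

    def test_small_B_rejected(self):
        gold, spt = _gold_and_scores(100, 100, seed=8, score_fn=lambda pos, rng: rng.uniform())
        with pytest.raises(DataError):
            bootstrap_lls_model(spt, gold, bin_size=50, B=5)


class TestApplyModel:
    def test_monotone_scores_map_to_monotone_lls(self):
        gold, spt = _gold_and_scores(
            2500, 2500, seed=9, score_fn=lambda pos, rng: rng.normal(1 if pos else 0)
        )
        model = fit_lls_model(spt, gold, bin_size=500)
        scores = np.linspace(-3, 4, 50)
        mapped = model.predict(scores)
        assert all(mapped[i] <= mapped[i + 1] + 1e-12 for i in range(len(mapped) - 1))

    def test_bin_mean_maps_to_fitted_bin_lls(self):
        gold, spt = _gold_and_scores(
            1500, 1500, seed=0,
            score_fn=lambda pos, rng: rng.uniform(10, 20) if pos else rng.uniform(0, 9),
        )
        model = fit_lls_model(spt, gold, bin_size=500)  # 6 bins -> isotonic
        fitted = model.predict([b.mean_score for b in model.bins])
        iso_values = model.predict([b.mean_score for b in model.bins])
        assert fitted == pytest.approx(iso_values)

    def test_threshold_above_max_gives_empty_network(self):
        gold, spt = _gold_and_scores(
            500, 500, seed=1, score_fn=lambda pos, rng: rng.normal(1 if pos else 0)
        )
        model = fit_lls_model(spt, gold, bin_size=250)
        net = apply_lls_model(model, spt, min_lls=1e9)
        assert len(net) == 0


class TestPrecisionRecall:
    def test_all_top_edges_positive_gives_first_point_precision_one(self):
        gold = GoldStandard(
            positives={(f"p{i}", f"q{i}") for i in range(10)},
            negatives={(f"u{i}", f"v{i}") for i in range(10)},
        )
        edges = {p: 10.0 - i for i, p in enumerate(sorted(gold.positives))}
        edges.update({p: -float(i) for i, p in enumerate(sorted(gold.negatives))})
        curve = precision_recall(list(edges.items()), gold, bin=5)
        assert curve.points[0][1] == 1.0

    def test_random_ranking_precision_near_base_rate(self):
        rng = np.random.default_rng(12)
        gold = GoldStandard(
            positives={(f"p{i:04d}", f"q{i:04d}") for i in range(500)},
            negatives={(f"u{i:04d}", f"v{i:04d}") for i in range(1500)},
        )
        edges = {p: float(rng.uniform()) for p in gold.positives | gold.negatives}
        curve = precision_recall(list(edges.items()), gold, bin=1000)
        final = curve.points[-1]
        assert final[1] == pytest.approx(0.25, abs=0.05)

    def test_final_recall_is_fraction_of_positives_present(self):
        gold = GoldStandard(
            positives={("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")},
            negatives={("i", "j")},
        )
        edges = {("a", "b"): 2.0, ("c", "d"): 1.0, ("i", "j"): 0.5}
        curve = precision_recall(list(edges.items()), gold, bin=1)
        assert curve.points[-1][0] == pytest.approx(2 / 4)

    def test_no_overlap_is_an_error(self):
        gold = GoldStandard(positives={("a", "b")}, negatives={("c", "d")})
        with pytest.raises(DataError):
            precision_recall([(("x", "y"), 1.0)], gold, bin=1)


def test_lls_vs_pairs_area_matches_hand_trapezoid():
    gold = GoldStandard(
        positives={(f"p{i}", f"q{i}") for i in range(6)},
        negatives={(f"u{i}", f"v{i}") for i in range(6)},
    )
    # ranking: 4 positives, then 4 negatives, then 2+2 interleaved
    ranked = (
        [(p, 12.0 - i) for i, p in enumerate(sorted(gold.positives)[:4])]
        + [(p, 8.0 - i) for i, p in enumerate(sorted(gold.negatives)[:4])]
        + [(p, 4.0 - i) for i, p in enumerate(sorted(gold.positives)[4:])]
        + [(p, 2.0 - i) for i, p in enumerate(sorted(gold.negatives)[4:])]
    )
    area = lls_vs_pairs_area(ranked, gold, bin=4)
    def cell(tp, fp):
        return math.log(((tp + 0.5) / (fp + 0.5)) / 1.0)
    y = [cell(4, 0), cell(4, 4), cell(6, 6)]
    x = [4, 8, 12]
    hand = 0.5 * (y[0] + y[1]) * (x[1] - x[0]) + 0.5 * (y[1] + y[2]) * (x[2] - x[1])
    assert area == pytest.approx(hand, abs=1e-12)
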