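"""Evidence scoring: MI, profiles, neighborhood statistics, co-expression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netforge import (
    AnnotationSet,
    DataError,
    ExpressionMatrix,
    GeneOrderTable,
    ProfileMatrix,
    coexpression_scores,
    domain_profiles,
    mutual_information,
    neighborhood_distance_scores,
    neighborhood_probability_scores,
    phylo_profile_scores,
)
from netforge.evidence import OrderRow, domain_cooccurrence_scores, profile_scores


class TestMutualInformation:
    def test_identical_binary_vectors_give_ln2(self):
        x = [0, 0, 1, 1]
        assert mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_binary_vectors_give_zero(self):
        assert mutual_information([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_constant_vector_gives_zero_not_error(self):
        assert mutual_information([2.0] * 6, [0, 1, 2, 3, 4, 5]) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12
        )

    def test_rejects_mismatched_or_tiny_inputs(self):
        with pytest.raises(DataError):
            mutual_information([1.0], [2.0])
        with pytest.raises(DataError):
            mutual_information([1, 2, 3], [1, 2])


class TestProfileScores:
    def test_identical_nonconstant_profiles_score_their_entropy(self):
        profile = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        pm = ProfileMatrix(genes=["a", "b"], columns=[f"s{i}" for i in range(6)],
                           values=np.vstack([profile, profile]))
        out = phylo_profile_scores(pm)
        p1 = profile.mean()
        entropy = -(p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
        assert out.rows[("a", "b")] == pytest.approx(entropy, abs=1e-12)

    def test_all_zero_profile_pairs_are_dropped(self):
        pm = ProfileMatrix(
            genes=["a", "b"],
            columns=["s1", "s2", "s3"],
            values=np.array([[0, 0, 0], [1, 0, 1]], dtype=float),
        )
        assert len(phylo_profile_scores(pm)) == 0

    def test_pair_count_bounded_by_combinations(self):
        rng = np.random.default_rng(0)
        pm = ProfileMatrix(genes=["a", "b", "c"], columns=[f"s{i}" for i in range(8)],
                           values=rng.integers(0, 2, (3, 8)).astype(float))
        assert len(phylo_profile_scores(pm)) <= 3

    def test_single_column_matrix_is_degenerate(self):
        pm = ProfileMatrix(genes=["a", "b"], columns=["s"], values=np.ones((2, 1)))
        with pytest.raises(DataError):
            phylo_profile_scores(pm)

    def test_binary_fast_path_matches_generic_mi(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, (6, 12)).astype(float)
        pm = ProfileMatrix(genes=[f"g{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(12)], values=vals)
        out = profile_scores(pm)
        for (a, b), s in out.rows.items():
            i, j = int(a[1:]), int(b[1:])
            assert s == pytest.approx(mutual_information(vals[i], vals[j]), abs=1e-12)


class TestDomainProfiles:
    def test_rare_domain_gets_large_weight(self):
        ann = AnnotationSet(terms={"D1": frozenset({"g1"})})
        pm = domain_profiles(ann, universe_size=100)
        assert pm.values.max() == pytest.approx(100.0)

    def test_universal_domain_gets_weight_one(self):
        ann = AnnotationSet(terms={"D1": frozenset({"g1", "g2"})})
        pm = domain_profiles(ann, universe_size=2)
        assert set(pm.values.ravel()) == {1.0}

    def test_weights_monotone_in_rarity(self):
        ann = AnnotationSet(terms={
            "Drare": frozenset({"g1", "g2"}),
            "Dcommon": frozenset({"g1", "g2", "g3", "g4"}),
        })
        pm = domain_profiles(ann, universe_size=10)
        w = {c: pm.values[:, j].max() for j, c in enumerate(pm.columns)}
        assert w["Drare"] > w["Dcommon"]

    def test_shared_rare_domain_scores_pairs(self):
        ann = AnnotationSet(terms={
            "Drare": frozenset({"g1", "g2"}),
            "D2": frozenset({"g3", "g4"}),
            "Dcommon": frozenset({"g1", "g3"}),
        })
        out = domain_cooccurrence_scores(ann, universe_size=4)
        assert ("g1", "g2") in out.rows


def _orders(rows):
    return GeneOrderTable(rows=[OrderRow(*r) for r in rows])


class TestNeighborhoodDistance:
    def test_adjacent_in_every_genome_scores_half(self):
        t = _orders([
            ("g1", "a", "c1", 0), ("g1", "b", "c1", 1),
            ("g2", "a", "c1", 5), ("g2", "b", "c1", 6),
        ])
        out = neighborhood_distance_scores(t)
        assert out.rows[("a", "b")] == pytest.approx(0.5)

    def test_split_contig_genome_halves_the_score(self):
        t = _orders([
            ("g1", "a", "c1", 0), ("g1", "b", "c1", 1),
            ("g2", "a", "c1", 0), ("g2", "b", "c2", 0),
        ])
        out = neighborhood_distance_scores(t)
        assert out.rows[("a", "b")] == pytest.approx(0.25)

    def test_pair_below_min_genomes_is_omitted(self):
        t = _orders([
            ("g1", "a", "c1", 0), ("g1", "b", "c1", 1),
            ("g2", "a", "c1", 0), ("g2", "c", "c1", 1),
        ])
        out = neighborhood_distance_scores(t, min_genomes=2)
        assert ("a", "b") not in out.rows

    def test_duplicate_position_rejected(self):
        with pytest.raises(DataError):
            _orders([("g1", "a", "c1", 0), ("g1", "b", "c1", 0)])


class TestNeighborhoodProbability:
    def test_single_genome_adjacent_pair_matches_binomial_tail(self):
        # contig of 11 genes, window 1: q = 2/10 = 0.2, score = -ln 0.2
        rows = [("g1", f"x{i}", "c1", i) for i in range(11)]
        out = neighborhood_probability_scores(_orders(rows), window=1)
        assert out.rows[("x0", "x1")] == pytest.approx(-math.log(0.2), abs=1e-12)

    def test_never_proximal_pairs_are_dropped(self):
        rows = [("g1", "a", "c1", 0), ("g1", "b", "c1", 5),
                ("g1", "x", "c1", 1), ("g1", "y", "c1", 2),
                ("g1", "z", "c1", 3), ("g1", "w", "c1", 4)]
        out = neighborhood_probability_scores(_orders(rows), window=1)
        assert ("a", "b") not in out.rows

    def test_score_non_decreasing_in_observed_proximity_count(self):
        # same pair proximal in k of 3 identical genomes
        def table(k):
            rows = []
            for gi in range(3):
                if gi < k:
                    rows += [(f"g{gi}", "a", "c1", 0), (f"g{gi}", "b", "c1", 1)]
                else:
                    rows += [(f"g{gi}", "a", "c1", 0), (f"g{gi}", "b", "c1", 5)]
                rows += [(f"g{gi}", f"f{i}", "c1", i + 10) for i in range(9)]
            return _orders(rows)

        scores = []
        for k in (1, 2, 3):
            out = neighborhood_probability_scores(table(k), window=1)
            scores.append(out.rows[("a", "b")])
        assert scores == sorted(scores)


class TestCoexpression:
    def _matrix(self, values, n_samples=None):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            genes=[f"g{i}" for i in range(values.shape[0])],
            samples=[f"s{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_perfect_linear_relation_retained_with_pcc_one(self):
        x = np.arange(12, dtype=float)
        em = self._matrix(np.vstack([x, 2 * x + 1]))
        out = coexpression_scores(em)
        assert out.rows[("g0", "g1")] == pytest.approx(1.0)

    def test_uncorrelated_noise_filtered_by_t_test(self):
        rng = np.random.default_rng(5)
        em = self._matrix(rng.standard_normal((2, 20)))
        from scipy import stats
        r = np.corrcoef(em.values)[0, 1]
        t = r * math.sqrt(18 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 18)
        out = coexpression_scores(em, min_samples=12, conf=0.99)
        assert (("g0", "g1") in out.rows) == (p < 0.01)

    def test_dataset_with_too_few_samples_rejected(self):
        em = self._matrix(np.random.default_rng(0).standard_normal((3, 11)))
        with pytest.raises(DataError, match="rejected"):
            coexpression_scores(em)

    def test_constant_genes_skipped(self):
        x = np.arange(12, dtype=float)
        em = self._matrix(np.vstack([x, x * 3, np.zeros(12)]))
        out = coexpression_scores(em)
        assert set(out.genes()) <= {"g0", "g1"}
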