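"""F84 distance engine: closed form vs independent oracles, matrix ops."""

import itertools

import numpy as np
import pytest
from scipy.optimize import brentq, minimize

from diplopop.genotype import (
    F84Params,
    combine_markers_euclidean,
    empirical_base_frequencies,
    f84_distance,
    f84_from_proportions,
    pairwise_distance_matrix,
    population_mean_distances,
)
from diplopop.model import AlignedMarkerSet, DistanceMatrix, PopulationMap

UNIFORM = np.array([0.25] * 4)

# ---------------------------------------------------------------- oracles


def _f84_transition_matrix(a, b, freqs):
    """F84 substitution probabilities over unit time.

    Two Poisson event classes: rate-b events draw any base from the
    stationary frequencies; rate-a events draw a base within the original
    purine/pyrimidine group, proportionally to its frequency in the group.
    """
    pa, pc, pg, pt = freqs
    gfreq = [pa + pg, pc + pt]
    group = [0, 1, 0, 1]
    P = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            val = (1 - np.exp(-b)) * freqs[j]
            if group[i] == group[j]:
                val += np.exp(-b) * (1 - np.exp(-a)) * freqs[j] / gfreq[group[i]]
            if i == j:
                val += np.exp(-(a + b))
            P[i, j] = val
    return P


def _expected_subs(a, b, freqs):
    pa, pc, pg, pt = freqs
    gf = [pa + pg, pc + pt, pa + pg, pc + pt]
    return sum(f * (b * (1 - f) + a * (1 - f / g)) for f, g in zip(freqs, gf))


def ml_f84_oracle(seq_a, seq_b, freqs):
    """Numeric maximum-likelihood F84 distance for an unambiguous pair."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pairs = [(idx[x], idx[y]) for x, y in zip(seq_a, seq_b)]

    def nll(theta):
        a, b = np.exp(theta)
        P = _f84_transition_matrix(a, b, freqs)
        return -sum(np.log(freqs[i] * P[i, j]) for i, j in pairs)

    best = None
    for x0 in [(-3, -3), (-1, -4), (-4, -1)]:
        r = minimize(nll, x0, method="Nelder-Mead",
                     options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 40000})
        if best is None or r.fun < best.fun:
            best = r
    a, b = np.exp(best.x)
    return _expected_subs(a, b, freqs)


def moment_inversion_oracle(p_obs, q_obs, freqs):
    """Invert the expected transition/transversion proportions numerically.

    Transversions arise only from whole-pool substitution events, so the
    expected transversion proportion depends on b alone and can be solved
    first; a is then bracketed from the expected transition proportion.
    """
    group = [0, 1, 0, 1]

    def expected_pq(a, b):
        P = _f84_transition_matrix(a, b, freqs)
        pexp = qexp = 0.0
        for i, j in itertools.product(range(4), repeat=2):
            if i == j:
                continue
            m = freqs[i] * P[i, j]
            if group[i] == group[j]:
                pexp += m
            else:
                qexp += m
        return pexp, qexp

    b = brentq(lambda bb: expected_pq(0.0, bb)[1] - q_obs, 1e-12, 60.0,
               xtol=1e-15)
    # a may be algebraically negative when transversions dominate
    a = brentq(lambda aa: expected_pq(aa, b)[0] - p_obs, -50.0, 60.0,
               xtol=1e-15)
    return _expected_subs(a, b, freqs)


# ----------------------------------------------------------------- tests


class TestF84Distance:
    def test_identical_sequences_zero(self):
        assert f84_distance("ACGTACGT", "ACGTACGT",
                            F84Params(base_frequencies=UNIFORM)) == 0.0

    def test_matches_numeric_ml_oracle_uniform(self):
        # 2 transitions + 1 transversion over 100 sites
        seq_a = "A" * 100
        seq_b = "G" * 2 + "T" + "A" * 97
        d = f84_distance(seq_a, seq_b, F84Params(base_frequencies=UNIFORM))
        assert d == pytest.approx(ml_f84_oracle(seq_a, seq_b, UNIFORM), abs=1e-6)

    def test_matches_moment_inversion_unequal_frequencies(self):
        freqs = np.array([0.35, 0.15, 0.2, 0.3])
        for p_obs, q_obs in [(0.03, 0.03), (0.1, 0.02), (0.01, 0.08)]:
            d = f84_from_proportions(p_obs, q_obs, freqs)
            assert d == pytest.approx(
                moment_inversion_oracle(p_obs, q_obs, freqs), abs=1e-8
            )

    def test_all_heterozygote_pair_is_zero(self):
        # identical ambiguity codes share their full base mass
        assert f84_distance("R" * 50, "R" * 50,
                            F84Params(base_frequencies=UNIFORM)) == 0.0

    def test_half_transition_for_hom_vs_het(self):
        # A vs R shares half its mass; residual half is an A<->G transition
        d_half = f84_distance("AR" + "C" * 98, "AA" + "C" * 98,
                              F84Params(base_frequencies=UNIFORM))
        d_full = f84_distance("AG" + "C" * 98, "AA" + "C" * 98,
                              F84Params(base_frequencies=UNIFORM))
        assert 0 < d_half < d_full

    def test_symmetry(self):
        params = F84Params(base_frequencies=UNIFORM)
        a, b = "ACGTRYGA", "ACTTAYGG"
        assert f84_distance(a, b, params) == pytest.approx(
            f84_distance(b, a, params), abs=1e-15
        )

    def test_missing_sites_excluded_pairwise(self):
        params = F84Params(base_frequencies=UNIFORM)
        assert f84_distance("ACGT-N", "ACGTAA", params) == 0.0

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            f84_distance("NN", "AC", F84Params(base_frequencies=UNIFORM))

    def test_saturation_hits_ceiling_with_warning(self):
        params = F84Params(base_frequencies=UNIFORM, saturation_ceiling=5.0)
        with pytest.warns(RuntimeWarning, match="saturated"):
            d = f84_distance("AG" * 20, "GA" * 20, params)
        assert d == 5.0

    def test_k2p_limit_at_equal_frequencies(self):
        # with uniform frequencies F84 reduces to Kimura's two-parameter form
        for p, q in [(0.01, 0.005), (0.05, 0.02)]:
            k2p = -0.5 * np.log(1 - 2 * p - q) - 0.25 * np.log(1 - 2 * q)
            assert f84_from_proportions(p, q, UNIFORM) == pytest.approx(k2p, rel=1e-12)


class TestPairwiseMatrix:
    def test_two_samples_single_value(self):
        m = AlignedMarkerSet("m", ["a", "b"], ["AAAACCCCGGGGTTTT",
                                               "AAAACCCCGGGGTTTA"])
        mat = pairwise_distance_matrix(m)
        assert mat.level == "individual"
        assert mat.values[0, 1] > 0
        assert mat.values[0, 1] == mat.values[1, 0]

    def test_label_equivariance(self):
        seqs = ["AAAACCCCGGGGTTTT", "AAAACCCCGGGGTTTA", "AAAACCCCGGGGTTAA"]
        m1 = AlignedMarkerSet("m", ["a", "b", "c"], seqs)
        m2 = AlignedMarkerSet("m", ["c", "b", "a"], seqs[::-1])
        p = F84Params(base_frequencies=UNIFORM)
        d1 = pairwise_distance_matrix(m1, p)
        d2 = pairwise_distance_matrix(m2, p)
        for x, y in itertools.combinations("abc", 2):
            assert d1.value(x, y) == pytest.approx(d2.value(x, y), abs=1e-15)

    def test_matches_scalar_path(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGTRY"), 30)) for _ in range(5)]
        m = AlignedMarkerSet("m", [f"s{i}" for i in range(5)], seqs)
        params = F84Params(base_frequencies=UNIFORM)
        mat = pairwise_distance_matrix(m, params)
        for i, j in itertools.combinations(range(5), 2):
            assert mat.values[i, j] == pytest.approx(
                f84_distance(seqs[i], seqs[j], params), abs=1e-12
            )

    def test_empirical_frequencies(self):
        # R contributes half a count to A and to G; missing sites ignored
        m = AlignedMarkerSet("m", ["a", "b"], ["ACGT", "ACGR"])
        f = empirical_base_frequencies(m)
        np.testing.assert_allclose(f, [2.5 / 8, 2 / 8, 2.5 / 8, 1 / 8])
        # a base absent everywhere leaves the F84 constants undefined
        with pytest.raises(ValueError, match="absent"):
            empirical_base_frequencies(AlignedMarkerSet("m", ["a"], ["AAAA"]))


class TestPopulationMeans:
    def test_singletons_equal_pairwise(self):
        mat = DistanceMatrix(["a", "b"], np.array([[0, 0.3], [0.3, 0]]),
                             "individual")
        pm = PopulationMap({"a": "P", "b": "Q"})
        pop = population_mean_distances(mat, pm)
        assert pop.value("P", "Q") == pytest.approx(0.3)

    def test_mean_of_four_cross_distances(self):
        labels = ["a1", "a2", "b1", "b2"]
        v = np.zeros((4, 4))
        v[0, 2], v[0, 3], v[1, 2], v[1, 3] = 1, 2, 3, 4
        v[0, 1], v[2, 3] = 9, 9  # within distances must not contribute
        v = v + v.T
        mat = DistanceMatrix(labels, v, "individual")
        pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert population_mean_distances(mat, pm).value("A", "B") == 2.5

    def test_constant_off_diagonal_preserved(self):
        n = 6
        v = 0.7 * (np.ones((n, n)) - np.eye(n))
        mat = DistanceMatrix([f"s{i}" for i in range(n)], v, "individual")
        pm = PopulationMap({f"s{i}": f"P{i % 3}" for i in range(n)})
        pop = population_mean_distances(mat, pm)
        off = pop.values[~np.eye(pop.n, dtype=bool)]
        np.testing.assert_allclose(off, 0.7)

    def test_unmapped_label_errors(self):
        mat = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(KeyError, match="missing"):
            population_mean_distances(mat, PopulationMap({"a": "P"}))


class TestCombineMarkers:
    def test_three_four_five(self):
        m1 = DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]]))
        m2 = DistanceMatrix(["a", "b"], np.array([[0, 4.0], [4.0, 0]]))
        assert combine_markers_euclidean([m1, m2]).value("a", "b") == 5.0

    def test_zero_matrix_identity(self):
        m1 = DistanceMatrix(["a", "b"], np.array([[0, 1.5], [1.5, 0]]))
        z = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        assert combine_markers_euclidean([m1, z]).value("a", "b") == 1.5

    def test_equal_matrices_scale_sqrt2(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 2.0], [2.0, 0]]))
        assert combine_markers_euclidean([m, m]).value("a", "b") == pytest.approx(
            2 * np.sqrt(2)
        )

    def test_label_mismatch_errors(self):
        m1 = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        m2 = DistanceMatrix(["a", "c"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="label"):
            combine_markers_euclidean([m1, m2])

    def test_reorders_same_label_set(self):
        m1 = DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]]))
        m2 = DistanceMatrix(["b", "a"], np.array([[0, 4.0], [4.0, 0]]))
        assert combine_markers_euclidean([m1, m2]).value("a", "b") == 5.0
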