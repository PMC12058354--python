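"""Diversity statistics: Hill numbers, rarefaction, accumulation fits,
beta partition, PERMANOVA, PCoA and ANOVA power."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swabdiv import ecodiv


class TestHillNumber:
    def test_equal_counts_q1_is_richness(self):
        assert ecodiv.hill_number([10] * 5, 1) == pytest.approx(5.0)

    def test_q0_is_richness(self):
        assert ecodiv.hill_number([1, 1, 2], 0) == 3

    def test_shannon_exponential(self):
        # p = (0.75, 0.25): H = -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.5623
        expected = math.exp(-(0.75 * math.log(0.75) + 0.25 * math.log(0.25)))
        assert ecodiv.hill_number([75, 25], 1) == pytest.approx(expected)
        assert ecodiv.hill_number([75, 25], 1) == pytest.approx(1.7548, abs=1e-4)

    def test_q1_continuous_limit(self):
        c = [5, 3, 2, 9]
        assert ecodiv.hill_number(c, 1 + 1e-9) == pytest.approx(
            ecodiv.hill_number(c, 1), rel=1e-6
        )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            ecodiv.hill_number([0, 0], 1)

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=12).filter(lambda c: sum(c) > 0))
    def test_q1_at_most_q0_with_equality_iff_even(self, counts):
        q0 = ecodiv.hill_number(counts, 0)
        q1 = ecodiv.hill_number(counts, 1)
        assert q1 <= q0 + 1e-9
        nonzero = [c for c in counts if c > 0]
        if len(set(nonzero)) == 1:
            assert q1 == pytest.approx(q0)
        else:
            assert q1 < q0


class TestRarefyExact:
    def test_at_full_effort_equals_richness(self):
        y = [3, 1, 0, 2, 4]
        assert ecodiv.rarefy_exact(y, 4, 4) == pytest.approx(4.0)  # 4 nonzero taxa

    def test_single_sample_identity(self):
        y = [3, 1, 2]
        assert ecodiv.rarefy_exact(y, 4, 1) == pytest.approx(sum(y) / 4)

    def test_matches_exhaustive_subset_average(self, rng):
        for T in (3, 4, 5):
            mat = (rng.random((T, 7)) < 0.5).astype(int)
            y = mat.sum(axis=0)
            for t in range(1, T + 1):
                brute = np.mean(
                    [
                        (mat[list(sub)].sum(axis=0) > 0).sum()
                        for sub in itertools.combinations(range(T), t)
                    ]
                )
                assert ecodiv.rarefy_exact(y, T, t) == pytest.approx(brute, abs=1e-10)

    def test_nondecreasing_in_t(self, rng):
        y = rng.integers(0, 7, size=20)
        curve = ecodiv.rarefaction_curve(y, 6)
        assert np.all(np.diff(curve) >= -1e-12)

    def test_t_out_of_range(self):
        with pytest.raises(ValueError):
            ecodiv.rarefy_exact([1, 2], 3, 4)


class TestAccumulationFits:
    def test_asymptotic_self_consistency(self):
        t = np.arange(1, 7)
        s = 50 + (5 - 50) * np.exp(-np.exp(0.0) * t)
        fit = ecodiv.fit_accumulation(t, s, "asymptotic")
        assert fit.converged
        assert fit.params["Asym"] == pytest.approx(50.0, abs=1e-6)
        assert fit.params["R0"] == pytest.approx(5.0, abs=1e-5)

    def test_constant_curve_asymptote(self):
        fit = ecodiv.fit_accumulation([1, 2, 3, 4], [7.0] * 4, "asymptotic")
        assert fit.params["Asym"] == pytest.approx(7.0, abs=1e-4)

    def test_logistic_data_prefers_logistic(self):
        t = np.arange(1, 9)
        s = 40 / (1 + np.exp((3.0 - t) / 1.2))
        fits = [ecodiv.fit_accumulation(t, s, m) for m in ecodiv.ACCUMULATION_MODELS]
        best = ecodiv.select_best_model(fits)
        assert best.model == "logistic"
        assert best.params["Asym"] == pytest.approx(40.0, rel=1e-4)

    def test_select_best_model_ties(self):
        f1 = ecodiv.AccumulationFit("a", {"x": 1, "y": 2, "z": 3}, 0, 10.0, np.array([]), True)
        f2 = ecodiv.AccumulationFit("b", {"x": 1}, 0, 12.0, np.array([]), True)
        assert ecodiv.select_best_model([f1, f2]) is f1
        f3 = ecodiv.AccumulationFit("c", {"x": 1}, 0, 10.0, np.array([]), True)
        assert ecodiv.select_best_model([f1, f3]) is f3  # fewer parameters wins the tie

    def test_no_converged_fit_errors(self):
        bad = ecodiv.AccumulationFit("a", {}, 0, 1.0, np.array([]), False)
        with pytest.raises(ValueError):
            ecodiv.select_best_model([bad])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ecodiv.fit_accumulation([1, 2], [1.0, 2.0])


class TestBetaPair:
    def test_identical_sets(self):
        bp = ecodiv.beta_pair({"a", "b"}, {"a", "b"})
        assert (bp.beta_jac, bp.beta_jtu, bp.beta_jnes) == (0, 0, 0)

    def test_disjoint_sets(self):
        bp = ecodiv.beta_pair({"a"}, {"b", "c"})
        assert (bp.beta_jac, bp.beta_jtu, bp.beta_jnes) == (1, 1, 0)

    def test_strict_subset_pure_nestedness(self):
        bp = ecodiv.beta_pair({"a", "b", "c"}, {"a", "b", "c", "d", "e"})
        assert bp.beta_jtu == 0
        assert bp.beta_jac == pytest.approx(0.4)
        assert bp.beta_jnes == pytest.approx(0.4)

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            ecodiv.beta_pair(set(), set())

    @given(
        st.sets(st.integers(0, 20), max_size=15),
        st.sets(st.integers(0, 20), max_size=15),
    )
    def test_partition_symmetry_and_bounds(self, s1, s2):
        if not s1 and not s2:
            return
        bp = ecodiv.beta_pair(s1, s2)
        assert bp.beta_jac == pytest.approx(bp.beta_jtu + bp.beta_jnes, abs=1e-12)
        for v in (bp.beta_jac, bp.beta_jtu, bp.beta_jnes):
            assert -1e-12 <= v <= 1 + 1e-12
        swapped = ecodiv.beta_pair(s2, s1)
        assert bp == swapped


def _cloud_distances(rng, sep=4.0, n=6):
    pts = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(sep, 1, (n, 3))])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(2 * n)]
    meta = pd.DataFrame({"habitat": ["a"] * n + ["b"] * n}, index=ids)
    return pd.DataFrame(d, index=ids, columns=ids), meta


class TestPermanova:
    def test_separated_clouds_detected(self, rng):
        d, meta = _cloud_distances(rng)
        res = ecodiv.permanova(d, meta, terms=["habitat"], n_perm=999, seed=7)
        assert res.r2["habitat"] > 0.5
        assert res.p["habitat"] == pytest.approx(1 / 1000)

    def test_r2_sums_to_one(self, rng):
        d, meta = _cloud_distances(rng)
        res = ecodiv.permanova(d, meta, terms=["habitat"], n_perm=99, seed=1)
        assert res.r2["habitat"] + res.residual_r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d, meta = _cloud_distances(rng, sep=1.5)
        res = ecodiv.permanova(d, meta, terms=["habitat"], n_perm=99, seed=1)
        sk = skbio_permanova(
            DistanceMatrix(d.to_numpy(), list(d.index)),
            grouping=list(meta["habitat"]),
            permutations=99,
        )
        assert res.pseudo_f["habitat"] == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_sequential_terms_partition(self, rng):
        d, meta = _cloud_distances(rng)
        meta = meta.assign(replicate=[1, 2, 3] * 4, time_of_day=["am"] * 5 + ["pm"] * 7)
        res = ecodiv.permanova(d, meta, n_perm=49, seed=1)
        total_r2 = sum(res.r2.values()) + res.residual_r2
        assert total_r2 == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 1 / 50 for p in res.p.values())

    def test_single_level_term_errors(self, rng):
        d, meta = _cloud_distances(rng)
        meta["habitat"] = "same"
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            ecodiv.permanova(d, meta, terms=["habitat"])

    def test_nonconforming_matrix_errors(self):
        with pytest.raises(ValueError):
            ecodiv.permanova(np.ones((3, 2)), pd.DataFrame({"habitat": list("abc")}))

    def test_deterministic_given_seed(self, rng):
        d, meta = _cloud_distances(rng, sep=1.0)
        r1 = ecodiv.permanova(d, meta, terms=["habitat"], n_perm=99, seed=5)
        r2 = ecodiv.permanova(d, meta, terms=["habitat"], n_perm=99, seed=5)
        assert r1.p == r2.p


class TestPcoa:
    def test_two_samples(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = ecodiv.pcoa(d)
        assert res.coordinates.shape == (2, 1)
        assert sorted(res.coordinates.iloc[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = ecodiv.pcoa(d)
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.abs(rec - d).max() < 1e-9

    def test_matches_independent_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = ecodiv.pcoa(d)
        theirs = skbio_pcoa(DistanceMatrix(d, list("abcdef")))
        k = len(ours.eigenvalues)
        assert np.allclose(ours.eigenvalues, theirs.eigvals.values[:k], atol=1e-9)

    def test_zero_matrix(self):
        res = ecodiv.pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0

    def test_asymmetric_errors(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ecodiv.pcoa(d)

    def test_eigenvalues_sorted_descending(self, rng):
        pts = rng.normal(size=(7, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ev = ecodiv.pcoa(d).eigenvalues
        assert np.all(np.diff(ev) <= 1e-12)


class TestAnovaPower:
    def test_minimality_contract(self):
        n = ecodiv.anova_power_n(3, 0.75, 0.05, 0.8)
        assert ecodiv.anova_power(3, n, 0.75) >= 0.8
        assert ecodiv.anova_power(3, n - 1, 0.75) < 0.8

    def test_continuous_solution_matches_solver_convention(self):
        # value cross-checked against the R uniroot solve of the same
        # noncentral-F power equation
        n = ecodiv.anova_power_n_continuous(3, 0.75, 0.05, 0.8)
        assert n == pytest.approx(6.8144, abs=1e-3)

    def test_nonincreasing_in_f(self):
        ns = [ecodiv.anova_power_n(3, f) for f in (0.3, 0.5, 0.75, 1.5)]
        assert ns == sorted(ns, reverse=True)
        assert ecodiv.anova_power_n(3, 1.5) <= ecodiv.anova_power_n(3, 0.75)

    def test_nonincreasing_in_alpha(self):
        assert ecodiv.anova_power_n(3, 0.75, alpha=0.01) >= ecodiv.anova_power_n(
            3, 0.75, alpha=0.10
        )

    def test_invalid_effect_size(self):
        with pytest.raises(ValueError):
            ecodiv.anova_power_n(3, 0.0)
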