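"""Covariance network: correlations, Fisher z, edge permutation test, NBS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morpet.atlas import make_atlas
from morpet.cohort import CohortSpec, bpnd_frame, simulate_bpnd
from morpet.network import (
    correlation_matrix,
    count_edges,
    edge_permutation_test,
    fisher_z,
    nbs_correct,
    run_network_comparison,
)


def _split(bp: pd.DataFrame, n_a: int):
    return bp.iloc[:n_a], bp.iloc[n_a:]


def _null_frames(atlas, seed, n_patients=19, n_controls=20):
    spec = CohortSpec(n_patients=n_patients, n_controls=n_controls,
                      striatal_means=(1.7, 1.7), covariance_strength=(0.3, 0.3),
                      seed=seed)
    bp = bpnd_frame(simulate_bpnd(spec, atlas))
    return _split(bp, n_patients)


class TestEdgeBasics:
    def test_edge_counts(self):
        assert count_edges(125) == 7750
        assert count_edges(2) == 1
        assert count_edges(10) == 45  # n(n-1)/2
        with pytest.raises(ValueError):
            count_edges(1)

    def test_correlation_matrix_definitional(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        r = correlation_matrix(X).to_numpy()
        # direct covariance / sigma sigma computation
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        cov = Xc.T @ Xc / 19
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(r, cov / np.outer(sd, sd), atol=1e-12)

    def test_correlation_degenerate_cases(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        X["b"] = X["a"]
        X["c"] = -X["a"]
        r = correlation_matrix(X)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        X["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(X)
        with pytest.raises(ValueError, match="3 subjects"):
            correlation_matrix(X.iloc[:2])

    def test_fisher_z_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, rel=1e-12)
        assert np.isfinite(fisher_z(1.0))  # clamped at |r| = 1 - 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r=st.floats(-1.0, 1.0))
    def test_fisher_z_antisymmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), rel=1e-12, abs=1e-300)


class TestEdgePermutationTest:
    def test_identical_groups_yield_null_stats(self, atlas8, rng):
        # exhaustive mode (C(10,5)=252): the relabelling multiset is closed
        # under complementation, so every one-sided p is exactly >= 0.5
        X = pd.DataFrame(rng.normal(size=(5, 8)), columns=atlas8.region_names)
        es = edge_permutation_test(X, X.copy(), n_permutations=300, seed=1)
        assert es.exhaustive
        np.testing.assert_allclose(es.observed_stat, 0.0, atol=1e-12)
        assert np.all(es.p_values >= 0.5)

    def test_exhaustive_mode_for_small_groups(self, atlas8, rng):
        X = pd.DataFrame(rng.normal(size=(8, 8)), columns=atlas8.region_names)
        es = edge_permutation_test(X.iloc[:4], X.iloc[4:], n_permutations=1000, seed=1)
        assert es.exhaustive
        assert es.n_permutations == 70  # C(8, 4)

    def test_exhaustive_agrees_with_random_sampling(self, atlas8, rng):
        X = pd.DataFrame(rng.normal(size=(12, 8)), columns=atlas8.region_names)
        a, b = X.iloc[:6], X.iloc[6:]
        exact = edge_permutation_test(a, b, n_permutations=2000, seed=1)  # C(12,6)=924
        assert exact.exhaustive
        sampled = edge_permutation_test(a, b, n_permutations=800, seed=7)
        assert not sampled.exhaustive
        assert np.max(np.abs(exact.p_values - sampled.p_values)) < 0.06

    def test_group_swap_symmetry(self, atlas8, rng):
        """Swapping groups negates stats and complements one-sided p."""
        X = pd.DataFrame(rng.normal(size=(8, 8)), columns=atlas8.region_names)
        a, b = X.iloc[:4], X.iloc[4:]
        es_ab = edge_permutation_test(a, b, n_permutations=1000, seed=1)  # exhaustive
        es_ba = edge_permutation_test(b, a, n_permutations=1000, seed=1)
        np.testing.assert_allclose(es_ab.observed_stat, -es_ba.observed_stat, atol=1e-12)
        # continuous data: the only tie with the observed statistic is itself
        np.testing.assert_allclose(es_ab.p_values + es_ba.p_values,
                                   1.0 + 1.0 / 70, atol=1e-12)

    def test_null_rejection_rate_calibrated(self, atlas8):
        fracs = []
        for rep in range(40):
            a, b = _null_frames(atlas8, seed=7000 + rep)
            es = edge_permutation_test(a, b, n_permutations=600, seed=rep)
            fracs.append(np.mean(es.p_values < 0.05))
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_p_granularity_never_zero(self, atlas20):
        clique = tuple(atlas20.region_names[:3])
        spec = CohortSpec(n_patients=40, n_controls=40, striatal_means=(1.7, 1.7),
                          covariance_strength=(0.9, 0.0), covariance_regions=clique,
                          seed=5)
        a, b = _split(bpnd_frame(simulate_bpnd(spec, atlas20)), 40)
        es = edge_permutation_test(a, b, n_permutations=400, seed=2)
        assert np.all(es.p_values > 0)
        assert es.p_values.min() == pytest.approx(1.0 / 401)

    def test_input_validation(self, atlas8, rng):
        X = pd.DataFrame(rng.normal(size=(10, 8)), columns=atlas8.region_names)
        with pytest.raises(ValueError, match="n_permutations"):
            edge_permutation_test(X.iloc[:5], X.iloc[5:], n_permutations=10)
        with pytest.raises(ValueError, match="direction"):
            edge_permutation_test(X.iloc[:5], X.iloc[5:], direction="less")
        with pytest.raises(ValueError, match="combined"):
            edge_permutation_test(X.iloc[:3], X.iloc[3:5], n_permutations=100)


class TestNBS:
    def test_empty_supra_threshold_set_is_valid(self, atlas8, rng):
        X = pd.DataFrame(rng.normal(size=(10, 8)), columns=atlas8.region_names)
        es = edge_permutation_test(X, X.copy(), n_permutations=300, seed=1)
        res = nbs_correct(es, primary_threshold=0.05)
        assert res.components == []
        assert res.supra_threshold_edges == []

    def test_planted_clique_recovered(self, atlas8):
        """A large covariance increase confined to a 3-region clique is found
        as the largest significant component containing exactly those 3 edges.

        Run at the conservative primary threshold (0.001): with a
        permutation-calibrated threshold every permuted graph carries ~alpha
        supra-threshold edge density, so at alpha=0.05 the null maximal
        component reaches 3 edges in ~10% of permutations and a 3-edge
        structure can never be significant; the conservative threshold is the
        one that isolates focal structure.
        """
        clique = ("caudate", "putamen", "insula")
        spec = CohortSpec(n_patients=40, n_controls=40, striatal_means=(1.7, 1.7),
                          covariance_strength=(0.95, 0.0), covariance_regions=clique,
                          seed=17)
        a, b = _split(bpnd_frame(simulate_bpnd(spec, atlas8)), 40)
        es = edge_permutation_test(a, b, n_permutations=2000, seed=17)
        res = nbs_correct(es, primary_threshold=0.001)
        sig = [c for c in res.components if c.p_corrected < 0.05]
        assert sig
        top = sig[0]
        assert top.n_edges == 3
        assert sorted(top.regions) == sorted(clique)

    def test_corrected_p_monotone_in_effect_size(self, atlas8):
        clique = ("caudate", "putamen", "insula")
        ps = []
        for lam in (0.5, 0.8, 0.95):
            spec = CohortSpec(n_patients=40, n_controls=40, striatal_means=(1.7, 1.7),
                              covariance_strength=(lam, 0.0), covariance_regions=clique,
                              seed=23)
            a, b = _split(bpnd_frame(simulate_bpnd(spec, atlas8)), 40)
            es = edge_permutation_test(a, b, n_permutations=1000, seed=23)
            res = nbs_correct(es, primary_threshold=0.001)
            ps.append(min((c.p_corrected for c in res.components), default=1.0))
        assert ps[0] >= ps[1] >= ps[2]
        assert ps[2] < 0.05

    def test_interface_contracts(self, atlas8, rng):
        X = pd.DataFrame(rng.normal(size=(12, 8)), columns=atlas8.region_names)
        es = edge_permutation_test(X.iloc[:6], X.iloc[6:], n_permutations=300, seed=3)
        with pytest.raises(ValueError, match="threshold"):
            nbs_correct(es, primary_threshold=1.5)
        with pytest.raises(ValueError, match="must match"):
            nbs_correct(es, n_permutations=999)
        es.perm_stats = None
        with pytest.raises(ValueError, match="perm_stats"):
            nbs_correct(es)


class TestRunNetworkComparison:
    def test_deterministic_given_seed(self, atlas8):
        spec = CohortSpec(seed=31)
        bp = bpnd_frame(simulate_bpnd(spec, atlas8))
        groups = pd.Series(["patient"] * 19 + ["control"] * 20, index=bp.index)
        r1 = run_network_comparison(bp, groups, n_permutations=300, seed=9)
        r2 = run_network_comparison(bp, groups, n_permutations=300, seed=9)
        np.testing.assert_array_equal(r1.edge_stats.p_values, r2.edge_stats.p_values)
        assert r1.n_significant_edges == r2.n_significant_edges

    def test_reports_7750_edges_for_125_region_atlas(self):
        atlas = make_atlas(125)
        spec = CohortSpec(n_patients=10, n_controls=10, seed=2)
        bp = bpnd_frame(simulate_bpnd(spec, atlas))
        groups = pd.Series(["patient"] * 10 + ["control"] * 10, index=bp.index)
        rep = run_network_comparison(bp, groups, n_permutations=100, seed=3)
        assert rep.n_edges == 7750
        assert rep.n_regions == 125

    def test_effect_cohort_has_more_significant_edges_than_null(self, atlas20):
        effect = CohortSpec(covariance_strength=(0.5, 0.2), seed=41)
        null = CohortSpec(striatal_means=(1.7, 1.7), covariance_strength=(0.3, 0.3),
                          seed=41)
        counts = {}
        for name, spec in (("effect", effect), ("null", null)):
            bp = bpnd_frame(simulate_bpnd(spec, atlas20))
            groups = pd.Series(["patient"] * 19 + ["control"] * 20, index=bp.index)
            rep = run_network_comparison(bp, groups, n_permutations=800, seed=41)
            counts[name] = rep.n_significant_edges[0.05]
        assert counts["effect"] > counts["null"]
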