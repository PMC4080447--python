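"""Ancestry LD statistics, significance, M_eff and FDR calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import hybridscan as hs
from hybridscan.ld import pairwise_complete_corr
from tests.conftest import iid_dosage_matrix


def dosage_vectors(n=12):
    return st.lists(
        st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=n, max_size=n
    )


class TestAncestryR:
    def test_perfect_and_inverse_correlation(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        assert hs.ancestry_R(x, x) == (1.0, 1.0)
        r, r2 = hs.ancestry_R(np.array([0.0, 1, 2]), np.array([2.0, 1, 0]))
        assert np.isclose(r, -1.0) and np.isclose(r2, 1.0)

    def test_hand_computed_oracle(self):
        x = np.array([0, 0, 1, 2, 2, 1], dtype=float)
        y = np.array([0, 1, 1, 2, 1, 0], dtype=float)
        # direct arithmetic: covariance over sd product (population moments)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        r, r2 = hs.ancestry_R(x, y)
        assert np.isclose(r, expected)
        assert np.isclose(r2, expected**2)

    def test_pairwise_complete_deletion(self):
        x = np.array([0, 1, 2, np.nan, 2])
        y = np.array([0, 1, 2, 2, np.nan])
        r, _ = hs.ancestry_R(x, y)
        assert np.isclose(r, 1.0)

    def test_constant_vector_undefined(self):
        r, r2 = hs.ancestry_R(np.array([1.0, 1, 1]), np.array([0.0, 1, 2]))
        assert np.isnan(r) and np.isnan(r2)

    @settings(derandomize=True, max_examples=30)
    @given(dosage_vectors())
    def test_parent_relabeling_symmetry(self, pairs):
        x = np.array([a for a, _ in pairs], dtype=float)
        y = np.array([b for _, b in pairs], dtype=float)
        r, _ = hs.ancestry_R(x, y)
        if np.isnan(r):
            return
        r_both, _ = hs.ancestry_R(2 - x, 2 - y)
        r_one, _ = hs.ancestry_R(2 - x, y)
        assert np.isclose(r, r_both)
        assert np.isclose(r, -r_one)


class TestPairPvalue:
    def test_deterministic_monotone_association(self):
        x = np.repeat([0.0, 1.0, 2.0], 34)  # n ~ 100
        _, p = hs.pair_pvalue(x, x)
        assert p < 1e-6

    def test_null_pvalues_uniform_vs_permutation_oracle(self, rng):
        ps_ord, ps_perm = [], []
        for k in range(250):
            x = rng.integers(0, 3, 100).astype(float)
            y = rng.integers(0, 3, 100).astype(float)
            ps_ord.append(hs.pair_pvalue(x, y)[1])
            if k < 60:
                ps_perm.append(
                    hs.pair_pvalue(x, y, method="permutation", n_perm=99, seed=k)[1]
                )
        assert sps.kstest(ps_ord, "uniform").pvalue > 0.01
        # permutation oracle is similarly calibrated
        assert sps.kstest(ps_perm, "uniform").pvalue > 0.01

    def test_constant_outcome_falls_back_to_permutation(self):
        x = np.array([0.0, 1, 2, 0, 1, 2])
        t, p = hs.pair_pvalue(x, np.ones_like(x))
        assert np.isnan(t) and p == 1.0

    def test_symmetric_orientation_averages(self, rng):
        x = rng.integers(0, 3, 80).astype(float)
        y = np.where(rng.random(80) < 0.5, x, rng.integers(0, 3, 80)).astype(float)
        t_sym, _ = hs.pair_pvalue(x, y, orientation="symmetric")
        t_xy, _ = hs.pair_pvalue(x, y)
        t_yx, _ = hs.pair_pvalue(y, x)
        assert np.isclose(t_sym, (t_xy + t_yx) / 2, atol=1e-8)


class TestScan:
    def test_pair_counting_and_within_group_exclusion(self, rng):
        ids = ["g1:1", "g1:2", "g1:3", "g2:1", "g2:2"]
        geno = iid_dosage_matrix(40, ids, 0.5, rng)
        res = hs.scan(geno, compute_p=False)
        assert len(res) == 6
        assert (res["group_i"] != res["group_j"]).all()

    def test_single_group_scan_is_empty(self, rng):
        geno = iid_dosage_matrix(20, ["g1:1", "g1:2"], 0.5, rng)
        assert len(hs.scan(geno)) == 0

    def test_scan_R_matches_direct_calls(self, rng):
        ids = ["g1:1", "g2:1", "g3:1"]
        geno = iid_dosage_matrix(30, ids, 0.4, rng)
        res = hs.scan(geno, compute_p=False)
        for _, row in res.iterrows():
            r, _ = hs.ancestry_R(geno.dosage(row.marker_i), geno.dosage(row.marker_j))
            assert np.isclose(row.R, r)


class TestDecayProfile:
    def test_parental_population_never_decays(self):
        gmap = hs.GenomeMap([("g1", 4_000_000)]).uniform_markers(250_000)
        scen = hs.HybridZoneScenario(admix_p=0.5, T_gen=0, N=100, seed=1)
        pop = hs.simulate_hybrid_population(scen, gmap)
        geno = hs.genotypes_at_markers(pop, gmap)
        prof = hs.decay_profile(geno, gmap)
        assert prof.crossing_distance is None
        assert (prof.bins["mean_R2"] > 0.9).all()

    def test_crossing_distance_decreases_with_age(self):
        gmap = hs.GenomeMap([("g1", 8_000_000), ("g2", 8_000_000)]).uniform_markers(80_000)
        crossings = []
        for T in (20, 60):
            scen = hs.HybridZoneScenario(admix_p=0.5, T_gen=T, N=800, seed=5)
            pop = hs.simulate_hybrid_population(scen, gmap)
            geno = hs.genotypes_at_markers(pop[:150], gmap)
            prof = hs.decay_profile(geno, gmap)
            crossings.append(prof.crossing_distance)
        assert crossings[0] > crossings[1]


class TestEffectiveMarkerNumber:
    def test_identity_gives_marker_count(self):
        assert hs.effective_marker_number(np.eye(7)) == pytest.approx(7.0)

    def test_duplicated_marker_collapses(self):
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 1.0
        assert hs.effective_marker_number(corr) == pytest.approx(4.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        a = rng.normal(size=(40, 10))
        corr = np.corrcoef(a, rowvar=False)
        lam = np.linalg.eig(corr)[0].real  # independent decomposition route
        lam = np.clip(np.sort(lam), 0, None)
        expected = sum((1.0 if l >= 1 else 0.0) + (l - np.floor(l)) for l in lam)
        assert hs.effective_marker_number(corr) == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_marker_order(self, rng):
        a = rng.normal(size=(30, 8))
        corr = np.corrcoef(a, rowvar=False)
        perm = rng.permutation(8)
        assert hs.effective_marker_number(corr[np.ix_(perm, perm)]) == pytest.approx(
            hs.effective_marker_number(corr)
        )

    def test_rejects_asymmetric_input(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            hs.effective_marker_number(m)


class TestPermutationFDR:
    def test_null_joint_positives_match_binomial_expectation(self, rng):
        ids = [f"g{g}:{1}" for g in range(1, 9)]
        g1 = iid_dosage_matrix(60, ids, 0.5, rng)
        g2 = iid_dosage_matrix(60, ids, 0.5, rng)
        alpha = 0.3
        cal = hs.permutation_fdr(
            g1, g2, M_eff=8.0, thresholds=[alpha], reps=40, seed=0,
            observed_counts={alpha: 10},
        )
        n_pairs = 28
        expected = n_pairs * alpha**2
        got = cal.table["expected_fp"].iloc[0]
        # Monte-Carlo tolerance: sd of the mean of 40 reps
        assert abs(got - expected) < 4 * np.sqrt(expected / 40) + 0.5

    def test_threshold_one_flags_everything(self, rng):
        ids = ["g1:1", "g2:1", "g3:1"]
        g1 = iid_dosage_matrix(25, ids, 0.5, rng)
        g2 = iid_dosage_matrix(25, ids, 0.5, rng)
        cal = hs.permutation_fdr(
            g1, g2, M_eff=3.0, thresholds=[1.01], reps=5, seed=1,
            observed_counts={1.01: 3},
        )
        row = cal.table.iloc[0]
        assert row["expected_fp"] == 3.0
        assert row["fdr"] == 1.0

    def test_undefined_fdr_when_nothing_observed(self, rng):
        ids = ["g1:1", "g2:1"]
        g1 = iid_dosage_matrix(25, ids, 0.5, rng)
        g2 = iid_dosage_matrix(25, ids, 0.5, rng)
        cal = hs.permutation_fdr(
            g1, g2, M_eff=2.0, thresholds=[0.5], reps=3, seed=2,
            observed_counts={0.5: 0},
        )
        assert np.isinf(cal.table["fdr"].iloc[0])


class TestJointSignificance:
    def make_results(self, ps1, ps2, signs1=None, signs2=None):
        n = len(ps1)
        base = {
            "marker_i": [f"g1:{k}" for k in range(n)],
            "marker_j": [f"g2:{k}" for k in range(n)],
            "group_i": ["g1"] * n,
            "group_j": ["g2"] * n,
            "n": [100] * n,
            "R": [0.2] * n,
            "R2": [0.04] * n,
            "t": [2.0] * n,
        }
        r1 = pd.DataFrame({**base, "p": ps1, "sign": signs1 or ["conspecific"] * n})
        r2 = pd.DataFrame({**base, "p": ps2, "sign": signs2 or ["conspecific"] * n})
        return r1, r2

    def test_joint_threshold_boundary(self):
        r1, r2 = self.make_results([0.012, 0.012], [0.012, 0.014])
        joint = hs.joint_significant_pairs(r1, r2, 0.013)
        assert list(joint["marker_i"]) == ["g1:0"]

    def test_sign_concordance_labels(self):
        r1, r2 = self.make_results(
            [0.001] * 3, [0.001] * 3,
            signs1=["conspecific", "heterospecific", "conspecific"],
            signs2=["conspecific", "heterospecific", "heterospecific"],
        )
        joint = hs.joint_significant_pairs(r1, r2)
        assert list(joint["concordance"]) == [
            "conspecific_both", "heterospecific_both", "discordant"
        ]

    def test_mismatched_universe_rejected(self):
        r1, r2 = self.make_results([0.01, 0.01], [0.01, 0.01])
        with pytest.raises(ValueError, match="universe"):
            hs.joint_significant_pairs(r1, r2.iloc[:1])


class TestConspecificExcess:
    def make_frames(self, sig_signs, bg_signs):
        sig = pd.DataFrame({"sign_1": sig_signs})
        bg = pd.DataFrame({"sign_1": bg_signs})
        return sig, bg

    def test_all_positive_significant_set_is_extreme(self):
        sig, bg = self.make_frames(
            ["conspecific"] * 20,
            ["conspecific", "heterospecific"] * 100,
        )
        obs, p = hs.conspecific_excess_test(sig, bg, n_boot=999, seed=0)
        assert obs == 1.0
        assert p < 0.002

    def test_background_draws_are_calibrated(self, rng):
        ps = []
        for k in range(30):
            signs = np.where(rng.random(200) < 0.5, "conspecific", "heterospecific")
            sig, bg = self.make_frames(list(signs[:20]), list(signs))
            _, p = hs.conspecific_excess_test(sig, bg, n_boot=199, seed=k)
            ps.append(p)
        assert 0.2 < np.mean(ps) < 0.9

    def test_degenerate_inputs_rejected(self):
        sig, bg = self.make_frames(["conspecific"] * 10, ["conspecific"] * 5)
        with pytest.raises(ValueError, match="background"):
            hs.conspecific_excess_test(sig, bg)
        with pytest.raises(ValueError, match="empty"):
            hs.conspecific_excess_test(sig.iloc[:0], bg)


def test_pairwise_complete_corr_handles_missingness(rng):
    data = rng.integers(0, 3, size=(30, 4)).astype(float)
    data[::3, 1] = np.nan
    corr = pairwise_complete_corr(data)
    assert corr.shape == (4, 4)
    np.testing.assert_allclose(np.diag(corr), 1.0)


class TestDemographicFDR:
    def test_neutral_scenario_matches_alpha_squared_scaling(self):
        # at a permissive threshold the joint false-positive rate of two
        # independent neutral populations is ~ alpha^2
        gmap = hs.GenomeMap(
            [(f"g{i}", 1000) for i in range(1, 13)]
        ).uniform_markers(2000)
        bases = (
            hs.HybridZoneScenario(admix_p=0.6, T_gen=10, N=300),
            hs.HybridZoneScenario(admix_p=0.4, T_gen=10, N=300),
        )
        alpha = 0.1
        table = hs.demographic_fdr(
            {"neutral": None,
             "bottleneck": hs.DemographicScenario(bottleneck_fraction=0.2)},
            bases, gmap, n_effective_tests=100.0, observed_positive_count=10,
            threshold=alpha, sample_sizes=(120, 120), seed=3,
        )
        neutral = table[table["scenario"] == "neutral"].iloc[0]
        analytic = alpha**2 * 100.0 / 10
        assert 0.3 * analytic < neutral["fdr"] < 3.0 * analytic
        bott = table[table["scenario"] == "bottleneck"].iloc[0]
        assert np.isfinite(bott["fdr"]) and bott["fdr"] >= 0.0


def test_divergence_time_conversion():
    demo = hs.DemographicScenario()
    # D_xy equal to theta means zero divergence time; 3*theta gives 1 (in 4N units)
    assert demo.t_div_4n(demo.theta) == 0.0
    assert demo.t_div_4n(3 * demo.theta) == pytest.approx(1.0)
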