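"""Two-locus BDM selection recursion, pair-set kernel and ABC machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hybridscan as hs
from hybridscan.bdm import (
    ABCPosterior,
    _pair_set_kernel,
    fitness_matrix,
    gamete_D,
    iterate_generation,
    pulse_freqs,
)


class TestFitnessMatrix:
    def test_variant_A_red_cells(self):
        w = fitness_matrix("A", 0.1).values
        # >=1 M at locus 1 combined with >=1 B at locus 2
        hit = [(1, 0), (1, 1), (2, 0), (2, 1)]
        for g1 in range(3):
            for g2 in range(3):
                expected = 0.9 if (g1, g2) in hit else 1.0
                assert w[g1, g2] == pytest.approx(expected)

    def test_variant_B_is_the_mirror(self):
        wa = fitness_matrix("A", 0.3).values
        wb = fitness_matrix("B", 0.3).values
        # exact mirror: swap M<->B at both loci
        np.testing.assert_allclose(wb, wa[::-1, ::-1])

    def test_all_hybrid_lethal_leaves_parentals(self):
        w = fitness_matrix("ALL_HYBRID", 1.0).values
        assert w[0, 0] == 1.0 and w[2, 2] == 1.0
        assert (w.sum() - 2.0) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0, 1), st.sampled_from(["A", "B", "ALL_HYBRID"]))
    def test_neutral_limit_and_bounds(self, s, variant):
        w = fitness_matrix(variant, s).values
        assert (np.isclose(w, 1.0) | np.isclose(w, 1.0 - s)).all()
        if s == 0:
            np.testing.assert_allclose(w, 1.0)

    def test_out_of_range_s_rejected(self):
        with pytest.raises(ValueError):
            fitness_matrix("A", 1.5)


def mating_table_oracle(freqs, w):
    """Exhaustive enumeration over parent pairs x gamete outcomes (N = inf)."""
    f = freqs * w
    f = f / f.sum()
    # per-genotype gamete distribution with c = 1/2
    gam = np.zeros((3, 3, 2, 2))
    for g1 in range(3):
        for g2 in range(3):
            for a in (0, 1):
                pa = g1 / 2 if a else 1 - g1 / 2
                for b in (0, 1):
                    pb = g2 / 2 if b else 1 - g2 / 2
                    gam[g1, g2, a, b] = pa * pb
    out = np.zeros((3, 3))
    for g1 in range(3):
        for g2 in range(3):
            for h1 in range(3):
                for h2 in range(3):
                    pair_p = f[g1, g2] * f[h1, h2]
                    if pair_p == 0:
                        continue
                    for a in (0, 1):
                        for b in (0, 1):
                            for a2 in (0, 1):
                                for b2 in (0, 1):
                                    out[a + a2, b + b2] += (
                                        pair_p
                                        * gam[g1, g2, a, b]
                                        * gam[h1, h2, a2, b2]
                                    )
    return out


class TestRecursion:
    def test_matches_exhaustive_mating_table_oracle(self, rng):
        raw = rng.random((3, 3))
        freqs = hs.TwoLocusGenotypeFreqs(raw / raw.sum())
        fit = fitness_matrix("A", 0.3)
        state = freqs
        oracle = freqs.values
        for _ in range(2):
            state = iterate_generation(state, fit, N=None)
            oracle = mating_table_oracle(oracle, fit.values)
        np.testing.assert_allclose(state.values, oracle, atol=1e-10)

    def test_neutral_gamete_D_halves_exactly(self):
        state = pulse_freqs(0.6)
        fit = fitness_matrix("A", 0.0)
        d = gamete_D(state.gamete_freqs())
        for t in range(1, 6):
            state = iterate_generation(state, fit, N=None)
            assert gamete_D(state.gamete_freqs()) == pytest.approx(
                d * 0.5**t, abs=1e-12
            )

    def test_neutral_gamete_frequencies_constant(self):
        state = pulse_freqs(0.3)
        fit = fitness_matrix("B", 0.0)
        x0 = state.gamete_freqs()
        state = iterate_generation(state, fit, N=None)
        # allele frequencies unchanged under neutrality
        x1 = state.gamete_freqs()
        assert x1.sum(axis=1)[1] == pytest.approx(x0.sum(axis=1)[1], abs=1e-12)
        assert x1.sum(axis=0)[1] == pytest.approx(x0.sum(axis=0)[1], abs=1e-12)

    def test_lethal_selection_zeroes_incompatible_classes(self):
        state = pulse_freqs(0.5)
        state = iterate_generation(state, fitness_matrix("A", 0.0), N=None)  # mix
        fit = fitness_matrix("A", 1.0)
        post = state.values * fit.values
        post /= post.sum()
        for g1, g2 in [(1, 0), (1, 1), (2, 0), (2, 1)]:
            assert post[g1, g2] == 0.0

    def test_total_wipeout_is_an_error(self):
        # population fixed for an incompatible combination, s = 1
        vals = np.zeros((3, 3))
        vals[2, 0] = 1.0
        with pytest.raises(RuntimeError, match="zero"):
            iterate_generation(
                hs.TwoLocusGenotypeFreqs(vals), fitness_matrix("A", 1.0), N=None
            )

    def test_frequency_conservation_with_drift(self, rng):
        state = pulse_freqs(0.4)
        fit = fitness_matrix("B", 0.2)
        for _ in range(10):
            state = iterate_generation(state, fit, N=200, rng=rng)
            assert state.values.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_selection_produces_conspecific_association(self, variant):
        state = pulse_freqs(0.5)
        fit = fitness_matrix(variant, 0.2)
        for _ in range(30):
            state = iterate_generation(state, fit, N=None)
            assert gamete_D(state.gamete_freqs()) >= -1e-12


class TestPairSetKernel:
    def test_large_N_kernel_matches_deterministic_recursion(self):
        s, p, T = 0.05, 0.6, 12
        stats = hs.simulate_pair_set(
            s, p, T, N=500_000, n_pairs=150, sample_sizes=2000, major="M", seed=3
        )
        state = pulse_freqs(p)
        fit = fitness_matrix("A", s)
        for _ in range(T):
            state = iterate_generation(state, fit, N=None)
        g = state.values
        expected_dh = g[2, 2]
        expected_mh = g[0, 1] + g[1, 0]
        expected_anc = state.mean_ancestry()
        # variants A and B give mirror trajectories; stats are a fair mix, and
        # for these orientation-pooled statistics the mirror is identical
        assert abs(stats.f_major_double_hom - expected_dh) < 0.01
        assert abs(stats.f_minor_hom_het - expected_mh) < 0.01
        assert abs(stats.mean_ancestry - expected_anc) < 0.01

    def test_neutral_mean_ancestry_matches_admixture_proportion(self):
        stats = hs.simulate_pair_set(0.0, 0.35, 20, 1000, n_pairs=100, seed=1)
        assert abs(stats.mean_ancestry - 0.35) < 0.02

    def test_selection_enriches_major_double_homozygotes(self):
        neutral = hs.simulate_pair_set(0.0, 0.6, 30, 2000, n_pairs=100, seed=2)
        selected = hs.simulate_pair_set(0.08, 0.6, 30, 2000, n_pairs=100, seed=2)
        assert selected.f_major_double_hom > neutral.f_major_double_hom

    def test_kernel_is_deterministic_given_seed(self):
        a = hs.simulate_pair_set(0.03, 0.5, 10, 300, n_pairs=1, seed=9)
        b = hs.simulate_pair_set(0.03, 0.5, 10, 300, n_pairs=1, seed=9)
        assert a == b


class TestABC:
    def test_full_tolerance_recovers_prior(self):
        prior = hs.ABCPrior(admix_p=(0.4, 0.6), T=(5, 15), N=(100, 1000))
        obs = hs.SummaryStats(0.2, 0.1, 0.5)
        post = hs.abc_infer(
            obs, prior, n_sims=2000, tolerance=1.0, n_pairs=5,
            sample_sizes=100, seed=0,
        )
        acc = post.accepted
        for name, (lo, hi) in prior.bounds().items():
            mid = (lo + hi) / 2
            width = hi - lo
            se = width / np.sqrt(12 * len(acc))
            assert abs(acc[name].mean() - mid) < 4 * se

    def test_map_and_ci_inside_prior_support(self):
        prior = hs.ABCPrior()
        obs = hs.simulate_pair_set(0.03, 0.6, 50, 2000, n_pairs=10, seed=4)
        post = hs.abc_infer(
            obs, prior, n_sims=3000, tolerance=0.05, n_pairs=10,
            sample_sizes=170, seed=5,
        )
        for name, (lo, hi) in prior.bounds().items():
            assert lo <= post.map_estimate[name] <= hi
            assert lo <= post.ci95[name][0] <= post.ci95[name][1] <= hi


class TestRandomMating:
    def test_balanced_frequencies_expectation(self, rng):
        x = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        y = rng.permutation(x)
        _, expected, _, _ = hs.random_mating_expectation(x, y)
        assert expected[2, 2] == pytest.approx(0.0625)

    def test_observed_equal_expected_zero_deviation(self):
        # exact HWE table at p = q = 0.5 for both loci, independent
        counts = np.outer([1, 2, 1], [1, 2, 1])
        x, y = [], []
        for g1 in range(3):
            for g2 in range(3):
                x += [g1] * counts[g1, g2]
                y += [g2] * counts[g1, g2]
        _, _, dev, collapsed = hs.random_mating_expectation(np.array(x, float), np.array(y, float))
        np.testing.assert_allclose(dev, 0.0, atol=1e-12)
        assert all(abs(v) < 1e-12 for v in collapsed.values())

    def test_ten_individual_worked_table(self):
        x = np.array([2, 2, 2, 1, 1, 1, 1, 0, 0, 0], dtype=float)
        y = np.array([2, 2, 1, 1, 1, 0, 0, 0, 2, 1], dtype=float)
        obs, exp, dev, _ = hs.random_mating_expectation(x, y)
        pa, pb = x.mean() / 2, y.mean() / 2
        assert obs[2, 2] == pytest.approx(0.2)
        assert exp[2, 2] == pytest.approx(pa**2 * pb**2)
        assert dev[2, 2] == pytest.approx(0.2 - pa**2 * pb**2)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hs.random_mating_expectation(
                np.array([2.0, 2.0, 2.0]), np.array([0.0, 1.0, 2.0])
            )


class TestPosteriorPredictive:
    def make_posterior(self, s, p=0.5, T=10, N=2000):
        adj = pd.DataFrame({"s": [s] * 5, "admix_p": [p] * 5, "T": [T] * 5, "N": [N] * 5})
        return ABCPosterior(adj.copy(), adj, {}, {}, hs.ABCPrior())

    def test_neutral_posterior_deviations_center_at_zero(self):
        post = self.make_posterior(0.0)
        dev = hs.posterior_predictive(
            post, n_draws=4, pair_target=6, significance_rule=lambda x, y: True,
            sample_size=300, seed=1,
        )
        assert abs(dev.mean().mean()) < 0.02

    def test_selection_sign_pattern(self):
        post = self.make_posterior(0.35, T=12)
        dev = hs.posterior_predictive(
            post, n_draws=4, pair_target=8, significance_rule=lambda x, y: True,
            sample_size=400, seed=2,
        )
        # parental double homozygotes enriched, incompatible het/hom depleted
        assert dev["MM_MM"].mean() > 0
        assert dev["MB_MB"].mean() < 0

    def test_reproducible_given_seed(self):
        post = self.make_posterior(0.1)
        kw = dict(n_draws=2, pair_target=3, significance_rule=lambda x, y: True,
                  sample_size=100, seed=7)
        pd.testing.assert_frame_equal(
            hs.posterior_predictive(post, **kw), hs.posterior_predictive(post, **kw)
        )

    def test_impossible_rule_errors(self):
        post = self.make_posterior(0.0)
        with pytest.raises(RuntimeError, match="attempt cap"):
            hs.posterior_predictive(
                post, n_draws=1, pair_target=2,
                significance_rule=lambda x, y: False, sample_size=50, seed=3,
                max_attempts_factor=5,
            )
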