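"""Tests for free, fixed-lifetime and model-comparison decay fitting."""

import numpy as np
import pytest

from flimkit.decay import BiexpParams, DecayHistogram
from flimkit.fitting import (BiexponentialFitter, FixedTauFitter,
                             LowSignalError, compare_models, fit_fixed_tau,
                             fit_free, reduced_chi2)
from flimkit.simulate import ChannelTruth, generate_decay

from oracles import grid_search_wls


class TestFreeFit:
    def test_noiseless_recovery_all_parameters(self, config, nadh):
        hist, truth = generate_decay(nadh, 0, 1e6, config, expectation=True)
        r = fit_free(hist, config.irf, min_photons=0, seed=0)
        assert r.converged
        for got, want in [(r.params.a1, truth.a1), (r.params.a2, truth.a2),
                          (r.params.tau1, truth.tau1), (r.params.tau2, truth.tau2)]:
            assert got == pytest.approx(want, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_poisson_recovery_high_counts(self, config, nadh, seed):
        hist, truth = generate_decay(nadh, 0, 1e6, config, seed=100 + seed)
        r = fit_free(hist, config.irf, seed=seed)
        assert r.params.tau1 == pytest.approx(truth.tau1, rel=0.03)
        assert r.params.tau2 == pytest.approx(truth.tau2, rel=0.03)
        f_true = 100 * truth.a1 / (truth.a1 + truth.a2)
        assert r.fractions[0] == pytest.approx(f_true, abs=1.5)

    def test_all_zero_histogram_is_low_signal(self, config):
        h = DecayHistogram(counts=np.zeros(256, dtype=int), bin_width_ps=48.8)
        with pytest.raises(LowSignalError):
            fit_free(h, config.irf)

    def test_canonical_ordering_of_result(self, config, nadh):
        hist, _ = generate_decay(nadh, 0, 1e5, config, seed=7)
        r = fit_free(hist, config.irf, seed=7)
        assert r.params.tau1 <= r.params.tau2

    def test_permutation_of_truth_components_is_irrelevant(self, config):
        # the same physical truth written with components swapped generates
        # the same data, hence identical canonical outputs
        p = BiexpParams(a0=0, a1=2.0, a2=8.0, tau1=2.53, tau2=0.53)
        q = BiexpParams(a0=0, a1=8.0, a2=2.0, tau1=0.53, tau2=2.53)
        assert (p.a1, p.a2, p.tau1, p.tau2) == (q.a1, q.a2, q.tau1, q.tau2)

    def test_poisson_objective_runs(self, config, nadh):
        hist, truth = generate_decay(nadh, 0, 2e4, config, seed=3)
        r = fit_free(hist, config.irf, objective="poisson", seed=3)
        assert r.objective == "poisson"
        assert r.params.tau1 == pytest.approx(truth.tau1, rel=0.1)


class TestFixedTauFit:
    def test_recovers_fractions_at_true_lifetimes(self, config, nadh):
        hist, truth = generate_decay(nadh, 0, 1e6, config, seed=21)
        r = fit_fixed_tau(hist, config.irf, nadh.tau1_ns, nadh.tau2_ns)
        f_true = 100 * truth.a1 / (truth.a1 + truth.a2)
        assert r.fractions[0] == pytest.approx(f_true, abs=1.0)
        assert r.mode == "fixed_tau"
        # clamped lifetimes are bit-equal to the constants supplied
        assert r.params.tau1 == nadh.tau1_ns and r.params.tau2 == nadh.tau2_ns

    def test_pure_fast_component_yields_tiny_a2(self, config):
        truth = ChannelTruth(name="X", tau1_ns=0.53, tau2_ns=2.53,
                             a1_fraction_by_day=(1.0 - 1e-9,),
                             offset_fraction=0.0)
        hist, _ = generate_decay(truth, 0, 1e6, config, seed=5)
        r = fit_fixed_tau(hist, config.irf, 0.53, 2.53)
        assert r.fractions[1] <= 1.0

    def test_equal_fixed_lifetimes_rejected(self, config, nadh):
        hist, _ = generate_decay(nadh, 0, 1e5, config, seed=1)
        with pytest.raises(ValueError):
            fit_fixed_tau(hist, config.irf, 2.5, 2.5)

    def test_refit_at_free_fit_solution_reproduces_amplitudes(self, config, nadh):
        hist, _ = generate_decay(nadh, 0, 2e5, config, seed=8)
        free = fit_free(hist, config.irf, seed=8)
        fixed = fit_fixed_tau(hist, config.irf, free.params.tau1,
                              free.params.tau2, shift_ps=free.shift_ps,
                              fit_window=free.window)
        for got, want in [(fixed.params.a0, free.params.a0),
                          (fixed.params.a1, free.params.a1),
                          (fixed.params.a2, free.params.a2)]:
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)


class TestCompareModels:
    def test_bi_flag_raised_for_biexponential_truth(self, config, nadh):
        hist, _ = generate_decay(nadh, 0, 1e5, config, seed=31)
        cmp = compare_models(hist, config.irf, seed=31)
        assert cmp.bi_required
        assert cmp.mono.mode == "mono" and cmp.bi.mode == "free"

    def test_flag_not_raised_for_monoexponential_truth(self, config):
        truth = ChannelTruth(name="X", tau1_ns=1.3, tau2_ns=5.0,
                             a1_fraction_by_day=(1.0 - 1e-9,),
                             offset_fraction=0.002)
        hist, _ = generate_decay(truth, 0, 1e5, config, seed=32)
        cmp = compare_models(hist, config.irf, seed=32)
        assert not cmp.bi_required

    def test_nesting_chi2_bi_not_worse(self, config, nadh):
        for seed in range(3):
            hist, _ = generate_decay(nadh, 0, 1e5, config, seed=40 + seed)
            cmp = compare_models(hist, config.irf, seed=seed)
            assert cmp.bi.chi2_red <= cmp.mono.chi2_red + 0.05


class TestReducedChi2:
    def test_perfect_model_gives_zero(self):
        h = DecayHistogram(counts=np.arange(10, 40), bin_width_ps=50.0)
        assert reduced_chi2(h, h.counts.astype(float), 3) == 0.0

    def test_residual_scaling_is_quadratic(self):
        h = DecayHistogram(counts=np.full(20, 100), bin_width_ps=50.0)
        m1 = h.counts + 1.0
        m2 = h.counts + 2.0
        c1 = reduced_chi2(h, m1, 0)
        c2 = reduced_chi2(h, m2, 0)
        assert c2 == pytest.approx(4 * c1)

    def test_nonpositive_dof_rejected(self):
        h = DecayHistogram(counts=np.full(4, 10), bin_width_ps=50.0)
        with pytest.raises(ValueError):
            reduced_chi2(h, h.counts.astype(float), 4)


class TestGridOracle:
    def test_optimizer_beats_dense_grid_on_small_decays(self, small64):
        """WLS objective <= best dense (tau1, tau2) lattice objective."""
        config, decays = small64
        for hist in decays[:5]:
            window = (0, hist.n_bins)
            r = fit_free(hist, config.irf, fit_window=window, min_photons=0,
                         seed=0)
            obj_grid, *_ = grid_search_wls(hist.counts, hist.bin_width_ps,
                                           config.irf, config.irf_shift_ps)
            assert r.objective_value <= obj_grid * (1 + 1e-9)


class TestEstimatorProtocol:
    def test_fitted_attributes_and_params(self, config, nadh):
        hist, _ = generate_decay(nadh, 0, 1e5, config, seed=2)
        est = BiexponentialFitter(irf=config.irf, seed=2).fit(hist)
        assert hasattr(est, "params_") and hasattr(est, "chi2_red_")
        assert est.fractions_[0] + est.fractions_[1] == pytest.approx(100.0)
        est.set_params(n_restarts=2)
        assert est.get_params()["n_restarts"] == 2

    def test_consistency_bias_shrinks_with_photons(self, config, nadh):
        budgets = [1e4, 1e5, 1e6]
        bias2 = []
        for b in budgets:
            t2 = []
            for seed in range(15):
                hist, truth = generate_decay(nadh, 0, b, config,
                                             seed=1000 + seed)
                r = fit_free(hist, config.irf, min_photons=0, seed=seed)
                t2.append(r.params.tau2 - truth.tau2)
            bias2.append(abs(np.mean(t2)))
        # |bias| falls by decade, up to a small Monte-Carlo allowance
        assert bias2[1] <= bias2[0] + 0.02
        assert bias2[2] <= bias2[1] + 0.01
        assert bias2[2] < bias2[0]
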