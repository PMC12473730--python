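import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from neuromusc import metrics as M


class TestRFD:
    def test_linear_ramp(self):
        t = np.arange(0, 1.0, 1e-3)
        fz = np.clip(t * 5000, 0, 500)
        assert M.compute_rfd(t, fz, mass=75, onset=0.0) == pytest.approx(
            5000.0)

    def test_constant_force_is_zero(self):
        t = np.arange(0, 1.0, 1e-3)
        assert M.compute_rfd(t, np.full_like(t, 400.0), mass=75,
                             onset=0.2) == 0.0

    def test_scaling_linearity(self):
        t = np.arange(0, 1.0, 1e-3)
        fz = 200 + 300 * np.sin(3 * t)
        r1 = M.compute_rfd(t, fz, mass=75, onset=0.1)
        r2 = M.compute_rfd(t, 2 * fz, mass=75, onset=0.1)
        assert r2 == pytest.approx(2 * r1)

    def test_window_beyond_trace_raises(self):
        t = np.arange(0, 0.05, 1e-3)
        with pytest.raises(ValueError):
            M.compute_rfd(t, np.ones_like(t), mass=75, onset=0.0)

    def test_independent_two_point_recomputation(self, model,
                                                 default_experiment):
        """The trial-level RFD equals a direct two-point difference
        evaluated at the same onset."""
        tr = next(t for t in default_experiment["trials"]
                  if t.task.name == "DJ50")
        onsets = [o for o in M.all_force_onsets(tr.t, tr.grf[:, 1], 75.0)
                  if o + 0.1 <= tr.t[-1]]
        expected = max(
            (np.interp(o + 0.1, tr.t, tr.grf[:, 1])
             - np.interp(o, tr.t, tr.grf[:, 1])) / 0.1 for o in onsets)
        ms = next(m for m in default_experiment["metric_sets"]
                  if m.task == "DJ50" and m.replicate == tr.replicate)
        assert ms.rfd == pytest.approx(expected, rel=1e-12)


class TestOnset:
    def test_interpolated_threshold_crossing(self):
        t = np.arange(0, 1.0, 1e-3)
        fz = np.where(t < 0.5, 0.0, 1000.0 * (t - 0.5) / 0.01)
        onset = M.force_onset(t, fz, mass=75)
        thr = 0.05 * 75 * 9.81
        assert onset == pytest.approx(0.5 + 0.01 * thr / 1000, abs=1e-6)

    def test_fallback_to_minimum_for_loaded_traces(self):
        t = np.arange(0, 1.0, 1e-3)
        fz = 800 - 200 * np.sin(np.pi * t)
        assert M.force_onset(t, fz, mass=75) == pytest.approx(0.5, abs=1e-3)


class TestSynchrony:
    def test_identical_traces(self):
        t = np.linspace(0, 1, 200)
        a = np.sin(2 * np.pi * t) + 2
        assert M.synchrony_index(np.stack([a, a, a], 1)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair(self):
        t = np.linspace(0, 1, 200)
        a = np.sin(2 * np.pi * t)
        assert M.synchrony_index(np.stack([a, -a], 1)) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids(self):
        t = np.arange(0, 1.0, 1e-3)
        act = np.stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)], 1)
        assert abs(M.synchrony_index(act)) < 1e-6

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_positive_affine_transforms(self, scale, shift):
        rng = np.random.default_rng(0)
        act = rng.random((50, 3))
        base = M.synchrony_index(act)
        act2 = act.copy()
        act2[:, 1] = scale * act2[:, 1] + shift
        assert M.synchrony_index(act2) == pytest.approx(base, abs=1e-9)

    def test_constant_pair_excluded_with_warning(self):
        t = np.linspace(0, 1, 100)
        act = np.stack([np.sin(t), np.cos(t), np.full_like(t, 0.5)], 1)
        with pytest.warns(RuntimeWarning):
            M.synchrony_index(act)

    def test_all_constant_is_undefined(self):
        act = np.full((100, 2), 0.3)
        with pytest.raises(ValueError, match="undefined"):
            M.synchrony_index(act)

    def test_needs_two_movers_and_three_samples(self):
        with pytest.raises(ValueError):
            M.synchrony_index(np.ones((100, 1)))
        with pytest.raises(ValueError):
            M.synchrony_index(np.ones((2, 3)))


class TestMomentVariability:
    def test_identical_replicates_zero(self):
        w = np.sin(np.linspace(0, np.pi, 150)) + 2
        assert M.moment_variability([w, w, w]) == \
            pytest.approx(0.0, abs=1e-10)

    def test_planted_multiplier_set(self):
        w = np.sin(np.linspace(0, np.pi, 150)) + 2
        reps = [w * 0.95, w, w * 1.05]
        # population SD of {0.95, 1, 1.05} over mean 1 -> 4.0825%
        assert M.moment_variability(reps) == pytest.approx(4.0825, abs=1e-3)

    def test_scale_invariance(self):
        w = np.cos(np.linspace(0, 2, 120)) + 3
        reps = [w * 0.9, w * 1.02, w * 1.1]
        assert M.moment_variability(reps) == pytest.approx(
            M.moment_variability([7.3 * r for r in reps]), rel=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            M.moment_variability([np.ones(50)])


class TestSMD:
    def test_null_when_median_equals_baseline(self):
        val, robust = M.smd([1.0, 2.0, 3.0], 2.0)
        assert val == 0.0 and not robust

    def test_sign_matches_direction(self):
        up, _ = M.smd([3.0, 4.0, 5.0], 2.0)
        down, _ = M.smd([3.0, 4.0, 5.0], 6.0)
        assert up > 0 > down

    def test_scale_invariance(self, rng):
        x = rng.normal(10, 2, 50)
        a, _ = M.smd(x, 8.0)
        b, _ = M.smd(3.5 * x, 3.5 * 8.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_large_sample_normal_recovers_unit_effect(self):
        rng = np.random.default_rng(42)
        x = rng.normal(5.0 + 1.0, 1.0, 10_000)
        val, robust = M.smd(x, 5.0)
        assert val == pytest.approx(1.0, abs=0.05)
        assert not robust

    def test_skewed_sample_switches_to_robust_scale(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(0, 1.2, 500))   # strongly right-skewed
        val, robust = M.smd(x, 0.5)
        assert robust

    def test_zero_dispersion_undefined(self):
        with pytest.raises(ValueError):
            M.smd([2.0, 2.0, 2.0], 1.0)


class TestBCa:
    def test_degenerate_replicates_collapse(self):
        with pytest.warns(RuntimeWarning):
            lo, hi = M.bca_interval(np.full(10, 3.3), np.mean, seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_containment_sweep(self, rng):
        for _ in range(100):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 25)
            lo, hi = M.bca_interval(x, np.mean, B=300,
                                    seed=int(rng.integers(2**31)))
            assert lo <= np.mean(x) <= hi

    def test_forcing_corrections_recovers_percentile(self, rng):
        x = rng.normal(2, 1, 40)
        lo, hi = M.bca_interval(x, np.mean, B=500, seed=3,
                                force_z0=0.0, force_accel=0.0)
        boot = []
        r2 = np.random.default_rng(3)
        idx = r2.integers(0, 40, size=(500, 40))
        boot = np.array([x[i].mean() for i in idx])
        assert lo == pytest.approx(np.quantile(boot, 0.025), rel=1e-9)
        assert hi == pytest.approx(np.quantile(boot, 0.975), rel=1e-9)

    def test_against_scipy_reference(self, rng):
        """Independent cross-check: interval endpoints agree with
        scipy.stats.bootstrap's BCa implementation to bootstrap noise."""
        x = rng.gamma(2.0, 1.5, 40)
        lo, hi = M.bca_interval(x, np.mean, B=4000, seed=5)
        ref = sps.bootstrap((x,), np.mean, confidence_level=0.95,
                            n_resamples=4000, method="BCa",
                            random_state=np.random.default_rng(5))
        assert lo == pytest.approx(ref.confidence_interval.low, rel=0.05)
        assert hi == pytest.approx(ref.confidence_interval.high, rel=0.05)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            M.bca_interval(np.ones(3), np.mean)


class TestPeakMetrics:
    def test_mass_normalized_equal_absolute_over_75(self, model,
                                                    default_experiment):
        tr = default_experiment["trials"][0]
        ms = default_experiment["metric_sets"][0]
        c = tr.contact
        assert ms.peak_moment_hip == pytest.approx(
            np.where(c[:, None], tr.tau, 0)[:, 0].max() / 75.0, rel=1e-12)
        assert ms.peak_vgrf == pytest.approx(tr.grf[:, 1].max() / 75.0,
                                             rel=1e-12)

    def test_constant_bodyweight_trace_normalizes_to_g(self, model, tasks):
        from neuromusc.pipeline import quiet_stance_spec
        from neuromusc.optimize import solve_trajectory
        from neuromusc.tasks import generate_trial
        tr = solve_trajectory(generate_trial(quiet_stance_spec(), 0, 1,
                                             model), model)
        ms = M.peak_metrics(tr, model)
        assert ms.peak_vgrf == pytest.approx(9.81, rel=1e-2)

    def test_missing_series_named(self, model, tasks):
        from neuromusc.tasks import generate_trial
        tr = generate_trial(tasks["CMJ"], 0, 1, model)   # not solved
        with pytest.raises(ValueError, match="activations"):
            M.peak_metrics(tr, model)


class TestAdaptationProxies:
    def test_zscore_contract(self, default_experiment):
        proxies = M.adaptation_proxies(default_experiment["metric_sets"])
        for name in ("maximal_strength", "explosive", "tendon_ssc",
                     "coordination"):
            z = np.array([getattr(p, name) for p in proxies])
            assert abs(z.mean()) < 1e-10
        z = np.array([p.coordination for p in proxies])
        assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-10)

    def test_rank_order_preserved(self, default_experiment):
        msets = default_experiment["metric_sets"]
        proxies = M.adaptation_proxies(msets)
        raw = np.array([m.peak_moment_ankle for m in msets])
        rng_cols = np.array([m.loading_rate for m in msets])
        z = np.array([p.tendon_ssc for p in proxies])
        # the tendon/SSC proxy averages both constituents; check rank
        # agreement against their averaged z-scores
        zz = ((raw - raw.mean()) / raw.std(ddof=0)
              + (rng_cols - rng_cols.mean()) / rng_cols.std(ddof=0)) / 2
        assert sps.spearmanr(z, zz).statistic == pytest.approx(1.0)

    def test_perturbing_one_trial_shifts_only_its_proxy_up(self,
                                                           default_experiment):
        import copy
        msets = [copy.copy(m) for m in default_experiment["metric_sets"]]
        base = M.adaptation_proxies(msets)
        msets[5].rfd *= 2.0
        new = M.adaptation_proxies(msets)
        assert new[5].explosive > base[5].explosive
        z = np.array([p.explosive for p in new])
        assert abs(z.mean()) < 1e-10

    def test_needs_two_trials(self, default_experiment):
        with pytest.raises(ValueError):
            M.adaptation_proxies(default_experiment["metric_sets"][:1])
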