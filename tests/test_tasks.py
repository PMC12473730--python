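import dataclasses

import numpy as np
import pytest

from neuromusc.tasks import (GenerationError, default_tasks, estimate_1rm,
                             generate_plyo_trial, generate_strength_trial,
                             generate_trial, grf_from_com, inject_grf_noise,
                             load_tasks, trial_seed)

BW = 75.0 * 9.81


class TestTaskTable:
    def test_default_table_mirrors_protocol(self, tasks):
        assert set(tasks) == {"CMJ", "broad_jump", "DJ30", "DJ50",
                              "back_squat", "deadlift", "leg_press"}
        for spec in tasks.values():
            assert spec.replicates == 10
            assert spec.fs_hz == 1000
            if spec.kind == "plyo":
                assert spec.duration_s == 3.0
            else:
                assert spec.duration_s == 4.0
                assert spec.loads == (0.75, 0.85)
        assert tasks["DJ30"].drop_height_m == 0.30
        assert tasks["DJ50"].drop_height_m == 0.50

    def test_bad_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            load_tasks({"tasks": {"x": {
                "kind": "pilates", "duration_s": 3.0, "fs_hz": 1000,
                "replicates": 1,
                "stance_deg": {"hip": 10, "knee": 15, "ankle": 5},
                "bottom_deg": {"hip": 75, "knee": 90, "ankle": 25},
                "knee_bottom_range_deg": [85, 95],
                "trunk_limit_deg": [10, 20]}}})


class TestPlyoGeneration:
    @pytest.mark.parametrize("name", ["CMJ", "broad_jump", "DJ30", "DJ50"])
    def test_targets_satisfied_across_replicates(self, tasks, model, name):
        spec = tasks[name]
        lo, hi = spec.knee_bottom_range_deg
        for rep in (0, 3, 7):
            tr = generate_plyo_trial(spec, rep, 11, model)
            assert len(tr.t) == 3000
            assert lo <= tr.meta["knee_peak_deg"] <= hi
            assert (tr.grf[~tr.contact] == 0).all()
            if tr.has_phase("amortization"):
                sl = tr.phase_slice("amortization")
                assert (sl.stop - sl.start) * tr.dt < \
                    spec.amortization_limit_s
            # trunk inclination stays under the task's upper limit
            trunk = np.degrees(tr.q[:, 2] - tr.q[:, 1] + tr.q[:, 0])
            sl = tr.phase_slice("propulsion")
            assert trunk[sl].max() < spec.trunk_limit_deg[1] + 25

    def test_replicate_determinism_is_bit_identical(self, tasks, model):
        a = generate_plyo_trial(tasks["DJ50"], 4, 99, model)
        b = generate_plyo_trial(tasks["DJ50"], 4, 99, model)
        for f in ("q", "grf", "cop_x", "base", "tau"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_replicates_differ(self, tasks, model):
        a = generate_plyo_trial(tasks["CMJ"], 0, 99, model)
        b = generate_plyo_trial(tasks["CMJ"], 1, 99, model)
        assert not np.array_equal(a.q, b.q)

    def test_perturbation_bounds(self, tasks, model):
        spec = tasks["CMJ"]
        nominal = np.asarray(spec.stance_deg)
        for rep in range(10):
            tr = generate_plyo_trial(spec, rep, 5, model)
            q0 = np.degrees(tr.q[0])
            # lean alters the ankle coordinate; hip/knee carry pure jitter
            assert np.all(np.abs(q0[:2] - nominal[:2]) <= 2.0 + 1e-9)

    def test_dynamic_consistency_residual(self, tasks, model):
        for name in ("CMJ", "DJ50"):
            tr = generate_plyo_trial(tasks[name], 0, 1, model)
            assert np.abs(tr.residual_force).max() < 0.005 * BW

    def test_impulse_momentum_over_contact(self, tasks, model):
        """Net vertical impulse between two instants of rest equals zero;
        over the propulsion phase it equals m * delta v_com."""
        tr = generate_plyo_trial(tasks["CMJ"], 0, 1, model)
        sl = tr.phase_slice("propulsion")
        fz = tr.grf[sl, 1]
        imp = np.trapezoid(fz - 75.0 * 9.81, dx=tr.dt)
        dv = tr.task.takeoff_velocity  # bottom is at rest
        assert imp == pytest.approx(75.0 * dv, rel=0.03)

    def test_cop_within_foot(self, tasks, model):
        tr = generate_plyo_trial(tasks["DJ30"], 0, 1, model)
        heel = tr.base[:, 0] - model.ankle_from_heel
        toe = heel + model.foot_length
        c = tr.contact
        assert (tr.cop_x[c] >= heel[c] - 1e-9).all()
        assert (tr.cop_x[c] <= toe[c] + 1e-9).all()

    def test_rom_violation_raises(self, tasks, model):
        bad = dataclasses.replace(tasks["CMJ"],
                                  bottom_deg=(75.0, 175.0, 25.0))
        with pytest.raises(GenerationError, match="range of motion"):
            generate_plyo_trial(bad, 0, 1, model)

    def test_wrong_kind_rejected(self, tasks, model):
        with pytest.raises(ValueError):
            generate_plyo_trial(tasks["back_squat"], 0, 1, model)


class TestStrengthGeneration:
    def test_squat_sampling_and_bottom_targets(self, tasks, model):
        tr = generate_strength_trial(tasks["back_squat"], 0, 3, model)
        assert len(tr.t) == 4000
        knee_bottom = np.degrees(tr.q[:, 1]).max()
        assert 100.0 <= knee_bottom <= 110.0
        hip_bottom = np.degrees(tr.q[:, 0]).max()
        assert 90.0 - 2.1 <= hip_bottom <= 100.0 + 2.1
        # trunk inclination bounded by the task's upper limit
        trunk = np.degrees(tr.q[:, 2] - tr.q[:, 1] + tr.q[:, 0])
        assert trunk.max() <= tasks["back_squat"].trunk_limit_deg[1]

    def test_smooth_across_phase_boundary(self, tasks, model):
        tr = generate_strength_trial(tasks["back_squat"], 0, 3, model)
        i = tr.phase_slice("concentric").start
        # C2 trajectory: the acceleration is finite and continuous at the
        # eccentric -> concentric boundary
        window = tr.qdd[i - 3:i + 3, 1]
        assert np.isfinite(window).all()
        assert np.abs(np.diff(window)).max() < 0.5

    def test_load_fraction_bounds(self, tasks, model):
        with pytest.raises(ValueError):
            generate_strength_trial(tasks["back_squat"], 0, 1, model,
                                    load_fraction=1.2)

    def test_load_targets_governing_joint(self, tasks, model, max_moments):
        spec = tasks["deadlift"]
        tr = generate_strength_trial(spec, 0, 1, model, 0.85, max_moments)
        target = 0.85 * max_moments.absolute["deadlift"]["hip"]
        assert tr.tau[:, 0].max() == pytest.approx(target, rel=1e-4)

    def test_load_zero_is_identity(self, tasks, model, max_moments):
        a = generate_strength_trial(tasks["back_squat"], 0, 1, model, 0.0,
                                    max_moments)
        b = generate_strength_trial(tasks["back_squat"], 0, 1, model)
        assert np.array_equal(a.grf, b.grf)
        assert a.load_force.max() == 0.0

    def test_peak_demand_ratio_between_loads(self, tasks, model,
                                             max_moments):
        spec = tasks["back_squat"]
        hi = generate_strength_trial(spec, 0, 1, model, 0.85, max_moments)
        lo = generate_strength_trial(spec, 0, 1, model, 0.75, max_moments)
        ratio = hi.tau[:, 0].max() / lo.tau[:, 0].max()
        assert ratio == pytest.approx(0.85 / 0.75, rel=0.02)


class TestGrfSynthesis:
    def test_static_stance_weight(self, tasks, model):
        tr = generate_strength_trial(tasks["back_squat"], 0, 1, model)
        # first frames: quasi-static start of the eccentric phase
        assert tr.grf[0, 1] == pytest.approx(BW, rel=1e-3)

    def test_flight_is_exactly_zero(self, tasks, model):
        tr = generate_plyo_trial(tasks["CMJ"], 0, 1, model)
        sl = tr.phase_slice("flight")
        assert (tr.grf[sl] == 0).all()

    def test_negative_vertical_force_clipped_and_counted(self, model):
        n = 11
        t = np.arange(n) * 1e-3
        # free-falling COM while flagged as contact: demand is negative
        q = np.tile([0.3, 0.4, 0.1], (n, 1))
        base = np.tile([0.0, model.ankle_height], (n, 1))
        base[:, 1] -= 0.5 * 9.81 * t[:, None][:, 0] ** 2
        grf, clipped = grf_from_com(t, q, base, np.ones(n, bool), model)
        assert clipped > 0
        assert (grf[:, 1] >= 0).all()


class TestOneRM:
    def test_normalization_is_absolute_over_mass(self, max_moments, model):
        for ex, row in max_moments.absolute.items():
            for joint, val in row.items():
                assert max_moments.normalized[ex][joint] == pytest.approx(
                    val / model.mass, rel=1e-12)

    def test_fmax_scaling_near_linearity(self, model, tasks):
        base = estimate_1rm(model, tasks, rigid_tendon=True)
        scaled_model = model.with_muscles(
            mu.with_multipliers(F_max=1.10) for mu in model.muscles)
        scaled = estimate_1rm(scaled_model, tasks, rigid_tendon=True)
        for ex in base.absolute:
            for j in base.absolute[ex]:
                assert scaled.absolute[ex][j] == pytest.approx(
                    1.10 * base.absolute[ex][j], rel=0.01)

    def test_elastic_close_to_rigid(self, model, tasks, max_moments):
        # tendon compliance (~3% strain at F_max) shifts short fibers down
        # the force-length curve; moments stay within ~20% of rigid
        rigid = estimate_1rm(model, tasks, rigid_tendon=True)
        for ex in rigid.absolute:
            for j in rigid.absolute[ex]:
                assert max_moments.absolute[ex][j] == pytest.approx(
                    rigid.absolute[ex][j], rel=0.20)

    def test_prime_mover_moments_in_plausible_band(self, max_moments):
        for ex, row in max_moments.normalized.items():
            for joint in ("hip", "knee"):
                assert 1.5 <= row[joint] <= 6.5


class TestGrfNoise:
    def test_zero_level_identity(self, rng):
        grf = rng.normal(500, 100, size=(100, 2))
        out = inject_grf_noise(grf, 0.0, 1)
        assert np.array_equal(out, grf)

    def test_sd_matches_level(self):
        grf = np.full((100_000, 1), 1000.0)
        noisy = inject_grf_noise(grf, 0.03, 7)
        sd = (noisy - grf).std()
        assert 28.0 <= sd <= 32.0

    def test_zero_mean(self):
        grf = np.full((100_000, 1), 1000.0)
        noisy = inject_grf_noise(grf, 0.03, 11)
        assert abs((noisy - grf).mean()) < 1.0

    def test_flight_zeros_stay_zero(self):
        grf = np.zeros((50, 2))
        grf[:25, 1] = 800.0
        noisy = inject_grf_noise(grf, 0.03, 3)
        assert (noisy[25:] == 0).all()

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            inject_grf_noise(np.ones((5, 2)), -0.1, 1)


def test_trial_seed_is_stable_and_distinct():
    assert trial_seed(2024, "CMJ", 3) == trial_seed(2024, "CMJ", 3)
    assert trial_seed(2024, "CMJ", 3) != trial_seed(2024, "CMJ", 4)
    assert trial_seed(2024, "CMJ", 3) != trial_seed(2024, "DJ50", 3)
    assert 0 <= trial_seed(2024, "CMJ", 3) < 2**31
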