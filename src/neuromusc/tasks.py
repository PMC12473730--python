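"""Synthetic task generator: dynamically consistent jump and lift trials.

Each trial is built from a one-parameter *posture path* — a straight line
in joint space between a stance posture and the task's bottom posture —
plus a whole-body lean degree of freedom (a rotation about the ankle).
During ground contact the whole-body centre of mass is prescribed as a
C2-to-C3 piecewise-polynomial trajectory (vertical and, for the broad
jump, horizontal), and the path parameter and lean are solved per frame so
the chain's COM follows it exactly. Flight phases are ballistic with the
posture held, so the ground reaction force computed from COM dynamics is
consistent with the kinematics by construction: applying inverse dynamics
to a generated trial leaves a residual trunk force at numerical-roundoff
level.

Replicate-level stochastic perturbations: initial joint angles +-2 deg
(uniform), phase timings +-5%, and for strength trials a +-5% jitter on
the optimizer's initial activation guess. The (task, replicate, seed)
triple fully determines a trial.
"""

from __future__ import annotations

import importlib.resources
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .body import JOINTS, ScaledModel, moment_arm_matrix, musculotendon_lengths
from .dynamics import (chain_kinematics, com_position,
                       inverse_dynamics, second_derivative)
from .muscle import mt_equilibrium, rigid_fiber_length, fiber_force, _cos_pennation
from .trajectory import PhasePlan, poly_bc, quintic_eval

__all__ = [
    "GenerationError", "TaskSpec", "TrialRecord", "MaxMomentTable",
    "load_tasks", "default_tasks", "trial_seed",
    "generate_plyo_trial", "generate_strength_trial", "generate_trial",
    "grf_from_com", "estimate_1rm", "apply_external_load", "inject_grf_noise",
]

FLIGHT_PHASES = ("fall", "flight")


class GenerationError(RuntimeError):
    """A task specification could not be realised as a consistent trial."""


@dataclass(frozen=True)
class TaskSpec:
    """Kinematic and timing targets of one task (one row of the shipped
    task table)."""

    name: str
    kind: str                          # 'plyo' | 'strength'
    duration_s: float
    fs_hz: float
    replicates: int
    stance_deg: tuple[float, float, float]   # (hip, knee, ankle)
    bottom_deg: tuple[float, float, float]
    knee_bottom_range_deg: tuple[float, float]
    trunk_limit_deg: tuple[float, float]
    # plyometric fields
    drop_height_m: float = 0.0
    takeoff_velocity: float = 0.0      # vertical COM velocity at take-off, m/s
    horizontal_velocity: float = 0.0   # broad jump forward take-off velocity
    quiet_s: float = 0.45
    descent_s: float = 0.70
    platform_s: float = 0.40
    amortization_limit_s: float = 0.2
    # strength fields
    eccentric_s: float = 2.0
    concentric_s: float = 2.0
    loads: tuple[float, ...] = (0.75, 0.85)
    default_load: float = 0.85
    governing_joint: str = "knee"
    posture_1rm_deg: tuple[float, float, float] = (60.0, 90.0, 15.0)
    # path extremes (fractions of the stance->bottom line)
    s_takeoff: float = 0.12
    s_platform: float = 0.12
    s_preland: float = 0.25
    s_land: float = 0.85
    s_rest: float = 0.10

    def __post_init__(self):
        if self.kind not in ("plyo", "strength"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sampling rate must be integral")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class TrialRecord:
    """One simulated repetition with all its traces on a common time base."""

    task: TaskSpec
    replicate: int
    seed: int
    t: np.ndarray             # (n,)
    q: np.ndarray             # (n, 3) joint angles (hip, knee, ankle), rad
    qd: np.ndarray
    qdd: np.ndarray
    base: np.ndarray          # (n, 2) ankle trajectory
    grf: np.ndarray           # (n, 2) total GRF (Fx, Fz), N
    cop_x: np.ndarray         # (n,)
    contact: np.ndarray       # (n,) bool
    phase_labels: np.ndarray  # (n,) str
    phases: list              # [(name, i0, i1)]
    load_force: np.ndarray    # (n,) external vertical load magnitude, N
    ext_line_x: float         # x of the load's vertical line of action
    tau: np.ndarray           # (n, 3) per-leg net joint moments, Nm
    residual_force: np.ndarray  # (n, 2) HAT residual from the ID audit
    load_fraction: float = 0.0
    activations: np.ndarray | None = None   # (n, n_muscles)
    fiber_lengths: np.ndarray | None = None
    reserves: np.ndarray | None = None      # (n, 3) per-leg reserve torques
    solver_flags: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def phase_slice(self, name: str) -> slice:
        for pname, s0, s1 in self.phases:
            if pname == name:
                return slice(s0, s1)
        raise KeyError(name)

    def has_phase(self, name: str) -> bool:
        return any(p == name for p, _, _ in self.phases)


@dataclass
class MaxMomentTable:
    """Maximal feasible joint moments per exercise (the 1RM reference)."""

    posture_deg: dict[str, tuple[float, float, float]]
    absolute: dict[str, dict[str, float]]     # exercise -> joint -> Nm (per leg)
    normalized: dict[str, dict[str, float]]   # exercise -> joint -> Nm/kg
    mass: float


# ---------------------------------------------------------------------------
# task table


def load_tasks(source) -> dict[str, TaskSpec]:
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    out = {}
    for name, c in cfg["tasks"].items():
        c = dict(c)
        for key in ("stance_deg", "bottom_deg", "posture_1rm_deg"):
            if key in c:
                d = c[key]
                c[key] = (float(d["hip"]), float(d["knee"]), float(d["ankle"]))
        for key in ("knee_bottom_range_deg", "trunk_limit_deg", "loads"):
            if key in c:
                c[key] = tuple(float(v) for v in c[key])
        out[name] = TaskSpec(name=name, **c)
    return out


def default_tasks() -> dict[str, TaskSpec]:
    ref = importlib.resources.files("neuromusc.data") / "tasks_default.yaml"
    with ref.open() as fh:
        return load_tasks(fh)


def trial_seed(seed: int, task_name: str, replicate: int) -> int:
    """Stable per-trial child seed from (experiment seed, task, replicate)."""
    tag = zlib.crc32(task_name.encode()) & 0xFFFF
    ss = np.random.SeedSequence([int(seed), tag, int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# posture path machinery


class _PosturePath:
    """Straight joint-space line q(s) = P0 + s (P1 - P0), rad, with its
    COM-height profile and inverse."""

    def __init__(self, p0_rad, p1_rad, model: ScaledModel,
                 s_lo: float = -0.12, s_hi: float = 1.30):
        self.p0 = np.asarray(p0_rad, dtype=float)
        self.dp = np.asarray(p1_rad, dtype=float) - self.p0
        self.model = model
        s_grid = np.linspace(s_lo, s_hi, 601)
        com = com_position(self.q_of_s(s_grid), model)
        z = com[:, 1]
        if np.any(np.diff(z) >= 0):
            raise GenerationError(
                "COM height is not monotone along the posture path")
        self._z_of_s = CubicSpline(s_grid, z)
        self._s_of_z = CubicSpline(z[::-1], s_grid[::-1])
        self._x_of_s = CubicSpline(s_grid, com[:, 0])
        self.s_lo, self.s_hi = s_lo, s_hi

    def q_of_s(self, s, lean=0.0):
        s = np.asarray(s, dtype=float)
        q = self.p0 + np.multiply.outer(s, self.dp)
        q[..., 2] = q[..., 2] + lean       # lean rotates the whole body
        return q

    def z_of_s(self, s):
        return self._z_of_s(s)

    def s_of_z(self, z):
        return self._s_of_z(z)

    def x_of_s(self, s):
        return self._x_of_s(s)


def _solve_path_frames(path: _PosturePath, x_star, z_star, base,
                       s_init, model: ScaledModel, tol=1e-10, max_iter=60):
    """Solve (s, lean) per frame so the chain COM tracks (x*, z*)."""
    n = len(z_star)
    s = np.array(s_init, dtype=float)
    lean = np.zeros(n)
    eps = 1e-6
    t_dummy = np.zeros(n)

    def com(s_v, lean_v):
        q = path.q_of_s(s_v, lean_v)
        kin = chain_kinematics(t_dummy, q, model, base=base)
        return kin.com

    for _ in range(max_iter):
        c = com(s, lean)
        fx = c[:, 0] - x_star
        fz = c[:, 1] - z_star
        err = np.maximum(np.abs(fx), np.abs(fz))
        if err.max() < tol:
            break
        cs = com(s + eps, lean)
        cl = com(s, lean + eps)
        j11 = (cs[:, 0] - c[:, 0]) / eps   # dx/ds
        j12 = (cl[:, 0] - c[:, 0]) / eps   # dx/dlean
        j21 = (cs[:, 1] - c[:, 1]) / eps   # dz/ds
        j22 = (cl[:, 1] - c[:, 1]) / eps
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-12, np.sign(det + 1e-30) * 1e-12, det)
        ds = (j22 * fx - j12 * fz) / det
        dl = (-j21 * fx + j11 * fz) / det
        biggest = np.maximum(np.abs(ds), np.abs(dl))
        scale = np.minimum(1.0, 0.2 / np.maximum(biggest, 1e-12))  # damped
        s = s - ds * scale
        lean = lean - dl * scale
    else:
        raise GenerationError("COM tracking did not converge "
                              f"(max error {err.max():.2e} m)")
    return s, lean


# ---------------------------------------------------------------------------
# phase-wise COM prescription


class _ComPlan:
    """Piecewise-polynomial COM prescription built phase by phase.

    Stores the analytic second derivatives alongside positions: the
    contact GRF is computed from these exact accelerations, so it does
    not inherit finite-difference noise from high-snap phases.
    """

    def __init__(self, n, dt):
        self.n, self.dt = n, dt
        self.z = np.empty(n)
        self.x = np.empty(n)
        self.z_acc = np.zeros(n)
        self.x_acc = np.zeros(n)
        self.contact = np.zeros(n, dtype=bool)
        self.base_z = np.zeros(n)

    def fill_poly(self, sl: slice, z_coef, x_coef, contact, base_z=0.0):
        tau = (np.arange(sl.stop - sl.start)) * self.dt
        self.z[sl] = quintic_eval(z_coef, tau)
        self.x[sl] = quintic_eval(x_coef, tau)
        self.z_acc[sl] = quintic_eval(z_coef, tau, deriv=2)
        self.x_acc[sl] = quintic_eval(x_coef, tau, deriv=2)
        self.contact[sl] = contact
        self.base_z[sl] = base_z

    def fill_ballistic(self, sl: slice, z0, vz0, x0, vx0, g):
        tau = (np.arange(sl.stop - sl.start)) * self.dt
        self.z[sl] = z0 + vz0 * tau - 0.5 * g * tau**2
        self.x[sl] = x0 + vx0 * tau
        self.z_acc[sl] = -g
        self.x_acc[sl] = 0.0
        self.contact[sl] = False


def _quantize(d, quantum=0.002):
    return max(round(d / quantum) * quantum, quantum)


def _jitter_angles(rng, deg_tuple, amount_deg=2.0):
    return tuple(v + rng.uniform(-amount_deg, amount_deg) for v in deg_tuple)


def _jitter_time(rng, t, frac=0.05):
    return t * rng.uniform(1.0 - frac, 1.0 + frac)


# ---------------------------------------------------------------------------
# generators


def generate_plyo_trial(spec: TaskSpec, replicate: int, seed: int,
                        model: ScaledModel, dt: float | None = None,
                        contact_stiffness: float = 1.0) -> TrialRecord:
    """Generate one plyometric trial (CMJ, broad jump, or drop jump).

    ``contact_stiffness`` scales the foot-ground interaction: amortization
    and landing-absorption times scale with 1/sqrt(k) (spring-mass
    contact), so stiffer contact gives shorter, harder decelerations.
    """
    if spec.kind != "plyo":
        raise ValueError(f"{spec.name} is not a plyometric task")
    return _generate_jump(spec, replicate, seed, model, dt,
                          contact_stiffness)


def generate_strength_trial(spec: TaskSpec, replicate: int, seed: int,
                            model: ScaledModel,
                            load_fraction: float | None = None,
                            max_moments: MaxMomentTable | None = None,
                            dt: float | None = None) -> TrialRecord:
    """Generate one strength-trial repetition (eccentric then concentric).

    When ``max_moments`` is given, the external load is applied so the
    peak moment demand at the governing joint equals
    ``load_fraction x maximal feasible moment``.
    """
    if spec.kind != "strength":
        raise ValueError(f"{spec.name} is not a strength task")
    if load_fraction is None:
        load_fraction = spec.default_load
    if not 0 <= load_fraction <= 1:
        raise ValueError("load_fraction must lie in [0, 1]")
    dt = 1.0 / spec.fs_hz if dt is None else dt
    n = int(round(spec.duration_s / dt))
    tseed = trial_seed(seed, spec.name, replicate)
    rng = np.random.default_rng(tseed)

    stance = _jitter_angles(rng, spec.stance_deg)
    p0 = np.radians(stance)
    p1 = np.radians(spec.bottom_deg)
    _check_rom(spec, p1)
    ecc = _quantize(_jitter_time(rng, spec.eccentric_s))
    con = spec.duration_s - ecc

    t = np.arange(n) * dt
    plan = PhasePlan(n, dt, [("eccentric", ecc), ("concentric", con)])
    s = np.empty(n)
    for name, lo, hi in plan.bounds:
        tau = (np.arange(hi - lo)) * dt
        T = (hi - lo) * dt
        if name == "eccentric":
            coef = poly_bc(T, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
        else:
            coef = poly_bc(T, (1.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        s[lo:hi] = quintic_eval(coef, tau)

    q = p0 + np.multiply.outer(s, (p1 - p0))
    base = np.tile([0.0, model.ankle_height], (n, 1))
    contact = np.ones(n, dtype=bool)
    midfoot_x = model.midfoot_offset()

    record = _assemble_record(
        spec, replicate, tseed, t, q, base, contact, plan, model,
        load=np.zeros(n), ext_line_x=midfoot_x, cop_mode="midfoot")
    record.load_fraction = 0.0
    record.meta["activation_jitter"] = float(rng.uniform(0.95, 1.05))

    if max_moments is not None and load_fraction > 0:
        record = apply_external_load(record, load_fraction, max_moments, model)
    return record


def generate_trial(spec: TaskSpec, replicate: int, seed: int,
                   model: ScaledModel, max_moments: MaxMomentTable | None = None,
                   load_fraction: float | None = None,
                   dt: float | None = None,
                   contact_stiffness: float = 1.0) -> TrialRecord:
    """Dispatch on task kind."""
    if spec.kind == "plyo":
        return generate_plyo_trial(spec, replicate, seed, model, dt=dt,
                                   contact_stiffness=contact_stiffness)
    return generate_strength_trial(spec, replicate, seed, model,
                                   load_fraction=load_fraction,
                                   max_moments=max_moments, dt=dt)


def _check_rom(spec: TaskSpec, p_rad, lo_deg=-25.0, hi_deg=160.0):
    deg = np.degrees(p_rad)
    if np.any(deg < lo_deg) or np.any(deg > hi_deg):
        joint = JOINTS[int(np.argmax((deg < lo_deg) | (deg > hi_deg)))]
        raise GenerationError(
            f"{spec.name}: bottom target for {joint} ({deg}) outside "
            f"range of motion [{lo_deg}, {hi_deg}] deg")


def _generate_jump(spec: TaskSpec, replicate: int, seed: int,
                   model: ScaledModel, dt: float | None,
                   contact_stiffness: float = 1.0) -> TrialRecord:
    dt = 1.0 / spec.fs_hz if dt is None else dt
    n = int(round(spec.duration_s / dt))
    g = model.gravity
    tseed = trial_seed(seed, spec.name, replicate)
    rng = np.random.default_rng(tseed)

    stance = _jitter_angles(rng, spec.stance_deg)
    p0 = np.radians(stance)
    p1 = np.radians(spec.bottom_deg)
    _check_rom(spec, p1)
    path = _PosturePath(p0, p1, model)

    z_stand = float(path.z_of_s(0.0))
    z_bottom = float(path.z_of_s(1.0))
    z_to = float(path.z_of_s(spec.s_takeoff))
    z_land = float(path.z_of_s(spec.s_land))
    z_pre = float(path.z_of_s(spec.s_preland))
    z_plat = float(path.z_of_s(spec.s_platform))
    z_rest = float(path.z_of_s(spec.s_rest))
    x0 = float(path.x_of_s(0.0))
    v_to = spec.takeoff_velocity
    vx_to = spec.horizontal_velocity

    is_dj = spec.drop_height_m > 0
    jit = {k: rng.uniform(0.95, 1.05) for k in ("p1", "p2", "amort", "prop")}
    jit["amort"] /= math.sqrt(contact_stiffness)

    def com_sl(s, lean):
        return com_position(path.q_of_s(np.array([s]), lean), model)

    lean_to = 0.0
    if vx_to:
        # the forward take-off COM shift is produced by a whole-body lean;
        # iterate propulsion time -> forward target -> lean -> take-off z
        for _ in range(4):
            t_prop = jit["prop"] * 1.9 * (z_to - z_bottom) / v_to
            x_to_target = x0 + 0.5 * vx_to * t_prop
            lean_to = brentq(
                lambda L: com_sl(spec.s_takeoff, L)[0] - x_to_target,
                -0.3, 1.0)
            z_to = float(com_sl(spec.s_takeoff, lean_to)[1])
        z_pre = float(com_sl(spec.s_preland, lean_to)[1])
        z_land = float(com_sl(spec.s_land, lean_to)[1])
        z_rest = float(com_sl(spec.s_rest, lean_to)[1])

    phases: list[tuple[str, float]] = []
    t_stepoff = 0.10
    if is_dj:
        # step off the platform with a jerk-limited unloading ramp, then
        # free fall; the touchdown velocity follows from the full COM drop
        # (platform height + posture change)
        v_td = math.sqrt(2 * g * (spec.drop_height_m + z_plat - z_pre))
        v_so = 0.5 * g * t_stepoff
        t_fall = (v_td - v_so) / g
        # amortization duration is a property of leg stiffness, not of
        # drop height (spring-mass contact), so it is a fixed setting;
        # deeper drops decelerate harder over the same interval
        t_amort = jit["amort"] * 0.11

        t_prop = jit["prop"] * 1.9 * (z_to - z_bottom) / v_to
        phases += [("platform", jit["p1"] * spec.platform_s),
                   ("stepoff", t_stepoff),
                   ("fall", t_fall), ("amortization", t_amort),
                   ("propulsion", t_prop)]
    else:
        t_prop = jit["prop"] * 1.9 * (z_to - z_bottom) / v_to
        phases += [("quiet", jit["p1"] * spec.quiet_s),
                   ("descent", jit["p2"] * spec.descent_s),
                   ("propulsion", t_prop)]
    # flight ends at the (lower) pre-landing posture height
    v_land = math.sqrt(v_to**2 + 2 * g * (z_to - z_pre))
    t_flight = (v_to + v_land) / g
    t_absorb = jit["amort"] * 1.9 * (z_pre - z_land) / v_land
    phases += [("flight", t_flight), ("absorb", t_absorb),
               ("stabilize", 0.0)]  # stabilize absorbs the remainder
    # quantize phase durations to a 2 ms grid so that regenerating the
    # trial at any sampling step in {0.0005, 0.001, 0.002} s yields the
    # same phase boundaries (numerical-convergence audits compare grids)
    phases = [(nm, _quantize(d)) if nm != "stabilize" else (nm, d)
              for nm, d in phases]
    used = sum(d for _, d in phases)
    if used > spec.duration_s:
        raise GenerationError(f"{spec.name}: phases ({used:.2f} s) exceed "
                              f"trial duration {spec.duration_s} s")
    plan = PhasePlan(n, dt, phases)

    t = np.arange(n) * dt
    plan_com = _ComPlan(n, dt)
    s_init = np.zeros(n)
    base_x_pred = {"amortization":
                   x0 - float(com_sl(spec.s_preland, 0.0)[0])}

    x_cursor = x0
    for name, lo, hi in plan.bounds:
        sl = slice(lo, hi)
        T = (hi - lo) * dt
        if T <= 0:
            continue
        if name == "platform":
            plan_com.fill_poly(sl, np.array([z_plat + spec.drop_height_m]),
                               np.array([x0]), True,
                               base_z=spec.drop_height_m)
            s_init[sl] = spec.s_platform
        elif name == "stepoff":
            # smoothstep unloading: acceleration ramps 0 -> -g with zero
            # jerk at both ends (GRF fades smoothly into free fall)
            z0_so = z_plat + spec.drop_height_m
            zc = np.array([z0_so, 0.0, 0.0, 0.0,
                           -g / (4.0 * T**2), g / (10.0 * T**3)])
            plan_com.fill_poly(sl, zc, np.array([x0]), True,
                               base_z=spec.drop_height_m)
            s_init[sl] = spec.s_platform
            z_entry = z0_so - 0.15 * g * T**2
            v_entry = -0.5 * g * T
        elif name == "fall":
            plan_com.fill_ballistic(sl, z_entry, v_entry, x0, 0.0, g)
            # entry state of the next phase: ballistic at the snapped
            # boundary time (phase durations are snapped to whole samples)
            z_entry = z_entry + v_entry * T - 0.5 * g * T**2
            v_entry = v_entry - g * T
        elif name == "quiet":
            plan_com.fill_poly(sl, np.array([z_stand]), np.array([x0]), True)
        elif name == "descent":
            zc = poly_bc(T, (z_stand, 0, 0), (z_bottom, 0, 0))
            plan_com.fill_poly(sl, zc, np.array([x0]), True)
            s_init[sl] = np.linspace(0, 1, hi - lo)
        elif name == "amortization":
            zc = poly_bc(T, (z_entry, v_entry, -g, 0.0), (z_bottom, 0, 0))
            plan_com.fill_poly(sl, zc, np.array([x0]), True)
            s_init[sl] = np.linspace(spec.s_preland, 1, hi - lo)
        elif name == "propulsion":
            zc = poly_bc(T, (z_bottom, 0, 0), (z_to, v_to, -g, 0.0))
            if vx_to:
                xc = poly_bc(T, (x0, 0, 0, 0.0),
                             (x0 + 0.5 * vx_to * T, vx_to, 0, 0.0))
                x_cursor = x0 + 0.5 * vx_to * T
            else:
                xc = np.array([x0])
            plan_com.fill_poly(sl, zc, xc, True)
            s_init[sl] = np.linspace(1, spec.s_takeoff, hi - lo)
        elif name == "flight":
            plan_com.fill_ballistic(sl, z_to, v_to, x_cursor, vx_to, g)
            z_entry = z_to + v_to * T - 0.5 * g * T**2
            v_entry = v_to - g * T
            x_cursor = x_cursor + vx_to * T
        elif name == "absorb":
            x_td = x_cursor
            if vx_to:
                x_end = x_td + 0.45 * vx_to * T
                xc = poly_bc(T, (x_td, vx_to, 0, 0.0), (x_end, 0, 0))
            else:
                x_end = x_td
                xc = np.array([x_td])
            # plant the foot where the COM will come to rest (a forward
            # landing arrives leaning back and rides over the foot)
            base_x_pred["absorb"] = x_end - float(
                com_sl(spec.s_land, 0.0)[0])
            lean_land = brentq(
                lambda L: com_sl(spec.s_land, L)[0]
                + base_x_pred["absorb"] - x_end, -0.4, 1.2)
            z_land = float(com_sl(spec.s_land, lean_land)[1])
            zc = poly_bc(T, (z_entry, v_entry, -g, 0.0), (z_land, 0, 0))
            plan_com.fill_poly(sl, zc, xc, True)
            s_init[sl] = np.linspace(spec.s_preland, spec.s_land, hi - lo)
            x_cursor = x_end
        elif name == "stabilize":
            T_set = min(T, 0.6)
            lean_end = brentq(
                lambda L: com_sl(spec.s_rest, L)[0]
                + base_x_pred.get("absorb", 0.0) - x_cursor, -0.4, 1.2)
            z_rest = float(com_sl(spec.s_rest, lean_end)[1])
            zc = poly_bc(T_set, (z_land, 0, 0), (z_rest, 0, 0))
            tau_loc = np.minimum(np.arange(hi - lo) * dt, T_set)
            plan_com.z[sl] = quintic_eval(zc, tau_loc)
            plan_com.z_acc[sl] = np.where(
                np.arange(hi - lo) * dt < T_set,
                quintic_eval(zc, tau_loc, deriv=2), 0.0)
            plan_com.x[sl] = x_cursor
            plan_com.x_acc[sl] = 0.0
            plan_com.contact[sl] = True
            s_init[sl] = spec.s_land

    # --- pass 1: solve (s, lean) on contact phases, in time order ---
    base = np.tile([0.0, model.ankle_height], (n, 1))
    base[:, 1] += plan_com.base_z
    q = np.empty((n, 3))
    contact = plan_com.contact
    crossed_flight = False

    for name, lo, hi in plan.bounds:
        sl = slice(lo, hi)
        if hi <= lo:
            continue
        if name in FLIGHT_PHASES:
            crossed_flight = True
            continue
        if crossed_flight:
            base[lo:, 0] = base_x_pred.get(name, base[lo - 1, 0])
            crossed_flight = False
        s_sol, lean_sol = _solve_path_frames(
            path, plan_com.x[sl], plan_com.z[sl], base[sl], s_init[sl], model)
        q[sl] = path.q_of_s(s_sol, lean_sol)

    # --- pass 2: fill airborne joint angles ---
    # Each airborne channel follows a three-segment profile: parabolic
    # stop of the boundary rate, zero-slope smoothstep bridge, parabolic
    # re-acceleration into the landing boundary rate (C1, velocity-matched
    # at both contact boundaries). Knee and ankle are interpolated in
    # joint space (small segment inertias; anatomical floors respected by
    # sizing the stop segment), while the trunk is interpolated as its
    # *absolute* lean angle, which changes slowly in the air — this keeps
    # swing-phase hip moments physiological. Hip flexion is recovered from
    # the trunk and distal angles.
    def _three_segment(T, tau_f, y0, yd0, y1, yd1, floor, tc_min=0.05,
                       ta_cap=0.12):
        if abs(yd0) < 1e-9:
            Ta = 0.0
        elif yd0 < 0 and floor is not None:
            Ta = min(0.30 * T, max(0.02, 2 * (floor - y0) / yd0))
        else:
            Ta = min(0.30 * T, ta_cap)
        y_stop = y0 + 0.5 * yd0 * Ta
        if abs(yd1) < 1e-9:
            Tc, y_hold = 0.0, y_stop
        else:
            Tc = float(np.clip(2 * abs(y1 - y0) / abs(yd1),
                               min(0.30 * T, tc_min), 0.35 * T))
            y_hold = y1 - 0.5 * yd1 * Tc
        Tb = T - Ta - Tc
        if Tb < 0:   # degenerate short flight: single Hermite
            return quintic_eval(poly_bc(T, (y0, yd0), (y1, yd1)), tau_f)
        vals = np.empty_like(tau_f)
        a_seg = tau_f < Ta
        vals[a_seg] = (y0 + yd0 * tau_f[a_seg]
                       - 0.5 * (yd0 / max(Ta, 1e-9)) * tau_f[a_seg] ** 2)
        b_seg = (tau_f >= Ta) & (tau_f <= Ta + Tb)
        u = (tau_f[b_seg] - Ta) / max(Tb, 1e-9)
        vals[b_seg] = y_stop + (y_hold - y_stop) * u**2 * (3 - 2 * u)
        c_seg = tau_f > Ta + Tb
        if Tc > 0:
            tc = tau_f[c_seg] - (Ta + Tb)
            vals[c_seg] = y_hold + 0.5 * (yd1 / Tc) * tc**2
        return vals

    def _trunk(qrow):
        return qrow[..., 2] - qrow[..., 1] + qrow[..., 0]

    _FLOORS = (math.radians(-3.0), math.radians(-35.0))   # knee, ankle

    for name, lo, hi in plan.bounds:
        if hi <= lo or name not in FLIGHT_PHASES:
            continue
        i0, i1 = lo - 1, hi
        if i0 < 1 or i1 + 1 >= n:
            raise GenerationError(f"{spec.name}: flight phase at trial edge")
        T = (i1 - i0) * dt
        tau_f = (np.arange(lo, hi) - i0) * dt
        # knee, ankle in joint space
        for j, floor in zip((1, 2), _FLOORS):
            yd0 = (q[i0, j] - q[i0 - 1, j]) / dt
            yd1 = (q[i1 + 1, j] - q[i1, j]) / dt
            q[lo:hi, j] = _three_segment(T, tau_f, q[i0, j], yd0,
                                         q[i1, j], yd1, floor)
        # trunk absolute angle, then recover hip
        y0, y1 = _trunk(q[i0]), _trunk(q[i1])
        yd0 = (y0 - _trunk(q[i0 - 1])) / dt
        yd1 = (_trunk(q[i1 + 1]) - y1) / dt
        th_h = _three_segment(T, tau_f, y0, yd0, y1, yd1, None,
                              tc_min=0.14, ta_cap=0.15)
        q[lo:hi, 0] = th_h - q[lo:hi, 2] + q[lo:hi, 1]

    # --- pass 3: flight base from the ballistic COM ---
    for name, lo, hi in plan.bounds:
        sl = slice(lo, hi)
        if hi <= lo or name not in FLIGHT_PHASES:
            continue
        ref = np.tile([0.0, model.ankle_height], (hi - lo, 1))
        rel = chain_kinematics(t[sl], q[sl], model, base=ref).com - ref
        base[sl, 0] = plan_com.x[sl] - rel[:, 0]
        base[sl, 1] = plan_com.z[sl] - rel[:, 1]

    record = _assemble_record(spec, replicate, tseed, t, q, base, contact,
                              plan, model, load=np.zeros(n),
                              ext_line_x=model.midfoot_offset(),
                              cop_mode="jump")
    # target audit
    knee_deg = np.degrees(q[:, 1])
    phase = "amortization" if is_dj else "descent"
    sl = record.phase_slice(phase)
    knee_peak = knee_deg[sl].max()
    lo_t, hi_t = spec.knee_bottom_range_deg
    if not (lo_t - 1e-6 <= knee_peak <= hi_t + 1e-6):
        raise GenerationError(
            f"{spec.name}: peak knee flexion {knee_peak:.1f} deg outside "
            f"target [{lo_t}, {hi_t}]")
    if knee_deg.min() < -8.0:
        raise GenerationError(
            f"{spec.name}: knee hyperextension {knee_deg.min():.1f} deg")
    record.meta["knee_peak_deg"] = float(knee_peak)
    return record


def _assemble_record(spec, replicate, tseed, t, q, base, contact, plan,
                     model, load, ext_line_x, cop_mode,
                     com_acc=None) -> TrialRecord:
    n = len(t)
    dt = t[1] - t[0]
    qd = np.gradient(q, dt, axis=0)
    qdd = np.gradient(qd, dt, axis=0)
    grf, clipped = grf_from_com(t, q, base, contact, model, load,
                                com_acc=com_acc)
    cop_x = _cop_trace(plan, base, model, cop_mode, n)
    ext = np.stack([np.zeros(n), -load], axis=-1)
    idr = inverse_dynamics(t, q, grf, cop_x, model, base=base,
                           contact=contact, ext_force=ext,
                           ext_line_x=np.full(n, ext_line_x))
    record = TrialRecord(
        task=spec, replicate=replicate, seed=tseed, t=t, q=q, qd=qd,
        qdd=qdd, base=base, grf=grf, cop_x=cop_x, contact=contact,
        phase_labels=plan.labels(), phases=list(plan.bounds),
        load_force=load, ext_line_x=ext_line_x, tau=idr.tau_per_leg,
        residual_force=idr.residual_force,
        meta={"grf_clipped_frames": int(clipped)})
    return record


def _cop_trace(plan: PhasePlan, base, model, mode, n):
    """Centre of pressure: mid-foot, shifting to the forefoot at push-off."""
    mid = model.midfoot_offset()
    fore = 0.8 * model.foot_length - model.ankle_from_heel
    cop = base[:, 0] + mid
    if mode == "jump":
        for name, lo, hi in plan.bounds:
            if name == "propulsion" and hi > lo:
                w = np.linspace(0.0, 1.0, hi - lo)
                cop[lo:hi] = base[lo:hi, 0] + mid + w * (fore - mid)
    return cop


def grf_from_com(t, q, base, contact, model: ScaledModel, load=None,
                 com_acc=None):
    """Ground reaction force from whole-body COM dynamics.

    During contact  F = M (a_com - g_vec) + load reaction; zero in flight.
    ``com_acc`` (n, 2) supplies exact prescribed COM accelerations when
    the trajectory is analytically known; otherwise the same
    central-difference operator as the inverse-dynamics recursion is
    used, so generated trials are dynamically consistent to roundoff.
    Negative vertical forces are clipped to zero and counted (contact
    about to break).
    """
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    if com_acc is not None:
        acc = np.asarray(com_acc, dtype=float)
    else:
        kin = chain_kinematics(t, np.asarray(q, dtype=float), model,
                               base=base)
        acc = second_derivative(kin.com, dt)
    M = model.mass
    if load is None:
        load = np.zeros(len(t))
    F = np.empty((len(t), 2))
    F[:, 0] = M * acc[:, 0]
    F[:, 1] = M * (acc[:, 1] + model.gravity) + load
    F[~np.asarray(contact, dtype=bool)] = 0.0
    neg = (F[:, 1] < 0) & np.asarray(contact, dtype=bool)
    F[neg, 1] = 0.0
    return F, int(neg.sum())


# ---------------------------------------------------------------------------
# 1RM estimation and external load


PRIME_MOVERS = ("gluteus_maximus", "hamstrings", "rectus_femoris", "vasti",
                "gastrocnemius", "soleus")
ANTAGONIST_LEVEL = 0.05


def estimate_1rm(model: ScaledModel, tasks: dict[str, TaskSpec] | None = None,
                 rigid_tendon: bool = False,
                 antagonist_level: float = ANTAGONIST_LEVEL) -> MaxMomentTable:
    """Maximal feasible joint moments at the task-specific reference postures.

    Prime movers are set to full activation (a = 1), antagonists to the
    minimal feasible level, musculotendon equilibrium is solved at the
    static posture, and tendon-force contributions are summed through the
    moment-arm matrix. Moments are per leg; normalised values divide by
    total body mass.
    """
    if tasks is None:
        tasks = default_tasks()
    strength = {k: v for k, v in tasks.items() if v.kind == "strength"}
    R = moment_arm_matrix(model)
    absolute, normalized, postures = {}, {}, {}
    for name, spec in strength.items():
        q = np.radians(spec.posture_1rm_deg)
        l_mt = musculotendon_lengths(model, q)
        forces = np.empty(len(model.muscles))
        for i, mu in enumerate(model.muscles):
            a = 1.0 if mu.name in PRIME_MOVERS else antagonist_level
            if rigid_tendon:
                l_m = rigid_fiber_length(l_mt[i], mu)
                cos_a = _cos_pennation(l_m, mu)
                forces[i] = fiber_force(a, l_m, 0.0, mu) * cos_a
            else:
                st = mt_equilibrium(a, float(l_mt[i]), None, 1.0, mu)
                if st.at_bracket_boundary:
                    raise GenerationError(
                        f"1RM equilibrium failed for muscle {mu.name}")
                forces[i] = st.tendon_force
        tau = R @ forces
        absolute[name] = {j: float(tau[k]) for k, j in enumerate(JOINTS)}
        normalized[name] = {j: float(tau[k] / model.mass)
                            for k, j in enumerate(JOINTS)}
        postures[name] = spec.posture_1rm_deg
    return MaxMomentTable(posture_deg=postures, absolute=absolute,
                          normalized=normalized, mass=model.mass)


def apply_external_load(trial: TrialRecord, load_fraction: float,
                        max_moments: MaxMomentTable,
                        model: ScaledModel) -> TrialRecord:
    """Apply the equivalent external resistance to a strength trial.

    A vertical downward force on the HAT segment, line of action through
    the mid-foot, with magnitude chosen so the peak per-leg moment demand
    at the task's governing joint equals
    ``load_fraction x maximal feasible moment``.
    """
    spec = trial.task
    if spec.kind != "strength":
        raise ValueError("external load applies to strength trials")
    if load_fraction == 0:
        return trial
    joint_idx = JOINTS.index(spec.governing_joint)
    target = load_fraction * max_moments.absolute[spec.name][spec.governing_joint]

    n = len(trial.t)
    mid = trial.ext_line_x

    def tau_for(Fmag: float) -> np.ndarray:
        load = np.full(n, Fmag)
        grf, _ = grf_from_com(trial.t, trial.q, trial.base, trial.contact,
                              model, load)
        ext = np.stack([np.zeros(n), -load], axis=-1)
        idr = inverse_dynamics(trial.t, trial.q, grf, trial.cop_x, model,
                               base=trial.base, contact=trial.contact,
                               ext_force=ext, ext_line_x=np.full(n, mid))
        return idr

    tau0 = tau_for(0.0).tau_per_leg[:, joint_idx]
    tau1 = tau_for(1.0).tau_per_leg[:, joint_idx]
    dtau = tau1 - tau0     # per-leg moment per newton of load

    def peak_minus_target(F):
        return np.max(tau0 + F * dtau) - target

    if peak_minus_target(0.0) >= 0:
        F_load = 0.0
        trial.meta["load_saturated"] = True
    else:
        hi = 1000.0
        while peak_minus_target(hi) < 0 and hi < 1e6:
            hi *= 2
        F_load = brentq(peak_minus_target, 0.0, hi, xtol=1e-6)

    load = np.full(n, F_load)
    grf, clipped = grf_from_com(trial.t, trial.q, trial.base, trial.contact,
                                model, load)
    ext = np.stack([np.zeros(n), -load], axis=-1)
    idr = inverse_dynamics(trial.t, trial.q, grf, trial.cop_x, model,
                           base=trial.base, contact=trial.contact,
                           ext_force=ext, ext_line_x=np.full(n, mid))
    trial.load_force = load
    trial.grf = grf
    trial.tau = idr.tau_per_leg
    trial.residual_force = idr.residual_force
    trial.load_fraction = load_fraction
    trial.meta["load_N"] = float(F_load)
    trial.meta["grf_clipped_frames"] = int(clipped)
    return trial


def inject_grf_noise(grf: np.ndarray, level: float, seed) -> np.ndarray:
    """Additive zero-mean Gaussian noise, per-frame SD = level x |signal|.

    Frames with zero force (flight) stay exactly zero.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        return np.array(grf, copy=True)
    rng = np.random.default_rng(seed)
    grf = np.asarray(grf, dtype=float)
    noisy = grf + rng.standard_normal(grf.shape) * level * np.abs(grf)
    return noisy
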