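"""Frame-wise static optimization of muscle redundancy.

Each frame minimizes the effort cost

    J = sum_i w_i a_i^2  +  w_res * sum_j tau_res_j^2

subject to torque equilibrium ``R(q)^T f_m(a, l_m, v_m) + tau_res = tau_ID``
and bounds ``0 <= a_i <= 1``. Under the rigid-tendon per-frame kinematics
the musculotendon force is affine in activation,
``F_t,i = g_i a_i + p_i`` with gain ``g_i = f_L f_V F_max cos(alpha)`` and
passive offset ``p_i``, so the penalty form is exactly a bounded linear
least-squares problem

    min || [ diag(sqrt(w)) ; sqrt(w_res) A ] a - [ 0 ; sqrt(w_res) b ] ||^2

with ``A = n_legs R^T diag(g)`` and ``b = tau_ID - n_legs R^T p``, solved
with scipy's bounded least squares. Reserve torques are reported as the
residual of the equilibrium constraint; the heavy penalty (default 1000)
keeps them numerically negligible whenever the muscles can carry the
demand.

The bilateral-symmetric model solves one leg's muscle set against the
total (two-leg) moment demand, ``n_legs = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .body import JOINTS, ScaledModel, moment_arm_matrix, musculotendon_lengths
from .muscle import (active_force_length, force_velocity, passive_force_length,
                     rigid_fiber_length, mt_equilibrium, _cos_pennation)
from .tasks import TrialRecord

__all__ = ["FrameProblem", "ActivationSolution", "solve_frame",
           "solve_trajectory", "brute_force_oracle", "frame_from_posture"]

DEFAULT_RESERVE_WEIGHT = 1000.0


@dataclass
class FrameProblem:
    """One quasi-static frame of the redundancy problem."""

    tau_id: np.ndarray                 # (n_joints,) demanded moments, Nm
    l_mt: np.ndarray                   # (n_muscles,) musculotendon lengths, m
    v_mt: np.ndarray | None = None     # (n_muscles,) lengthening rates, m/s
    weights: np.ndarray | None = None  # w_i, default 1
    reserve_weight: float = DEFAULT_RESERVE_WEIGHT
    n_legs: int = 2                    # bilateral symmetry factor

    def validate(self, model: ScaledModel) -> None:
        m = len(model.muscles)
        if self.tau_id.shape != (len(JOINTS),):
            raise ValueError("tau_id must have one entry per joint")
        if self.l_mt.shape != (m,):
            raise ValueError("l_mt must have one entry per muscle")
        if self.weights is not None and (self.weights <= 0).any():
            raise ValueError("weights must be positive")


@dataclass
class ActivationSolution:
    activations: np.ndarray            # (n_muscles,) in [0, 1]
    reserves: np.ndarray               # (n_joints,) Nm
    objective: float
    residual: np.ndarray               # equilibrium residual per joint, Nm
    converged: bool
    kkt_residual: float = 0.0
    meta: dict = field(default_factory=dict)


def _affine_coefficients(problem: FrameProblem, model: ScaledModel):
    """Tendon-force gains and passive offsets under rigid-tendon kinematics."""
    gains = np.empty(len(model.muscles))
    offsets = np.empty(len(model.muscles))
    v_mt = (np.zeros_like(problem.l_mt) if problem.v_mt is None
            else problem.v_mt)
    for i, mu in enumerate(model.muscles):
        l_m = rigid_fiber_length(problem.l_mt[i], mu)
        cos_a = _cos_pennation(l_m, mu)
        l_norm = l_m / mu.l_opt
        # fiber lengthening rate: d l_m / dt = d l_mt / dt / cos(alpha)
        v_m = v_mt[i] / cos_a
        v_norm = -v_m / (mu.v_max * mu.l_opt)
        fl = active_force_length(l_norm, mu.curves)
        fv = force_velocity(v_norm, mu.curves)
        fp = passive_force_length(l_norm, mu.curves)
        gains[i] = fl * fv * mu.F_max * cos_a
        offsets[i] = fp * mu.F_max * cos_a
    return gains, offsets


def solve_frame(problem: FrameProblem, model: ScaledModel,
                x0: np.ndarray | None = None,
                tol: float = 1e-10) -> ActivationSolution:
    """Solve one frame as a bounded linear least-squares problem."""
    problem.validate(model)
    m = len(model.muscles)
    w = np.ones(m) if problem.weights is None else np.asarray(problem.weights)
    R = moment_arm_matrix(model)                      # joints x muscles
    gains, offsets = _affine_coefficients(problem, model)
    A = problem.n_legs * R * gains                    # joints x muscles
    b = problem.tau_id - problem.n_legs * (R @ offsets)
    sw = np.sqrt(problem.reserve_weight)
    M = np.vstack([np.diag(np.sqrt(w)), sw * A])
    rhs = np.concatenate([np.zeros(m), sw * b])
    res = lsq_linear(M, rhs, bounds=(0.0, 1.0), tol=tol, method="bvls")
    a = np.clip(res.x, 0.0, 1.0)
    reserves = problem.tau_id - (A @ a + problem.n_legs * (R @ offsets))
    resid = A @ a + problem.n_legs * (R @ offsets) + reserves - problem.tau_id
    obj = float(w @ a**2 + problem.reserve_weight * reserves @ reserves)
    grad = 2 * w * a - 2 * problem.reserve_weight * (A.T @ reserves)
    kkt = float(np.max(np.abs(np.where(
        a <= 1e-12, np.minimum(grad, 0.0),
        np.where(a >= 1 - 1e-12, np.maximum(grad, 0.0), grad)))))
    return ActivationSolution(
        activations=a, reserves=reserves, objective=obj, residual=resid,
        converged=bool(res.success), kkt_residual=kkt,
        meta={"lsq_status": int(res.status)})


def frame_from_posture(model: ScaledModel, q, tau_id, qd=None,
                       n_legs: int = 2,
                       reserve_weight: float = DEFAULT_RESERVE_WEIGHT
                       ) -> FrameProblem:
    """Build a FrameProblem from joint angles (rad) and moment demand."""
    q = np.asarray(q, dtype=float)
    l_mt = musculotendon_lengths(model, q)
    v_mt = None
    if qd is not None:
        R = moment_arm_matrix(model)
        v_mt = np.asarray(qd, dtype=float) @ R
    return FrameProblem(tau_id=np.asarray(tau_id, dtype=float), l_mt=l_mt,
                        v_mt=v_mt, n_legs=n_legs,
                        reserve_weight=reserve_weight)


def solve_trajectory(trial: TrialRecord, model: ScaledModel,
                     stride_s: float = 0.010, contact_only: bool = True,
                     elastic_tendon: bool = False,
                     reserve_weight: float = DEFAULT_RESERVE_WEIGHT,
                     max_bad_fraction: float = 0.01,
                     tol: float = 1e-10) -> TrialRecord:
    """Attach activation and fiber-state series to a trial.

    Frames are solved on a decimated grid (default every 10 ms —
    activation waveforms are band-limited far below the trace sampling
    rate) and linearly interpolated back to the full grid, with
    warm starts from the previous solved frame. With ``contact_only``
    (default) only stance frames are solved; airborne frames carry zero
    activation, since swing-phase moment demands in the reduced planar
    model reflect the interpolated limb kinematics rather than muscular
    effort.

    When ``elastic_tendon`` is set, fiber kinematics are fixed-point
    iterated (up to 5 passes) with the tendon equilibrium per muscle.
    """
    n = len(trial.t)
    m = len(model.muscles)
    dt = trial.dt
    R = moment_arm_matrix(model)
    l_mt_all = musculotendon_lengths(model, trial.q)       # (n, m)
    tau_total = 2.0 * trial.tau                            # chain totals

    stride = max(int(round(stride_s / dt)), 1)
    # backward difference of musculotendon length over the solve stride
    # (a fixed physical interval, so the estimate is independent of the
    # trace sampling step); first frame zero
    v_mt_all = np.zeros_like(l_mt_all)
    back = np.minimum(np.arange(n), stride)
    rows = np.arange(n) - back
    nz = back > 0
    v_mt_all[nz] = ((l_mt_all[nz] - l_mt_all[rows[nz]])
                    / (back[nz, None] * dt))
    idx = np.arange(0, n, stride)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    # relocate knots that sit within 4 ms of a phase boundary: the moment
    # demand there carries finite-difference transients of the junction
    # kinks, whose size depends on the sampling step; 4 ms is a multiple
    # of every supported step, so relocated knots are grid-independent
    margin = max(int(round(0.004 / dt)), 1)
    boundaries = np.array(sorted({b for _, lo2, hi2 in trial.phases
                                  for b in (lo2, hi2)}))
    idx_new = idx.copy()
    for k, i in enumerate(idx):
        near = boundaries[np.abs(boundaries - i) < margin]
        if len(near) and 0 < i < n - 1:
            b = int(near[0])
            cand = b + margin if i >= b else b - margin
            idx_new[k] = min(max(cand, 0), n - 1)
    idx = np.unique(idx_new)
    solve_mask = np.ones(len(idx), dtype=bool)
    if contact_only:
        solve_mask = trial.contact[idx]

    act = np.zeros((len(idx), m))
    reserves = np.zeros((len(idx), len(JOINTS)))
    bad = 0
    jitter = trial.meta.get("activation_jitter", 1.0)
    x0 = np.full(m, 0.1 * jitter)
    prev_l_m = None
    for k, i in enumerate(idx):
        if not solve_mask[k]:
            prev_l_m = None
            continue
        prob = FrameProblem(tau_id=tau_total[i], l_mt=l_mt_all[i],
                            v_mt=v_mt_all[i], n_legs=2,
                            reserve_weight=reserve_weight)
        if elastic_tendon:
            sol = _solve_elastic(prob, model, prev_l_m, dt * stride, x0)
        else:
            sol = solve_frame(prob, model, x0=x0, tol=tol)
        if not sol.converged:
            bad += 1
            if k > 0:
                act[k] = act[k - 1]
                reserves[k] = reserves[k - 1]
            continue
        act[k] = sol.activations
        reserves[k] = sol.reserves
        x0 = np.maximum(sol.activations, 1e-3)
        if elastic_tendon:
            prev_l_m = sol.meta.get("l_m")

    frac_bad = bad / max(solve_mask.sum(), 1)
    # interpolate to the full grid
    t_idx = trial.t[idx]
    act_full = np.empty((n, m))
    res_full = np.empty((n, len(JOINTS)))
    for j in range(m):
        act_full[:, j] = np.interp(trial.t, t_idx, act[:, j])
    for j in range(len(JOINTS)):
        res_full[:, j] = np.interp(trial.t, t_idx, reserves[:, j])
    if contact_only:
        act_full[~trial.contact] = 0.0
        res_full[~trial.contact] = 0.0

    l_slack = np.array([mu.l_slack for mu in model.muscles])
    h = np.array([mu.l_opt * np.sin(mu.alpha0) for mu in model.muscles])
    proj = np.clip(l_mt_all - l_slack, 1e-6, None)
    fib = np.sqrt(proj**2 + h**2)       # rigid-tendon fiber lengths
    trial.activations = act_full
    trial.fiber_lengths = fib
    trial.reserves = 0.5 * res_full       # per leg, like trial.tau
    trial.solver_flags = {
        "solved_frames": int(solve_mask.sum()),
        "non_converged": int(bad),
        "stride": stride,
        "valid": bool(frac_bad <= max_bad_fraction),
    }
    if frac_bad > max_bad_fraction:
        trial.meta["invalid_reason"] = (
            f"{100 * frac_bad:.1f}% of frames failed to converge")
    return trial


def _solve_elastic(prob: FrameProblem, model: ScaledModel, prev_l_m,
                   dt: float, x0) -> ActivationSolution:
    """Fixed-point iteration between activation solve and tendon equilibrium."""
    sol = solve_frame(prob, model, x0=x0)
    l_m = None
    for _ in range(5):
        l_m = np.empty(len(model.muscles))
        gains = np.empty_like(l_m)
        offsets = np.empty_like(l_m)
        for i, mu in enumerate(model.muscles):
            prev = None if prev_l_m is None else prev_l_m[i]
            st = mt_equilibrium(float(sol.activations[i]),
                                float(prob.l_mt[i]), prev, dt, mu)
            l_m[i] = st.l_m
            cos_a = _cos_pennation(st.l_m, mu)
            fl = active_force_length(st.l_m / mu.l_opt, mu.curves)
            fv = force_velocity(-st.v_m / (mu.v_max * mu.l_opt), mu.curves)
            fp = passive_force_length(st.l_m / mu.l_opt, mu.curves)
            gains[i] = fl * fv * mu.F_max * cos_a
            offsets[i] = fp * mu.F_max * cos_a
        R = moment_arm_matrix(model)
        A = prob.n_legs * R * gains
        b = prob.tau_id - prob.n_legs * (R @ offsets)
        m_mus = len(model.muscles)
        sw = np.sqrt(prob.reserve_weight)
        M = np.vstack([np.eye(m_mus), sw * A])
        rhs = np.concatenate([np.zeros(m_mus), sw * b])
        res = lsq_linear(M, rhs, bounds=(0.0, 1.0), method="bvls")
        new_a = np.clip(res.x, 0.0, 1.0)
        if np.max(np.abs(new_a - sol.activations)) < 1e-6:
            sol.activations = new_a
            break
        sol.activations = new_a
    sol.reserves = prob.tau_id - (prob.n_legs
                                  * (moment_arm_matrix(model)
                                     @ ((gains * sol.activations) + offsets)))
    sol.meta["l_m"] = l_m
    return sol


def brute_force_oracle(problem: FrameProblem, model: ScaledModel,
                       grid: float = 1e-3) -> ActivationSolution:
    """Exhaustive grid search over the activation box (test oracle).

    Minimizes the same penalty objective as :func:`solve_frame`; refuses
    more than 3 muscles (grid explosion guard).
    """
    problem.validate(model)
    m = len(model.muscles)
    if m > 3:
        raise ValueError("brute-force oracle limited to <= 3 muscles")
    w = np.ones(m) if problem.weights is None else np.asarray(problem.weights)
    R = moment_arm_matrix(model)
    gains, offsets = _affine_coefficients(problem, model)
    A = problem.n_legs * R * gains
    b = problem.tau_id - problem.n_legs * (R @ offsets)

    axes = [np.arange(0.0, 1.0 + grid / 2, grid)] * m
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in mesh], axis=-1)    # (N, m)
    resid = pts @ A.T - b                                  # (N, n_joints)
    # grid-consistent equilibrium tolerance: half a grid step of the
    # largest single-muscle torque contribution at each joint (tight
    # enough that slack cannot be traded for effort)
    tol = 0.5 * grid * np.abs(A).max(axis=1)
    tol = np.maximum(tol, 1e-12)
    feasible = (np.abs(resid) <= tol).all(axis=1)
    J_pen = pts**2 @ w + problem.reserve_weight * (resid**2).sum(axis=1)
    if feasible.any():
        effort = pts**2 @ w
        effort_f = np.where(feasible, effort, np.inf)
        k = int(np.argmin(effort_f))
    else:   # demand beyond capacity: reserves must carry the remainder
        k = int(np.argmin(J_pen))
    a = pts[k]
    reserves = problem.tau_id - (A @ a + problem.n_legs * (R @ offsets))
    return ActivationSolution(activations=a, reserves=reserves,
                              objective=float(J_pen[k]),
                              residual=resid[k],
                              converged=True, meta={"grid": grid})
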