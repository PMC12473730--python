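"""Planar chain kinematics and Newton-Euler inverse dynamics.

Geometry convention: x forward, z up. Segment orientation is measured as
the forward-lean angle of the segment's long axis from vertical, so the
up-axis unit vector of a segment at angle ``theta`` is
``(sin(theta), cos(theta))``. With the foot flat on the ground,

    theta_shank = q_ankle              (dorsiflexion)
    theta_thigh = theta_shank - q_knee (knee flexion)
    theta_trunk = theta_thigh + q_hip  (hip flexion)

Planar torques are computed counter-clockwise positive in the x-z plane
(``tau = r_x F_z - r_z F_x``) and then mapped to the reported
extension/plantarflexion-positive joint convention.

The inverse-dynamics recursion runs bottom-up from the measured ground
reaction force: foot, shank, thigh, with the hip moment closing the chain.
Applying the same Newton-Euler balance to the HAT segment yields a
residual force that is zero for dynamically consistent inputs — the
pipeline's dynamic-consistency audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import ScaledModel

__all__ = ["ChainKinematics", "chain_kinematics", "com_position",
           "second_derivative", "InverseDynamicsResult",
           "inverse_dynamics"]

# map CCW internal torques to extension/plantarflexion-positive reporting
_SIGN = {"hip": -1.0, "knee": 1.0, "ankle": -1.0}


@dataclass
class ChainKinematics:
    """Positions (m) and orientations (rad) of the chain at n frames.

    All position arrays have shape (n, 2); angles (n,).
    """

    t: np.ndarray
    ankle: np.ndarray
    knee: np.ndarray
    hip: np.ndarray
    com_foot: np.ndarray
    com_shank: np.ndarray
    com_thigh: np.ndarray
    com_hat: np.ndarray
    theta_shank: np.ndarray
    theta_thigh: np.ndarray
    theta_trunk: np.ndarray
    com: np.ndarray          # whole-body COM


def _upvec(theta: np.ndarray) -> np.ndarray:
    return np.stack([np.sin(theta), np.cos(theta)], axis=-1)


def chain_kinematics(t, q, model: ScaledModel, base=None) -> ChainKinematics:
    """Forward kinematics of the chain.

    ``q`` is (n, 3) joint flexion angles ordered (hip, knee, ankle);
    ``base`` is the ankle-joint trajectory (n, 2); default: ankle fixed at
    (0, ankle_height) — foot flat on the ground at the origin.
    """
    t = np.asarray(t, dtype=float)
    q = np.atleast_2d(np.asarray(q, dtype=float))
    n = q.shape[0]
    if base is None:
        base = np.tile([0.0, model.ankle_height], (n, 1))
    ankle = np.asarray(base, dtype=float)

    q_hip, q_knee, q_ankle = q[:, 0], q[:, 1], q[:, 2]
    th_s = q_ankle
    th_t = th_s - q_knee
    th_H = th_t + q_hip

    u_s, u_t, u_H = _upvec(th_s), _upvec(th_t), _upvec(th_H)
    knee = ankle + model.shank.length * u_s
    hip = knee + model.thigh.length * u_t

    # COMs: shank/thigh offsets measured from the proximal joint downward
    com_shank = knee - model.shank.com_offset * u_s
    com_thigh = hip - model.thigh.com_offset * u_t
    com_hat = hip + model.hat.com_offset * u_H
    # foot: rigid with the ankle; COM at mid-foot, half ankle height
    foot_off = np.array([model.foot.length * 0.5 - model.ankle_from_heel,
                         -0.5 * model.ankle_height])
    com_foot = ankle + foot_off

    masses = np.array([model.foot.mass, model.shank.mass,
                       model.thigh.mass, model.hat.mass])
    com = (masses[0] * com_foot + masses[1] * com_shank
           + masses[2] * com_thigh + masses[3] * com_hat) / masses.sum()

    return ChainKinematics(t=t, ankle=ankle, knee=knee, hip=hip,
                           com_foot=com_foot, com_shank=com_shank,
                           com_thigh=com_thigh, com_hat=com_hat,
                           theta_shank=th_s, theta_thigh=th_t,
                           theta_trunk=th_H, com=com)


def com_position(q, model: ScaledModel, base=None) -> np.ndarray:
    """Whole-body COM at posture(s) ``q`` (hip, knee, ankle) rad."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    kin = chain_kinematics(np.zeros(q.shape[0]), q, model, base=base)
    return kin.com[0] if q.shape[0] == 1 else kin.com


def _cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Scalar planar cross product, CCW positive: r_x F_z - r_z F_x."""
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


def second_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central second derivative along axis 0.

    The interior stencil (-1, 16, -30, 16, -1)/(12 dt^2) keeps the
    discretization error of smooth high-snap trajectories far below the
    sampling-step grid, so quantities derived from accelerations are
    stable under grid refinement; near the edges the stencil degrades to
    second order. Both the GRF synthesis and the inverse-dynamics
    recursion use this same operator, which is what makes generated
    trials dynamically consistent to roundoff.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    if len(x) < 7:
        g = np.gradient(np.gradient(x, dt, axis=0), dt, axis=0)
        return g
    c = dt * dt
    out[2:-2] = (-x[:-4] + 16 * x[1:-3] - 30 * x[2:-2]
                 + 16 * x[3:-1] - x[4:]) / (12 * c)
    for i in (0, 1):
        out[i] = (x[i] - 2 * x[i + 1] + x[i + 2]) / c
    for i in (-1, -2):
        out[i] = (x[i] - 2 * x[i - 1] + x[i - 2]) / c
    return out


def _ddt(x: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(x, dt, axis=0)


@dataclass
class InverseDynamicsResult:
    """Net sagittal joint moments and the HAT consistency residual.

    ``tau`` is (n, 3), ordered (hip, knee, ankle), chain totals (both legs),
    extension/plantarflexion-positive. ``tau_per_leg`` halves them for the
    bilateral-symmetric model. ``residual_force`` (n, 2) is the unexplained
    force on the HAT segment; near zero for consistent kinematics + GRF.
    """

    tau: np.ndarray
    residual_force: np.ndarray
    residual_moment: np.ndarray
    joint_forces: dict[str, np.ndarray]

    @property
    def tau_per_leg(self) -> np.ndarray:
        return 0.5 * self.tau


def inverse_dynamics(t, q, grf, cop_x, model: ScaledModel, base=None,
                     contact=None, ext_force=None,
                     ext_line_x=None) -> InverseDynamicsResult:
    """Bottom-up Newton-Euler inverse dynamics on the planar chain.

    Parameters
    ----------
    t : (n,) time base, uniformly sampled.
    q : (n, 3) joint angles (hip, knee, ankle), rad.
    grf : (n, 2) ground reaction force (Fx, Fz), N (total under both feet).
    cop_x : (n,) centre of pressure x-position, m (ignored where GRF = 0).
    base : optional (n, 2) ankle trajectory (flight phases translate it).
    contact : optional (n,) bool; defaults to |GRF| > 0.
    ext_force : optional (n, 2) external load applied to the HAT segment.
    ext_line_x : optional (n,) x-position of the external load's vertical
        line of action (default: HAT COM x).
    """
    t = np.asarray(t, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 frames")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-12):
        raise ValueError("time base must be uniformly sampled")
    grf = np.asarray(grf, dtype=float)
    q = np.asarray(q, dtype=float)
    if grf.shape[0] != q.shape[0] or q.shape[0] != t.size:
        raise ValueError("kinematics and GRF must share one time base")
    cop_x = np.asarray(cop_x, dtype=float)

    kin = chain_kinematics(t, q, model, base=base)
    g_vec = np.array([0.0, -model.gravity])

    # linear accelerations of segment COMs (shared high-order operator)
    acc = {name: second_derivative(getattr(kin, f"com_{name}"), dt)
           for name in ("foot", "shank", "thigh", "hat")}
    # angular accelerations, CCW positive (theta is a clockwise lean angle)
    ang = {"foot": np.zeros_like(kin.theta_shank),
           "shank": kin.theta_shank, "thigh": kin.theta_thigh,
           "hat": kin.theta_trunk}
    alpha = {k: -second_derivative(v, dt) for k, v in ang.items()}

    segs = {"foot": model.foot, "shank": model.shank,
            "thigh": model.thigh, "hat": model.hat}
    W = {k: segs[k].mass * g_vec for k in segs}

    cop = np.stack([cop_x, np.zeros_like(cop_x)], axis=-1)

    # --- foot ---
    F_a = segs["foot"].mass * acc["foot"] - W["foot"] - grf
    M_a = (segs["foot"].inertia * alpha["foot"]
           - _cross2(cop - kin.com_foot, grf)
           - _cross2(kin.ankle - kin.com_foot, F_a))
    # --- shank ---
    F_k = segs["shank"].mass * acc["shank"] - W["shank"] + F_a
    M_k = (segs["shank"].inertia * alpha["shank"] + M_a
           + _cross2(kin.ankle - kin.com_shank, F_a)
           - _cross2(kin.knee - kin.com_shank, F_k))
    # --- thigh ---
    F_h = segs["thigh"].mass * acc["thigh"] - W["thigh"] + F_k
    M_h = (segs["thigh"].inertia * alpha["thigh"] + M_k
           + _cross2(kin.knee - kin.com_thigh, F_k)
           - _cross2(kin.hip - kin.com_thigh, F_h))

    # --- HAT closure: residual force/moment ---
    if ext_force is None:
        ext_force = np.zeros_like(grf)
    else:
        ext_force = np.asarray(ext_force, dtype=float)
    if ext_line_x is None:
        ext_line_x = kin.com_hat[:, 0]
    ext_pt = np.stack([np.asarray(ext_line_x, dtype=float),
                       kin.com_hat[:, 1]], axis=-1)
    F_res = segs["hat"].mass * acc["hat"] - W["hat"] - ext_force + F_h
    M_res = (segs["hat"].inertia * alpha["hat"] + M_h
             + _cross2(kin.hip - kin.com_hat, F_h)
             - _cross2(ext_pt - kin.com_hat, ext_force))

    tau = np.stack([_SIGN["hip"] * M_h, _SIGN["knee"] * M_k,
                    _SIGN["ankle"] * M_a], axis=-1)
    return InverseDynamicsResult(
        tau=tau, residual_force=F_res, residual_moment=M_res,
        joint_forces={"ankle": F_a, "knee": F_k, "hip": F_h})
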