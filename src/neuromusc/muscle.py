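"""Hill-type musculotendon mechanics.

A muscle-tendon unit is modelled as an active contractile element in
parallel with a passive elastic element, in series with an elastic tendon,
with force transmission through a pennation angle that obeys the
constant-thickness rule ``l_m * sin(alpha) = l_opt * sin(alpha0)``.

Fiber force:  F = [a * f_L(l~) * f_V(v~) + f_P(l~)] * F_max
Tendon force: F_t = F_max * k_T * strain   for strain > 0, else 0
Equilibrium:  F * cos(alpha) = F_t

All curve shapes are configurable through :class:`HillCurves`; the shipped
defaults are a Gaussian active force-length curve (width 0.45), a Hill
hyperbola force-velocity curve (concentric shape 0.25, eccentric plateau
1.4), an exponential passive curve normalised to 1 at strain 0.6, and a
linear tendon with normalised stiffness 35 (force fraction of F_max per
unit tendon strain).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HillCurves",
    "MuscleParams",
    "MuscleState",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "tendon_force",
    "fiber_force",
    "pennation_angle",
    "rigid_fiber_length",
    "mt_equilibrium",
]

# minimum cos(alpha) to avoid the pennation singularity
_COS_ALPHA_FLOOR = 0.1


@dataclass(frozen=True)
class HillCurves:
    """Shape constants of the four Hill-model curves."""

    fl_width: float = 0.45          # Gaussian width of the active f_L curve
    fv_shape: float = 0.25          # Hill hyperbola a/F0 for shortening
    ecc_plateau: float = 1.4        # eccentric force asymptote (x F_max)
    passive_strain_max: float = 0.6  # fiber strain where f_P reaches 1
    passive_exponent: float = 4.0   # steepness of the passive exponential


DEFAULT_CURVES = HillCurves()


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one muscle-tendon actuator.

    ``joint_spans`` maps joint name -> signed constant moment arm (m),
    positive for extension/plantarflexion torque.
    """

    name: str
    F_max: float            # maximal isometric force, N
    l_opt: float            # optimal fiber length, m
    l_slack: float          # tendon slack length, m
    alpha0: float = 0.0     # pennation at l_opt, rad
    k_T: float = 35.0       # tendon stiffness, F_max per unit strain
    v_max: float = 10.0     # max shortening velocity, l_opt/s
    joint_spans: dict[str, float] = field(default_factory=dict)
    curves: HillCurves = DEFAULT_CURVES

    def __post_init__(self) -> None:
        if self.F_max <= 0:
            raise ValueError(f"{self.name}: F_max must be positive")
        if self.l_opt <= 0:
            raise ValueError(f"{self.name}: l_opt must be positive")
        if self.l_slack < 0:
            raise ValueError(f"{self.name}: l_slack must be non-negative")
        if not 0 <= self.alpha0 < math.pi / 2:
            raise ValueError(f"{self.name}: alpha0 must be in [0, pi/2)")
        if self.k_T <= 0:
            raise ValueError(f"{self.name}: k_T must be positive")
        if self.v_max <= 0:
            raise ValueError(f"{self.name}: v_max must be positive")
        if not self.joint_spans:
            raise ValueError(f"{self.name}: at least one joint span required")

    def with_multipliers(self, *, F_max: float = 1.0, l_opt: float = 1.0,
                         l_slack: float = 1.0, k_T: float = 1.0) -> "MuscleParams":
        """Return a perturbed copy with multiplicative parameter scalings."""
        return replace(self, F_max=self.F_max * F_max, l_opt=self.l_opt * l_opt,
                       l_slack=self.l_slack * l_slack, k_T=self.k_T * k_T)


@dataclass
class MuscleState:
    """Instantaneous mechanical state of one muscle-tendon actuator."""

    activation: float
    l_m: float              # fiber length, m
    v_m: float              # fiber velocity, m/s (shortening negative dl/dt)
    l_t: float              # tendon length, m
    fiber_force: float      # N, along the fiber
    tendon_force: float     # N, along the tendon
    at_bracket_boundary: bool = False


def active_force_length(l_norm, curves: HillCurves = DEFAULT_CURVES):
    """Active force-length curve, Gaussian in normalised fiber length.

    Maximum of exactly 1 at ``l_norm == 1``.
    """
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalised fiber length must be positive")
    out = np.exp(-((l_norm - 1.0) ** 2) / curves.fl_width)
    return float(out) if out.ndim == 0 else out


def force_velocity(v_norm, curves: HillCurves = DEFAULT_CURVES):
    """Force-velocity curve; ``v_norm`` is fiber velocity / (v_max * l_opt),
    with shortening positive.

    Concentric branch is the Hill hyperbola
    ``(1 - v) / (1 + v / a_f)`` with shape ``a_f``; the eccentric branch
    rises smoothly from 1 to the configured plateau with matched slope at
    ``v = 0``.
    """
    v = np.asarray(v_norm, dtype=float)
    a_f = curves.fv_shape
    fmax_e = curves.ecc_plateau
    # concentric: f = (1 - v)/(1 + v/a_f) for 0 <= v <= 1, clamp beyond
    vc = np.clip(v, 0.0, 1.0)
    f_con = (1.0 - vc) / (1.0 + vc / a_f)
    # eccentric: exponential approach to the plateau, slope-matched at v = 0
    # (d f_con/dv at 0 is -(1 + 1/a_f), so s = (1 + 1/a_f)/(fmax_e - 1))
    s = (1.0 + 1.0 / a_f) / (fmax_e - 1.0)
    ve = np.clip(-v, 0.0, None)
    f_ecc = fmax_e - (fmax_e - 1.0) * np.exp(-ve * s)
    out = np.where(v >= 0, f_con, f_ecc)
    return float(out) if out.ndim == 0 else out


def passive_force_length(l_norm, curves: HillCurves = DEFAULT_CURVES):
    """Passive force-length curve: 0 at or below optimal length, exponential
    above, normalised to 1 at strain ``passive_strain_max``."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalised fiber length must be positive")
    strain = np.clip(l_norm - 1.0, 0.0, None)
    k = curves.passive_exponent
    e0 = curves.passive_strain_max
    out = np.expm1(k * strain / e0) / np.expm1(k)
    out = np.where(l_norm <= 1.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def tendon_force(l_t, params: MuscleParams):
    """Tendon force (N): linear in strain above slack, zero below."""
    if params.l_slack == 0:
        raise ValueError(f"{params.name}: elastic tendon requires l_slack > 0")
    l_t = np.asarray(l_t, dtype=float)
    if np.any(l_t < 0):
        raise ValueError("tendon length must be non-negative")
    strain = l_t / params.l_slack - 1.0
    out = params.F_max * params.k_T * np.clip(strain, 0.0, None)
    return float(out) if out.ndim == 0 else out


def fiber_force(a, l_m, v_m, params: MuscleParams):
    """Force along the fiber: ``[a f_L f_V + f_P] F_max``.

    ``v_m`` is the fiber lengthening rate dl_m/dt in m/s; shortening
    (negative dl_m/dt) maps to positive normalised velocity in f_V.
    """
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    l_norm = np.asarray(l_m, dtype=float) / params.l_opt
    v_norm = -np.asarray(v_m, dtype=float) / (params.v_max * params.l_opt)
    out = (a * active_force_length(l_norm, params.curves)
           * force_velocity(v_norm, params.curves)
           + passive_force_length(l_norm, params.curves)) * params.F_max
    return float(out) if np.ndim(out) == 0 else out


def pennation_angle(l_m, params: MuscleParams):
    """Pennation from the constant-thickness rule; cos floored at 0.1."""
    h = params.l_opt * math.sin(params.alpha0)
    l_m = np.asarray(l_m, dtype=float)
    sin_a = np.clip(h / np.maximum(l_m, 1e-9), 0.0, math.sqrt(1 - _COS_ALPHA_FLOOR**2))
    out = np.arcsin(sin_a)
    return float(out) if out.ndim == 0 else out


def _cos_pennation(l_m, params: MuscleParams):
    return np.maximum(np.cos(pennation_angle(l_m, params)), _COS_ALPHA_FLOOR)


def rigid_fiber_length(l_mt, params: MuscleParams):
    """Fiber length under the rigid-tendon approximation (l_t = l_slack).

    With constant muscle thickness h = l_opt sin(alpha0):
    ``l_m = sqrt((l_mt - l_slack)^2 + h^2)``.
    """
    h = params.l_opt * math.sin(params.alpha0)
    proj = np.clip(np.asarray(l_mt, dtype=float) - params.l_slack, 1e-6, None)
    out = np.sqrt(proj**2 + h**2)
    return float(out) if out.ndim == 0 else out


def mt_equilibrium(a: float, l_mt: float, l_m_prev: float | None, dt: float,
                   params: MuscleParams) -> MuscleState:
    """Solve fiber-tendon force equilibrium at one frame.

    Finds the fiber length such that
    ``F_fiber(a, l_m, v_m) cos(alpha(l_m)) = F_tendon(l_mt - l_m cos(alpha))``
    with the fiber velocity from a backward difference against
    ``l_m_prev`` (zero for the first frame when ``l_m_prev`` is None).

    The root is bracketed in ``[0.2, 1.8] l_opt``; if the residual does not
    change sign there, the boundary with the smaller |residual| is returned
    with ``at_bracket_boundary`` set.
    """
    if l_mt <= 0:
        raise ValueError("musculotendon length must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 <= a <= 1:
        raise ValueError("activation must lie in [0, 1]")

    def residual(l_m: float) -> float:
        cos_a = _cos_pennation(l_m, params)
        v_m = 0.0 if l_m_prev is None else (l_m - l_m_prev) / dt
        l_t = l_mt - l_m * cos_a
        f_t = tendon_force(max(l_t, 0.0), params)
        return fiber_force(a, l_m, v_m, params) * cos_a - f_t

    lo, hi = 0.2 * params.l_opt, 1.8 * params.l_opt
    r_lo, r_hi = residual(lo), residual(hi)
    boundary = False
    if r_lo == 0.0:
        l_m = lo
    elif r_hi == 0.0:
        l_m = hi
    elif r_lo * r_hi > 0:
        l_m = lo if abs(r_lo) < abs(r_hi) else hi
        boundary = True
        warnings.warn(
            f"{params.name}: no equilibrium root in bracket, returning boundary",
            RuntimeWarning, stacklevel=2)
    else:
        l_m = brentq(residual, lo, hi, xtol=1e-12, rtol=1e-14)

    cos_a = _cos_pennation(l_m, params)
    v_m = 0.0 if l_m_prev is None else (l_m - l_m_prev) / dt
    l_t = max(l_mt - l_m * cos_a, 0.0)
    f_t = tendon_force(l_t, params)
    f_f = fiber_force(a, l_m, v_m, params)
    return MuscleState(activation=a, l_m=l_m, v_m=v_m, l_t=l_t,
                       fiber_force=f_f, tendon_force=f_t,
                       at_bracket_boundary=boundary)
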