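"""Reduced sagittal-plane body model.

The body is a planar kinematic chain of four segments — foot, shank, thigh
and a lumped head-arms-trunk (HAT) segment — articulated at the ankle,
knee and hip. The model is bilaterally symmetric: both legs move
identically, so the leg segments carry the mass of both legs and reported
joint moments are *per-leg* values (half of the chain totals).

Joint coordinates are flexion/dorsiflexion angles in radians (zero in the
upright anatomical posture); joint torques are reported
extension/plantarflexion-positive. Muscle moment arms are constant per
muscle-joint pair, so musculotendon length is affine in the joint angles:

    l_mt(q) = l_opt cos(alpha0) + l_slack + sum_j r_j (q_j - q_ref_j)

with the reference posture (where every fiber sits at optimal length)
placed mid-range of the task repertoire.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .muscle import HillCurves, MuscleParams

__all__ = [
    "JOINTS",
    "Segment",
    "ScaledModel",
    "load_model",
    "default_model",
    "scale_model",
    "moment_arm_matrix",
    "musculotendon_lengths",
]

JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class Segment:
    """One rigid segment of the planar chain.

    ``com_offset`` is the distance from the proximal joint to the centre of
    mass along the segment axis; ``gyration`` is the radius of gyration
    about the COM as a fraction of segment length (kept so that inertia
    scaling stays compositional).
    """

    name: str
    length: float       # m
    mass: float         # kg (leg segments: both legs lumped)
    com_offset: float   # m from proximal joint
    gyration: float     # fraction of length

    @property
    def inertia(self) -> float:
        """Moment of inertia about the COM, kg m^2 (mass * (gyration*L)^2)."""
        return self.mass * (self.gyration * self.length) ** 2


@dataclass(frozen=True)
class ScaledModel:
    """Anthropometrically scaled planar model with its muscle set."""

    height: float               # m
    mass: float                 # kg
    gravity: float              # m/s^2
    foot: Segment
    shank: Segment
    thigh: Segment
    hat: Segment
    ankle_height: float         # ankle joint height above ground, m
    ankle_from_heel: float      # ankle x-offset from heel, m
    muscles: tuple[MuscleParams, ...]
    q_ref: tuple[float, float, float]   # reference posture (hip, knee, ankle), rad

    def __post_init__(self) -> None:
        total = self.foot.mass + self.shank.mass + self.thigh.mass + self.hat.mass
        if abs(total - self.mass) > 1e-6 * self.mass:
            raise ValueError("segment masses must sum to total mass")

    @property
    def segments(self) -> tuple[Segment, ...]:
        return (self.foot, self.shank, self.thigh, self.hat)

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    @property
    def foot_length(self) -> float:
        return self.foot.length

    def midfoot_offset(self) -> float:
        """Horizontal offset of the mid-foot point from the ankle, m."""
        return 0.5 * self.foot.length - self.ankle_from_heel

    def with_muscles(self, muscles) -> "ScaledModel":
        return replace(self, muscles=tuple(muscles))


# ---------------------------------------------------------------------------
# construction and scaling

def _build_segments(height: float, mass: float, cfg: dict) -> dict[str, Segment]:
    segs = {}
    for name, s in cfg.items():
        L = s["length_frac"] * height
        segs[name] = Segment(
            name=name,
            length=L,
            mass=s["mass_frac"] * mass,
            com_offset=s["com_frac"] * L,
            gyration=s["gyration_frac"],
        )
    return segs


def load_model(source) -> ScaledModel:
    """Build a :class:`ScaledModel` from a YAML model definition.

    ``source`` may be a path, an open file, or an already-parsed dict.
    """
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    m = cfg["model"]
    height, mass = float(m["height"]), float(m["mass"])
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    segs = _build_segments(height, mass, m["segments"])
    curves = HillCurves(**m.get("curves", {}))
    muscles = []
    for name, mu in m["muscles"].items():
        muscles.append(MuscleParams(
            name=name,
            F_max=float(mu["F_max"]),
            l_opt=float(mu["l_opt"]),
            l_slack=float(mu["l_slack"]),
            alpha0=math.radians(float(mu.get("alpha0_deg", 0.0))),
            k_T=float(mu.get("k_T", 35.0)),
            v_max=float(mu.get("v_max", 10.0)),
            joint_spans={j: float(r) for j, r in mu["moment_arms"].items()},
            curves=curves,
        ))
    q_ref_deg = m.get("reference_posture_deg", {"hip": 45, "knee": 60, "ankle": 10})
    q_ref = tuple(math.radians(float(q_ref_deg[j])) for j in JOINTS)
    return ScaledModel(
        height=height, mass=mass, gravity=float(m.get("gravity", 9.81)),
        foot=segs["foot"], shank=segs["shank"], thigh=segs["thigh"],
        hat=segs["hat"],
        ankle_height=float(m["ankle_height_frac"]) * height,
        ankle_from_heel=float(m["ankle_from_heel_frac"]) * segs["foot"].length,
        muscles=tuple(muscles), q_ref=q_ref,
    )


def default_model() -> ScaledModel:
    """The shipped reference athlete: 1.80 m, 75 kg."""
    ref = importlib.resources.files("neuromusc.data") / "model_default.yaml"
    with ref.open() as fh:
        return load_model(fh)


def scale_model(height: float, mass: float, reference: ScaledModel) -> ScaledModel:
    """Scale a reference model to new anthropometrics.

    Lengths scale with the height ratio, masses with the mass ratio,
    inertias follow mass * length^2 (via the stored gyration fractions),
    muscle F_max with the mass ratio and l_opt / l_slack with the height
    ratio. Scaling is compositional: rescaling a scaled model equals
    scaling the original reference.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    hr, mr = height / reference.height, mass / reference.mass

    def _seg(s: Segment) -> Segment:
        return Segment(name=s.name, length=s.length * hr, mass=s.mass * mr,
                       com_offset=s.com_offset * hr, gyration=s.gyration)

    muscles = tuple(
        replace(mu, F_max=mu.F_max * mr, l_opt=mu.l_opt * hr,
                l_slack=mu.l_slack * hr)
        for mu in reference.muscles
    )
    return ScaledModel(
        height=height, mass=mass, gravity=reference.gravity,
        foot=_seg(reference.foot), shank=_seg(reference.shank),
        thigh=_seg(reference.thigh), hat=_seg(reference.hat),
        ankle_height=reference.ankle_height * hr,
        ankle_from_heel=reference.ankle_from_heel * hr,
        muscles=muscles, q_ref=reference.q_ref,
    )


# ---------------------------------------------------------------------------
# muscle geometry

def moment_arm_matrix(model: ScaledModel, q=None) -> np.ndarray:
    """Moment-arm matrix R, joints x muscles (m), at posture ``q``.

    Entries are signed (extension/plantarflexion-positive) and constant in
    posture with the shipped constant-arm routing; ``q`` is accepted for
    interface stability with posture-dependent routings.
    """
    R = np.zeros((len(JOINTS), len(model.muscles)))
    for i, mu in enumerate(model.muscles):
        for j, joint in enumerate(JOINTS):
            R[j, i] = mu.joint_spans.get(joint, 0.0)
    return R


def musculotendon_lengths(model: ScaledModel, q) -> np.ndarray:
    """Musculotendon lengths (m) at posture ``q`` = (hip, knee, ankle) rad.

    ``q`` may be a single posture (3,) or a trajectory (n, 3); returns
    (n_muscles,) or (n, n_muscles).
    """
    q = np.asarray(q, dtype=float)
    dq = q - np.asarray(model.q_ref)
    R = moment_arm_matrix(model)                      # joints x muscles
    l_ref = np.array([mu.l_opt * math.cos(mu.alpha0) + mu.l_slack
                      for mu in model.muscles])
    return l_ref + dq @ R
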