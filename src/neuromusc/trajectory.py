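"""Smooth trajectory primitives for the task generator.

Quintic Hermite segments (position, velocity and acceleration prescribed at
both ends) are the minimal polynomial family that joins phases with C2
continuity; the classic minimum-jerk profile is the special case with zero
boundary velocity and acceleration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["quintic", "quintic_eval", "poly_bc", "min_jerk", "PhasePlan"]


def poly_bc(T: float, start: tuple, end: tuple) -> np.ndarray:
    """Coefficients (ascending powers) of the minimal-degree polynomial on
    [0, T] matching the given derivative values at each end.

    ``start`` and ``end`` list (position, velocity, acceleration, jerk, ...)
    values; the polynomial degree is ``len(start) + len(end) - 1``. Used to
    join movement phases with whatever continuity order the adjacent phase
    requires (e.g. jerk-continuous entry into ballistic flight).
    """
    if T <= 0:
        raise ValueError("phase duration must be positive")
    n = len(start) + len(end)
    M = np.zeros((n, n))
    b = np.zeros(n)
    k = np.arange(n)
    from math import factorial
    for d, val in enumerate(start):
        M[d, d] = factorial(d)
        b[d] = val
    for i, (d, val) in enumerate(enumerate(end)):
        row = len(start) + i
        # falling factorial k (k-1) ... (k-d+1) * T^(k-d)
        coef = np.ones(n)
        for j in range(d):
            coef *= np.clip(k - j, 0, None)
        M[row] = coef * T ** np.clip(k - d, 0, None)
        b[row] = val
    return np.linalg.solve(M, b)


def quintic(T: float, y0: float, v0: float, a0: float,
            y1: float, v1: float, a1: float) -> np.ndarray:
    """Coefficients (ascending powers) of the quintic on [0, T] matching
    position/velocity/acceleration at both ends."""
    return poly_bc(T, (y0, v0, a0), (y1, v1, a1))


def quintic_eval(coef: np.ndarray, t, deriv: int = 0):
    """Evaluate a quintic (ascending coefficients) or its derivative."""
    c = np.polynomial.polynomial.polyder(coef, deriv) if deriv else coef
    return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), c)


def min_jerk(t, T: float, y0: float, y1: float):
    """Minimum-jerk profile from rest to rest over duration T."""
    s = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    return y0 + (y1 - y0) * (10 * s**3 - 15 * s**4 + 6 * s**5)


class PhasePlan:
    """Ordered movement phases on a fixed uniform time grid.

    Durations are snapped to whole samples (cumulative rounding, so the
    total is exact); the last phase absorbs any remainder of the trial.
    """

    def __init__(self, n_samples: int, dt: float,
                 phases: list[tuple[str, float]]):
        self.n = n_samples
        self.dt = dt
        total = n_samples * dt
        if sum(d for _, d in phases) > total + 1e-9:
            raise ValueError("phase durations exceed trial duration")
        bounds = []
        acc = 0.0
        start = 0
        for name, dur in phases:
            acc += dur
            end = min(int(round(acc / dt)), n_samples)
            bounds.append((name, start, end))
            start = end
        if start < n_samples:  # remainder -> extend final phase
            name, s0, _ = bounds[-1]
            bounds[-1] = (name, s0, n_samples)
        self.bounds = bounds

    def slice(self, name: str) -> slice:
        for pname, s0, s1 in self.bounds:
            if pname == name:
                return slice(s0, s1)
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(p == name for p, _, _ in self.bounds)

    def labels(self) -> np.ndarray:
        out = np.empty(self.n, dtype=object)
        for name, s0, s1 in self.bounds:
            out[s0:s1] = name
        return out

    def duration(self, name: str) -> float:
        s = self.slice(name)
        return (s.stop - s.start) * self.dt
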