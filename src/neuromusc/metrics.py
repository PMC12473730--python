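"""Derived neuromuscular metrics, adaptation proxies, and replicate-based
uncertainty quantification.

Scalar summaries per trial (peak vertical GRF, rate of force development,
loading rate, impulses, stance-phase peak joint moments, activation
synchrony, timing), z-scored adaptation proxies across a task x load
ensemble, standardized mean differences against a named baseline, and
bias-corrected and accelerated (BCa) bootstrap intervals over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import stats


from .tasks import TrialRecord

__all__ = [
    "METRIC_UNITS", "MetricSet", "ProxyVector", "UncertaintySummary",
    "force_onset", "all_force_onsets", "compute_rfd", "loading_rate",
    "synchrony_index",
    "moment_variability", "peak_metrics", "adaptation_proxies",
    "smd", "bca_interval", "PRIME_MOVER_GROUPS",
]

METRIC_UNITS = {
    "peak_vgrf": "N/kg", "rfd": "N/s", "loading_rate": "N/s",
    "impulse": "N*s", "peak_moment_hip": "Nm/kg",
    "peak_moment_knee": "Nm/kg", "peak_moment_ankle": "Nm/kg",
    "moment_impulse_hip": "Nm*s", "moment_impulse_knee": "Nm*s",
    "moment_impulse_ankle": "Nm*s", "time_to_peak_moment": "s",
    "peak_moment_propulsion": "Nm/kg", "peak_power": "W/kg",
    "synchrony": "1", "contact_time": "s", "amortization_time": "s",
}

# prime movers for the synchrony index: hip extensors, knee extensors,
# plantar flexors
PRIME_MOVER_GROUPS = ("gluteus_maximus", "hamstrings", "vasti",
                      "rectus_femoris", "gastrocnemius", "soleus")


@dataclass
class MetricSet:
    """Scalar summaries of one trial. Mass-normalized fields divide by the
    athlete's total body mass."""

    task: str
    replicate: int
    peak_vgrf: float                  # N/kg
    rfd: float                        # N/s
    loading_rate: float               # N/s
    impulse: float                    # N*s (net vertical, over contact)
    peak_moment_hip: float            # Nm/kg, per leg, stance frames
    peak_moment_knee: float
    peak_moment_ankle: float
    moment_impulse_hip: float         # Nm*s per leg (extensor side)
    moment_impulse_knee: float
    moment_impulse_ankle: float
    time_to_peak_moment: float        # s from contact onset
    peak_moment_propulsion: float     # Nm/kg, max of hip/knee during the
                                      # concentric (propulsion) effort
    peak_power: float                 # W/kg, peak joint power summed
    synchrony: float                  # mean pairwise Pearson r, [-1, 1]
    contact_time: float               # s
    amortization_time: float          # s (nan for tasks without one)
    peak_activations: dict[str, float] = field(default_factory=dict)

    def scalar_fields(self) -> dict[str, float]:
        out = {}
        for f in fields(self):
            if f.name in ("task", "replicate", "peak_activations"):
                continue
            out[f.name] = getattr(self, f.name)
        for name, v in self.peak_activations.items():
            out[f"peak_act_{name}"] = v
        return out


@dataclass
class ProxyVector:
    """z-scored adaptation proxies for one trial."""

    task: str
    replicate: int
    maximal_strength: float
    explosive: float
    tendon_ssc: float
    coordination: float
    ensemble_id: str = ""

    @property
    def composite(self) -> float:
        return float(np.mean([self.maximal_strength, self.explosive,
                              self.tendon_ssc, self.coordination]))


@dataclass
class UncertaintySummary:
    outcome: str
    point: float                      # median over replicates
    ci_lo: float
    ci_hi: float
    smd_vs_baseline: float
    robust_scale: bool
    n_replicates: int
    n_bootstrap: int


# ---------------------------------------------------------------------------
# GRF-derived metrics


def force_onset(t, fz, mass, gravity=9.81, threshold_frac=0.05):
    """Force onset: first upward crossing of ``threshold_frac x body
    weight`` after a phase in which the force was below the threshold
    (flight or quiet unloading). Falls back to the time of the force
    minimum for traces that never unload (strength trials). The crossing
    time is linearly interpolated between samples."""
    t = np.asarray(t, dtype=float)
    fz = np.asarray(fz, dtype=float)
    onsets = all_force_onsets(t, fz, mass, gravity, threshold_frac)
    return onsets[0]


def all_force_onsets(t, fz, mass, gravity=9.81, threshold_frac=0.05):
    """All force onsets (interpolated threshold-crossing times); falls
    back to the force-minimum time when the trace never unloads."""
    t = np.asarray(t, dtype=float)
    fz = np.asarray(fz, dtype=float)
    thr = threshold_frac * mass * gravity
    below = fz < thr
    crossings = np.flatnonzero(below[:-1] & ~below[1:])
    out = []
    dt = t[1] - t[0]
    for i in crossings:
        f0, f1 = fz[i], fz[i + 1]
        frac = (thr - f0) / (f1 - f0) if f1 != f0 else 0.0
        # refine with a local quadratic through (i, i+1, i+2): the force
        # rise at contact is strongly curved, and the linear crossing
        # carries an O(dt^2) bias that the sampling step would otherwise
        # leak into RFD
        if i + 2 < len(fz):
            c0 = f0
            c1 = (-3 * fz[i] + 4 * fz[i + 1] - fz[i + 2]) / 2.0
            c2 = (fz[i] - 2 * fz[i + 1] + fz[i + 2]) / 2.0
            disc = c1**2 - 4 * c2 * (c0 - thr)
            if abs(c2) > 1e-12 and disc >= 0:
                for root in ((-c1 + np.sqrt(disc)) / (2 * c2),
                             (-c1 - np.sqrt(disc)) / (2 * c2)):
                    if 0.0 <= root <= 1.0:
                        frac = root
                        break
        out.append(float(t[i] + frac * dt))
    if not out:
        # no unloaded phase (lifts): onset at the force minimum, located
        # to sub-sample precision by parabolic interpolation so the onset
        # is continuous in the sampling step
        i = int(np.argmin(fz))
        if 0 < i < len(fz) - 1:
            denom = fz[i - 1] - 2 * fz[i] + fz[i + 1]
            delta = (0.5 * (fz[i - 1] - fz[i + 1]) / denom
                     if abs(denom) > 1e-12 else 0.0)
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        out = [float(t[i] + delta * (t[1] - t[0]))]
    return out


def compute_rfd(t, fz, mass, window=0.100, gravity=9.81, onset=None):
    """Rate of force development: (F(t0 + window) - F(t0)) / window, with
    t0 the force onset; values at the window ends are linearly
    interpolated in time."""
    t = np.asarray(t, dtype=float)
    fz = np.asarray(fz, dtype=float)
    if onset is None:
        onset = force_onset(t, fz, mass, gravity)
    if onset + window > t[-1]:
        raise ValueError("trace ends before the RFD window")
    f0 = float(np.interp(onset, t, fz))
    f1 = float(np.interp(onset + window, t, fz))
    return (f1 - f0) / window


def loading_rate(t, fz, mass, onset=None, window=0.100, slope_win=0.010,
                 gravity=9.81):
    """Peak moving-window (default 10 ms) slope of the vertical GRF during
    the first ``window`` seconds after force onset."""
    t = np.asarray(t, dtype=float)
    fz = np.asarray(fz, dtype=float)
    if onset is None:
        onset = force_onset(t, fz, mass, gravity)
    dt = t[1] - t[0]
    k = max(int(round(slope_win / dt)), 1)
    i0 = int(np.searchsorted(t, onset))
    i1 = min(int(np.searchsorted(t, onset + window)), len(t) - k)
    if i1 <= i0:
        return 0.0
    seg = fz[i0:i1 + k]
    slopes = (seg[k:] - seg[:-k]) / (k * dt)
    return float(slopes.max()) if len(slopes) else 0.0


# ---------------------------------------------------------------------------
# activation metrics


def synchrony_index(activations, prime_movers=None, names=None,
                    resample=None):
    """Mean pairwise Pearson correlation between prime-mover activation
    time series, optionally resampled to ``resample`` points (the trial
    pipeline resamples its contact window to 101 points).

    Constant traces are excluded pairwise with a warning; if every pair is
    excluded the index is undefined and an error is raised.
    """
    act = np.asarray(activations, dtype=float)
    if act.ndim != 2:
        raise ValueError("activations must be (frames, muscles)")
    if names is not None and prime_movers is not None:
        cols = [names.index(p) for p in prime_movers if p in names]
        act = act[:, cols]
    if act.shape[1] < 2:
        raise ValueError("need at least two prime movers")
    if act.shape[0] < 3:
        raise ValueError("need at least three samples")
    if resample is not None:
        x = np.linspace(0, 1, act.shape[0])
        xi = np.linspace(0, 1, resample)
        act = np.stack([np.interp(xi, x, act[:, j])
                        for j in range(act.shape[1])], axis=1)
    sd = act.std(axis=0)
    rs = []
    excluded = 0
    for i in range(act.shape[1]):
        for j in range(i + 1, act.shape[1]):
            if sd[i] < 1e-12 or sd[j] < 1e-12:
                excluded += 1
                continue
            rs.append(float(np.corrcoef(act[:, i], act[:, j])[0, 1]))
    if excluded:
        warnings.warn(f"{excluded} constant-trace pairs excluded from the "
                      "synchrony index", RuntimeWarning, stacklevel=2)
    if not rs:
        raise ValueError("synchrony undefined: all pairs constant")
    return float(np.clip(np.mean(rs), -1.0, 1.0))


def moment_variability(waveforms, resample=101):
    """Across-replicate waveform variability, percent.

    Each replicate waveform is time-normalized to 0-100% of its cycle;
    the point-wise across-replicate coefficient of variation (population
    SD / |mean|) is averaged and returned x100.
    """
    if len(waveforms) < 2:
        raise ValueError("need at least two replicates")
    xi = np.linspace(0, 1, resample)
    W = np.stack([np.interp(xi, np.linspace(0, 1, len(w)),
                            np.asarray(w, dtype=float))
                  for w in waveforms])
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=0)
    keep = np.abs(mean) > 1e-9
    cv = np.zeros(resample)
    cv[keep] = sd[keep] / np.abs(mean[keep])
    return float(cv[keep].mean() * 100) if keep.any() else 0.0


# ---------------------------------------------------------------------------
# per-trial summary


def _main_effort_slice(trial: TrialRecord) -> slice:
    """Contact window of the main effort: amortization+propulsion for drop
    jumps, descent+propulsion for jumps, the whole repetition for lifts."""
    if trial.task.kind == "strength":
        return slice(0, len(trial.t))
    first = ("amortization" if trial.has_phase("amortization")
             else "descent")
    s0 = trial.phase_slice(first).start
    s1 = trial.phase_slice("propulsion").stop
    return slice(s0, s1)


def peak_metrics(trial: TrialRecord, model) -> MetricSet:
    """All MetricSet fields for one solved trial."""
    for attr in ("grf", "tau"):
        if getattr(trial, attr) is None:
            raise ValueError(f"trial is missing the {attr} series")
    if trial.activations is None:
        raise ValueError("trial is missing the activations series "
                         "(run static optimization first)")
    mass = model.mass
    g = model.gravity
    t, fz = trial.t, trial.grf[:, 1]
    contact = trial.contact
    dt = trial.dt

    # the trial-level RFD / loading rate is the steepest rise over all
    # force onsets (drop landing, rebound landing)
    onsets = [o for o in all_force_onsets(t, fz, mass, g)
              if o + 0.100 <= t[-1]]
    onset = onsets[0] if onsets else force_onset(t, fz, mass, g)
    rfd = max(compute_rfd(t, fz, mass, onset=o, gravity=g) for o in onsets) \
        if onsets else compute_rfd(t, fz, mass, gravity=g)
    lr = max(loading_rate(t, fz, mass, onset=o, gravity=g) for o in onsets) \
        if onsets else loading_rate(t, fz, mass, gravity=g)
    impulse = float(np.trapezoid(np.where(contact, fz - mass * g, 0.0), t))

    # stance-phase per-leg moments
    tau_st = np.where(contact[:, None], trial.tau, 0.0)
    peaks = tau_st.max(axis=0) / mass
    mom_imp = np.trapezoid(np.clip(tau_st, 0.0, None), t, axis=0)
    # time to peak moment (dominant joint), from first contact onset
    jdom = int(np.argmax(tau_st.max(axis=0)))
    i_peak = int(np.argmax(tau_st[:, jdom]))
    i_con = int(np.argmax(contact))
    ttp = max(float(t[i_peak] - t[i_con]), 0.0)

    # peak joint power: sum over joints of per-leg moment x joint velocity
    qd_sign = -trial.qd        # extension-positive angular velocities
    power = (trial.tau * qd_sign).sum(axis=1)
    peak_power = float(np.where(contact, power, 0.0).max() / mass)

    if trial.task.kind == "strength":
        psl = slice(0, len(t))
    else:
        psl = trial.phase_slice("propulsion")
    peak_prop = float(trial.tau[psl, :2].max() / mass)

    # synchrony: resample the main-effort window at 101 fixed *times*
    # (ending 2 ms before the window boundary), so the index is
    # independent of the trace sampling step
    sl = _main_effort_slice(trial)
    names = list(model.muscle_names)
    t_lo = float(t[sl.start])
    t_hi = float(t[sl.stop - 1]) + dt
    ts = np.linspace(t_lo, t_hi - 0.002, 101)
    cols = [names.index(p) for p in PRIME_MOVER_GROUPS if p in names]
    act_win = np.stack([np.interp(ts, t, trial.activations[:, i])
                        for i in cols], axis=1)
    sync = synchrony_index(act_win)
    peak_act = {n: float(trial.activations[contact, i].max())
                for i, n in enumerate(names)}

    contact_time = float(contact.sum() * dt)
    if trial.has_phase("amortization"):
        asl = trial.phase_slice("amortization")
        amort = (asl.stop - asl.start) * dt
    else:
        amort = float("nan")

    return MetricSet(
        task=trial.task.name, replicate=trial.replicate,
        peak_vgrf=float(fz.max() / mass), rfd=rfd, loading_rate=lr,
        impulse=impulse,
        peak_moment_hip=float(peaks[0]), peak_moment_knee=float(peaks[1]),
        peak_moment_ankle=float(peaks[2]),
        moment_impulse_hip=float(mom_imp[0]),
        moment_impulse_knee=float(mom_imp[1]),
        moment_impulse_ankle=float(mom_imp[2]),
        time_to_peak_moment=ttp, peak_moment_propulsion=peak_prop,
        peak_power=peak_power, synchrony=sync,
        contact_time=contact_time, amortization_time=amort,
        peak_activations=peak_act)


# ---------------------------------------------------------------------------
# adaptation proxies


def _zscores(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd < 1e-12:
        warnings.warn("zero-variance proxy set to 0", RuntimeWarning,
                      stacklevel=3)
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def adaptation_proxies(metric_sets, ensemble_id="default"):
    """Map a MetricSet ensemble to z-scored adaptation proxies.

    maximal strength <- peak (dominant-joint) moment + moment impulse;
    explosive <- RFD and (negated) time-to-peak; tendon/SSC <- peak ankle
    moment + GRF loading rate; coordination <- synchrony index. Each
    proxy is the mean of its z-scored constituents across the ensemble.
    """
    ms = list(metric_sets)
    if len(ms) < 2:
        raise ValueError("proxy standardization needs >= 2 trials")

    def col(name):
        return np.array([getattr(m, name) for m in ms])

    peak_mom = np.maximum(col("peak_moment_hip"), col("peak_moment_knee"))
    z = {}
    z["strength"] = np.mean([_zscores(peak_mom)[0],
                             _zscores(np.maximum(col("moment_impulse_hip"),
                                                 col("moment_impulse_knee"))
                                      )[0]], axis=0)
    z["explosive"] = np.mean([_zscores(col("rfd"))[0],
                              -_zscores(col("time_to_peak_moment"))[0]],
                             axis=0)
    z["tendon"] = np.mean([_zscores(col("peak_moment_ankle"))[0],
                           _zscores(col("loading_rate"))[0]], axis=0)
    z["coord"] = _zscores(col("synchrony"))[0]
    out = []
    for i, m in enumerate(ms):
        out.append(ProxyVector(
            task=m.task, replicate=m.replicate,
            maximal_strength=float(z["strength"][i]),
            explosive=float(z["explosive"][i]),
            tendon_ssc=float(z["tendon"][i]),
            coordination=float(z["coord"][i]),
            ensemble_id=ensemble_id))
    return out


# ---------------------------------------------------------------------------
# uncertainty


def smd(replicates, baseline, skew_threshold=1.0):
    """Standardized mean difference (median(m) - m0) / s_m.

    ``s_m`` is the across-replicate SD, replaced by MAD x 1.4826 when the
    adjusted Fisher-Pearson sample skewness exceeds ``skew_threshold`` in
    magnitude (the robust-scale flag is returned alongside).
    """
    x = np.asarray(replicates, dtype=float)
    if len(x) < 3:
        raise ValueError("SMD needs at least 3 replicates")
    med = np.median(x)
    skew = stats.skew(x, bias=False)
    robust = bool(abs(skew) > skew_threshold)
    if robust:
        s = stats.median_abs_deviation(x, scale=1 / 1.4826)
    else:
        s = x.std(ddof=1)
    if s < 1e-12:
        raise ValueError("SMD undefined: zero dispersion")
    return float((med - baseline) / s), robust


def bca_interval(replicates, statistic=np.mean, B=200, seed=0, level=0.95,
                 force_z0=None, force_accel=None):
    """Bias-corrected and accelerated bootstrap confidence interval.

    Bias correction z0 is the normal quantile of the bootstrap fraction
    below the point estimate; acceleration comes from the jackknife
    skewness. Forcing both to zero recovers the percentile interval.
    Deterministic given ``seed``.
    """
    x = np.asarray(replicates, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("BCa needs at least 5 replicates")
    rng = np.random.default_rng(seed)
    theta = float(statistic(x))
    boot = np.empty(B)
    idx = rng.integers(0, n, size=(B, n))
    for b in range(B):
        boot[b] = statistic(x[idx[b]])
    if np.ptp(boot) < 1e-12:
        warnings.warn("degenerate bootstrap distribution: point interval",
                      RuntimeWarning, stacklevel=2)
        return theta, theta
    # bias correction
    prop = np.mean(boot < theta)
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = stats.norm.ppf(prop) if force_z0 is None else force_z0
    # acceleration from the jackknife
    if force_accel is None:
        jack = np.array([statistic(np.delete(x, i)) for i in range(n)])
        d = jack.mean() - jack
        denom = (d**2).sum() ** 1.5
        accel = (d**3).sum() / (6 * denom) if denom > 1e-24 else 0.0
    else:
        accel = force_accel
    alpha = (1 - level) / 2
    out = []
    for a in (alpha, 1 - alpha):
        z = stats.norm.ppf(a)
        adj = z0 + (z0 + z) / (1 - accel * (z0 + z))
        out.append(float(np.quantile(boot, stats.norm.cdf(adj))))
    return out[0], out[1]


def summarize_outcome(name, replicates, baseline, B=200, seed=0):
    """Replicate-based uncertainty summary for one outcome."""
    x = np.asarray(replicates, dtype=float)
    lo, hi = bca_interval(x, np.median, B=B, seed=seed)
    try:
        effect, robust = smd(x, baseline)
    except ValueError:
        effect, robust = float("nan"), False
    return UncertaintySummary(
        outcome=name, point=float(np.median(x)), ci_lo=lo, ci_hi=hi,
        smd_vs_baseline=effect, robust_scale=robust,
        n_replicates=len(x), n_bootstrap=B)
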