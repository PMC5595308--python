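"""Measurements and curve fits applied to simulated (or recorded) sweeps.

This module reduces sweep families to the standard electrophysiology curves
— conductance-voltage (GV), steady-state fast inactivation (SSFI),
charge-voltage (QV), recovery/onset time courses, persistent-current
fractions — and fits them with the standard functional forms:

* single Boltzmann  Y/Ymax = 1 / (1 + exp(-z e (V - V1/2) / kB T))
* mono/bi-exponential  y(t) = offset + sum_i a_i exp(-t / tau_i)
* global biexponential: one shared (tau_fast, tau_slow) pair across a set of
  curves with per-curve amplitudes and offsets
* Hill equation for proton block of conductance,
  G(pH) = plateau / (1 + ([H+] / Ka)^h) with Ka = 10^(-pKa)

All fits are bounded nonlinear least squares (scipy) with a small fixed
multi-start to avoid local minima in the exponential and Hill problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .engine import Trajectory
from .protocols import SweepFamily

__all__ = [
    "CurveSet", "BoltzmannFit", "ExpFit", "HillFit", "GlobalBiexpFit",
    "peak_current", "gv_curve", "availability_curve", "qv_curve",
    "fit_boltzmann", "measure_persistent", "integrate_charge",
    "fit_exponentials", "global_biexp_fit", "fit_hill",
]

#: Boltzmann constant in meV/K, so z*(V-V1/2)[mV]/(KB*T) is dimensionless
KB_MEV_PER_K = 0.08617333


@dataclass
class CurveSet:
    """An (x, y) summary curve with provenance.

    ``x`` must be strictly monotone (voltages in mV, times in ms, or pH).
    """

    x: np.ndarray
    y: np.ndarray
    normalized: bool = False
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have matching shapes")
        d = np.diff(self.x)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("curve x values must be strictly monotone")

    def normalize(self) -> "CurveSet":
        """Scale y to a peak magnitude of 1."""
        peak = np.max(np.abs(self.y))
        if peak == 0:
            return CurveSet(self.x, self.y.copy(), True, self.label, dict(self.meta))
        return CurveSet(self.x, self.y / peak, True, self.label, dict(self.meta))


@dataclass
class BoltzmannFit:
    v_half: float        # midpoint, mV
    z: float             # apparent valence, elementary charges
    y_max: float
    temperature: float   # K
    residual: float

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        kt = KB_MEV_PER_K * self.temperature
        return self.y_max / (1.0 + np.exp(-self.z * (V - self.v_half) / kt))


@dataclass
class ExpFit:
    taus: tuple[float, ...]        # ms, ascending
    amplitudes: tuple[float, ...]  # matched to taus
    offset: float
    residual: float
    degenerate: bool = False       # n=2 fit with tau ratio < 1.5

    @property
    def tau_fast(self) -> float:
        return self.taus[0]

    @property
    def tau_slow(self) -> float:
        return self.taus[-1]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        y = np.full(t.shape, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            y = y + a * np.exp(-t / tau)
        return y


@dataclass
class GlobalBiexpFit:
    tau_fast: float
    tau_slow: float
    amplitudes: list[tuple[float, float]]   # per-curve (a_fast, a_slow)
    offsets: list[float]
    residual: float


@dataclass
class HillFit:
    pka: float
    hill: float
    plateau: float
    residual: float

    def __call__(self, ph):
        ph = np.asarray(ph, dtype=float)
        return self.plateau / (1.0 + (10.0 ** (self.pka - ph)) ** self.hill)


# ---------------------------------------------------------------------------
# Trace measurements
# ---------------------------------------------------------------------------

def _blank_mask(traj: Trajectory, blank: float | None) -> np.ndarray:
    if blank is None:
        blank = 3.0 * float(traj.meta.get("clamp_tau", 0.05))
    return traj.t >= blank


def peak_current(traj: Trajectory, *, blank: float | None = None,
                 t_max: float | None = None, smooth: float = 0.1) -> float:
    """Signed extremum of ionic current after the clamp-settling blank.

    The blanking window (default 3x clamp_tau) excludes the capacitive
    settling period; a short boxcar of width ``smooth`` ms (default 0.1,
    emulating the recording low-pass filter) suppresses single-sample noise
    spikes before the extremum is taken.  Returns the signed value of
    largest magnitude, so inward peaks are negative.
    """
    mask = _blank_mask(traj, blank)
    if t_max is not None:
        mask &= traj.t <= t_max
    i = traj.i_ionic[mask]
    if i.size == 0:
        raise ValueError("no samples after the blanking window")
    if smooth > 0 and i.size > 2:
        dt = float(np.median(np.diff(traj.t[mask])))
        w = max(int(round(smooth / dt)), 1)
        if w > 1:
            kernel = np.ones(w) / w
            i = np.convolve(i, kernel, mode="valid")
    return float(i[np.argmax(np.abs(i))])


def gv_curve(family: SweepFamily, e_rev: float, *, normalize: bool = True,
             blank: float | None = None, min_driving: float = 5.0) -> CurveSet:
    """Conductance-voltage curve: G(V) = I_peak / (V - E_rev) per sweep.

    Steps within ``min_driving`` mV of the reversal potential are excluded:
    the conductance there divides a near-zero current by a near-zero driving
    force and is dominated by noise.  The curve is normalised to its maximum
    by default.
    """
    vs, gs = [], []
    for v, traj in zip(family.variables, family.sweeps):
        if abs(v - e_rev) < max(min_driving, 1e-9):
            continue
        gs.append(peak_current(traj, blank=blank) / (v - e_rev))
        vs.append(v)
    curve = CurveSet(np.array(vs), np.array(gs), label=f"gv:{family.label}",
                     meta=dict(family.meta))
    return curve.normalize() if normalize else curve


def availability_curve(family: SweepFamily, *, test_segment: int = -1,
                       blank: float | None = None) -> CurveSet:
    """Normalised peak test-pulse current vs the family variable.

    Used for SSFI and recovery families: availability is read as the peak
    inward current during the final test pulse, normalised to the sweep with
    maximal availability.
    """
    peaks = []
    for traj in family.sweeps:
        # restrict to the final command segment (the test pulse)
        seg_v = traj.v_command
        last_v = seg_v[-1]
        changes = np.flatnonzero(np.diff(seg_v) != 0)
        t_start = traj.t[changes[-1] + 1] if changes.size else traj.t[0]
        mask = traj.t >= t_start + (3.0 * float(traj.meta.get("clamp_tau", 0.05))
                                    if blank is None else blank)
        i = traj.i_ionic[mask]
        peaks.append(float(i[np.argmax(np.abs(i))]))
    peaks = np.array(peaks)
    ref = np.max(np.abs(peaks))
    y = np.abs(peaks) / ref if ref > 0 else peaks
    return CurveSet(family.variables.copy(), y, normalized=True,
                    label=f"avail:{family.label}", meta=dict(family.meta))


def measure_persistent(traj: Trajectory, *, window: float = 5.0,
                       blank: float | None = None) -> float:
    """Persistent-current fraction of a long depolarising sweep.

    Mean current over the final ``window`` ms divided by the peak inward
    current of the same sweep.  Raises on a zero peak.
    """
    if traj.t[-1] < 100.0 - 1e-9:
        raise ValueError("persistent current requires a depolarization of >= 100 ms")
    peak = peak_current(traj, blank=blank)
    if peak == 0:
        raise ValueError("zero peak current; persistent fraction undefined")
    tail = traj.i_ionic[traj.t >= traj.t[-1] - window]
    return float(abs(tail.mean()) / abs(peak))


def integrate_charge(traj: Trajectory, window: tuple[float, float] | None = None) -> float:
    """Trapezoidal time-integral of the gating current over ``window`` (ms)."""
    t, ig = traj.t, traj.i_gating
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ValueError(f"window {window} outside trajectory span ({t[0]}, {t[-1]})")
        mask = (t >= lo) & (t <= hi)
        t, ig = t[mask], ig[mask]
    return float(np.trapezoid(ig, t))


def qv_curve(family: SweepFamily, *, segment: int = 0, normalize: bool = True,
             invert: bool = False) -> CurveSet:
    """Charge-voltage curve: integrated gating current of one segment per sweep.

    ``segment`` selects which command segment to integrate (0 = the
    depolarising step for QV-on; 1 = the repolarisation for QV-off).  With
    ``invert`` the off-charge is reported as 1 - |Q|/max|Q| (how much charge
    remains in the outward conformation), the convention used for
    deactivation curves.
    """
    qs = []
    for traj in family.sweeps:
        changes = np.flatnonzero(np.diff(traj.v_command) != 0)
        bounds = np.concatenate(([traj.t[0]], traj.t[changes + 1], [traj.t[-1]]))
        lo, hi = bounds[segment], bounds[segment + 1]
        qs.append(integrate_charge(traj, (lo, hi)))
    qs = np.array(qs)
    if invert:
        qmax = np.max(np.abs(qs))
        y = 1.0 - np.abs(qs) / qmax if qmax > 0 else qs
        return CurveSet(family.variables.copy(), y, normalized=True,
                        label=f"qv_off:{family.label}", meta=dict(family.meta))
    curve = CurveSet(family.variables.copy(), qs, label=f"qv:{family.label}",
                     meta=dict(family.meta))
    return curve.normalize() if normalize else curve


# ---------------------------------------------------------------------------
# Curve fits
# ---------------------------------------------------------------------------

def fit_boltzmann(curve: CurveSet, temperature: float = 293.0) -> BoltzmannFit:
    """Least-squares single-Boltzmann fit of a voltage-dependence curve.

    ``z > 0`` describes activation-type curves (rising with depolarisation);
    inactivation-type curves fit with ``z < 0``.  Requires at least five
    points spanning the transition.
    """
    x, y = curve.x, curve.y
    if x.size < 5:
        raise ValueError("need at least 5 points for a Boltzmann fit")
    kt = KB_MEV_PER_K * temperature

    def model(p, V):
        v_half, z, y_max = p
        return y_max / (1.0 + np.exp(np.clip(-z * (V - v_half) / kt, -500, 500)))

    y_max0 = np.max(np.abs(y)) or 1.0
    # crude midpoint guess: where y crosses half max
    yy = y / y_max0
    k = int(np.argmin(np.abs(yy - 0.5)))
    rising = yy[-1] > yy[0]
    p0 = np.array([x[k], 3.0 if rising else -3.0, y_max0])

    sol = least_squares(lambda p: model(p, x) - y, p0,
                        bounds=([x.min() - 200, -60, 0], [x.max() + 200, 60, np.inf]))
    if not sol.success:
        raise RuntimeError(
            f"Boltzmann fit failed on curve {curve.label!r} "
            f"(x range {x.min()}..{x.max()}, n={x.size})"
        )
    v_half, z, y_max = sol.x
    return BoltzmannFit(float(v_half), float(z), float(y_max), temperature,
                        float(np.linalg.norm(sol.fun)))


def _exp_model(p: np.ndarray, t: np.ndarray, n: int) -> np.ndarray:
    offset = p[0]
    y = np.full(t.shape, offset)
    for i in range(n):
        a, log_tau = p[1 + 2 * i], p[2 + 2 * i]
        y = y + a * np.exp(-t / np.exp(log_tau))
    return y


def fit_exponentials(t, y, n: int = 1, *, n_starts: int = 3,
                     seed: int = 1234) -> ExpFit:
    """Fit y(t) = offset + sum of ``n`` decaying exponentials (n in {1, 2}).

    Time constants are optimised in log space with a small fixed-seed
    multi-start; they are returned ascending, and ``tau_fast`` accesses the
    smaller one.  A biexponential fit whose tau ratio is below 1.5 is flagged
    ``degenerate``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    if t.size < 3 * n + 1:
        raise ValueError(f"need at least {3 * n + 1} points for n={n}")

    span = max(t[-1] - t[0], 1e-12)
    amp0 = y[0] - y[-1]
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        if n == 1:
            taus0 = [span / 3 * 10 ** rng.uniform(-0.5, 0.5)] if s else [span / 3]
            p0 = [y[-1], amp0, math.log(taus0[0])]
        else:
            f = 10 ** rng.uniform(-0.5, 0.5, size=2) if s else np.ones(2)
            p0 = [y[-1], amp0 / 2, math.log(span / 20 * f[0]),
                  amp0 / 2, math.log(span / 2 * f[1])]
        sol = least_squares(lambda p: _exp_model(p, t, n) - y, p0, method="lm",
                            max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("exponential fit failed to converge")

    offset = float(best.x[0])
    comps = sorted(
        ((math.exp(best.x[2 + 2 * i]), float(best.x[1 + 2 * i])) for i in range(n)),
        key=lambda c: c[0],
    )
    taus = tuple(c[0] for c in comps)
    amps = tuple(c[1] for c in comps)
    degenerate = n == 2 and taus[1] / taus[0] < 1.5
    return ExpFit(taus, amps, offset, float(np.linalg.norm(best.fun)), degenerate)


def global_biexp_fit(curves: list[CurveSet], *, n_starts: int = 3,
                     seed: int = 1234) -> GlobalBiexpFit:
    """Biexponential fit with the two time constants shared across curves.

    Each curve keeps its own amplitude pair and offset; only (tau_fast,
    tau_slow) are global, as used for multi-duration slow-inactivation
    recovery/onset families.
    """
    if not curves:
        raise ValueError("need at least one curve")
    ts = [np.asarray(c.x, float) for c in curves]
    ys = [np.asarray(c.y, float) for c in curves]
    m = len(curves)

    def unpack(p):
        tau_f, tau_s = np.exp(p[0]), np.exp(p[1])
        rest = p[2:].reshape(m, 3)
        return tau_f, tau_s, rest

    def resid(p):
        tau_f, tau_s, rest = unpack(p)
        out = []
        for (t, y, (af, as_, off)) in zip(ts, ys, rest):
            out.append(off + af * np.exp(-t / tau_f) + as_ * np.exp(-t / tau_s) - y)
        return np.concatenate(out)

    span = max(t[-1] for t in ts)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        f = np.ones(2) if s == 0 else 10 ** rng.uniform(-0.7, 0.7, size=2)
        p0 = np.concatenate([
            [math.log(span / 30 * f[0]), math.log(span / 2 * f[1])],
            np.concatenate([[y[0] - y[-1], 0.0, y[-1]] for y in ys]),
        ])
        sol = least_squares(resid, p0, method="lm", max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("global biexponential fit failed to converge")

    tau_f, tau_s, rest = unpack(best.x)
    if tau_f > tau_s:
        tau_f, tau_s = tau_s, tau_f
        rest = rest[:, [1, 0, 2]]
    return GlobalBiexpFit(
        float(tau_f), float(tau_s),
        [(float(r[0]), float(r[1])) for r in rest],
        [float(r[2]) for r in rest],
        float(np.linalg.norm(best.fun)),
    )


def fit_hill(ph_values, conductances, *, n_starts: int = 3, seed: int = 1234) -> HillFit:
    """Hill fit of proton block: G(pH) = plateau / (1 + (10^(pKa - pH))^h).

    ``pKa`` is reported on the pH scale; ``h`` (the Hill coefficient) is
    constrained positive.  Needs at least four pH points.
    """
    ph = np.asarray(ph_values, dtype=float)
    g = np.asarray(conductances, dtype=float)
    if ph.size < 4:
        raise ValueError("need at least 4 pH points for a Hill fit")

    def model(p):
        pka, log_h, plateau = p
        return plateau / (1.0 + (10.0 ** np.clip(pka - ph, -30, 30)) ** np.exp(log_h))

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        pka0 = float(np.median(ph)) + (0 if s == 0 else rng.uniform(-1, 1))
        p0 = [pka0, 0.0, float(np.max(g)) or 1.0]
        sol = least_squares(lambda p: model(p) - g, p0, method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("Hill fit failed to converge")
    pka, log_h, plateau = best.x
    return HillFit(float(pka), float(math.exp(log_h)), float(plateau),
                   float(np.linalg.norm(best.fun)))
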