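"""Voltage-clamp protocol families and their simulation.

Each protocol is a piecewise-constant command-voltage program started from a
holding potential.  A *family* is the list of protocol instances produced by
sweeping one variable (the step voltage, or a conditioning/recovery
duration).  ``run_family`` simulates every member from the holding-potential
equilibrium, which assumes full re-equilibration between sweeps.

Built-in families (grids as used in the cut-open-oocyte experiments):

========== =============================================================
gv          20 ms steps, -100..+60 mV in 10 mV, holding -150 mV
ssfi        500 ms conditioning -150..-10 mV, then 20 ms test at -10 mV
persistent  100 ms steps, -30..0 mV in 10 mV
recovery    500 ms at 0 mV; recovery interval at -130..-70 mV; test -10 mV
closed_onset  onset steps to -70/-50 mV of varying duration; test -10 mV
qv_on       20 ms depolarizations -150..+40 mV, then 20 ms at -150 mV
qv_off      20 ms at +50 mV, then 20 ms repolarizations +20..-150 mV
charge_return  500 ms at 0 mV; repolarization to -150 mV; test 0 mV
slow_inact  onset 0.5-64 s at +30/0/-30 mV; timed recovery at matched
            repolarization (-120/-80/-90 mV); 5 ms test pulses
========== =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory, integrate
from .rates import ChannelParams

__all__ = ["VoltageProtocol", "SweepFamily", "build_protocol", "run_family",
           "PROTOCOL_NAMES"]


@dataclass(frozen=True)
class VoltageProtocol:
    """A piecewise-constant command-voltage program.

    ``segments`` are (level mV, duration ms) pairs executed in order from
    ``holding``.  ``variable`` records the swept quantity of this instance
    (step voltage or an interval duration) for downstream bookkeeping.
    """

    segments: tuple[tuple[float, float], ...]
    holding: float = -150.0
    sample_interval: float = 0.02      # ms; 50 kHz digitisation
    clamp_tau: float | None = None     # None -> use the parameter set's value
    label: str = ""
    variable: float | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for level, dur in self.segments:
            if not dur > 0:
                raise ValueError(f"non-positive segment duration {dur} ms at {level} mV")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass
class SweepFamily:
    """One simulated trajectory per value of the protocol variable."""

    variable_name: str
    variables: np.ndarray
    sweeps: list[Trajectory]
    label: str = ""
    meta: dict = field(default_factory=dict)
    protocols: list[VoltageProtocol] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variables = np.asarray(self.variables, dtype=float)
        d = np.diff(self.variables)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("family variable values must be strictly monotone")

    def __len__(self) -> int:
        return len(self.sweeps)


def _steps(v0: float, v1: float, dv: float) -> np.ndarray:
    n = int(round((v1 - v0) / dv))
    return v0 + dv * np.arange(n + 1)


#: default recovery/onset interval grid: log-spaced, 10 points per decade
def _log_intervals(lo: float = 0.1, hi: float = 3000.0, per_decade: int = 10) -> np.ndarray:
    n = int(round(np.log10(hi / lo) * per_decade)) + 1
    return np.geomspace(lo, hi, n)


SLOW_INACT_ONSETS_MS = tuple(1000.0 * x for x in (0.5, 1, 2, 4, 8, 16, 32, 64))
SLOW_INACT_RECOVERY_MS = tuple(1000.0 * x for x in
                               (0.02, 0.1, 0.25, 0.5, 1, 2, 5, 10, 20, 60))
#: onset potential -> matched repolarization potential
SLOW_INACT_PAIRINGS = {30.0: -120.0, 0.0: -80.0, -30.0: -90.0}

PROTOCOL_NAMES = ("gv", "ssfi", "recovery", "closed_onset", "persistent",
                  "qv_on", "qv_off", "charge_return", "slow_inact")


def build_protocol(name: str, **options) -> list[VoltageProtocol]:
    """Build the named protocol family with its default (overridable) grid.

    Returns a list of :class:`VoltageProtocol`, one per value of the family
    variable.  See the module docstring for the built-in grids; keyword
    options override voltages (``voltages``), durations (``duration``),
    intervals (``intervals``), holding potential and sampling.
    """
    if name not in PROTOCOL_NAMES:
        raise KeyError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
    holding = options.pop("holding", -150.0)
    dt = options.pop("sample_interval", 0.02)
    common = dict(holding=holding, sample_interval=dt,
                  clamp_tau=options.pop("clamp_tau", None))

    if name == "gv":
        voltages = np.asarray(options.pop("voltages", _steps(-100, 60, 10)), float)
        dur = options.pop("duration", 20.0)
        _reject_extra(options, name)
        return [VoltageProtocol(((v, dur),), label=f"gv_{v:+.0f}mV",
                                variable=v, **common) for v in voltages]

    if name == "ssfi":
        voltages = np.asarray(options.pop("voltages", _steps(-150, -10, 10)), float)
        cond = options.pop("conditioning_duration", 500.0)
        test_v = options.pop("test_voltage", -10.0)
        test_dur = options.pop("test_duration", 20.0)
        _reject_extra(options, name)
        return [VoltageProtocol(((v, cond), (test_v, test_dur)),
                                label=f"ssfi_{v:+.0f}mV", variable=v, **common)
                for v in voltages]

    if name == "persistent":
        voltages = np.asarray(options.pop("voltages", _steps(-30, 0, 10)), float)
        dur = options.pop("duration", 100.0)
        _reject_extra(options, name)
        return [VoltageProtocol(((v, dur),), label=f"persistent_{v:+.0f}mV",
                                variable=v, **common) for v in voltages]

    if name == "recovery":
        rec_v = options.pop("recovery_voltage", -90.0)
        intervals = np.asarray(options.pop("intervals", _log_intervals()), float)
        cond = options.pop("conditioning_duration", 500.0)
        _reject_extra(options, name)
        return [VoltageProtocol(((0.0, cond), (rec_v, dt_i), (-10.0, 20.0)),
                                label=f"recovery_{rec_v:+.0f}mV_{dt_i:g}ms",
                                variable=dt_i, **common) for dt_i in intervals]

    if name == "closed_onset":
        onset_v = options.pop("onset_voltage", -70.0)
        intervals = np.asarray(options.pop("intervals", _log_intervals()), float)
        _reject_extra(options, name)
        return [VoltageProtocol(((onset_v, dt_i), (-10.0, 20.0)),
                                label=f"closed_onset_{onset_v:+.0f}mV_{dt_i:g}ms",
                                variable=dt_i, **common) for dt_i in intervals]

    if name == "qv_on":
        voltages = np.asarray(options.pop("voltages", _steps(-150, 40, 10)), float)
        dur = options.pop("duration", 20.0)
        _reject_extra(options, name)
        return [VoltageProtocol(((v, dur), (-150.0, 20.0)),
                                label=f"qv_on_{v:+.0f}mV", variable=v, **common)
                for v in voltages]

    if name == "qv_off":
        voltages = np.asarray(options.pop("voltages", _steps(-150, 20, 10)), float)
        dur = options.pop("duration", 20.0)
        _reject_extra(options, name)
        return [VoltageProtocol(((50.0, 20.0), (v, dur)),
                                label=f"qv_off_{v:+.0f}mV", variable=v, **common)
                for v in voltages]

    if name == "charge_return":
        intervals = np.asarray(options.pop("intervals", _log_intervals()), float)
        _reject_extra(options, name)
        return [VoltageProtocol(((0.0, 500.0), (-150.0, dt_i), (0.0, 20.0)),
                                label=f"charge_return_{dt_i:g}ms",
                                variable=dt_i, **common) for dt_i in intervals]

    # slow_inact: for one onset voltage, family over onset durations; each
    # sweep holds the onset then samples availability with 5 ms test pulses
    # at the listed recovery times (matched onset/repolarization pairings).
    onset_v = options.pop("onset_voltage", -30.0)
    rec_v = options.pop("recovery_voltage", SLOW_INACT_PAIRINGS.get(onset_v, -90.0))
    onsets = np.asarray(options.pop("onsets", SLOW_INACT_ONSETS_MS), float)
    rec_times = np.asarray(options.pop("recovery_times", SLOW_INACT_RECOVERY_MS), float)
    _reject_extra(options, name)
    protos = []
    for onset in onsets:
        segs: list[tuple[float, float]] = [(-10.0, 5.0), (onset_v, onset)]
        prev = 0.0
        for rt in rec_times:
            segs.append((rec_v, rt - prev))
            segs.append((-10.0, 5.0))
            prev = rt + 5.0
        protos.append(VoltageProtocol(tuple(segs),
                                      label=f"slow_inact_{onset_v:+.0f}mV_{onset:g}ms",
                                      variable=onset, **common))
    return protos


def _reject_extra(options: dict, name: str) -> None:
    if options:
        raise TypeError(f"unknown options for protocol {name!r}: {sorted(options)}")


def run_family(
    params: ChannelParams,
    family: list[VoltageProtocol],
    *,
    variable_name: str = "value",
    label: str = "",
    **integrate_kwargs,
) -> SweepFamily:
    """Simulate every protocol of a family from holding-potential equilibrium.

    Deterministic: identical params and family give identical output.  Solver
    errors are re-raised naming the offending family member.
    """
    sweeps = []
    for proto in family:
        try:
            sweeps.append(integrate(params, proto, **integrate_kwargs))
        except Exception as exc:
            raise RuntimeError(f"simulation failed for sweep {proto.label!r}: {exc}") from exc
    variables = np.array([p.variable for p in family], dtype=float)
    return SweepFamily(
        variable_name=variable_name,
        variables=variables,
        sweeps=sweeps,
        label=label or (family[0].label.rsplit("_", 1)[0] if family else ""),
        meta={"genotype": params.genotype, "ph": params.ph,
              **{k: v for k, v in integrate_kwargs.items() if isinstance(v, (int, float, str))}},
        protocols=list(family),
    )
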