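"""Synthetic voltage-clamp recordings: model current + recording artifacts.

Real cut-open-oocyte sweeps contain, besides the channel current, linear
leak, capacitive transients at every voltage step, and baseline noise, and
are corrected online with P/N subtraction: N sub-threshold pulses scaled to
1/N of the step are averaged and the scaled average removed.  This module
adds those artifacts to clean model sweeps and implements the subtraction,
so the full analysis pipeline can be exercised end-to-end without any
experimental recordings.

Artifact model (deliberately idealised):

* white Gaussian noise of standard deviation ``sd`` per sample;
* ohmic leak ``g_leak * (V(t) - 0)``;
* a capacitive transient ``cap_scale * dV * exp(-dt/cap_tau)`` at each
  command step of height ``dV``;
* subtraction pulses are channel-free (pure leak + capacitance + noise),
  i.e. scaled far below the activation threshold.

All randomness flows through the recorded seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory, integrate
from .protocols import VoltageProtocol, build_protocol
from .rates import load_parameter_table, params_to_yaml

__all__ = ["NoiseModel", "SyntheticSweep", "corrupt", "artifact_trace",
           "p_over_n_subtract", "make_fixture_suite"]


@dataclass(frozen=True)
class NoiseModel:
    """Recording-artifact parameters for synthetic sweeps."""

    sd: float = 0.0            # Gaussian noise SD, current units
    g_leak: float = 0.0        # linear leak conductance (current/mV)
    cap_scale: float = 0.0     # capacitive transient amplitude per mV of step
    cap_tau: float = 0.1       # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.cap_tau <= 0:
            raise ValueError("capacitive tau must be positive")


@dataclass
class SyntheticSweep:
    """A corrupted sweep plus everything needed to reconstruct/correct it."""

    t: np.ndarray
    v_command: np.ndarray
    i_raw: np.ndarray
    i_clean: np.ndarray
    noise: NoiseModel
    meta: dict


def artifact_trace(t: np.ndarray, v_command: np.ndarray, noise: NoiseModel,
                   rng: np.random.Generator | None = None,
                   v_pre: float | None = None) -> np.ndarray:
    """Deterministic (leak + capacitive) artifact for a command waveform.

    ``v_pre`` is the potential held before the first sample (holding), used
    for the step transient at t = 0; None suppresses that transient.
    """
    out = noise.g_leak * v_command.astype(float)
    if noise.cap_scale:
        v_prev = np.concatenate(([v_command[0] if v_pre is None else v_pre],
                                 v_command[:-1]))
        steps = np.flatnonzero(v_command != v_prev)
        for k in steps:
            dv = v_command[k] - v_prev[k]
            dt = t[k:] - t[k]
            out[k:] += noise.cap_scale * dv * np.exp(-dt / noise.cap_tau)
    if rng is not None and noise.sd > 0:
        out += rng.normal(0.0, noise.sd, size=t.shape)
    return out


def corrupt(traj: Trajectory, noise: NoiseModel, *,
            v_pre: float | None = None) -> SyntheticSweep:
    """Add noise, leak and capacitive transients to a clean model sweep.

    Reproducible: the random stream is seeded from ``noise.seed`` alone.
    With sd = leak = cap = 0 the raw sweep equals the clean one exactly.
    """
    rng = np.random.default_rng(noise.seed)
    holding = v_pre if v_pre is not None else traj.meta.get("holding")
    art = artifact_trace(traj.t, traj.v_command, noise, rng, v_pre=holding)
    return SyntheticSweep(
        t=traj.t.copy(),
        v_command=traj.v_command.copy(),
        i_raw=traj.i_ionic + art,
        i_clean=traj.i_ionic.copy(),
        noise=noise,
        meta={**traj.meta, "seed": noise.seed},
    )


def p_over_n_subtract(sweep: SyntheticSweep, n: int = 4) -> np.ndarray:
    """P/N leak subtraction: raw minus n times the mean of n scaled sub-pulses.

    The n sub-pulses replay the command waveform scaled by 1/n (relative to
    a 0 mV reference) and are channel-free, so each contains leak and
    capacitance at 1/n amplitude plus fresh noise.  In the noiseless case
    the correction removes linear leak and capacitive transients exactly;
    with noise the corrected trace has per-sample variance (1 + n) * sd^2.
    """
    if n not in (4, 8):
        raise ValueError("P/N subtraction uses n = 4 or 8")
    noise = sweep.noise
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, n, 7]))
    sub_scaled = NoiseModel(sd=noise.sd, g_leak=noise.g_leak,
                            cap_scale=noise.cap_scale, cap_tau=noise.cap_tau,
                            seed=noise.seed)
    acc = np.zeros_like(sweep.i_raw)
    holding = sweep.meta.get("holding")
    v_sub = sweep.v_command / n
    v_pre_sub = None if holding is None else float(holding) / n
    for _ in range(n):
        acc += artifact_trace(sweep.t, v_sub, sub_scaled, rng, v_pre=v_pre_sub)
    return sweep.i_raw - acc  # n * mean(sub) = sum(sub)


def make_fixture_suite(
    out_dir: str | Path,
    conditions=(("CF", 7.4),),
    protocol_names=("gv",),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    *,
    protocol_options: dict | None = None,
    overwrite: bool = False,
    integrate_kwargs: dict | None = None,
) -> dict:
    """Write a deterministic tree of clean/raw/corrected sweeps as CSV.

    Layout: ``<out>/<genotype>_pH<ph>/<protocol>/<label>.csv`` with columns
    t_ms, v_command, i_clean, i_raw, i_corrected, plus a ``manifest.json``
    recording the noise model, seeds, and parameter-set hashes.  Identical
    seeds give byte-identical trees.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    integrate_kwargs = integrate_kwargs or {}
    protocol_options = protocol_options or {}

    manifest: dict = {"seed": seed, "noise": asdict(noise), "entries": []}
    ss = np.random.SeedSequence(seed)
    for geno, ph in conditions:
        params = load_parameter_table(geno, ph)
        params_hash = hashlib.sha256(params_to_yaml(params).encode()).hexdigest()[:16]
        cond_dir = out_dir / f"{geno}_pH{ph:g}"
        for pname in protocol_names:
            pdir = cond_dir / pname
            pdir.mkdir(parents=True, exist_ok=True)
            for proto in build_protocol(pname, **protocol_options.get(pname, {})):
                traj = integrate(params, proto, **integrate_kwargs)
                sweep_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                sweep = corrupt(traj, replace(noise, seed=sweep_seed),
                                v_pre=proto.holding)
                corrected = p_over_n_subtract(sweep, 4)
                df = pd.DataFrame({
                    "t_ms": sweep.t,
                    "v_command": sweep.v_command,
                    "i_clean": sweep.i_clean,
                    "i_raw": sweep.i_raw,
                    "i_corrected": corrected,
                })
                path = pdir / f"{proto.label}.csv"
                df.to_csv(path, index=False, float_format="%.10g")
                manifest["entries"].append({
                    "condition": [geno, ph],
                    "protocol": pname,
                    "label": proto.label,
                    "variable": proto.variable,
                    "path": str(path.relative_to(out_dir)),
                    "sweep_seed": sweep_seed,
                    "params_hash": params_hash,
                })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
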