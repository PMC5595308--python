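"""Time propagation of the coupled 16-state voltage-sensor system.

The channel is represented by four independent four-state chains (one per
domain), coupled only through charge immobilization: the DIII deactivation
rate (A -> D) is scaled by the fraction of DIV sensors *not* fast-inactivated.
The state vector is a flat length-16 occupancy vector in domain-major order

    [DI_S, DI_D, DI_A, DI_X,  DII_S, ...,  DIV_S, DIV_D, DIV_A, DIV_I]

with each domain's occupancies summing to one.  The command voltage is
piecewise constant; the membrane sees an exponentially filtered version of it
with time constant ``clamp_tau`` (the voltage-clamp settling time).

Ionic current uses a Hodgkin-Huxley-style pore rule (the default:
``P_open = A_DI * A_DII * A_DIII * (1 - I_DIV)``) and gating current is the
charge-weighted sum of net D -> A fluxes; transitions S <-> D and A <-> X
carry no gating charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .rates import DOMAINS, ChannelParams

__all__ = [
    "StateVector",
    "Trajectory",
    "state_index",
    "derivatives",
    "equilibrium_state",
    "integrate",
    "ionic_current",
    "gating_current",
    "open_probability",
]

STATES = ("S", "D", "A", "X")

#: index of the DIV fast-inactivated occupancy in the flat state vector
IDX_DIV_I = 15
IDX_DIV_A = 14

_COUPLING_FORMS = ("text", "table", "none")


def state_index(domain: str, state: str) -> int:
    """Flat index of ``(domain, state)``; state "I" aliases DIV's "X"."""
    if state == "I":
        state = "X"
    return 4 * DOMAINS.index(domain) + STATES.index(state)


@dataclass
class StateVector:
    """Occupancy fractions of the 16 sensor states (thin view over a vector)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (16,):
            raise ValueError("state vector must have 16 entries")

    def occupancy(self, domain: str, state: str) -> float:
        return float(self.values[state_index(domain, state)])

    def validate(self, tol: float = 1e-9) -> None:
        v = self.values
        if np.any(v < -tol) or np.any(v > 1 + tol):
            raise ValueError("occupancies outside [0, 1]")
        sums = v.reshape(4, 4).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            raise ValueError(f"per-domain occupancy sums deviate from 1: {sums}")


class _RateTable:
    """Vectorised evaluator of all 24 directed rates of a parameter set.

    Rates are ordered per domain as (sd, ds, da, ad, onset, recovery), giving
    a (4, 6) array for a scalar V.
    """

    def __init__(self, params: ChannelParams):
        consts = np.zeros((4, 6))
        amps: list[float] = []
        inv_slopes: list[float] = []
        owner: list[int] = []
        for di, dom in enumerate(params.domains):
            laws = (dom.rate_sd, dom.rate_ds, dom.rate_da,
                    dom.rate_ad, dom.rate_onset, dom.rate_recovery)
            for ri, law in enumerate(laws):
                consts[di, ri] = law.constant
                for amp, slope in law.terms:
                    amps.append(amp)
                    inv_slopes.append(1.0 / slope)
                    owner.append(di * 6 + ri)
        self._consts = consts
        self._amps = np.asarray(amps)
        self._inv_slopes = np.asarray(inv_slopes)
        self._owner = np.asarray(owner, dtype=np.intp)

    def __call__(self, V: float) -> np.ndarray:
        out = self._consts.copy()
        if self._amps.size:
            vals = self._amps * np.exp(V * self._inv_slopes)
            np.add.at(out.reshape(-1), self._owner, vals)
        return out

    def batch(self, V: np.ndarray) -> np.ndarray:
        """Rates for a vector of potentials: shape (len(V), 4, 6)."""
        out = np.broadcast_to(self._consts.reshape(-1), (V.size, 24)).copy()
        if self._amps.size:
            vals = self._amps * np.exp(np.outer(V, self._inv_slopes))
            scatter = np.zeros((self._amps.size, 24))
            scatter[np.arange(self._amps.size), self._owner] = 1.0
            out += vals @ scatter
        return out.reshape(V.size, 4, 6)


def _coupling_index(params: ChannelParams) -> int:
    """Row index (0..3) of the immobilization-coupled domain."""
    return next(i for i, d in enumerate(params.domains) if d.immobilization_coupled)


def _domain_flows(y: np.ndarray, rates: np.ndarray, params: ChannelParams,
                  coupling: str) -> np.ndarray:
    """Directed net flows for each domain: columns (S->D, D->A, A->X) net.

    Returns a (4, 3) array of net fluxes (occupancy/ms) along the three
    bonds of each chain, with the immobilization coupling applied to the
    coupled domain's A -> D rate.
    """
    y4 = y.reshape(4, 4)
    sd, ds, da, ad, on, rec = (rates[:, i] for i in range(6))
    ad = ad.copy()
    ci = _coupling_index(params)
    i4 = y[IDX_DIV_I]
    flows = np.empty((4, 3))
    flows[:, 0] = sd * y4[:, 0] - ds * y4[:, 1]
    flows[:, 1] = da * y4[:, 1] - ad * y4[:, 2]
    flows[:, 2] = on * y4[:, 2] - rec * y4[:, 3]
    if coupling == "text":
        factor = 1.0 - i4
        if factor < -1e-12:
            raise ValueError(f"immobilization coupling factor {factor} outside [0, 1]")
        flows[ci, 1] = da[ci] * y4[ci, 1] - ad[ci] * max(factor, 0.0) * y4[ci, 2]
    elif coupling == "table":
        # literal printed form: deactivation flux = beta3 * (A_DIII - I_DIV),
        # floored at zero so the flow never reverses sign unphysically
        flows[ci, 1] = da[ci] * y4[ci, 1] - ad[ci] * max(y4[ci, 2] - i4, 0.0)
    elif coupling != "none":
        raise ValueError(f"unknown coupling form {coupling!r}; one of {_COUPLING_FORMS}")
    return flows


def _div_deact_flux(y: np.ndarray, rates: np.ndarray, div_recovery: str) -> float:
    """Extra I -> D exit flux of DIV under the "deactivation" recovery path.

    The literal four-state chain leaves the inactivated sensor only the slow
    FR route back to A, which makes recovery from fast inactivation
    voltage-independent and hundreds of ms slow.  The "deactivation" option
    lets the inactivated DIV sensor deactivate directly (I -> D) at the
    voltage-dependent beta4 rate, restoring millisecond-scale,
    hyperpolarization-accelerated recovery.
    """
    if div_recovery == "chain":
        return 0.0
    if div_recovery == "deactivation":
        return float(rates[3, 3] * y[IDX_DIV_I])  # beta4 * I_DIV
    raise ValueError(f"unknown div_recovery {div_recovery!r}; 'chain' or 'deactivation'")


def derivatives(state: StateVector | np.ndarray, V: float, params: ChannelParams,
                *, coupling: str = "text", div_recovery: str = "chain") -> np.ndarray:
    """Mass-action time derivatives of the 16 occupancies at potential ``V``.

    ``coupling`` selects the charge-immobilization form: "text" scales the
    DIII deactivation rate by (1 - I_DIV), "table" uses the literal
    (A_DIII - I_DIV) occupancy difference, "none" disables it.
    ``div_recovery`` selects the exit path from the DIV inactivated state
    (see :func:`_div_deact_flux`).  Per-domain derivative sums are exactly
    zero (conservation by construction).
    """
    y = state.values if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    rates = _RateTable(params)(V)
    return _apply_flows(_domain_flows(y, rates, params, coupling),
                        _div_deact_flux(y, rates, div_recovery))


def _apply_flows(flows: np.ndarray, div_deact: float = 0.0) -> np.ndarray:
    dy = np.zeros((4, 4))
    dy[:, 0] = -flows[:, 0]
    dy[:, 1] = flows[:, 0] - flows[:, 1]
    dy[:, 2] = flows[:, 1] - flows[:, 2]
    dy[:, 3] = flows[:, 2]
    if div_deact:
        dy[3, 1] += div_deact
        dy[3, 3] -= div_deact
    return dy.reshape(-1)


def _chain_equilibrium(sd: float, ds: float, da: float, ad: float,
                       on: float, rec: float) -> np.ndarray:
    """Stationary distribution of one linear 4-state chain via detailed balance.

    Rates may be zero: a bond with zero forward rate cuts the chain (states
    beyond it are unreachable from rest, or drain back, so carry no mass); a
    bond with zero backward rate is absorbing (all upstream mass eventually
    crosses it).  The convention matches starting the system from the S end.
    """
    p = np.zeros(4)
    p[0] = 1.0
    for i, (fwd, bwd) in enumerate(((sd, ds), (da, ad), (on, rec))):
        if fwd == 0.0:
            break  # downstream states hold no stationary mass
        if bwd == 0.0:
            p[: i + 1] = 0.0  # irreversible bond drains everything upstream
            p[i + 1] = 1.0
        else:
            p[i + 1] = p[i] * fwd / bwd
    return p / p.sum()


def _table_coupled_equilibrium(sd: float, ds: float, da: float, ad: float,
                               on: float, rec: float, i4: float) -> np.ndarray:
    """Stationary DIII distribution under the literal occupancy-difference
    coupling, where the deactivation flux is ad * (A - i4).

    Flux balance da*D = ad*(A - i4) is linear in the unnormalised occupancies
    once the DIV inactivated fraction ``i4`` is fixed, giving a closed form.
    Degenerate rate combinations fall back to the uncoupled chain.
    """
    if ad <= 0 or ds <= 0 or rec <= 0:
        return _chain_equilibrium(sd, ds, da, ad, on, rec)
    D = sd / ds
    k = on / rec
    denom = ad * (1.0 - i4 * (1.0 + k))
    if denom > 0:
        A = (da * D + ad * i4 * (1.0 + D)) / denom
        p = np.array([1.0, D, A, k * A])
        p /= p.sum()
        if p[2] >= i4:          # interior solution: floored flux is active
            return p
    # boundary solution: the deactivation flux is floored at zero, so the
    # S and D states drain completely and only A <-> X balance remains
    return _chain_equilibrium(sd, ds, da, 0.0, on, rec)


def _cycle_equilibrium(sd: float, ds: float, da: float, ad: float,
                       on: float, rec: float, deact: float) -> np.ndarray:
    """Stationary distribution of the DIV system with the extra I -> D edge.

    The added edge makes the graph a cycle, so detailed balance no longer
    applies; solve the stationary linear system directly.
    """
    Q = np.array([
        [-sd, sd, 0.0, 0.0],
        [ds, -(ds + da), da, 0.0],
        [0.0, ad, -(ad + on), on],
        [0.0, deact, rec, -(rec + deact)],
    ])
    A = np.vstack([Q.T, np.ones(4)])
    b = np.zeros(5)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def equilibrium_state(params: ChannelParams, V: float, *, coupling: str = "text",
                      div_recovery: str = "chain", tol: float = 1e-13,
                      max_iter: int = 200) -> StateVector:
    """Stationary occupancy distribution of the coupled system at fixed ``V``.

    Each chain obeys detailed balance, so per-domain equilibria are closed
    form; the DIII <- DIV immobilization coupling is resolved by fixed-point
    iteration (it converges immediately since DIV is autonomous).  Under the
    "deactivation" DIV recovery path the DIV stationary state is solved as a
    linear system instead.
    """
    rates = _RateTable(params)(V)
    y = np.tile([1.0, 0.0, 0.0, 0.0], 4)
    ci = _coupling_index(params)
    for _ in range(max_iter):
        prev = y.copy()
        for di in range(4):
            sd, ds, da, ad, on, rec = rates[di]
            if di == 3 and div_recovery == "deactivation":
                y.reshape(4, 4)[di] = _cycle_equilibrium(sd, ds, da, ad, on, rec, ad)
            elif coupling == "text" and di == ci:
                ad = ad * (1.0 - y[IDX_DIV_I])
                y.reshape(4, 4)[di] = _chain_equilibrium(sd, ds, da, ad, on, rec)
            elif coupling == "table" and di == ci:
                y.reshape(4, 4)[di] = _table_coupled_equilibrium(
                    sd, ds, da, ad, on, rec, y[IDX_DIV_I])
            else:
                y.reshape(4, 4)[di] = _chain_equilibrium(sd, ds, da, ad, on, rec)
        if np.max(np.abs(y - prev)) < tol:
            sv = StateVector(y)
            sv.validate(tol=1e-9)
            return sv
    residual = float(np.max(np.abs(derivatives(y, V, params, coupling=coupling,
                                               div_recovery=div_recovery))))
    raise RuntimeError(
        f"equilibrium iteration did not converge at V={V} mV (residual {residual:.2e})"
    )


@dataclass
class Trajectory:
    """A simulated voltage-clamp sweep.

    Attributes
    ----------
    t : ndarray
        Sample times in ms (from sweep start).
    v_command, v_filtered : ndarray
        Programmed and clamp-filtered membrane potential (mV).
    occupancy : ndarray, shape (n, 16)
        Sensor-state occupancies at each sample (domain-major order).
    i_ionic : ndarray
        Ionic current (arbitrary units; inward negative).
    i_gating : ndarray
        Gating current (charge-weighted net outward flux; outward positive).
    meta : dict
        Provenance: condition, pore rule, coupling form, solver tolerances.
    """

    t: np.ndarray
    v_command: np.ndarray
    v_filtered: np.ndarray
    occupancy: np.ndarray
    i_ionic: np.ndarray
    i_gating: np.ndarray
    meta: dict = field(default_factory=dict)

    def occ(self, domain: str, state: str) -> np.ndarray:
        return self.occupancy[:, state_index(domain, state)]

    def to_frame(self):
        """Tidy table (pandas) of the sweep: time, voltages, states, currents."""
        import pandas as pd

        cols = {"t_ms": self.t, "v_command": self.v_command, "v_filtered": self.v_filtered}
        for d in DOMAINS:
            for s in STATES:
                cols[f"{d}_{s}"] = self.occupancy[:, state_index(d, s)]
        cols["i_ionic"] = self.i_ionic
        cols["i_gating"] = self.i_gating
        return pd.DataFrame(cols)


def open_probability(occupancy: np.ndarray, pore_rule: str = "product3") -> np.ndarray:
    """Pore-open probability from sensor occupancies.

    "product3" (default): A_DI * A_DII * A_DIII * (1 - I_DIV) — conduction
    requires the three activation-linked sensors up and fast inactivation
    absent.  "product4" additionally multiplies by A_DIV.
    """
    occ = np.atleast_2d(occupancy)
    p = (occ[:, state_index("DI", "A")]
         * occ[:, state_index("DII", "A")]
         * occ[:, state_index("DIII", "A")]
         * (1.0 - occ[:, IDX_DIV_I]))
    if pore_rule == "product4":
        p = p * occ[:, IDX_DIV_A]
    elif pore_rule != "product3":
        raise ValueError(f"unknown pore rule {pore_rule!r}")
    return p if occupancy.ndim == 2 else p[0]


def ionic_current(traj: Trajectory, params: ChannelParams,
                  pore_rule: str = "product3") -> np.ndarray:
    """Ionic current I = g_max * P_open * (V - E_rev); inward negative."""
    p_open = open_probability(traj.occupancy, pore_rule)
    return params.g_max * p_open * (traj.v_filtered - params.e_rev)


def gating_current(traj: Trajectory, params: ChannelParams, *,
                   coupling: str | None = None,
                   div_recovery: str | None = None) -> np.ndarray:
    """Gating current: charge-weighted sum of net D -> A fluxes (outward +).

    Only the D <-> A charge-translocation step carries gating charge; DIII
    and DIV contribute 1.5x the weight of DI/DII (30/30/20/20 % charge
    shares).  Under the "deactivation" DIV recovery path the I -> D exit
    moves the sensor down across the same step and counts as inward charge.
    """
    coupling = coupling if coupling is not None else traj.meta.get("coupling", "text")
    div_recovery = (div_recovery if div_recovery is not None
                    else traj.meta.get("div_recovery", "chain"))
    rates = _RateTable(params).batch(traj.v_filtered)     # (N, 4, 6)
    y4 = traj.occupancy.reshape(-1, 4, 4)
    da, ad = rates[:, :, 2], rates[:, :, 3].copy()
    ci = _coupling_index(params)
    i4 = traj.occupancy[:, IDX_DIV_I]
    flux = da * y4[:, :, 1] - ad * y4[:, :, 2]            # net D -> A per domain
    if coupling == "text":
        flux[:, ci] = (da[:, ci] * y4[:, ci, 1]
                       - ad[:, ci] * np.clip(1.0 - i4, 0.0, None) * y4[:, ci, 2])
    elif coupling == "table":
        flux[:, ci] = (da[:, ci] * y4[:, ci, 1]
                       - ad[:, ci] * np.clip(y4[:, ci, 2] - i4, 0.0, None))
    elif coupling != "none":
        raise ValueError(f"unknown coupling form {coupling!r}; one of {_COUPLING_FORMS}")
    weights = np.array([d.charge_weight for d in params.domains])
    out = flux @ weights
    if div_recovery == "deactivation":
        out -= weights[3] * rates[:, 3, 3] * i4
    elif div_recovery != "chain":
        raise ValueError(f"unknown div_recovery {div_recovery!r}; 'chain' or 'deactivation'")
    return out


def _segment_voltage(level: float, v0: float, tau: float) -> Callable[[float], float]:
    if tau <= 0 or v0 == level:
        return lambda t: level
    dv = v0 - level
    return lambda t: level + dv * np.exp(-t / tau)


def integrate(
    params: ChannelParams,
    protocol,
    *,
    y0: np.ndarray | StateVector | None = None,
    pore_rule: str = "product3",
    coupling: str = "text",
    div_recovery: str = "chain",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the occupancy system through a piecewise-constant protocol.

    The initial state defaults to the equilibrium at the protocol's holding
    potential.  Output is sampled on the protocol's grid (default 0.02 ms,
    the 50 kHz digitisation interval).  The clamp-filtered voltage follows
    each command step exponentially with ``params.clamp_tau``.
    """
    segments = protocol.segments
    dt = protocol.sample_interval
    tau = params.clamp_tau if protocol.clamp_tau is None else protocol.clamp_tau

    if y0 is None:
        y = equilibrium_state(params, protocol.holding, coupling=coupling,
                              div_recovery=div_recovery).values.copy()
    else:
        y = (y0.values if isinstance(y0, StateVector) else np.asarray(y0, dtype=float)).copy()

    table = _RateTable(params)
    ci = _coupling_index(params)

    def rhs_factory(vfun):
        def rhs(t, yv):
            rates = table(vfun(t))
            return _apply_flows(_domain_flows(yv, rates, params, coupling),
                                _div_deact_flux(yv, rates, div_recovery))
        return rhs

    t_all: list[np.ndarray] = []
    v_cmd_all: list[np.ndarray] = []
    v_filt_all: list[np.ndarray] = []
    occ_all: list[np.ndarray] = []

    t0 = 0.0
    v_now = protocol.holding
    for level, duration in segments:
        vfun = _segment_voltage(level, v_now, tau)
        n = max(int(round(duration / dt)), 1)
        t_local = np.linspace(0.0, duration, n + 1)
        sol = solve_ivp(
            rhs_factory(vfun), (0.0, duration), y, method=method,
            t_eval=t_local, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed in segment at {level} mV (t0={t0} ms): {sol.message}"
            )
        # renormalise tiny conservation drift before the next segment
        y = sol.y[:, -1].copy()
        y4 = y.reshape(4, 4)
        y4 /= y4.sum(axis=1, keepdims=True)

        keep = slice(0 if not t_all else 1, None)  # avoid duplicating joints
        t_all.append(t_local[keep] + t0)
        v_cmd_all.append(np.full(t_local[keep].shape, level))
        v_filt_all.append(np.array([vfun(tt) for tt in t_local])[keep])
        occ_all.append(sol.y.T[keep])
        t0 += duration
        v_now = vfun(duration)

    traj = Trajectory(
        t=np.concatenate(t_all),
        v_command=np.concatenate(v_cmd_all),
        v_filtered=np.concatenate(v_filt_all),
        occupancy=np.concatenate(occ_all, axis=0),
        i_ionic=np.empty(0),
        i_gating=np.empty(0),
        meta={
            "genotype": params.genotype,
            "ph": params.ph,
            "pore_rule": pore_rule,
            "coupling": coupling,
            "div_recovery": div_recovery,
            "rtol": rtol,
            "atol": atol,
            "clamp_tau": tau,
            "holding": protocol.holding,
            "label": getattr(protocol, "label", ""),
        },
    )
    traj.i_ionic = ionic_current(traj, params, pore_rule)
    traj.i_gating = gating_current(traj, params, coupling=coupling,
                                   div_recovery=div_recovery)
    return traj
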