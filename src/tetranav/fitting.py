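"""Two-stage parameter estimation: genetic algorithm, then hill climbing.

The search adjusts named rate-law coefficients of a :class:`ChannelParams`
to minimise the root-mean-square deviation between simulated ionic-current
sweeps and a target sweep family, under the structural constraint that the
DI and DII sensors are equivalent (their laws are kept identical throughout
the search).  Rates span many orders of magnitude, so free parameters are
searched in log space by default.

Stage 1 is a generational genetic algorithm (tournament selection, blend
crossover, log-normal mutation, elitism); stage 2 refines the best candidate
with coordinate-wise hill climbing on a shrinking step schedule.  Both are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .engine import integrate
from .protocols import SweepFamily, VoltageProtocol
from .rates import RATE_SYMBOLS, ChannelParams, RateLaw, make_variant

__all__ = ["FreeParameter", "FitSpec", "SearchConfig", "objective",
           "ga_search", "hill_climb", "get_coefficient", "set_coefficients"]

#: DI <-> DII equality: symbols tied together (DII follows DI)
DI_DII_GROUPS = (("alpha1", "alpha2"), ("beta1", "beta2"),
                 ("I1", "I2"), ("R1", "R2"))

_ADDR_RE = re.compile(r"^(?P<symbol>\w+)\.(?:constant|term(?P<term>\d)\.(?P<field>amplitude|slope))$")


@dataclass(frozen=True)
class FreeParameter:
    """One searchable coefficient, addressed as e.g. ``alpha3.term0.amplitude``.

    Addresses are ``<symbol>.constant`` or ``<symbol>.term<i>.<amplitude|slope>``.
    ``log`` searches the coefficient in log10 space (the default for
    amplitudes and constants; slopes are signed and use linear space).
    """

    address: str
    lower: float
    upper: float
    log: bool = True

    def __post_init__(self) -> None:
        if _ADDR_RE.match(self.address) is None:
            raise ValueError(f"malformed parameter address {self.address!r}")
        sym = self.address.split(".", 1)[0]
        if sym not in RATE_SYMBOLS:
            raise ValueError(f"unknown rate symbol in address {self.address!r}")
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("parameter bounds must be finite")
        if self.log and self.lower <= 0:
            raise ValueError(f"log-space parameter {self.address!r} needs positive bounds")

    def to_internal(self, value: float) -> float:
        return math.log10(value) if self.log else value

    def from_internal(self, x: float) -> float:
        return 10.0 ** x if self.log else x

    @property
    def internal_bounds(self) -> tuple[float, float]:
        return (self.to_internal(self.lower), self.to_internal(self.upper))


def get_coefficient(params: ChannelParams, address: str) -> float:
    """Read one rate-law coefficient by address."""
    m = _ADDR_RE.match(address)
    if m is None:
        raise ValueError(f"malformed parameter address {address!r}")
    law = params.rate(m.group("symbol"))
    if m.group("term") is None:
        return law.constant
    ti = int(m.group("term"))
    if ti >= len(law.terms):
        raise IndexError(f"{address!r}: law has only {len(law.terms)} terms")
    return law.terms[ti][0 if m.group("field") == "amplitude" else 1]


def set_coefficients(params: ChannelParams, updates: dict[str, float],
                     *, enforce_di_dii: bool = True) -> ChannelParams:
    """Return params with the addressed coefficients replaced.

    With ``enforce_di_dii`` any change to a DI symbol is mirrored onto the
    corresponding DII symbol (and vice versa), preserving the equivalence of
    the first two sensors.
    """
    by_symbol: dict[str, dict] = {}
    for address, value in updates.items():
        m = _ADDR_RE.match(address)
        if m is None:
            raise ValueError(f"malformed parameter address {address!r}")
        by_symbol.setdefault(m.group("symbol"), {})[address] = value

    overrides: dict[str, RateLaw] = {}
    for symbol, upd in by_symbol.items():
        law = params.rate(symbol)
        constant = law.constant
        terms = [list(t) for t in law.terms]
        for address, value in upd.items():
            m = _ADDR_RE.match(address)
            if m.group("term") is None:
                constant = value
            else:
                ti = int(m.group("term"))
                if ti >= len(terms):
                    raise IndexError(f"{address!r}: law has only {len(terms)} terms")
                terms[ti][0 if m.group("field") == "amplitude" else 1] = value
        overrides[symbol] = RateLaw(constant, tuple(tuple(t) for t in terms))

    if enforce_di_dii:
        for a, b in DI_DII_GROUPS:
            if a in overrides:
                overrides[b] = overrides[a]
            elif b in overrides:
                overrides[a] = overrides[b]
    return make_variant(params, overrides)


@dataclass
class FitSpec:
    """What to fit: free parameters, the base parameter set, and the target.

    ``target`` sweeps must share the integration options used here (the
    objective re-simulates with ``integrate_kwargs``).  Currents are
    peak-normalised per family so the conductance scale g_max drops out.
    """

    base_params: ChannelParams
    free: list[FreeParameter]
    target: SweepFamily
    protocols: list[VoltageProtocol] = field(default_factory=list)
    enforce_di_dii: bool = True
    normalize: bool = True
    integrate_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protocols:
            self.protocols = list(self.target.protocols)
        if len(self.protocols) != len(self.target.sweeps):
            raise ValueError("need one protocol per target sweep")

    def apply(self, x: np.ndarray) -> ChannelParams:
        updates = {fp.address: fp.from_internal(v) for fp, v in zip(self.free, x)}
        return set_coefficients(self.base_params, updates,
                                enforce_di_dii=self.enforce_di_dii)

    def initial_vector(self) -> np.ndarray:
        return np.array([fp.to_internal(get_coefficient(self.base_params, fp.address))
                         for fp in self.free])


@dataclass
class SearchConfig:
    """Genetic-algorithm and hill-climb hyper-parameters (all configurable)."""

    population: int = 24
    generations: int = 20
    mutation_scale: float = 0.15   # log-normal sigma in internal units
    crossover_rate: float = 0.7
    tournament: int = 3
    elite: int = 2
    seed: int = 0
    hill_steps: tuple[float, ...] = (0.1, 0.03, 0.01, 0.003)
    hill_iter_cap: int = 400

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")


def objective(params: ChannelParams, target: SweepFamily, *,
              protocols: list[VoltageProtocol] | None = None,
              normalize: bool = True, **integrate_kwargs) -> float:
    """RMS deviation between ``params``-simulated sweeps and a target family.

    Each target sweep is re-simulated under its protocol (taken from the
    family unless given explicitly) and compared point-by-point on the
    target's own time grids; grids must match exactly.  With ``normalize``
    both families are scaled by their largest absolute current first, so the
    conductance normalisation g_max is not a nuisance parameter.
    Deterministic given ``params``.
    """
    protocols = list(protocols) if protocols is not None else list(target.protocols)
    if len(protocols) != len(target.sweeps):
        raise ValueError("need one protocol per target sweep")
    sq = 0.0
    n = 0
    target_scale = _family_scale(target) if normalize else 1.0
    sim_sweeps = [integrate(params, proto, **integrate_kwargs) for proto in protocols]
    sim_scale = (max(float(np.max(np.abs(s.i_ionic))) for s in sim_sweeps)
                 if normalize else 1.0) or 1.0
    for sim, tgt in zip(sim_sweeps, target.sweeps):
        if sim.t.shape != tgt.t.shape or not np.allclose(sim.t, tgt.t):
            raise ValueError("simulated and target sweeps are on different time grids")
        d = sim.i_ionic / sim_scale - tgt.i_ionic / target_scale
        sq += float(d @ d)
        n += d.size
    return math.sqrt(sq / n)


def objective_for_spec(spec: FitSpec, params: ChannelParams) -> float:
    """RMS deviation of ``params`` against the spec's target family."""
    return objective(params, spec.target, protocols=spec.protocols,
                     normalize=spec.normalize, **spec.integrate_kwargs)


def _family_scale(family: SweepFamily) -> float:
    return max(float(np.max(np.abs(s.i_ionic))) for s in family.sweeps) or 1.0


def rmsd(family_a: SweepFamily, family_b: SweepFamily, *, normalize: bool = True) -> float:
    """Direct RMS deviation between two sweep families on identical grids.

    Symmetric in its arguments and homogeneous of degree one in the currents
    (without normalisation).
    """
    if len(family_a) != len(family_b):
        raise ValueError("families have different sweep counts")
    sa = _family_scale(family_a) if normalize else 1.0
    sb = _family_scale(family_b) if normalize else 1.0
    sq = 0.0
    n = 0
    for a, b in zip(family_a.sweeps, family_b.sweeps):
        if a.t.shape != b.t.shape or not np.allclose(a.t, b.t):
            raise ValueError("sweeps are on different time grids")
        d = a.i_ionic / sa - b.i_ionic / sb
        sq += float(d @ d)
        n += d.size
    return math.sqrt(sq / n)


@dataclass
class SearchResult:
    best_params: ChannelParams
    best_vector: np.ndarray
    best_objective: float
    objective_trace: list[float]
    evaluations: int
    seed: int


def ga_search(spec: FitSpec, config: SearchConfig) -> SearchResult:
    """Genetic-algorithm stage: returns the best candidate found.

    Tournament selection, blend (BLX-alpha) crossover, log-normal mutation in
    internal (log) coordinates, and elitism; the DI = DII constraint is
    enforced by construction inside :meth:`FitSpec.apply`.  The best
    objective is non-increasing across generations.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([fp.internal_bounds[0] for fp in spec.free])
    hi = np.array([fp.internal_bounds[1] for fp in spec.free])
    dim = len(spec.free)

    evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        try:
            return objective_for_spec(spec, spec.apply(x))
        except (RuntimeError, OverflowError, ValueError):
            return math.inf

    pop = rng.uniform(lo, hi, size=(config.population, dim))
    pop[0] = np.clip(spec.initial_vector(), lo, hi)  # seed with the base set
    fitness = np.array([evaluate(x) for x in pop])
    if not np.any(np.isfinite(fitness)):
        raise RuntimeError("entire initial population has non-finite objective")

    trace = [float(np.min(fitness))]
    for _ in range(config.generations):
        order = np.argsort(fitness)
        new_pop = [pop[i].copy() for i in order[: config.elite]]
        while len(new_pop) < config.population:
            a = _tournament(pop, fitness, config.tournament, rng)
            b = _tournament(pop, fitness, config.tournament, rng)
            if rng.random() < config.crossover_rate:
                mix = rng.uniform(-0.25, 1.25, size=dim)
                child = a + mix * (b - a)
            else:
                child = a.copy()
            child += rng.normal(0.0, config.mutation_scale, size=dim)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.asarray(new_pop)
        fitness = np.concatenate([
            fitness[order[: config.elite]],
            [evaluate(x) for x in pop[config.elite:]],
        ])
        trace.append(float(np.min(fitness)))

    best = int(np.argmin(fitness))
    return SearchResult(spec.apply(pop[best]), pop[best].copy(), float(fitness[best]),
                        trace, evals, config.seed)


def _tournament(pop: np.ndarray, fitness: np.ndarray, k: int,
                rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[np.argmin(fitness[idx])]]


def hill_climb(spec: FitSpec, start: ChannelParams | np.ndarray,
               config: SearchConfig | None = None) -> SearchResult:
    """Coordinate-wise hill climbing with a shrinking step schedule.

    From ``start`` (a parameter set or an internal coordinate vector), each
    coordinate is probed up and down by the current step; only improvements
    are accepted.  When a full pass makes no progress the step shrinks to the
    next schedule entry.  The result's objective never exceeds the start's.
    """
    config = config or SearchConfig()
    if isinstance(start, ChannelParams):
        x = np.array([fp.to_internal(get_coefficient(start, fp.address))
                      for fp in spec.free])
    else:
        x = np.asarray(start, dtype=float).copy()
    lo = np.array([fp.internal_bounds[0] for fp in spec.free])
    hi = np.array([fp.internal_bounds[1] for fp in spec.free])
    x = np.clip(x, lo, hi)

    evals = 0

    def evaluate(xv: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        try:
            return objective_for_spec(spec, spec.apply(xv))
        except (RuntimeError, OverflowError, ValueError):
            return math.inf

    best_f = evaluate(x)
    trace = [best_f]
    for step in config.hill_steps:
        improved = True
        while improved and evals < config.hill_iter_cap:
            improved = False
            for i in range(len(x)):
                for sign in (+1.0, -1.0):
                    if evals >= config.hill_iter_cap:
                        break
                    cand = x.copy()
                    cand[i] = np.clip(cand[i] + sign * step, lo[i], hi[i])
                    if cand[i] == x[i]:
                        continue
                    f = evaluate(cand)
                    if f < best_f:
                        x, best_f = cand, f
                        trace.append(best_f)
                        improved = True
                        break
    return SearchResult(spec.apply(x), x, best_f, trace, evals, config.seed)


def two_stage_fit(spec: FitSpec, config: SearchConfig) -> SearchResult:
    """GA followed by hill climbing; combined evaluation count reported."""
    ga = ga_search(spec, config)
    hc = hill_climb(spec, ga.best_vector, config)
    return SearchResult(hc.best_params, hc.best_vector, hc.best_objective,
                        ga.objective_trace + hc.objective_trace,
                        ga.evaluations + hc.evaluations, config.seed)
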