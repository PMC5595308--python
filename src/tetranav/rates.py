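"""Rate laws and parameter sets for the tetrameric NaV1.5 voltage-sensor model.

Each of the four channel domains (DI-DIV) is described by a four-state chain

    S  <->  D  <->  A  <->  X

where S is the resting (down) position of the S4 segment, D is a deployed
intermediate, A is the activated (charge-moved) position, and X is a fourth
state: a "relaxed" state modelling slow inactivation for DI-DIII, or the
fast-inactivated state I for DIV.  Every transition rate is either a constant
or a sum of exponential functions of membrane potential, in ms^-1 with V in
mV.  The built-in parameter table covers four experimental conditions: the
C373F background construct ("CF") and the C373F/E1784K double mutant
("CF_EK"), each at extracellular pH 7.4 and pH 6.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "RateLaw",
    "DomainParams",
    "ChannelParams",
    "eval_rate",
    "load_parameter_table",
    "make_variant",
    "params_to_yaml",
    "params_from_yaml",
    "CONDITIONS",
    "RATE_SYMBOLS",
    "DOMAINS",
]

DOMAINS = ("DI", "DII", "DIII", "DIV")

#: rate-symbol -> (domain, role) map.  Roles: sd (S->D), ds (D->S),
#: da (D->A), ad (A->D), onset (A->X), recovery (X->A).
RATE_SYMBOLS = {
    "delta": (None, "sd"),
    "lambda": (None, "ds"),
    "alpha1": ("DI", "da"),
    "beta1": ("DI", "ad"),
    "alpha2": ("DII", "da"),
    "beta2": ("DII", "ad"),
    "alpha3": ("DIII", "da"),
    "beta3": ("DIII", "ad"),
    "alpha4": ("DIV", "da"),
    "beta4": ("DIV", "ad"),
    "I1": ("DI", "onset"),
    "R1": ("DI", "recovery"),
    "I2": ("DII", "onset"),
    "R2": ("DII", "recovery"),
    "I3": ("DIII", "onset"),
    "R3": ("DIII", "recovery"),
    "FI": ("DIV", "onset"),
    "FR": ("DIV", "recovery"),
}

_ROLE_ATTR = {
    "sd": "rate_sd",
    "ds": "rate_ds",
    "da": "rate_da",
    "ad": "rate_ad",
    "onset": "rate_onset",
    "recovery": "rate_recovery",
}


@dataclass(frozen=True)
class RateLaw:
    """A voltage-dependent transition rate: constant + sum of exponentials.

    value(V) = constant + sum_i amplitude_i * exp(V / slope_i)

    with rates in ms^-1, V and slopes in mV.  A law with no terms is
    voltage-independent.  Slopes are signed: a negative slope gives a rate
    that decays with depolarization.
    """

    constant: float = 0.0
    terms: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "constant", float(self.constant))
        if self.constant < 0:
            raise ValueError(f"negative constant rate: {self.constant}")
        object.__setattr__(self, "terms", tuple((float(a), float(s)) for a, s in self.terms))
        for amp, slope in self.terms:
            if slope == 0:
                raise ValueError("exponential term with zero slope")
            if amp < 0:
                raise ValueError(f"negative term amplitude: {amp}")

    def __call__(self, V: float) -> float:
        return eval_rate(self, V)

    @property
    def is_voltage_independent(self) -> bool:
        return not self.terms

    def scaled(self, factor: float) -> "RateLaw":
        """Return a copy with constant and all amplitudes multiplied."""
        return RateLaw(self.constant * factor, tuple((a * factor, s) for a, s in self.terms))


#: the all-zero law; assigning it to FI disables fast inactivation.
ZERO_RATE = RateLaw(0.0, ())


def eval_rate(law: RateLaw, V: float) -> float:
    """Evaluate a rate law at membrane potential ``V`` (mV) -> ms^-1.

    Raises ``OverflowError`` naming the law if the exponentials overflow
    (only possible far outside the physiological range).
    """
    total = law.constant
    for amp, slope in law.terms:
        try:
            total += amp * math.exp(V / slope)
        except OverflowError:
            raise OverflowError(f"rate law {law} overflows at V={V} mV") from None
    if not math.isfinite(total):
        raise OverflowError(f"rate law {law} is non-finite at V={V} mV")
    return total


@dataclass(frozen=True)
class DomainParams:
    """Rate laws for one voltage-sensing domain's four-state chain."""

    domain_id: str
    rate_sd: RateLaw          # S -> D (voltage-independent delta in the table)
    rate_ds: RateLaw          # D -> S (lambda)
    rate_da: RateLaw          # D -> A (alpha)
    rate_ad: RateLaw          # A -> D (beta)
    rate_onset: RateLaw       # A -> X (relaxation I for DI-DIII, FI for DIV)
    rate_recovery: RateLaw    # X -> A (de-relaxation R, FR for DIV)
    charge_weight: float = 1.0
    immobilization_coupled: bool = False

    def __post_init__(self) -> None:
        if self.domain_id not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain_id!r}; expected one of {DOMAINS}")


@dataclass(frozen=True)
class ChannelParams:
    """Complete parameterisation of one channel condition.

    ``domains`` holds one :class:`DomainParams` per domain in DI..DIV order.
    ``e_rev`` is the sodium reversal potential (mV), ``g_max`` an arbitrary
    maximal conductance, ``temperature`` (K) enters only Boltzmann fits, and
    ``clamp_tau`` (ms) is the exponential settling time of the voltage clamp.
    """

    genotype: str
    ph: float
    domains: tuple[DomainParams, DomainParams, DomainParams, DomainParams]
    e_rev: float = 58.0
    g_max: float = 1.0
    temperature: float = 293.0
    clamp_tau: float = 0.05

    def __post_init__(self) -> None:
        ids = tuple(d.domain_id for d in self.domains)
        if ids != DOMAINS:
            raise ValueError(f"domains must be ordered {DOMAINS}, got {ids}")
        coupled = [d.domain_id for d in self.domains if d.immobilization_coupled]
        if len(coupled) != 1:
            raise ValueError(f"exactly one domain must be immobilization-coupled, got {coupled}")

    def domain(self, domain_id: str) -> DomainParams:
        return self.domains[DOMAINS.index(domain_id)]

    def rate(self, symbol: str) -> RateLaw:
        """Look up a rate law by its table symbol (delta, alpha3, FI, ...)."""
        dom, role = _resolve_symbol(symbol)
        if dom is None:
            dom = "DI"  # delta/lambda are shared; DI holds the canonical copy
        return getattr(self.domain(dom), _ROLE_ATTR[role])


def _resolve_symbol(symbol: str) -> tuple[str | None, str]:
    if symbol not in RATE_SYMBOLS:
        raise KeyError(
            f"unknown rate symbol {symbol!r}; expected one of {sorted(RATE_SYMBOLS)}"
        )
    return RATE_SYMBOLS[symbol]


# ---------------------------------------------------------------------------
# Built-in parameter table (all rates ms^-1, V in mV).
#
# Laws are written as {"constant": c, "terms": [(amplitude, slope), ...]} with
# term value amplitude*exp(V/slope).  The DI/DII relaxation entries are the
# final printed values; see ``load_parameter_table(apply_sqrt_half=...)``.
# ---------------------------------------------------------------------------

_L = lambda c=0.0, *terms: RateLaw(c, tuple(terms))  # noqa: E731

_TABLE: dict[tuple[str, float], dict[str, RateLaw]] = {
    ("CF", 7.4): {
        "delta": _L(2.2897),
        "lambda": _L(22.897),
        "alpha1": _L(0.0, (381.14, 9.657)),
        "beta1": _L(0.0, (0.3446, -78.1)),
        "alpha2": _L(0.0, (381.14, 9.657)),
        "beta2": _L(0.0, (0.3446, -78.1)),
        "alpha3": _L(0.0, (183.94, 22.4)),
        "beta3": _L(0.0, (0.3867, -38.76)),
        "alpha4": _L(0.0, (91.93, 8.417), (48.39, 11.51)),
        "beta4": _L(0.0, (9.273e-6, -11.51)),
        "I1": _L(9.39e-5),
        "R1": _L(3.874e-4, (4.687e-6, -15.06)),
        "I2": _L(9.39e-5),
        "R2": _L(3.874e-4, (4.687e-6, -15.06)),
        "I3": _L(3.971e-5),
        "R3": _L(5.199e-5, (2.642e-6, -22.47)),
        "FI": _L(1.522),
        "FR": _L(0.002),
    },
    ("CF_EK", 7.4): {
        "delta": _L(2.2897),
        "lambda": _L(22.897),
        "alpha1": _L(0.0, (381.14, 9.657)),
        "beta1": _L(0.0, (0.3446, -78.1)),
        "alpha2": _L(0.0, (381.14, 9.657)),
        "beta2": _L(0.0, (0.3446, -78.1)),
        "alpha3": _L(0.0, (183.94, 22.4)),
        "beta3": _L(0.0, (0.3867, -38.76)),
        "alpha4": _L(0.0, (152.0, 11.8), (60.88, 12.97)),
        "beta4": _L(0.0, (3.904e-5, -12.52)),
        "I1": _L(9.39e-5),
        "R1": _L(3.874e-4, (4.687e-6, -15.06)),
        "I2": _L(9.39e-5),
        "R2": _L(3.874e-4, (4.687e-6, -15.06)),
        "I3": _L(3.971e-5),
        "R3": _L(9.436e-5, (2.396e-6, -18.97)),
        "FI": _L(2.50),
        "FR": _L(0.024),
    },
    ("CF", 6.0): {
        "delta": _L(1.922),
        "lambda": _L(19.22),
        "alpha1": _L(0.0, (371.54, 7.813)),
        "beta1": _L(0.0, (0.104, -49.96)),
        "alpha2": _L(0.0, (371.54, 7.813)),
        "beta2": _L(0.0, (0.104, -49.96)),
        "alpha3": _L(0.0, (134.71, 10.73)),
        "beta3": _L(0.0, (0.1025, -30.29)),
        "alpha4": _L(0.0, (237.0, 7.207), (4.99, 16.01)),
        "beta4": _L(0.0, (1.432e-5, -11.51)),
        "I1": _L(4.278e-5),
        "R1": _L(3.597e-4, (3.666e-6, -14.32)),
        "I2": _L(4.278e-5),
        "R2": _L(3.597e-4, (3.666e-6, -14.32)),
        "I3": _L(2.716e-5),
        "R3": _L(3.852e-5, (9.863e-7, -17.85)),
        "FI": _L(1.178),
        "FR": _L(0.0015),
    },
    ("CF_EK", 6.0): {
        "delta": _L(1.922),
        "lambda": _L(19.22),
        "alpha1": _L(0.0, (371.54, 7.813)),
        "beta1": _L(0.0, (0.104, -49.96)),
        "alpha2": _L(0.0, (371.54, 7.813)),
        "beta2": _L(0.0, (0.104, -49.96)),
        "alpha3": _L(0.0, (134.71, 10.73)),
        "beta3": _L(0.0, (0.1025, -30.29)),
        "alpha4": _L(0.0, (204.65, 11.02), (19.59, 15.31)),
        "beta4": _L(0.0, (1.144e-4, -14.0)),
        "I1": _L(4.278e-5),
        "R1": _L(3.597e-4, (3.666e-6, -14.32)),
        "I2": _L(4.278e-5),
        "R2": _L(3.597e-4, (3.666e-6, -14.32)),
        "I3": _L(2.716e-5),
        "R3": _L(4.994e-5, (6.335e-7, -14.21)),
        "FI": _L(1.71),
        "FR": _L(0.023),
    },
}

CONDITIONS = tuple(sorted(_TABLE, key=lambda k: (k[0], -k[1])))

_SQRT_HALF = math.sqrt(0.5)


def load_parameter_table(
    genotype: str,
    ph: float,
    *,
    apply_sqrt_half: bool = False,
    e_rev: float = 58.0,
    g_max: float = 1.0,
    clamp_tau: float = 0.05,
) -> ChannelParams:
    """Build the :class:`ChannelParams` for one of the four built-in conditions.

    Parameters
    ----------
    genotype : {"CF", "CF_EK"}
        C373F background or C373F/E1784K double mutant.
    ph : {7.4, 6.0}
        Extracellular pH of the condition.
    apply_sqrt_half : bool
        If True, multiply the DI/DII relaxation and de-relaxation laws by
        sqrt(0.5) ~= 0.707, reflecting that relaxation of either of the two
        equivalent sensors suffices for slow inactivation.  Off by default:
        the built-in table entries are taken as final.
    e_rev : float
        Sodium reversal potential in mV.  The default +58 mV follows from the
        Nernst relation for 96 mM external / 9.6 mM internal sodium at 293 K.
    """
    key = (str(genotype), float(ph))
    if key not in _TABLE:
        raise KeyError(
            f"unknown condition {key}; available conditions: {list(CONDITIONS)}"
        )
    laws = dict(_TABLE[key])
    if apply_sqrt_half:
        for sym in ("I1", "R1", "I2", "R2"):
            laws[sym] = laws[sym].scaled(_SQRT_HALF)

    domains = []
    for i, dom in enumerate(DOMAINS, start=1):
        domains.append(
            DomainParams(
                domain_id=dom,
                rate_sd=laws["delta"],
                rate_ds=laws["lambda"],
                rate_da=laws[f"alpha{i}"],
                rate_ad=laws[f"beta{i}"],
                rate_onset=laws["FI" if dom == "DIV" else f"I{i}"],
                rate_recovery=laws["FR" if dom == "DIV" else f"R{i}"],
                charge_weight=1.5 if dom in ("DIII", "DIV") else 1.0,
                immobilization_coupled=(dom == "DIII"),
            )
        )
    return ChannelParams(
        genotype=key[0],
        ph=key[1],
        domains=tuple(domains),
        e_rev=e_rev,
        g_max=g_max,
        clamp_tau=clamp_tau,
    )


def make_variant(params: ChannelParams, overrides: dict[str, RateLaw | float]) -> ChannelParams:
    """Return a copy of ``params`` with named rate laws replaced.

    ``overrides`` maps table symbols to replacement :class:`RateLaw` objects
    (a bare number is shorthand for a constant voltage-independent law).
    Setting ``FI`` to zero yields the fast-inactivation-deficient analogue of
    the IFM/QQQ construct.  The shared delta/lambda symbols apply to all four
    domains at once.
    """
    resolved: dict[str, RateLaw] = {}
    for sym, law in overrides.items():
        _resolve_symbol(sym)  # raises KeyError for unknown symbols
        if not isinstance(law, RateLaw):
            law = RateLaw(float(law), ())
        resolved[sym] = law

    new_domains = []
    for dom_params in params.domains:
        updates: dict[str, RateLaw] = {}
        for sym, law in resolved.items():
            dom, role = RATE_SYMBOLS[sym]
            if dom is None or dom == dom_params.domain_id:
                updates[_ROLE_ATTR[role]] = law
        new_domains.append(replace(dom_params, **updates) if updates else dom_params)
    return replace(params, domains=tuple(new_domains))


# ---------------------------------------------------------------------------
# Serialisation: human-readable YAML mirroring the rate table layout.
# ---------------------------------------------------------------------------

def _law_to_dict(law: RateLaw) -> dict:
    return {"constant": law.constant, "terms": [[a, s] for a, s in law.terms]}


def _law_from_dict(d: dict) -> RateLaw:
    return RateLaw(d.get("constant", 0.0), tuple((a, s) for a, s in d.get("terms", ())))


def params_to_yaml(params: ChannelParams) -> str:
    """Serialise a parameter set as YAML (symbol -> {constant, terms}).

    The round trip through :func:`params_from_yaml` is bit-exact on the rate
    values (YAML stores full float repr).
    """
    rates = {sym: _law_to_dict(params.rate(sym)) for sym in RATE_SYMBOLS}
    doc = {
        "genotype": params.genotype,
        "ph": params.ph,
        "e_rev": params.e_rev,
        "g_max": params.g_max,
        "temperature": params.temperature,
        "clamp_tau": params.clamp_tau,
        "charge_weights": {d.domain_id: d.charge_weight for d in params.domains},
        "immobilization_coupled": next(
            d.domain_id for d in params.domains if d.immobilization_coupled
        ),
        "rates": rates,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def params_from_yaml(text: str) -> ChannelParams:
    """Inverse of :func:`params_to_yaml`."""
    doc = yaml.safe_load(text)
    laws = {sym: _law_from_dict(d) for sym, d in doc["rates"].items()}
    weights = doc.get("charge_weights", {})
    coupled = doc.get("immobilization_coupled", "DIII")
    domains = []
    for i, dom in enumerate(DOMAINS, start=1):
        domains.append(
            DomainParams(
                domain_id=dom,
                rate_sd=laws["delta"],
                rate_ds=laws["lambda"],
                rate_da=laws[f"alpha{i}"],
                rate_ad=laws[f"beta{i}"],
                rate_onset=laws["FI" if dom == "DIV" else f"I{i}"],
                rate_recovery=laws["FR" if dom == "DIV" else f"R{i}"],
                charge_weight=weights.get(dom, 1.5 if dom in ("DIII", "DIV") else 1.0),
                immobilization_coupled=(dom == coupled),
            )
        )
    return ChannelParams(
        genotype=doc["genotype"],
        ph=doc["ph"],
        domains=tuple(domains),
        e_rev=doc.get("e_rev", 58.0),
        g_max=doc.get("g_max", 1.0),
        temperature=doc.get("temperature", 293.0),
        clamp_tau=doc.get("clamp_tau", 0.05),
    )
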