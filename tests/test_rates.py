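"""Rate-law evaluation, the built-in parameter table, and variants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetranav import (
    CONDITIONS,
    RATE_SYMBOLS,
    RateLaw,
    eval_rate,
    load_parameter_table,
    make_variant,
    params_from_yaml,
    params_to_yaml,
)

# Independent transcription of the published rate table, written directly as
# lambdas (V in mV, rates in ms^-1).  This duplicates the package's own table
# on purpose: it is the audit oracle for the transcription test below.
HAND_TABLE = {
    ("CF", 7.4): {
        "delta": lambda V: 2.2897,
        "lambda": lambda V: 22.897,
        "alpha1": lambda V: 381.14 * math.exp(V / 9.657),
        "beta1": lambda V: 0.3446 * math.exp(V / -78.1),
        "alpha2": lambda V: 381.14 * math.exp(V / 9.657),
        "beta2": lambda V: 0.3446 * math.exp(V / -78.1),
        "alpha3": lambda V: 183.94 * math.exp(V / 22.4),
        "beta3": lambda V: 0.3867 * math.exp(V / -38.76),
        "alpha4": lambda V: 91.93 * math.exp(V / 8.417) + 48.39 * math.exp(V / 11.51),
        "beta4": lambda V: 9.273e-6 * math.exp(V / -11.51),
        "I1": lambda V: 9.39e-5,
        "R1": lambda V: 3.874e-4 + 4.687e-6 * math.exp(-V / 15.06),
        "I2": lambda V: 9.39e-5,
        "R2": lambda V: 3.874e-4 + 4.687e-6 * math.exp(-V / 15.06),
        "I3": lambda V: 3.971e-5,
        "R3": lambda V: 5.199e-5 + 2.642e-6 * math.exp(V / -22.47),
        "FI": lambda V: 1.522,
        "FR": lambda V: 0.002,
    },
    ("CF_EK", 7.4): {
        "delta": lambda V: 2.2897,
        "lambda": lambda V: 22.897,
        "alpha1": lambda V: 381.14 * math.exp(V / 9.657),
        "beta1": lambda V: 0.3446 * math.exp(V / -78.1),
        "alpha2": lambda V: 381.14 * math.exp(V / 9.657),
        "beta2": lambda V: 0.3446 * math.exp(V / -78.1),
        "alpha3": lambda V: 183.94 * math.exp(V / 22.4),
        "beta3": lambda V: 0.3867 * math.exp(V / -38.76),
        "alpha4": lambda V: 152.0 * math.exp(V / 11.8) + 60.88 * math.exp(V / 12.97),
        "beta4": lambda V: 3.904e-5 * math.exp(V / -12.52),
        "I1": lambda V: 9.39e-5,
        "R1": lambda V: 3.874e-4 + 4.687e-6 * math.exp(-V / 15.06),
        "I2": lambda V: 9.39e-5,
        "R2": lambda V: 3.874e-4 + 4.687e-6 * math.exp(-V / 15.06),
        "I3": lambda V: 3.971e-5,
        "R3": lambda V: 9.436e-5 + 2.396e-6 * math.exp(V / -18.97),
        "FI": lambda V: 2.50,
        "FR": lambda V: 0.024,
    },
    ("CF", 6.0): {
        "delta": lambda V: 1.922,
        "lambda": lambda V: 19.22,
        "alpha1": lambda V: 371.54 * math.exp(V / 7.813),
        "beta1": lambda V: 0.104 * math.exp(V / -49.96),
        "alpha2": lambda V: 371.54 * math.exp(V / 7.813),
        "beta2": lambda V: 0.104 * math.exp(V / -49.96),
        "alpha3": lambda V: 134.71 * math.exp(V / 10.73),
        "beta3": lambda V: 0.1025 * math.exp(V / -30.29),
        "alpha4": lambda V: 237.0 * math.exp(V / 7.207) + 4.99 * math.exp(V / 16.01),
        "beta4": lambda V: 1.432e-5 * math.exp(V / -11.51),
        "I1": lambda V: 4.278e-5,
        "R1": lambda V: 3.597e-4 + 3.666e-6 * math.exp(V / -14.32),
        "I2": lambda V: 4.278e-5,
        "R2": lambda V: 3.597e-4 + 3.666e-6 * math.exp(V / -14.32),
        "I3": lambda V: 2.716e-5,
        "R3": lambda V: 3.852e-5 + 9.863e-7 * math.exp(V / -17.85),
        "FI": lambda V: 1.178,
        "FR": lambda V: 0.0015,
    },
    ("CF_EK", 6.0): {
        "delta": lambda V: 1.922,
        "lambda": lambda V: 19.22,
        "alpha1": lambda V: 371.54 * math.exp(V / 7.813),
        "beta1": lambda V: 0.104 * math.exp(V / -49.96),
        "alpha2": lambda V: 371.54 * math.exp(V / 7.813),
        "beta2": lambda V: 0.104 * math.exp(V / -49.96),
        "alpha3": lambda V: 134.71 * math.exp(V / 10.73),
        "beta3": lambda V: 0.1025 * math.exp(V / -30.29),
        "alpha4": lambda V: 204.65 * math.exp(V / 11.02) + 19.59 * math.exp(V / 15.31),
        "beta4": lambda V: 1.144e-4 * math.exp(V / -14.0),
        "I1": lambda V: 4.278e-5,
        "R1": lambda V: 3.597e-4 + 3.666e-6 * math.exp(V / -14.32),
        "I2": lambda V: 4.278e-5,
        "R2": lambda V: 3.597e-4 + 3.666e-6 * math.exp(V / -14.32),
        "I3": lambda V: 2.716e-5,
        "R3": lambda V: 4.994e-5 + 6.335e-7 * math.exp(V / -14.21),
        "FI": lambda V: 1.71,
        "FR": lambda V: 0.023,
    },
}


@pytest.mark.parametrize("condition", CONDITIONS, ids=lambda c: f"{c[0]}_pH{c[1]:g}")
@pytest.mark.parametrize("V", [-150.0, -90.0, 0.0])
def test_transcription_matches_independent_hand_copy(condition, V):
    """Every rate symbol agrees with an independent transcription to 4 sig figs."""
    params = load_parameter_table(*condition)
    for symbol in RATE_SYMBOLS:
        expected = HAND_TABLE[condition][symbol](V)
        got = eval_rate(params.rate(symbol), V)
        assert got == pytest.approx(expected, rel=1e-4), (condition, symbol, V)


def test_rate_examples():
    cf = load_parameter_table("CF", 7.4)
    ek = load_parameter_table("CF_EK", 7.4)
    cf6 = load_parameter_table("CF", 6.0)
    # voltage-independent constant
    assert eval_rate(cf.rate("delta"), -137.0) == 2.2897
    assert cf.rate("delta").is_voltage_independent
    # exponent vanishes at 0 mV
    assert eval_rate(cf.rate("alpha1"), 0.0) == pytest.approx(381.14)
    # two-term sum evaluated at -50 mV
    assert eval_rate(cf.rate("alpha4"), -50.0) == pytest.approx(0.870, abs=5e-4)
    # fast-inactivation entries and the pH dependence of delta
    assert cf.rate("FI").constant == 1.522 and cf.rate("FR").constant == 0.002
    assert ek.rate("FI").constant == 2.50 and ek.rate("FR").constant == 0.024
    assert cf6.rate("delta").constant == 1.922


def test_unknown_condition_lists_available():
    with pytest.raises(KeyError, match="available conditions"):
        load_parameter_table("CF", 7.0)


def test_genotypes_differ_only_in_div_and_r3():
    """CF vs CF/EK at matched pH differ only in alpha4, beta4, FI, FR, R3."""
    changed = {"alpha4", "beta4", "FI", "FR", "R3"}
    for ph in (7.4, 6.0):
        cf = load_parameter_table("CF", ph)
        ek = load_parameter_table("CF_EK", ph)
        for symbol in RATE_SYMBOLS:
            same = cf.rate(symbol) == ek.rate(symbol)
            assert same != (symbol in changed), (ph, symbol)


def test_di_dii_equivalent_in_builtin_table():
    for condition in CONDITIONS:
        p = load_parameter_table(*condition)
        assert p.rate("alpha1") == p.rate("alpha2")
        assert p.rate("beta1") == p.rate("beta2")
        assert p.rate("I1") == p.rate("I2")
        assert p.rate("R1") == p.rate("R2")


def test_charge_weights_and_coupling_flags():
    p = load_parameter_table("CF", 7.4)
    weights = {d.domain_id: d.charge_weight for d in p.domains}
    assert weights == {"DI": 1.0, "DII": 1.0, "DIII": 1.5, "DIV": 1.5}
    assert [d.domain_id for d in p.domains if d.immobilization_coupled] == ["DIII"]


def test_sqrt_half_switch_scales_di_dii_relaxation_only():
    base = load_parameter_table("CF", 7.4)
    scaled = load_parameter_table("CF", 7.4, apply_sqrt_half=True)
    f = math.sqrt(0.5)
    assert scaled.rate("I1").constant == pytest.approx(base.rate("I1").constant * f)
    assert scaled.rate("R2").constant == pytest.approx(base.rate("R2").constant * f)
    assert scaled.rate("I3") == base.rate("I3")
    assert scaled.rate("FI") == base.rate("FI")


class TestMakeVariant:
    def test_zero_fi_disables_div_fourth_state(self, cf74):
        v = make_variant(cf74, {"FI": 0.0})
        assert eval_rate(v.rate("FI"), 0.0) == 0.0
        assert v.rate("FR") == cf74.rate("FR")

    def test_empty_overrides_is_identity(self, cf74):
        assert make_variant(cf74, {}) == cf74

    def test_amplitude_doubling_doubles_rate_everywhere(self, cf74):
        law = cf74.rate("alpha4")
        doubled = RateLaw(law.constant * 2, tuple((2 * a, s) for a, s in law.terms))
        v = make_variant(cf74, {"alpha4": doubled})
        for V in (-120.0, -40.0, 0.0, 40.0):
            assert eval_rate(v.rate("alpha4"), V) == pytest.approx(
                2 * eval_rate(cf74.rate("alpha4"), V))

    def test_unknown_symbol_raises(self, cf74):
        with pytest.raises(KeyError, match="unknown rate symbol"):
            make_variant(cf74, {"gamma9": 1.0})

    def test_shared_delta_applies_to_all_domains(self, cf74):
        v = make_variant(cf74, {"delta": 5.0})
        for dom in v.domains:
            assert dom.rate_sd.constant == 5.0


def test_yaml_round_trip_is_exact():
    for condition in CONDITIONS:
        p = load_parameter_table(*condition)
        q = params_from_yaml(params_to_yaml(p))
        assert q == p


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    amp=st.floats(1e-6, 1e3),
    slope=st.floats(1.0, 100.0),
    v1=st.floats(-200.0, 100.0),
    v2=st.floats(-200.0, 100.0),
)
def test_single_term_positive_slope_law_is_monotone(amp, slope, v1, v2):
    law = RateLaw(0.0, ((amp, slope),))
    lo, hi = sorted((v1, v2))
    assert eval_rate(law, lo) <= eval_rate(law, hi)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    const=st.floats(0.0, 10.0),
    amp=st.floats(0.0, 1e3),
    slope=st.floats(5.0, 100.0).flatmap(lambda s: st.sampled_from([s, -s])),
    V=st.floats(-200.0, 100.0),
)
def test_rate_laws_finite_nonnegative_on_physiological_range(const, amp, slope, V):
    law = RateLaw(const, ((amp, slope),))
    value = eval_rate(law, V)
    assert math.isfinite(value) and value >= 0.0


def test_invalid_rate_laws_rejected():
    with pytest.raises(ValueError):
        RateLaw(-1.0)
    with pytest.raises(ValueError):
        RateLaw(0.0, ((1.0, 0.0),))
    with pytest.raises(ValueError):
        RateLaw(0.0, ((-2.0, 10.0),))
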