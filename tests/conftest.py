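import numpy as np
import pytest

from tetranav import build_protocol, load_parameter_table, run_family

#: coarse-but-adequate solver settings for tests that only need qualitative
#: accuracy; acceptance-grade checks use the engine defaults instead
FAST_KW = dict(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def cf74():
    return load_parameter_table("CF", 7.4)


@pytest.fixture(scope="session")
def ek74():
    return load_parameter_table("CF_EK", 7.4)


@pytest.fixture(scope="session")
def gv_families():
    """Default-tolerance GV families for all four built-in conditions."""
    fams = {}
    for geno in ("CF", "CF_EK"):
        for ph in (7.4, 6.0):
            params = load_parameter_table(geno, ph)
            fams[(geno, ph)] = run_family(params, build_protocol("gv"))
    return fams


@pytest.fixture(scope="session")
def qv_on_vhalves():
    """Boltzmann midpoints of the simulated QV-on curve, all four conditions."""
    from tetranav import fit_boltzmann, qv_curve

    out = {}
    for geno in ("CF", "CF_EK"):
        for ph in (7.4, 6.0):
            params = load_parameter_table(geno, ph)
            fam = run_family(params, build_protocol("qv_on"))
            out[(geno, ph)] = fit_boltzmann(qv_curve(fam, segment=0)).v_half
    return out


@pytest.fixture(scope="session")
def small_gv_target(cf74):
    """A 5-voltage, coarse-grid GV family used as a fitting target."""
    protos = build_protocol("gv", voltages=[-60, -40, -20, 0, 20],
                            sample_interval=0.05)
    return run_family(cf74, protos, **FAST_KW), protos
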