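"""State propagation: conservation, equilibria, currents, coupling."""

import numpy as np
import pytest
from scipy.linalg import expm

from tetranav import (
    StateVector,
    VoltageProtocol,
    derivatives,
    equilibrium_state,
    eval_rate,
    gating_current,
    integrate,
    ionic_current,
    load_parameter_table,
    make_variant,
    open_probability,
    state_index,
)
from tetranav.engine import IDX_DIV_I

from conftest import FAST_KW


def chain_generator(dom, V):
    """4x4 generator of one domain's chain at fixed V (rows = from-state)."""
    sd = eval_rate(dom.rate_sd, V)
    ds = eval_rate(dom.rate_ds, V)
    da = eval_rate(dom.rate_da, V)
    ad = eval_rate(dom.rate_ad, V)
    on = eval_rate(dom.rate_onset, V)
    rec = eval_rate(dom.rate_recovery, V)
    return np.array([
        [-sd, sd, 0.0, 0.0],
        [ds, -(ds + da), da, 0.0],
        [0.0, ad, -(ad + on), on],
        [0.0, 0.0, rec, -rec],
    ])


class TestDerivatives:
    def test_per_domain_conservation_is_exact(self, cf74):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.dirichlet(np.ones(4), size=4).reshape(-1)
            for V in (-150.0, -20.0, 40.0):
                dy = derivatives(y, V, cf74)
                sums = dy.reshape(4, 4).sum(axis=1)
                # conservation up to float cancellation in the flux sums
                scale = max(1.0, float(np.max(np.abs(dy))))
                assert np.max(np.abs(sums)) < 1e-14 * scale

    def test_uninactivated_div_leaves_diii_deactivation_uncoupled(self, cf74):
        y = np.tile([0.1, 0.2, 0.6, 0.1], 4)
        y[12:] = [0.25, 0.25, 0.5, 0.0]  # I_DIV = 0
        dy_coupled = derivatives(y, -50.0, cf74, coupling="text")
        dy_free = derivatives(y, -50.0, cf74, coupling="none")
        assert dy_coupled == pytest.approx(dy_free)

    def test_fully_inactivated_div_blocks_diii_deactivation(self, cf74):
        y = np.tile([0.0, 0.0, 1.0, 0.0], 4)
        y[12:] = [0.0, 0.0, 0.0, 1.0]  # I_DIV = 1
        dy = derivatives(y, -120.0, cf74, coupling="text")
        # DIII A occupancy can only leave via relaxation now
        i3 = eval_rate(cf74.domain("DIII").rate_onset, -120.0)
        assert dy[state_index("DIII", "A")] == pytest.approx(-i3, rel=1e-12)


class TestEquilibrium:
    def test_two_state_subsystem_matches_closed_form(self, cf74):
        # S <-> D only: zero every other transition
        v = make_variant(cf74, {s: 0.0 for s in
                                ("alpha1", "alpha2", "alpha3", "alpha4",
                                 "beta1", "beta2", "beta3", "beta4",
                                 "I1", "I2", "I3", "FI", "R1", "R2", "R3", "FR")})
        eq = equilibrium_state(v, -80.0)
        delta, lam = 2.2897, 22.897
        for dom in ("DI", "DII", "DIII", "DIV"):
            assert eq.occupancy(dom, "D") == pytest.approx(delta / (delta + lam), rel=1e-9)

    @pytest.mark.parametrize("V", [-150.0, -90.0, -20.0])
    @pytest.mark.parametrize("coupling", ["text", "table", "none"])
    def test_equilibrium_is_a_fixed_point(self, cf74, V, coupling):
        eq = equilibrium_state(cf74, V, coupling=coupling)
        dy = derivatives(eq, V, cf74, coupling=coupling)
        assert np.max(np.abs(dy)) < 1e-10

    def test_equilibrium_matches_long_relaxation(self, cf74):
        """10 s of relaxation from uniform occupancy reaches the fixed point."""
        proto = VoltageProtocol(((-150.0, 10_000.0),), holding=-150.0,
                                sample_interval=100.0)
        y0 = np.tile([0.25, 0.25, 0.25, 0.25], 4)
        traj = integrate(cf74, proto, y0=y0, rtol=1e-10, atol=1e-12)
        eq = equilibrium_state(cf74, -150.0)
        assert traj.occupancy[-1] == pytest.approx(eq.values, abs=1e-6)

    def test_deactivation_recovery_equilibrium_is_stationary(self, cf74):
        eq = equilibrium_state(cf74, -120.0, div_recovery="deactivation")
        dy = derivatives(eq, -120.0, cf74, div_recovery="deactivation")
        assert np.max(np.abs(dy)) < 1e-10


class TestIntegrate:
    def test_constant_hold_at_equilibrium_is_stationary(self, cf74):
        proto = VoltageProtocol(((-150.0, 10.0),), holding=-150.0)
        traj = integrate(cf74, proto)
        assert np.max(np.abs(traj.occupancy - traj.occupancy[0])) < 1e-8
        assert np.max(np.abs(traj.i_gating)) < 1e-9

    def test_occupancy_conservation_along_sweep(self, cf74):
        proto = VoltageProtocol(((-20.0, 20.0), (-150.0, 10.0)), holding=-150.0)
        traj = integrate(cf74, proto)
        sums = traj.occupancy.reshape(-1, 4, 4).sum(axis=2)
        assert np.max(np.abs(sums - 1.0)) < 1e-9

    def test_filtered_voltage_settles_with_clamp_tau(self, cf74):
        proto = VoltageProtocol(((0.0, 5.0),), holding=-150.0)
        traj = integrate(cf74, proto)
        tau = cf74.clamp_tau
        expected = 0.0 + (-150.0 - 0.0) * np.exp(-traj.t / tau)
        assert traj.v_filtered == pytest.approx(expected, abs=1e-9)
        # with tau -> 0 the filtered voltage equals the command immediately
        traj0 = integrate(cf74, VoltageProtocol(((0.0, 5.0),), holding=-150.0,
                                                clamp_tau=0.0))
        assert np.all(traj0.v_filtered == traj0.v_command)

    def test_step_size_self_convergence(self, cf74):
        """Tightening tolerance changes the persistent readout < 0.1 % relative."""
        proto = VoltageProtocol(((-20.0, 100.0),), holding=-150.0)
        coarse = integrate(cf74, proto)
        fine = integrate(cf74, proto, rtol=1e-10, atol=1e-12)
        p_coarse = abs(coarse.i_ionic[coarse.t >= 95].mean())
        p_fine = abs(fine.i_ionic[fine.t >= 95].mean())
        assert abs(p_coarse - p_fine) / p_fine < 1e-3

    def test_matrix_exponential_oracle_uncoupled_fixed_V(self, cf74):
        """With coupling off, each domain follows expm of its own chain."""
        V = -20.0
        proto = VoltageProtocol(((V, 20.0),), holding=-150.0, clamp_tau=0.0)
        traj = integrate(cf74, proto, coupling="none", rtol=1e-10, atol=1e-12)
        y0 = equilibrium_state(cf74, -150.0, coupling="none").values
        for di, dom in enumerate(cf74.domains):
            Q = chain_generator(dom, V)
            p0 = y0[4 * di: 4 * di + 4]
            for k in (0, len(traj.t) // 3, len(traj.t) - 1):
                expected = p0 @ expm(Q * traj.t[k])
                got = traj.occupancy[k, 4 * di: 4 * di + 4]
                assert np.max(np.abs(got - expected)) < 1e-6, (dom.domain_id, k)

    def test_return_to_holding_equilibrium_after_depolarization(self, cf74):
        """A depolarising step fully reverses given a long recovery."""
        proto = VoltageProtocol(((-20.0, 20.0), (-150.0, 60_000.0)),
                                holding=-150.0, sample_interval=50.0)
        traj = integrate(cf74, proto, **FAST_KW)
        eq = equilibrium_state(cf74, -150.0)
        assert traj.occupancy[-1] == pytest.approx(eq.values, abs=1e-5)


class TestCurrents:
    def test_open_probability_extremes(self):
        occ = np.zeros(16)
        for dom in ("DI", "DII", "DIII"):
            occ[state_index(dom, "A")] = 1.0
        occ[state_index("DIV", "A")] = 1.0
        assert open_probability(occ[None, :])[0] == 1.0
        occ[state_index("DIV", "A")] = 0.0
        occ[IDX_DIV_I] = 1.0  # fast-inactivated: closed pore
        assert open_probability(occ[None, :])[0] == 0.0

    def test_zero_driving_force_gives_zero_current(self, cf74):
        proto = VoltageProtocol(((cf74.e_rev, 5.0),), holding=-150.0, clamp_tau=0.0)
        traj = integrate(cf74, proto)
        assert np.max(np.abs(traj.i_ionic)) == 0.0

    def test_inward_current_is_negative_below_reversal(self, cf74):
        proto = VoltageProtocol(((-20.0, 20.0),), holding=-150.0)
        traj = integrate(cf74, proto)
        assert traj.i_ionic.min() < 0
        assert np.max(traj.i_ionic[traj.t > 0.2]) <= 1e-12

    def test_gating_charge_shares_20_20_30_30(self, cf74):
        """Complete D->A transfer distributes charge 20/20/30/30 % by domain."""
        v = make_variant(cf74, {"I1": 0.0, "I2": 0.0, "I3": 0.0, "FI": 0.0})
        # fine sampling so the flux transient through the clamp settling
        # window is resolved by the trapezoidal charge integral
        proto = VoltageProtocol(((60.0, 20.0),), holding=-150.0,
                                sample_interval=0.002)
        traj = integrate(v, proto)
        weights = np.array([d.charge_weight for d in v.domains])
        delta_a = np.array([
            traj.occ(d, "A")[-1] - traj.occ(d, "A")[0]
            for d in ("DI", "DII", "DIII", "DIV")
        ])
        assert np.all(delta_a > 0.99)  # transfer is essentially complete
        shares = weights * delta_a / (weights * delta_a).sum()
        assert shares == pytest.approx([0.2, 0.2, 0.3, 0.3], abs=0.002)
        # and the integrated gating current equals the weighted flux sum
        q_total = np.trapezoid(traj.i_gating, traj.t)
        assert q_total == pytest.approx(float(weights @ delta_a), rel=1e-3)

    def test_charge_integral_equals_weighted_da_transfer_generic(self, cf74):
        """Time-integral of I_g matches the weighted net D->A transfer."""
        proto = VoltageProtocol(((0.0, 20.0),), holding=-150.0)
        traj = integrate(cf74, proto)
        q_total = np.trapezoid(traj.i_gating, traj.t)
        # net charge moved across D<->A per domain: change in (A + downstream X)
        weights = np.array([d.charge_weight for d in cf74.domains])
        moved = np.array([
            (traj.occ(d, "A") + traj.occ(d, "X"))[-1]
            - (traj.occ(d, "A") + traj.occ(d, "X"))[0]
            for d in ("DI", "DII", "DIII", "DIV")
        ])
        assert q_total == pytest.approx(float(weights @ moved), rel=1e-3)


def test_fast_inactivation_knockout_makes_genotypes_identical(cf74, ek74):
    """With FI = 0 (and matched DIII de-relaxation) CF and CF/EK conduct
    identically: DIV no longer reaches the pore rule or the coupling.

    R3 is equalised because the two genotypes also differ in that slow
    DIII rate, which contributes a separate ~1e-5 relative difference.
    """
    proto = VoltageProtocol(((-30.0, 15.0),), holding=-150.0)
    kw = dict(rtol=1e-10, atol=1e-12)
    tr_cf = integrate(make_variant(cf74, {"FI": 0.0}), proto, **kw)
    tr_ek = integrate(make_variant(ek74, {"FI": 0.0, "R3": cf74.rate("R3")}),
                      proto, **kw)
    scale = np.max(np.abs(tr_cf.i_ionic))
    assert np.max(np.abs(tr_cf.i_ionic - tr_ek.i_ionic)) / scale < 1e-6


def test_state_vector_validation():
    good = StateVector(np.tile([0.7, 0.1, 0.1, 0.1], 4))
    good.validate()
    with pytest.raises(ValueError, match="sums"):
        StateVector(np.tile([0.5, 0.1, 0.1, 0.1], 4)).validate()
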