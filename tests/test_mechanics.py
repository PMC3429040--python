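"""Biomechanical model: pressures, implicit rate solve and integration."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from coughsim.mechanics import (
    D_MIN_MM,
    MechState,
    MuscleActivations,
    abdominal_fraction,
    abdominal_recoil,
    airway_resistance,
    diaphragm_recoil,
    glottal_diameter,
    intercostal_pressure,
    lung_recoil,
    lung_volume,
    rib_cage_recoil,
    rib_cage_volume,
    scripted_activation_trial,
)
from coughsim.params import hill_force_velocity


class TestGlottis:
    def test_resting_diameter(self):
        assert glottal_diameter(0.0) == pytest.approx(10.9)

    def test_closed_at_minus_one(self):
        assert glottal_diameter(-1.0) == pytest.approx(0.0)

    def test_continuous_at_upper_break(self):
        # At u_lm = 71/109 the proportional branch meets the tracheal bore.
        break_u = 71.0 / 109.0
        assert glottal_diameter(break_u) == pytest.approx(18.0)
        assert glottal_diameter(break_u + 1e-9) == pytest.approx(18.0)

    def test_rohrer_resting_coefficients(self):
        rrs, k1, k2 = airway_resistance(10.9, 0.0)
        assert k1 == pytest.approx(0.0035, rel=0.005)
        assert k2 == pytest.approx(0.681, rel=0.005)
        assert rrs == pytest.approx(k1 + 0.72)

    def test_resistance_grows_with_flow(self):
        r0, _, _ = airway_resistance(10.9, 0.0)
        r1, _, _ = airway_resistance(10.9, 2.0)
        assert r1 > r0

    def test_closed_airway_rejected(self):
        with pytest.raises(ValueError):
            airway_resistance(0.0, 1.0)


class TestRecoils:
    def test_lung_recoil_linear(self, free, derived):
        assert lung_recoil(derived.V_L0, free, derived) == 0.0
        assert lung_recoil(free.V_L_FRC, free, derived) == pytest.approx(
            (2.29 - derived.V_L_RV) / 0.201)
        d = 0.37
        assert (lung_recoil(3.0 + d, free, derived)
                - lung_recoil(3.0, free, derived)) == pytest.approx(d / free.C_L)

    def test_hill_force_velocity_at_rest(self):
        assert hill_force_velocity(0.0) == pytest.approx(1.005, abs=0.005)

    def test_diaphragm_passive_zero_at_frc(self, free, derived):
        assert diaphragm_recoil(0.0, free.V_di_FRC, 0.0, free, derived) == 0.0

    def test_diaphragm_force_velocity_asymmetry(self, free, derived):
        # shortening (inspiration, negative rate) weakens, lengthening
        # strengthens the active pressure
        base = diaphragm_recoil(1.0, derived.V_di_TLC, 0.0, free, derived)
        short = diaphragm_recoil(1.0, derived.V_di_TLC, -1.0, free, derived)
        lengthen = diaphragm_recoil(1.0, derived.V_di_TLC, 1.0, free, derived)
        assert short < base - free.R_di < base + free.R_di < lengthen

    def test_rib_cage_zero_at_resting_volume(self, free, derived):
        assert rib_cage_recoil(derived.V_rc0, 0.0, free, derived) == pytest.approx(
            0.0, abs=1e-12)

    def test_rib_cage_diverges_at_limits(self, free, derived):
        near_max = rib_cage_recoil(derived.V_rc_max - 1e-6, 0.0, free, derived)
        assert near_max > 100
        with pytest.raises(ValueError):
            rib_cage_recoil(derived.V_rc_max + 0.1, 0.0, free, derived)

    def test_rib_cage_compliance(self, free, derived):
        # the sigmoid's maximal compliance (at its midpoint) is C_rc/(1+C1);
        # at the resting volume, slightly off-centre, it is a few % below
        eps = 1e-6
        mid = 0.5 * (derived.V_rc_min + derived.V_rc_max)
        dsig = (rib_cage_recoil(mid + eps, 0.0, free, derived)
                - rib_cage_recoil(mid - eps, 0.0, free, derived))
        assert 2 * eps / dsig == pytest.approx(free.C_rc / (1 + free.C1), rel=1e-6)
        dsig0 = (rib_cage_recoil(derived.V_rc0 + eps, 0.0, free, derived)
                 - rib_cage_recoil(derived.V_rc0 - eps, 0.0, free, derived))
        assert 2 * eps / dsig0 == pytest.approx(free.C_rc / (1 + free.C1), rel=0.05)

    def test_abdominal_passive_zero_at_reference(self, free, derived, geom):
        assert abdominal_recoil(0.0, derived.V_ab0, 0.0, free, derived, geom) == \
            pytest.approx(0.0, abs=1e-12)


class TestInterostalAndFraction:
    def test_zero_activation(self, free, derived):
        assert intercostal_pressure(0.0, 0.0, 2.0, 7.0, free, derived) == 0.0

    def test_inspiratory_part_inactive_above_frc_volume(self, free, derived):
        # above the FRC diaphragm volume only the abdominal part remains
        assert intercostal_pressure(1.0, 0.0, free.V_di_FRC + 0.1, 7.0,
                                    free, derived) == 0.0

    def test_expiratory_endpoint(self, free, derived):
        pica = intercostal_pressure(0.0, 1.0, 2.0, derived.V_rc_TLC, free, derived)
        assert pica == pytest.approx(free.P_icaab_TLC)

    def test_fraction_at_tlc_volume(self, free, derived):
        assert abdominal_fraction(derived.V_di_TLC, 6.5, free, derived) == \
            pytest.approx(free.fa_TLC)

    def test_fraction_monotone_and_bounded(self, free, derived):
        vals = [abdominal_fraction(v, 3.0, free, derived)
                for v in np.linspace(derived.V_di_TLC, derived.V_di_RV, 50)]
        assert np.all(np.diff(vals) > 0)
        assert max(vals) <= 1 / (1 + free.C1) + free.fa_TLC + 1e-12


class TestVolumes:
    def test_lung_volume_identity(self, free, derived):
        state = MechState(V_di=free.V_di_FRC, V_ab=derived.V_ab_FRC)
        v_l = lung_volume(state, free, derived)
        assert v_l == pytest.approx(free.V_L_FRC, abs=1e-9)
        v_rc = rib_cage_volume(state, free, derived)
        assert state.V_di + free.C1 * v_rc + state.V_ab == pytest.approx(
            derived.V_sum, abs=1e-9)

    def test_lung_volume_slope(self, free, derived):
        s0 = MechState(3.0, 2.2)
        s1 = MechState(3.0 + 1e-6, 2.2)
        slope = (lung_volume(s1, free, derived) - lung_volume(s0, free, derived)) / 1e-6
        assert slope == pytest.approx(-(1 + free.C1) / free.C1, rel=1e-6)


class TestBalanceAndIntegration:
    def test_equilibrium_against_independent_oracle(self, model, equilibrium, free, derived, geom):
        # brute-force oracle: nested 1-D root finds over the static balances,
        # written here independently of the package's Newton solver
        def di_residual(v_di, v_ab):
            st = MechState(v_di, v_ab)
            v_l = lung_volume(st, free, derived)
            sig_di = diaphragm_recoil(0.0, v_di, 0.0, free, derived)
            sig_ab = abdominal_recoil(0.0, v_ab, 0.0, free, derived, geom)
            return sig_ab + lung_recoil(v_l, free, derived) - sig_di

        def rc_residual(v_di, v_ab):
            st = MechState(v_di, v_ab)
            v_l = lung_volume(st, free, derived)
            v_rc = rib_cage_volume(st, free, derived)
            sig_di = diaphragm_recoil(0.0, v_di, 0.0, free, derived)
            fa = abdominal_fraction(v_di, v_l, free, derived)
            return (-lung_recoil(v_l, free, derived) + (fa + free.F_di) * sig_di
                    - rib_cage_recoil(v_rc, 0.0, free, derived))

        def di_for_ab(v_ab):
            return brentq(lambda v: di_residual(v, v_ab),
                          derived.V_di_TLC + 0.05, derived.V_di_RV + 1.5,
                          xtol=1e-13)

        v_ab = brentq(lambda v: rc_residual(di_for_ab(v), v),
                      1.5, 3.0, xtol=1e-13)
        v_di = di_for_ab(v_ab)
        assert equilibrium.V_di == pytest.approx(v_di, abs=1e-6)
        assert equilibrium.V_ab == pytest.approx(v_ab, abs=1e-6)
        r1, r2 = model.balance_residuals(equilibrium, (0.0, 0.0), MuscleActivations())
        assert abs(r1) < 1e-8 and abs(r2) < 1e-8

    def test_rates_vanish_at_equilibrium(self, model, equilibrium):
        rates = model.solve_rates(equilibrium, MuscleActivations())
        assert abs(rates[0]) < 1e-9 and abs(rates[1]) < 1e-9

    def test_inspiratory_drive_direction(self, model, equilibrium, free):
        vdot_di, vdot_ab = model.solve_rates(equilibrium, MuscleActivations(u_di=0.2))
        vdot_l = (-(1 + free.C1) * vdot_di - vdot_ab) / free.C1
        assert vdot_di < 0    # diaphragm descends
        assert vdot_l > 0     # inspiratory airflow

    def test_closed_glottis_freezes_lung_volume(self, model, equilibrium, free):
        u = MuscleActivations(u_di=0.3, u_ab=0.5, u_lm=-1.0)
        vdot_di, vdot_ab = model.solve_rates(equilibrium, u)
        vdot_l = (-(1 + free.C1) * vdot_di - vdot_ab) / free.C1
        assert abs(vdot_l) < 1e-12

    def test_residual_kernel_matches_python_composition(self, model, free, derived, geom):
        # dual route: the jitted residual must equal the residual composed
        # from the documented pressure operations
        from coughsim import _kernels
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 20:
            v_di = rng.uniform(derived.V_di_TLC + 0.3, derived.V_di_RV)
            v_ab = rng.uniform(1.2, derived.V_ab_TLC - 0.2)
            st = MechState(v_di, v_ab)
            v_rc_probe = rib_cage_volume(st, free, derived)
            if not derived.V_rc_min + 0.1 < v_rc_probe < derived.V_rc_max - 0.1:
                continue
            checked += 1
            vd, va = rng.uniform(-1, 1, 2)
            u_di, u_ab = rng.uniform(0, 1, 2)
            d = 10.9
            res = _kernels.mech_residuals(vd, va, False, v_di, v_ab, u_di,
                                          u_ab, d, *model.kernel_args())
            st = MechState(v_di, v_ab)
            v_l = lung_volume(st, free, derived)
            v_rc = rib_cage_volume(st, free, derived)
            vdot_l = (-(1 + free.C1) * vd - va) / free.C1
            vdot_rc = vdot_l + vd
            rrs, _, _ = airway_resistance(d, vdot_l)
            ppl = -rrs * vdot_l - lung_recoil(v_l, free, derived)
            sig_di = diaphragm_recoil(u_di, v_di, vd, free, derived)
            sig_ab = abdominal_recoil(u_ab, v_ab, va, free, derived, geom)
            sig_rc = rib_cage_recoil(v_rc, vdot_rc, free, derived)
            fa = abdominal_fraction(v_di, v_l, free, derived)
            pica = intercostal_pressure(u_di, u_ab, v_di, v_rc, free, derived)
            r_rc = ppl + fa * sig_di + free.F_di * sig_di + pica - sig_rc
            r_di = sig_ab - ppl - sig_di
            # the engine uses a dense linear table for the wall geometry,
            # the composed route the spline itself
            assert res[0] == pytest.approx(r_rc, abs=5e-4)
            assert res[1] == pytest.approx(r_di, abs=5e-4)

    def test_equilibrium_state_is_stationary(self, model, equilibrium):
        state = equilibrium
        u = MuscleActivations()
        for _ in range(20):
            state, _ = model.step(state, u, 0.5)
        assert abs(state.V_di - equilibrium.V_di) < 1e-6
        assert abs(state.V_ab - equilibrium.V_ab) < 1e-6

    def test_volume_identity_preserved_during_motion(self, model, equilibrium, free, derived):
        state = equilibrium
        u = MuscleActivations(u_di=0.4, u_lm=0.3)
        for _ in range(40):
            state, ev = model.step(state, u, 0.05)
            total = state.V_di + free.C1 * ev.V_rc + state.V_ab
            assert total == pytest.approx(derived.V_sum, abs=1e-9)

    def test_step_halving_convergence(self, model, equilibrium):
        # breathing-like activation for 10 s at two substep sizes
        def run(substep):
            state = equilibrium
            for k in range(100):
                u = MuscleActivations(u_di=0.3 * (1 + math.sin(2 * math.pi * k / 40)) / 2)
                state, _ = model.step(state, u, 0.1, substep=substep)
            return state

        a = run(1e-3)
        b = run(5e-4)
        assert abs(a.V_di - b.V_di) < 1e-4
        assert abs(a.V_ab - b.V_ab) < 1e-4

    def test_compressive_phase_behaviour(self, model, equilibrium):
        # closed larynx: lung volume constant while alveolar pressure rises
        # under abdominal activation
        state = equilibrium
        u = MuscleActivations(u_ab=0.6, u_lm=-1.0)
        ev0 = model.evaluate(state, MuscleActivations())
        state1, ev1 = model.step(state, u, 0.05)
        v_l0 = ev1.V_L
        state2, ev2 = model.step(state1, u, 0.3)
        assert ev2.V_L == pytest.approx(v_l0, abs=1e-9)
        assert min(ev1.P_alv, ev2.P_alv) > ev0.P_alv + 5.0


def test_scripted_trial_runs(model):
    wave = np.array([
        [0.0, 0.0, 0.0, 0.0],
        [0.5, 0.4, 0.0, 0.3],
        [1.0, 0.0, 0.0, 0.0],
        [1.5, 0.0, 0.3, 0.0],
        [2.0, 0.0, 0.0, 0.0],
    ])
    t, out = scripted_activation_trial(model, wave, dt=0.005)
    assert len(t) == 400
    # inspiration then active expiration
    assert out["V_L"].max() > out["V_L"][0] + 0.05
    assert out["flow"].min() < 0 < out["flow"].max()
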