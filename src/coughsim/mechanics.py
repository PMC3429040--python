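"""Deterministic biomechanics of the supine respiratory system.

Two state variables describe the thoracoabdominal configuration: the volume
under the diaphragm ``V_di`` and the volume behind the abdominal wall
``V_ab``.  Lung and rib-cage volumes follow algebraically from the
three-movable-wall constraint ``V_di + C1 V_rc + V_ab = V_sum``.  At every
instant two pressure balances must hold -- on the rib cage (pleural pressure,
zone-of-apposition pressure, diaphragm insertional pressure and intercostal
pressure against rib-cage recoil) and across the diaphragm (abdominal minus
pleural pressure against diaphragm recoil).  These are implicit in the state
rates, which are found by Newton iteration at each evaluation.

Tracheal flow is reported expiration-positive, matching the usual clinical
plotting convention; internally the lung-volume derivative is
inspiration-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from ._kernels import MC_NAMES
from .params import (
    AbdominalGeometry,
    DerivedParameters,
    FreeParameters,
    build_abdominal_geometry,
    derive_parameters,
    hill_force_velocity,
)

__all__ = [
    "MechState",
    "MuscleActivations",
    "MechEval",
    "MechanicsModel",
    "lung_volume",
    "rib_cage_volume",
    "glottal_diameter",
    "airway_resistance",
    "lung_recoil",
    "diaphragm_recoil",
    "rib_cage_recoil",
    "abdominal_recoil",
    "intercostal_pressure",
    "abdominal_fraction",
]

D_MIN_MM = 0.05  # below this equivalent diameter the airway is treated as closed


@dataclass
class MechState:
    """Thoracoabdominal configuration: the two mechanical state volumes (L)."""
    V_di: float
    V_ab: float


@dataclass
class MuscleActivations:
    """Motor activations; clipped to their admissible ranges on creation."""
    u_di: float = 0.0   # diaphragm, [0, 1]
    u_ab: float = 0.0   # abdominal muscle, [0, 1]
    u_lm: float = 0.0   # net laryngeal, [-1 (closed), +1 (fully open)]

    def __post_init__(self) -> None:
        self.u_di = min(max(self.u_di, 0.0), 1.0)
        self.u_ab = min(max(self.u_ab, 0.0), 1.0)
        self.u_lm = min(max(self.u_lm, -1.0), 1.0)


@dataclass
class MechEval:
    """Instantaneous mechanical observables at a state/activation/rate point."""
    V_L: float
    V_rc: float
    flow: float          # tracheal flow, L/s, expiration positive
    d: float             # glottal diameter, mm
    P_pl: float
    P_alv: float
    sigma_L: float
    sigma_di: float
    sigma_ab: float
    sigma_rc: float
    P_ica: float
    P_ab_pl: float
    f_a: float
    Vdot_di: float
    Vdot_ab: float


def lung_volume(state: MechState, free: FreeParameters, p: DerivedParameters) -> float:
    """Lung volume (L) from the three-movable-wall volume constraint."""
    return (p.V_sum - (1.0 + free.C1) * state.V_di - state.V_ab
            - free.C1 * free.V_c) / free.C1


def rib_cage_volume(state: MechState, free: FreeParameters, p: DerivedParameters) -> float:
    return lung_volume(state, free, p) + state.V_di + free.V_c


def glottal_diameter(u_lm: float, D: float = FreeParameters.D) -> float:
    """Equivalent glottal diameter (mm); proportional to net activation.

    The diameter is the resting 10.9 mm at zero activation, saturates at the
    tracheal diameter ``D`` above ``u_lm = 71/109`` and closes at -1.
    """
    return float(_kernels.glottal_diameter_mm(u_lm, D))


def airway_resistance(d: float, flow: float, D: float = FreeParameters.D
                      ) -> tuple[float, float, float]:
    """Rohrer resistance of the whole airway at glottal diameter d (mm).

    Returns (R_rs, k1, k2) where ``R_rs = (k1 + 0.72) + (k2 + 0.44)|flow|``;
    k1 follows laminar-pipe 1/d^4 scaling and k2 the orifice expression,
    which vanishes as the glottis opens to the tracheal bore.
    """
    if d <= 0.0:
        raise ValueError("airway closed: resistance undefined, flow must be zero")
    k1 = float(_kernels.rohrer_k1(d))
    k2 = float(_kernels.rohrer_k2(d, D))
    return (k1 + 0.72) + (k2 + 0.44) * abs(flow), k1, k2


def lung_recoil(V_L: float, free: FreeParameters, p: DerivedParameters) -> float:
    """Linear lung recoil pressure (cmH2O); zero at the RV lung volume."""
    return (V_L - p.V_L0) / free.C_L


def diaphragm_recoil(u_di: float, V_di: float, Vdot_di: float,
                     free: FreeParameters, p: DerivedParameters) -> float:
    """Hill-model diaphragm recoil pressure (cmH2O).

    Active pressure is activation x maximal pressure x force-length x
    force-velocity on the volume-mapped length scale; passive recoil is
    quadratic above the FRC volume; a viscous term resists volume change.
    """
    ratio = (1.0 - p.L_di_min) * V_di / p.V_di0 + p.L_di_min
    z = (ratio - 1.05) / 0.192
    ffl = math.exp(-0.5 * z * z)
    ffv = hill_force_velocity(Vdot_di / free.Vdot_di_max)
    psv = p.K_dipsv * (V_di - free.V_di_FRC) ** 2 if V_di > free.V_di_FRC else 0.0
    return u_di * p.sigma_di_max * ffl * ffv + psv + free.R_di * Vdot_di


def rib_cage_recoil(V_rc: float, Vdot_rc: float,
                    free: FreeParameters, p: DerivedParameters) -> float:
    """Logistic rib-cage recoil (cmH2O), increasing in volume, zero at V_rc0."""
    if not p.V_rc_min < V_rc < p.V_rc_max:
        raise ValueError("rib cage volume outside its physical limits")
    return (p.sigma_rc_mul * math.log((V_rc - p.V_rc_min) / (p.V_rc_max - V_rc))
            + p.sigma_rc_add + free.R_rc * Vdot_rc)


def abdominal_recoil(u_ab: float, V_ab: float, Vdot_ab: float,
                     free: FreeParameters, p: DerivedParameters,
                     geom: AbdominalGeometry) -> float:
    """Abdominal pressure (cmH2O): Laplace-converted Hill muscle + passive wall."""
    r_t = geom.radius_from_volume(V_ab)
    r_s = geom.sagittal_radius(r_t)
    l_ce = geom.muscle_length(V_ab)
    z = (l_ce / free.L_CE0 - 1.05) / 0.192
    ffl = math.exp(-0.5 * z * z)
    ldot = geom.dmuscle_length_dv(V_ab) * Vdot_ab
    ffv = hill_force_velocity(ldot / free.V_CEmax)
    active = u_ab * free.F_CEmax * ffl * ffv * (free.k / r_t + free.k / r_s)
    return active + (V_ab - p.V_ab0) / free.C_ab + free.R_ab * Vdot_ab


def intercostal_pressure(u_di: float, u_ab: float, V_di: float, V_rc: float,
                         free: FreeParameters, p: DerivedParameters) -> float:
    """Equivalent pressure of intercostal/accessory muscles (cmH2O).

    The inspiratory part follows diaphragm activation and is silent below
    FRC-level lung volumes (V_di above its FRC value); the expiratory part
    follows abdominal activation and scales linearly with rib-cage volume.
    """
    pica_di = 0.0
    if V_di < free.V_di_FRC:
        pica_di = (u_di * p.P_icadi_TLC
                   * (V_di - free.V_di_FRC) / (p.V_di_TLC - free.V_di_FRC))
    pica_ab = u_ab * (p.P_icaab_RV + (V_rc - p.V_rc_RV) / (p.V_rc_TLC - p.V_rc_RV)
                      * (free.P_icaab_TLC - p.P_icaab_RV))
    return pica_di + pica_ab


def abdominal_fraction(V_di: float, V_L: float,
                       free: FreeParameters, p: DerivedParameters) -> float:
    """Fraction of the rib cage exposed to abdominal pressure (zone of apposition)."""
    num = max(V_di - p.V_di_TLC, 0.0)
    return num / (num + V_L) / (1.0 + free.C1) + free.fa_TLC


class MechanicsModel:
    """Bundled parameters, geometry and solver state for the mechanical model."""

    def __init__(self, free: FreeParameters | None = None,
                 derived: DerivedParameters | None = None,
                 geom: AbdominalGeometry | None = None,
                 table_size: int = 4096):
        self.free = free or FreeParameters()
        self.geom = geom or build_abdominal_geometry(self.free.c_t)
        self.derived = derived or derive_parameters(self.free, self.geom)
        self._pack(table_size)
        self._warm = np.zeros(3)

    # -- packing for the numba kernels ------------------------------------
    def _pack(self, table_size: int) -> None:
        free, p = self.free, self.derived
        vals = {
            "C1": free.C1, "V_c": free.V_c, "V_sum": p.V_sum, "V_L0": p.V_L0,
            "C_L": free.C_L, "sigma_di_max": p.sigma_di_max,
            "V_di_FRC": free.V_di_FRC, "K_dipsv": p.K_dipsv, "R_di": free.R_di,
            "L_di_min": p.L_di_min, "V_di0": p.V_di0,
            "Vdot_di_max": free.Vdot_di_max, "V_ab0": p.V_ab0,
            "C_ab": free.C_ab, "R_ab": free.R_ab, "F_CEmax": free.F_CEmax,
            "k": free.k, "L_CE0": free.L_CE0, "V_CEmax": free.V_CEmax,
            "sigma_rc_mul": p.sigma_rc_mul, "sigma_rc_add": p.sigma_rc_add,
            "V_rc_min": p.V_rc_min, "V_rc_max": p.V_rc_max, "R_rc": free.R_rc,
            "V_di_TLC": p.V_di_TLC, "fa_TLC": free.fa_TLC, "F_di": free.F_di,
            "P_icadi_TLC": p.P_icadi_TLC, "P_icaab_RV": p.P_icaab_RV,
            "P_icaab_TLC": free.P_icaab_TLC, "V_rc_RV": p.V_rc_RV,
            "V_rc_TLC": p.V_rc_TLC, "D": free.D, "d_min": D_MIN_MM,
            "VC": free.VC, "V_L_RV": p.V_L_RV, "c_t": free.c_t,
        }
        self.mc = np.array([vals[name] for name in MC_NAMES])
        # Dense uniform tables of the abdominal geometry for the kernels.
        v_lo, v_hi = 0.05, min(self.geom.v_max, 9.5)
        vg = np.linspace(v_lo, v_hi, table_size)
        self.gv0 = v_lo
        self.gdv = vg[1] - vg[0]
        self.rt_tab = np.array([self.geom.radius_from_volume(v) for v in vg])
        self.lce_tab = np.array([self.geom.muscle_length(v) for v in vg])
        self.dld_tab = np.array([self.geom.dmuscle_length_dv(v) for v in vg])

    def kernel_args(self):
        return self.mc, self.gv0, self.gdv, self.rt_tab, self.lce_tab, self.dld_tab

    # -- model evaluation --------------------------------------------------
    def balance_residuals(self, state: MechState, rates: tuple[float, float],
                          u: MuscleActivations) -> tuple[float, float]:
        """Residuals (cmH2O) of the rib-cage and diaphragm pressure balances.

        With a closed glottis the first residual is evaluated on the
        trapped-gas branch: lung volume is frozen and pleural pressure is the
        second unknown, so callers must supply rates consistent with
        ``Vdot_L = 0`` for the residuals to be meaningful.
        """
        d = glottal_diameter(u.u_lm, self.free.D)
        closed = d < D_MIN_MM
        if closed:
            # Pleural pressure consistent with the diaphragm balance is
            # substituted, leaving the rib-cage residual.
            vdot_di, vdot_ab = rates
            res = _kernels.mech_residuals(
                vdot_di, 0.0, True, state.V_di, state.V_ab, u.u_di, u.u_ab, d,
                *self.kernel_args())
            ppl = res[6] - res[5]  # sigma_ab - sigma_di
            res = _kernels.mech_residuals(
                vdot_di, ppl, True, state.V_di, state.V_ab, u.u_di, u.u_ab, d,
                *self.kernel_args())
            return res[0], res[1]
        res = _kernels.mech_residuals(
            rates[0], rates[1], False, state.V_di, state.V_ab,
            u.u_di, u.u_ab, d, *self.kernel_args())
        return res[0], res[1]

    def solve_rates(self, state: MechState, u: MuscleActivations,
                    guess: tuple[float, float] | None = None
                    ) -> tuple[float, float]:
        """State rates (V'di, V'ab in L/s) satisfying both pressure balances."""
        if guess is not None:
            self._warm[0], self._warm[1] = guess
        vdot_di, vdot_ab, _, _, ok = _kernels.mech_solve(
            state.V_di, state.V_ab, u.u_di, u.u_ab, u.u_lm,
            *self.kernel_args(), self._warm)
        if not ok:
            raise RuntimeError(
                f"rate solve failed at V_di={state.V_di:.4f}, "
                f"V_ab={state.V_ab:.4f}, u=({u.u_di:.3f},{u.u_ab:.3f},{u.u_lm:.3f})")
        return vdot_di, vdot_ab

    def evaluate(self, state: MechState, u: MuscleActivations) -> MechEval:
        """All instantaneous observables at the solved rates."""
        vdot_di, vdot_ab = self.solve_rates(state, u)
        d = glottal_diameter(u.u_lm, self.free.D)
        closed = d < D_MIN_MM
        if closed:
            res = _kernels.mech_residuals(
                vdot_di, self._warm[2], True, state.V_di, state.V_ab,
                u.u_di, u.u_ab, d, *self.kernel_args())
        else:
            res = _kernels.mech_residuals(
                vdot_di, vdot_ab, False, state.V_di, state.V_ab,
                u.u_di, u.u_ab, d, *self.kernel_args())
        (_, _, vdot_l, ppl, sigma_l, sigma_di, sigma_ab, sigma_rc,
         pica, fa, v_l, v_rc) = res
        return MechEval(
            V_L=v_l, V_rc=v_rc, flow=-vdot_l, d=d, P_pl=ppl,
            P_alv=ppl + sigma_l, sigma_L=sigma_l, sigma_di=sigma_di,
            sigma_ab=sigma_ab, sigma_rc=sigma_rc, P_ica=pica,
            P_ab_pl=fa * sigma_di, f_a=fa, Vdot_di=vdot_di, Vdot_ab=vdot_ab)

    def step(self, state: MechState, u: MuscleActivations, dt: float,
             substep: float = 5e-4) -> tuple[MechState, MechEval]:
        """Advance the state by dt seconds (RK4 substeps of `substep` s)."""
        y = np.array([state.V_di, state.V_ab])
        nsub = max(1, int(round(dt / substep)))
        h = dt / nsub
        for _ in range(nsub):
            ok = _kernels.mech_rk4_step(y, u.u_di, u.u_ab, u.u_lm, h,
                                        *self.kernel_args(), self._warm)
            if not ok:
                raise RuntimeError("mechanics integration step failed to converge")
        new_state = MechState(V_di=y[0], V_ab=y[1])
        return new_state, self.evaluate(new_state, u)

    def percent_vc(self, V_L: float) -> float:
        """Lung volume in %VC relative to residual volume."""
        return 100.0 * (V_L - self.derived.V_L_RV) / self.free.VC

    def passive_equilibrium(self) -> MechState:
        """Static configuration with all muscles relaxed (zero rates).

        Found by solving the diaphragm balance for V_di at each abdominal
        volume (1-D inner root) and the rib-cage balance over V_ab (outer).
        """
        free, p = self.free, self.derived
        u = MuscleActivations()

        def inner(v_ab: float) -> float:
            def di_balance(v_di: float) -> float:
                st = MechState(v_di, v_ab)
                v_l = lung_volume(st, free, p)
                return (abdominal_recoil(0.0, v_ab, 0.0, free, p, self.geom)
                        + lung_recoil(v_l, free, p)
                        - diaphragm_recoil(0.0, v_di, 0.0, free, p))
            return brentq(di_balance, p.V_di_TLC + 0.05, p.V_di_RV + 1.5, xtol=1e-12)

        def outer(v_ab: float) -> float:
            v_di = inner(v_ab)
            st = MechState(v_di, v_ab)
            r_rc, _ = self.balance_residuals(st, (0.0, 0.0), u)
            return r_rc

        v_ab = brentq(outer, 1.0, p.V_ab_TLC, xtol=1e-12)
        return MechState(inner(v_ab), v_ab)


def scripted_activation_trial(model: MechanicsModel, waveform: np.ndarray,
                              dt: float = 5e-4,
                              state: MechState | None = None):
    """Run the isolated mechanics under piecewise-linear activation waveforms.

    waveform : array (n, 4) of rows (t_s, u_di, u_ab, u_lm); activations are
    linearly interpolated between rows.  Returns (t, traces) where traces is
    a dict of observable arrays sampled every dt.
    """
    if state is None:
        state = model.passive_equilibrium()
    t_end = waveform[-1, 0]
    n = int(round(t_end / dt))
    t = np.arange(n) * dt
    u_di = np.interp(t, waveform[:, 0], waveform[:, 1])
    u_ab = np.interp(t, waveform[:, 0], waveform[:, 2])
    u_lm = np.interp(t, waveform[:, 0], waveform[:, 3])
    keys = ("V_L", "flow", "P_alv", "P_pl", "sigma_di", "sigma_ab",
            "V_di", "V_ab", "Vdot_di", "Vdot_ab")
    out = {k: np.empty(n) for k in keys}
    for i in range(n):
        u = MuscleActivations(u_di[i], u_ab[i], u_lm[i])
        state, ev = model.step(state, u, dt, substep=dt)
        out["V_L"][i] = ev.V_L
        out["flow"][i] = ev.flow
        out["P_alv"][i] = ev.P_alv
        out["P_pl"][i] = ev.P_pl
        out["sigma_di"][i] = ev.sigma_di
        out["sigma_ab"][i] = ev.sigma_ab
        out["V_di"][i] = state.V_di
        out["V_ab"][i] = state.V_ab
        out["Vdot_di"][i] = ev.Vdot_di
        out["Vdot_ab"][i] = ev.Vdot_ab
    return t, out
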