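"""Mechanical parameters of the supine respiratory system.

The biomechanical model is parameterised by a set of *free* constants
measured in (or derived from) human subjects -- compliances, resistances,
reference volumes of the lung, rib cage, diaphragm and abdominal wall, and
Hill-muscle constants -- plus a larger set of *calculated* parameters that
follow from them.  Two of the calculated parameters are fixed by implicit
calibrations:

* the abdominal-wall volume at residual volume (``V_ab_RV``) is the volume
  at which the fully activated abdominal muscle, at zero rate, produces the
  residual-volume abdominal recoil pressure ``sigma_ab_RV``;
* the maximal active diaphragm pressure (``sigma_di_max``) is the value for
  which full diaphragm activation at TLC volume and zero rate reproduces the
  TLC transdiaphragmatic recoil ``sigma_di_TLC``.

Units used throughout the package: volumes in L, pressures in cmH2O,
flows in L/s, abdominal-wall geometry lengths in m (muscle length is
reported in cm), glottal diameters in mm.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "FreeParameters",
    "DerivedParameters",
    "AbdominalGeometry",
    "build_abdominal_geometry",
    "muscle_length_from_radius",
    "derive_parameters",
    "hill_force_velocity",
    "write_parameters",
    "read_free_parameters",
]

# Linear relation between the sagittal and transverse radii of curvature of
# the abdominal wall, fitted to insufflation measurements.
RS_SLOPE = 8.00479
RS_INTERCEPT = -1.10158


@dataclass(frozen=True)
class FreeParameters:
    """Free constants of the biomechanical model (defaults: supine adult male).

    Konno-Mead fractions (``V_*km_*``) express compartment displacements as
    fractions of vital capacity relative to residual volume.
    """

    C1: float = 0.369          # rib cage contribution to abdominal volume (-)
    C_ab: float = 0.108        # abdominal wall compliance (L/cmH2O)
    C_L: float = 0.201         # lung compliance (L/cmH2O)
    c_t: float = 0.32          # transverse chord of the abdominal wall (m)
    D: float = 18.0            # tracheal diameter (mm)
    fa_TLC: float = 0.15       # obligatory-ring fraction of the rib cage (-)
    F_CEmax: float = 33.0      # max force of abdominal contractile element (N)
    F_di: float = 0.15         # insertional fraction of diaphragm pressure (-)
    k: float = 0.68            # force -> surface tension conversion (m cmH2O/N)
    L_CE0: float = 19.1        # resting length of transversus abdominis (cm)
    P_icaab_TLC: float = -135.0  # max expiratory intercostal pressure at TLC
    R_ab: float = 1.5          # abdominal wall resistance (cmH2O/(L/s))
    R_di: float = 6.0          # diaphragm resistance (cmH2O/(L/s))
    R_rc: float = 2.7          # rib cage resistance (cmH2O/(L/s))
    V_c: float = 1.756         # mediastinum + lung tissue/blood volume (L)
    V_CEmax: float = 34.7      # max contractile velocity, abdominal muscle (cm/s)
    V_di_FRC: float = 2.967    # volume under the diaphragm at FRC (L)
    Vdot_di_max: float = 2.449  # max rate of change of diaphragm volume (L/s)
    V_L_FRC: float = 2.29      # lung volume at FRC (L)
    V_rckm_FRC: float = 0.1282  # Konno-Mead rib cage fraction at FRC (-)
    V_abkm_FRC: float = 0.0400  # Konno-Mead abdominal fraction at FRC (-)
    V_abkm_TLC: float = 0.3391  # Konno-Mead abdominal fraction at TLC (-)
    V_rckm_TLC: float = 0.6609  # Konno-Mead rib cage fraction at TLC (-)
    VC: float = 5.370          # vital capacity (L)
    sigma_di_RV: float = 20.0  # passive diaphragm recoil at RV (cmH2O)
    V_rc_FRC: float = 7.013    # rib cage volume at FRC (L)
    f_di: float = 0.65         # diaphragm length at TLC / length at RV (-)
    C_rc: float = 0.110        # rib cage compliance (L/cmH2O)

    def __post_init__(self) -> None:
        positive = (
            "C_ab C_L c_t D F_CEmax k L_CE0 R_ab R_di R_rc V_c V_CEmax "
            "V_di_FRC Vdot_di_max V_L_FRC VC sigma_di_RV V_rc_FRC C_rc"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f_di < 1:
            raise ValueError("f_di must lie in (0, 1)")
        if not 0 <= self.fa_TLC < 1:
            raise ValueError("fa_TLC must lie in [0, 1)")
        for name in ("V_rckm_FRC", "V_abkm_FRC", "V_rckm_TLC", "V_abkm_TLC"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.V_rckm_TLC <= self.V_rckm_FRC:
            raise ValueError("V_rckm_TLC must exceed V_rckm_FRC")
        if self.V_abkm_TLC <= self.V_abkm_FRC:
            raise ValueError("V_abkm_TLC must exceed V_abkm_FRC")


@dataclass(frozen=True)
class DerivedParameters:
    """Calculated mechanical parameters (units as in :class:`FreeParameters`)."""

    V_ab_RV: float
    V_L_RV: float
    sigma_L_RV: float
    sigma_ab_RV: float
    V_ab_FRC: float
    V_di_RV: float
    V_ab_TLC: float
    V_L_TLC: float
    sigma_L_TLC: float
    sigma_ab_TLC: float
    sigma_di_TLC: float
    sigma_rc_TLC: float
    sigma_rc_RV: float
    fa_RV: float
    V_sum: float
    V_ab0: float
    V_L0: float
    K_dipsv: float
    L_di_min: float
    P_icaab_RV: float
    P_icadi_TLC: float
    sigma_di_max: float
    sigma_rc_add: float
    sigma_rc_mul: float
    V_di0: float
    V_di_TLC: float
    V_rc_max: float
    V_rc_min: float
    V_rc_RV: float
    V_rc_TLC: float
    V_rc0: float


def muscle_length_from_radius(r_t: float, c_t: float) -> float:
    """Arc length (cm) of the transverse abdominal muscle band.

    The muscle follows a circular arc of radius ``r_t`` subtending the fixed
    transverse chord ``c_t`` (both in m): ``L = 100 r_t asin(c_t / 2 r_t)``.
    """
    if r_t < c_t / 2:
        raise ValueError("transverse radius smaller than half the chord")
    return 100.0 * r_t * math.asin(c_t / (2.0 * r_t))


def hill_force_velocity(rate_ratio: float) -> float:
    """Hill force-velocity factor; argument is shortening rate / max rate.

    Shortening (muscle doing work) is negative; the factor falls to ~0 at the
    maximal shortening rate and saturates at ~1.33 for lengthening.
    """
    return 0.1433 / (0.1074 + math.exp(-1.409 * math.sinh(3.2 * rate_ratio + 1.6)))


def _segment_area(r_t: float, h: float) -> float:
    """Area of a circular segment of radius r_t and sagitta h."""
    if h <= 0.0:
        return 0.0
    h = min(h, 2.0 * r_t)
    theta = math.acos(1.0 - h / r_t)
    return 0.5 * r_t * r_t * (2.0 * theta - math.sin(2.0 * theta))


def _volume_behind_wall(r_t: float, c_t: float, epsrel: float = 1e-8) -> float:
    """Volume (L) behind the abdominal wall at transverse radius r_t (m).

    The wall is a surface with circular-segment cross sections: radius
    ``r_t`` in every transverse plane and ``r_s`` (linearly related to
    ``r_t``) in every sagittal plane.  The volume between the wall and the
    bounding frontal plane is the integral of the transverse segment area
    over the craniocaudal extent of the sagittal chord.
    """
    r_s = RS_SLOPE * r_t + RS_INTERCEPT
    if r_s <= 0 or r_t < c_t / 2:
        raise ValueError("geometry infeasible at this radius")
    h0 = r_t - math.sqrt(r_t * r_t - (c_t / 2.0) ** 2)
    if h0 > 2.0 * r_s:
        raise ValueError("geometry infeasible at this radius")
    c_s = 2.0 * math.sqrt(r_s * r_s - (h0 - r_s) ** 2)
    flat = math.sqrt(r_s * r_s - (c_s / 2.0) ** 2)

    def area(y: float) -> float:
        h = math.sqrt(r_s * r_s - y * y) - flat
        return _segment_area(r_t, h)

    half = c_s / 2.0
    val, _ = quad(area, -half, half, epsrel=epsrel, limit=200)
    return val * 1000.0  # m^3 -> L


class AbdominalGeometry:
    """Tabulated map between abdominal-wall volume and its radii of curvature.

    The forward map ``V_ab(r_t)`` is evaluated by quadrature on a log-spaced
    radius grid at build time and approximated, together with its monotone
    inverse and the muscle length ``L_CE(V_ab)``, by monotone cubic (PCHIP)
    interpolants.  ``V_ab(r_t)`` is strictly decreasing: a flatter wall
    (larger radius) encloses less volume.  Non-positive volumes clamp the
    radius to ``0.5 c_t``, the fully bulged configuration.
    """

    def __init__(self, c_t: float, r_t_grid: np.ndarray, volumes: np.ndarray):
        self.c_t = float(c_t)
        order = np.argsort(volumes)
        self.r_t_grid = np.asarray(r_t_grid, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        v_sorted = self.volumes[order]
        r_sorted = self.r_t_grid[order]
        self._forward = PchipInterpolator(self.r_t_grid, self.volumes, extrapolate=False)
        self._inverse = PchipInterpolator(v_sorted, r_sorted, extrapolate=False)
        self.v_min = float(v_sorted[0])
        self.v_max = float(v_sorted[-1])
        self.r_min = float(self.r_t_grid[0])
        self.r_max = float(self.r_t_grid[-1])

    def volume_from_radius(self, r_t: float) -> float:
        r = min(max(r_t, self.r_min), self.r_max)
        return float(self._forward(r))

    def radius_from_volume(self, v_ab: float) -> float:
        if v_ab <= 0.0:
            return 0.5 * self.c_t
        v = min(max(v_ab, self.v_min), self.v_max)
        return float(self._inverse(v))

    def sagittal_radius(self, r_t: float) -> float:
        return RS_SLOPE * r_t + RS_INTERCEPT

    def muscle_length(self, v_ab: float) -> float:
        """Transversus abdominis length (cm) at abdominal volume v_ab (L)."""
        return muscle_length_from_radius(self.radius_from_volume(v_ab), self.c_t)

    def dmuscle_length_dv(self, v_ab: float, dv: float = 1e-4) -> float:
        """Centered-difference derivative dL_CE/dV_ab (cm/L)."""
        return (self.muscle_length(v_ab + dv) - self.muscle_length(v_ab - dv)) / (2.0 * dv)


def build_abdominal_geometry(
    c_t: float = FreeParameters.c_t,
    resolution: int = 500,
    r_t_max: float = 40.0,
) -> AbdominalGeometry:
    """Tabulate the abdominal-wall volume over a log-spaced radius grid."""
    if c_t <= 0:
        raise ValueError("c_t must be positive")
    if resolution < 100:
        raise ValueError("resolution must be at least 100")
    r_lo = max(c_t / 2.0, (1e-9 - RS_INTERCEPT) / RS_SLOPE)
    # log spacing in the offset from the fully bulged radius: the volume
    # varies steeply as r_t approaches c_t/2, gently at large radii
    grid = r_lo + np.geomspace(1e-4, r_t_max - r_lo, resolution)
    radii, volumes = [], []
    for r_t in grid:
        try:
            v = _volume_behind_wall(r_t, c_t)
        except ValueError:
            continue
        radii.append(r_t)
        volumes.append(v)
    return AbdominalGeometry(c_t, np.array(radii), np.array(volumes))


def _max_active_abdominal_pressure(v_ab: float, free: FreeParameters,
                                   geom: AbdominalGeometry) -> float:
    """Static abdominal muscle pressure at full activation, zero rate (cmH2O)."""
    r_t = geom.radius_from_volume(v_ab)
    r_s = geom.sagittal_radius(r_t)
    l_ce = muscle_length_from_radius(r_t, free.c_t)
    z = (l_ce / free.L_CE0 - 1.05) / 0.192
    ffl = math.exp(-0.5 * z * z)
    ffv0 = hill_force_velocity(0.0)
    return free.F_CEmax * ffl * ffv0 * (free.k / r_t + free.k / r_s)


def derive_parameters(
    free: FreeParameters,
    geom: AbdominalGeometry | None = None,
    tol: float = 1e-9,
) -> DerivedParameters:
    """Derive every calculated mechanical parameter from the free constants.

    Pure function of its inputs.  The residual-volume calibration of the
    abdominal wall is an implicit equation: because the zero-tension volume
    ``V_ab0`` is tied to ``V_ab_RV`` by a fixed Konno-Mead displacement, the
    passive term at RV is a constant and the calibration reduces to a 1-D
    root-find for ``V_ab_RV`` (solved to ``tol`` litres).
    """
    if geom is None:
        geom = build_abdominal_geometry(free.c_t)

    # Lung chain: zero-recoil lung volume equals the RV volume.
    V_L_RV = free.V_L_FRC - (free.V_rckm_FRC + free.V_abkm_FRC) * free.VC
    V_L0 = V_L_RV
    sigma_L_RV = (V_L_RV - V_L0) / free.C_L  # identically zero
    sigma_ab_RV = free.sigma_di_RV - sigma_L_RV

    # Abdominal-wall calibration at RV.  V_ab0 = V_ab_RV + dV with
    # dV = V_abkm_FRC * VC, so the passive recoil at RV is -dV/C_ab and the
    # active Hill term must make up the difference to sigma_ab_RV.
    dv_frc = free.V_abkm_FRC * free.VC
    target = sigma_ab_RV + dv_frc / free.C_ab

    def f(v: float) -> float:
        return _max_active_abdominal_pressure(v, free, geom) - target

    lo, hi = 1e-3, min(8.0, geom.v_max)
    if f(lo) * f(hi) > 0:
        raise RuntimeError(
            "abdominal RV calibration failed to bracket a root; "
            "free parameters are inconsistent with the wall geometry"
        )
    V_ab_RV = brentq(f, lo, hi, xtol=tol)
    V_ab0 = V_ab_RV + dv_frc
    V_ab_FRC = V_ab0

    # Rib cage chain.
    V_rc_RV = free.V_rc_FRC - free.V_rckm_FRC * free.VC / (1.0 + free.C1)
    V_rc_TLC = free.V_rc_FRC + (free.V_rckm_TLC - free.V_rckm_FRC) * free.VC / (1.0 + free.C1)
    V_rc_max = V_rc_TLC + 0.05 * (V_rc_TLC - V_rc_RV)
    V_rc_min = V_rc_RV - 0.99 * (V_rc_TLC - V_rc_RV)
    V_rc0 = free.V_rc_FRC
    # Sigmoid slope set so the mid-range compliance equals C_rc/(1+C1); the
    # offset zeroes the recoil at the resting volume V_rc0.  The recoil is
    # oriented to increase with volume (positive compliance).
    sigma_rc_mul = (V_rc_max - V_rc_min) * (1.0 + free.C1) / (4.0 * free.C_rc)
    sigma_rc_add = -sigma_rc_mul * math.log((V_rc0 - V_rc_min) / (V_rc_max - V_rc0))

    def sigma_rc_static(v_rc: float) -> float:
        return sigma_rc_mul * math.log((v_rc - V_rc_min) / (V_rc_max - v_rc)) + sigma_rc_add

    sigma_rc_TLC = sigma_rc_static(V_rc_TLC)
    sigma_rc_RV = sigma_rc_static(V_rc_RV)

    # Volume bookkeeping.
    V_sum = free.V_di_FRC + free.C1 * free.V_rc_FRC + V_ab_FRC
    V_di_RV = V_sum - V_ab_RV - free.C1 * V_rc_RV
    V_ab_TLC = V_ab_FRC + (free.V_abkm_TLC - free.V_abkm_FRC) * free.VC
    V_di_TLC = V_sum - V_ab_TLC - free.C1 * V_rc_TLC
    V_L_TLC = V_rc_TLC - V_di_TLC - free.V_c

    sigma_L_TLC = (V_L_TLC - V_L0) / free.C_L
    sigma_ab_TLC = (V_ab_TLC - V_ab0) / free.C_ab
    sigma_di_TLC = sigma_L_TLC - sigma_ab_TLC

    # Diaphragm chain.
    V_di0 = V_di_RV
    K_dipsv = free.sigma_di_RV / (V_di_RV - free.V_di_FRC) ** 2
    L_di_min = ((V_di_TLC - free.f_di * V_di_RV) / (V_di_TLC - V_di_RV)) / 1.05
    # Full-activation calibration at TLC: the passive quadratic term vanishes
    # below the FRC volume, so sigma_di_max follows in closed form.
    ratio_tlc = (1.0 - L_di_min) * V_di_TLC / V_di0 + L_di_min
    ffl_tlc = math.exp(-0.5 * ((ratio_tlc - 1.05) / 0.192) ** 2)
    sigma_di_max = sigma_di_TLC / (ffl_tlc * hill_force_velocity(0.0))

    # Intercostal/accessory muscle calibrations.
    fa_RV = (1.0 / (1.0 + free.C1)) * (V_di_RV - V_di_TLC) / (
        (V_di_RV - V_di_TLC) + V_L_RV
    ) + free.fa_TLC
    P_icaab_RV = sigma_L_RV + sigma_rc_RV - (fa_RV + free.F_di) * free.sigma_di_RV
    P_icadi_TLC = sigma_L_TLC + sigma_rc_TLC - (free.fa_TLC + free.F_di) * sigma_di_TLC

    return DerivedParameters(
        V_ab_RV=V_ab_RV, V_L_RV=V_L_RV, sigma_L_RV=sigma_L_RV,
        sigma_ab_RV=sigma_ab_RV, V_ab_FRC=V_ab_FRC, V_di_RV=V_di_RV,
        V_ab_TLC=V_ab_TLC, V_L_TLC=V_L_TLC, sigma_L_TLC=sigma_L_TLC,
        sigma_ab_TLC=sigma_ab_TLC, sigma_di_TLC=sigma_di_TLC,
        sigma_rc_TLC=sigma_rc_TLC, sigma_rc_RV=sigma_rc_RV, fa_RV=fa_RV,
        V_sum=V_sum, V_ab0=V_ab0, V_L0=V_L0, K_dipsv=K_dipsv,
        L_di_min=L_di_min, P_icaab_RV=P_icaab_RV, P_icadi_TLC=P_icadi_TLC,
        sigma_di_max=sigma_di_max, sigma_rc_add=sigma_rc_add,
        sigma_rc_mul=sigma_rc_mul, V_di0=V_di0, V_di_TLC=V_di_TLC,
        V_rc_max=V_rc_max, V_rc_min=V_rc_min, V_rc_RV=V_rc_RV,
        V_rc_TLC=V_rc_TLC, V_rc0=V_rc0,
    )


_UNITS = {
    "C1": "-", "C_ab": "L/cmH2O", "C_L": "L/cmH2O", "c_t": "m", "D": "mm",
    "fa_TLC": "-", "F_CEmax": "N", "F_di": "-", "k": "m cmH2O/N",
    "L_CE0": "cm", "P_icaab_TLC": "cmH2O", "R_ab": "cmH2O/(L/s)",
    "R_di": "cmH2O/(L/s)", "R_rc": "cmH2O/(L/s)", "V_c": "L",
    "V_CEmax": "cm/s", "V_di_FRC": "L", "Vdot_di_max": "L/s", "V_L_FRC": "L",
    "V_rckm_FRC": "-", "V_abkm_FRC": "-", "V_abkm_TLC": "-", "V_rckm_TLC": "-",
    "VC": "L", "sigma_di_RV": "cmH2O", "V_rc_FRC": "L", "f_di": "-",
    "C_rc": "L/cmH2O",
}


def write_parameters(params, path: str | Path) -> None:
    """Write free or derived parameters as tab-delimited (name, value, units)."""
    lines = ["name\tvalue\tunits"]
    for field in dataclasses.fields(params):
        unit = _UNITS.get(field.name, "")
        lines.append(f"{field.name}\t{getattr(params, field.name)!r}\t{unit}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_free_parameters(path: str | Path) -> FreeParameters:
    """Read a (name, value, units) table written by :func:`write_parameters`."""
    values = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, value = line.split("\t")[:2]
        values[name] = float(value)
    return FreeParameters(**values)
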