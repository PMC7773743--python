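"""Physical calibrations linking biosensor signal, surface densities and
dissociation constants.

A resonant waveguide grating (RWG) biosensor reports cell adhesion as a
resonant-wavelength shift in picometres.  The shift is proportional to the
surface density of integrin--RGD complexes inside the evanescent field, so a
single conversion factor ``alpha`` (molecules/µm² per pm) turns kinetic
traces into surface concentrations.  Membrane-confined ("2D") dissociation
constants carry units of µm⁻²; dividing by the cell--substrate separation
distance ``d_c`` converts them to ordinary molar constants comparable with
solution-phase measurements.

The module also computes the RGD ligand density of PLL-g-PEG / PLL-g-PEG-RGD
copolymer coatings from the mixing recipe, and the Smoluchowski zeta
potential from electrophoretic mobility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "VACUUM_PERMITTIVITY",
    "SignalCalibration",
    "CoatingSpec",
    "SurfaceDensityResult",
    "ZetaInput",
    "pm_to_density",
    "density_to_pm",
    "kd2d_to_kd3d",
    "rgd_surface_density",
    "rgd_spacing",
    "zeta_from_mobility",
    "coating_table",
]

#: Avogadro constant (exact, 2019 SI), mol^-1.
AVOGADRO = 6.02214076e23

#: Vacuum permittivity, F/m.
VACUUM_PERMITTIVITY = 8.8541878128e-12


@dataclass(frozen=True)
class SignalCalibration:
    """Conversion between wavelength shift and bound-receptor density.

    Parameters
    ----------
    alpha : float
        Bound-complex surface density per unit wavelength shift,
        molecules/µm² per pm.  The default 1/200 means 1 pm of shift
        corresponds to 1/200 integrin--ligand complexes per µm²
        (1200 pm at saturation ≙ 6 µm⁻²).
    d_c : float
        Average cell--substrate separation distance in nm; thickness of
        the confinement zone used to convert areal to molar dissociation
        constants.  Literature values span roughly 40--160 nm; default 100.
    """

    alpha: float = 1.0 / 200.0
    d_c: float = 100.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.d_c > 0):
            raise ValueError(f"d_c must be positive, got {self.d_c}")


@dataclass(frozen=True)
class CoatingSpec:
    """Recipe of a mixed PLL-g-PEG : PLL-g-PEG-RGD copolymer coating.

    ``Q`` is the volume percentage of the RGD-functionalized copolymer
    (PPR) solution in the coating mixture; 100 means pure PPR.  The
    remaining fields are polymer constants: adsorbed areal mass ``Gamma``
    (ng/cm²), PPR molecular weight ``M_PPR`` (kDa), mean number of lysine
    monomers per PLL backbone ``N_Lys``, grafting ratio ``g`` (lysine
    units per PEG side chain) and the percentage ``P`` of PEG chains
    carrying an RGD motif.
    """

    Q: float
    Gamma: float = 97.0
    M_PPR: float = 107.76
    N_Lys: float = 136.82
    g: float = 3.5
    P: float = 14.7

    def __post_init__(self) -> None:
        if not (0.0 <= self.Q <= 100.0):
            raise ValueError(f"Q must be within [0, 100] %, got {self.Q}")
        for name in ("Gamma", "M_PPR", "N_Lys", "g", "P"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class SurfaceDensityResult:
    """RGD ligand density of a coating in the two conventional units,
    plus the mean nearest-neighbour RGD--RGD spacing.

    ``d_rgd`` is infinite for a ligand-free surface (Q = 0).
    """

    L0_pmol_cm2: float
    L0_per_um2: float
    d_rgd: float


@dataclass(frozen=True)
class ZetaInput:
    """Electrophoretic mobility measurement and medium properties.

    mobility : µm·cm/(V·s);  eta : viscosity, mPa·s;
    eps_r : relative permittivity (dimensionless, SI convention).
    """

    mobility: float
    eta: float = 0.89
    eps_r: float = 78.5

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise ValueError(f"viscosity must be positive, got {self.eta}")
        if not (self.eps_r > 0):
            raise ValueError(f"permittivity must be positive, got {self.eps_r}")


def pm_to_density(dlambda, cal: SignalCalibration = SignalCalibration()):
    """Convert a wavelength shift (pm) to bound-complex density (µm⁻²).

    Scalar or array input; exact inverse of :func:`density_to_pm`.
    """
    dlambda = np.asarray(dlambda, dtype=float)
    if not np.all(np.isfinite(dlambda)):
        raise ValueError("wavelength shift must be finite")
    out = dlambda * cal.alpha
    return float(out) if out.ndim == 0 else out


def density_to_pm(density, cal: SignalCalibration = SignalCalibration()):
    """Convert a bound-complex density (µm⁻²) to wavelength shift (pm)."""
    density = np.asarray(density, dtype=float)
    if not np.all(np.isfinite(density)):
        raise ValueError("density must be finite")
    out = density / cal.alpha
    return float(out) if out.ndim == 0 else out


def kd2d_to_kd3d(kd2d: float, d_c: float = 100.0) -> float:
    """Convert an areal dissociation constant to a molar one.

    The 2D constant (µm⁻²) is divided by the confinement-zone thickness
    ``d_c`` (nm) to give a volumetric number density, which Avogadro's
    number turns into a molar concentration, returned in µM.

    Examples
    --------
    >>> round(kd2d_to_kd3d(4708.0, 100.0), 2)
    78.18
    """
    if kd2d < 0:
        raise ValueError(f"kd2d must be non-negative, got {kd2d}")
    if not (d_c > 0):
        raise ValueError(f"d_c must be positive, got {d_c}")
    d_c_um = d_c * 1e-3
    number_density_per_um3 = kd2d / d_c_um
    # 1 litre = 1e15 µm³
    molar = number_density_per_um3 * 1e15 / AVOGADRO
    return molar * 1e6  # mol/L -> µmol/L


def _l0_pmol_cm2(spec: CoatingSpec) -> float:
    # Gamma [ng/cm2] / M [kDa = 1e3 g/mol]: ng/(g/mol)/cm2 = 1e-9 mol/cm2 per unit
    # -> Gamma/M in units of 1e-12 mol/cm2 = pmol/cm2 directly (ng/kDa = pmol).
    return (
        (spec.Gamma / spec.M_PPR)
        * (spec.Q / 100.0)
        * (spec.N_Lys / spec.g)
        * (spec.P / 100.0)
    )


def rgd_surface_density(spec: CoatingSpec) -> SurfaceDensityResult:
    """RGD ligand surface density of a mixed-copolymer coating.

    L0 [pmol/cm²] = (Γ/M_PPR) · (Q/100) · (N_Lys/g) · (P/100), with Γ in
    ng/cm² and M_PPR in kDa (ng/kDa = pmol, so the units collapse
    directly to pmol/cm²).  The molecules/µm² value follows via
    Avogadro's number; the spacing via :func:`rgd_spacing`.
    """
    l0_pmol = _l0_pmol_cm2(spec)
    # pmol/cm2 -> mol/cm2 -> molecules/cm2 -> molecules/um2 (1 cm2 = 1e8 um2)
    l0_per_um2 = l0_pmol * 1e-12 * AVOGADRO / 1e8
    return SurfaceDensityResult(
        L0_pmol_cm2=l0_pmol,
        L0_per_um2=l0_per_um2,
        d_rgd=rgd_spacing(l0_per_um2),
    )


def rgd_spacing(L0: float) -> float:
    """Mean nearest-neighbour spacing (nm) of ligands at density ``L0`` (µm⁻²).

    Assumes hexagonal close packing, where each molecule occupies an area
    (√3/2)·d², i.e. d = sqrt(2 / (√3·L0)).  Returns ``inf`` for an empty
    surface.
    """
    if L0 < 0:
        raise ValueError(f"density must be non-negative, got {L0}")
    if L0 == 0:
        return math.inf
    l0_per_nm2 = L0 * 1e-6
    return math.sqrt(2.0 / (math.sqrt(3.0) * l0_per_nm2))


def zeta_from_mobility(z: ZetaInput) -> float:
    """Zeta potential (mV) from electrophoretic mobility, Smoluchowski limit.

    SI form ζ = µη/(ε0·εr).  (The equivalent Gaussian-units form carries a
    4π/ε factor; only the unit convention differs.)  Mobility in
    µm·cm/(V·s), viscosity in mPa·s.
    """
    mobility_si = z.mobility * 1e-6 * 1e-2  # µm·cm/(V·s) -> m²/(V·s)
    eta_si = z.eta * 1e-3  # mPa·s -> Pa·s
    zeta_volts = mobility_si * eta_si / (VACUUM_PERMITTIVITY * z.eps_r)
    return zeta_volts * 1e3  # V -> mV


def coating_table(
    q_values,
    base: CoatingSpec | None = None,
) -> pd.DataFrame:
    """Ligand density table over a grid of mixing ratios Q.

    Returns a DataFrame with columns ``Q``, ``L0_pmol_cm2``, ``d_rgd_nm``
    and ``L0_per_um2`` — one row per Q, suitable for writing as
    delimited text.
    """
    rows = []
    for q in q_values:
        spec = (
            CoatingSpec(Q=float(q))
            if base is None
            else replace(base, Q=float(q))
        )
        res = rgd_surface_density(spec)
        rows.append(
            {
                "Q": float(q),
                "L0_pmol_cm2": res.L0_pmol_cm2,
                "d_rgd_nm": res.d_rgd,
                "L0_per_um2": res.L0_per_um2,
            }
        )
    return pd.DataFrame(rows)
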