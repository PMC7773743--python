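"""Static (equilibrium) receptor--ligand isotherm on RGD-density-tuned surfaces.

At saturation, monovalent integrin--RGD binding in the contact zone obeys a
hyperbolic (Langmuir-type) isotherm in the ligand surface density L0:

    B_eq = L0·I0 / (L0 + K_d^2D),

valid when L0 greatly exceeds B_eq.  Because the biosensor's saturation
signal Δλ_max is proportional to B_eq, fitting Δλ_max against L0 across a
grid of coating compositions yields the static 2D dissociation constant
and, through the confinement-distance conversion, its molar equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .calibration import SignalCalibration, kd2d_to_kd3d

__all__ = ["SaturationDataset", "StaticFit", "isotherm", "fit_isotherm"]


@dataclass(frozen=True)
class SaturationDataset:
    """Saturation signals measured across RGD ligand densities.

    ``L0`` in molecules/µm² (typically from the coating-density grid),
    ``dlambda_max`` in pm, optional per-point replicate SDs in pm.
    """

    L0: np.ndarray
    dlambda_max: np.ndarray
    sd: np.ndarray | None = None
    enzyme_conc: float = 0.0

    def __post_init__(self) -> None:
        L0 = np.asarray(self.L0, dtype=float)
        y = np.asarray(self.dlambda_max, dtype=float)
        object.__setattr__(self, "L0", L0)
        object.__setattr__(self, "dlambda_max", y)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if L0.ndim != 1 or len(L0) != len(y):
            raise ValueError("L0 and dlambda_max must be 1-D, equal length")
        if np.any(L0 < 0):
            raise ValueError("ligand densities must be >= 0")
        pos = L0[L0 > 0]
        if len(np.unique(pos)) < 4:
            raise ValueError("need at least 4 distinct nonzero ligand densities")
        if pos.max() / pos.min() < 10.0:
            raise ValueError(
                "ligand densities must span at least one order of magnitude"
            )


@dataclass(frozen=True)
class StaticFit:
    """Fitted isotherm: amplitude (pm, ∝ total integrin density I0),
    the static 2D and 3D dissociation constants, and standard errors."""

    kd2d_static: float
    amplitude: float
    I0: float
    kd3d_static: float
    kd2d_stderr: float | None
    amplitude_stderr: float | None
    r_squared: float
    warnings: tuple = field(default_factory=tuple)


def isotherm(L0, I0: float, kd2d: float):
    """Equilibrium bound density B_eq = L0·I0/(L0 + K_d^2D).

    Increasing and saturating in L0: half of I0 is bound when
    L0 = K_d^2D, and B_eq → I0 as L0 → ∞.
    """
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 < 0) or I0 < 0 or kd2d < 0:
        raise ValueError("L0, I0 and kd2d must be >= 0")
    if kd2d == 0 and np.any(L0 == 0):
        raise ValueError("L0 and kd2d cannot both be zero")
    out = L0 * I0 / (L0 + kd2d)
    return float(out) if out.ndim == 0 else out


def _signal_model(L0, amplitude, kd2d):
    return amplitude * L0 / (L0 + kd2d)


def fit_isotherm(
    data: SaturationDataset,
    cal: SignalCalibration = SignalCalibration(),
) -> StaticFit:
    """Fit Δλ_max = A·L0/(L0 + K_d^2D) to a saturation dataset.

    Two free parameters: the amplitude A (pm, the asymptotic signal,
    proportional to the total integrin density I0) and the static 2D
    dissociation constant.  Weighted least squares when replicate SDs
    are supplied, unweighted otherwise.  I0 (µm⁻²) and the molar
    constant are derived afterwards from the calibration, keeping the
    fit itself calibration-free.

    The isotherm presumes ligand excess; the fit warns when
    min(L0)/B_eq(min L0) < 10.
    """
    L0, y = data.L0, data.dlambda_max
    if float(np.ptp(y)) == 0.0:
        raise ValueError("all saturation signals are equal; nothing to fit")

    ymax = float(np.max(y))
    m = lmfit.Model(_signal_model, independent_vars=["L0"])
    kd_hi = 1e4 * float(np.max(L0))
    params = m.make_params(
        amplitude=dict(value=ymax, min=1e-6, max=100.0 * ymax),
        kd2d=dict(value=float(np.median(L0)), min=1e-9, max=kd_hi),
    )
    weights = None
    if data.sd is not None and np.all(data.sd > 0):
        weights = 1.0 / data.sd
    result = m.fit(y, params, L0=L0, weights=weights)

    amplitude = float(result.params["amplitude"].value)
    kd2d = float(result.params["kd2d"].value)
    warnings = []
    if kd2d >= 0.99 * kd_hi or amplitude >= 99.0 * ymax:
        warnings.append("fit pinned at parameter bound; estimates unreliable")

    i0 = amplitude * cal.alpha
    pos = L0[L0 > 0]
    b_eq_min = isotherm(float(pos.min()), i0, kd2d)
    if b_eq_min > 0 and float(pos.min()) / b_eq_min < 10.0:
        warnings.append(
            "ligand-excess condition L0 >> B_eq violated at the lowest "
            "density; isotherm approximation may bias K_d"
        )

    ss_res = float(np.sum((y - result.best_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return StaticFit(
        kd2d_static=kd2d,
        amplitude=amplitude,
        I0=i0,
        kd3d_static=kd2d_to_kd3d(kd2d, cal.d_c),
        kd2d_stderr=(
            float(result.params["kd2d"].stderr)
            if result.params["kd2d"].stderr is not None
            else None
        ),
        amplitude_stderr=(
            float(result.params["amplitude"].stderr)
            if result.params["amplitude"].stderr is not None
            else None
        ),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        warnings=tuple(warnings),
    )
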