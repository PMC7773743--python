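"""Synthetic biosensor datasets with the structure the analysis assumes.

The generator emulates a resonant-waveguide-grating adhesion experiment:
HeLa-like cells settling on RGD-displaying surfaces while their
glycocalyx is digested by chondroitinase ABC (ChrABC) at a range of
doses.  Each dose maps to a set of three-state-model parameters whose
dose dependence mirrors the experimentally observed signature:

* k2 (integrin--RGD off-rate) is unaffected by digestion;
* k3 (recruitment rate) decreases monotonically with dose;
* k1 (on-rate) is elevated above baseline at the two mildest doses,
  then falls below it, so the kinetic K_d^2D rises from ~600 µm⁻²
  at baseline to ~1700 µm⁻² at the highest dose;
* I_max (free-integrin ceiling) is flat at 0.3 µm⁻² up to ~0.01 U/ml
  and about twice that above ~0.1 U/ml.

Traces are the noiseless model signal plus additive i.i.d. Gaussian
measurement noise, sampled at the instrument's 3 s resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import SignalCalibration, rgd_surface_density
from .calibration import CoatingSpec
from .kinetic_model import AdhesionKineticParams, InitialState, simulate, predict_signal
from .logistic import KineticTrace
from .static_model import SaturationDataset, isotherm

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "EnzymeParamProfile",
    "NoiseSpec",
    "default_profile",
    "generate_kinetic_dataset",
    "generate_saturation_dataset",
]

#: ChrABC dose grid of the emulated experiment: an untreated control plus a
#: 2x/5x-alternating dilution series from 6.25e-5 to 1.25 U/ml (11 doses).
DEFAULT_CONCENTRATIONS = (
    0.0,
    6.25e-5,
    1.25e-4,
    6.25e-4,
    1.25e-3,
    6.25e-3,
    1.25e-2,
    6.25e-2,
    0.125,
    0.625,
    1.25,
)

# baseline (untreated) model parameters
_K2_BASE = 0.1  # 1/min
_KD_BASE = 600.0  # µm⁻², k2/k1 at dose 0
_KD_TOP = 1700.0  # µm⁻² at the highest dose
_IMAX_BASE = 0.3  # µm⁻²
_K3_BASE = 0.7  # µm²/min; gives a ~30 min half-rise at baseline


def _smootherstep(x: float) -> float:
    x = min(max(x, 0.0), 1.0)
    return x * x * (3.0 - 2.0 * x)


def _k1_shape(log_c: float) -> float:
    """Dose response of k1 relative to baseline (dose on log10 scale)."""
    bump = 1.0 + 0.3 * np.exp(-0.5 * ((log_c + 4.0) / 0.22) ** 2)
    span = np.log10(1.25) + 3.3
    decline = 1.0 - (1.0 - _KD_BASE / _KD_TOP) * _smootherstep((log_c + 3.3) / span)
    return float(bump * decline)


def params_at_concentration(c: float) -> AdhesionKineticParams:
    """Three-state-model parameters at ChrABC dose ``c`` (U/ml)."""
    if c < 0:
        raise ValueError(f"enzyme concentration must be >= 0, got {c}")
    if c == 0:
        return AdhesionKineticParams(
            k1=_K2_BASE / _KD_BASE, k2=_K2_BASE, k3=_K3_BASE, I_max=_IMAX_BASE
        )
    log_c = float(np.log10(c))
    k1 = (_K2_BASE / _KD_BASE) * _k1_shape(log_c)
    k3 = _K3_BASE * (1.0 - 0.75 * _smootherstep((log_c + 4.5) / (np.log10(1.25) + 4.5)))
    i_max = _IMAX_BASE * (1.0 + _smootherstep((log_c + 2.0) / 1.0))
    return AdhesionKineticParams(k1=k1, k2=_K2_BASE, k3=k3, I_max=i_max)


@dataclass(frozen=True)
class EnzymeParamProfile:
    """Mapping from enzyme dose (U/ml) to true model parameters."""

    concentrations: tuple
    params: dict

    def params_at(self, c: float) -> AdhesionKineticParams:
        return self.params[float(c)]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise and sampling description of a synthetic plate.

    ``sigma`` is the SD of additive Gaussian noise on Δλ in pm,
    ``sampling_dt`` the sampling interval in seconds (the instrument's
    time resolution is 3 s).
    """

    sigma: float = 10.0
    n_replicates: int = 3
    sampling_dt: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (self.sampling_dt > 0):
            raise ValueError("sampling_dt must be positive")


def default_profile(c_grid=DEFAULT_CONCENTRATIONS) -> EnzymeParamProfile:
    """Dose-response profile of the emulated digestion experiment.

    Anchored at the untreated baseline (K_d^2D = 600 µm⁻², I_max = 0.3
    µm⁻²) and interpolated smoothly on the log-dose axis so that the four
    qualitative signatures in the module docstring hold on any grid.
    """
    c_grid = tuple(float(c) for c in c_grid)
    if any(c < 0 for c in c_grid):
        raise ValueError("concentrations must be >= 0")
    if 0.0 not in c_grid:
        raise ValueError("the dose grid must include the untreated control 0")
    return EnzymeParamProfile(
        concentrations=c_grid,
        params={c: params_at_concentration(c) for c in c_grid},
    )


def generate_kinetic_dataset(
    profile: EnzymeParamProfile,
    init: InitialState = InitialState(),
    cal: SignalCalibration = SignalCalibration(),
    noise: NoiseSpec = NoiseSpec(),
    duration: float = 100.0,
) -> list[KineticTrace]:
    """Simulate noisy replicate adhesion traces for every dose.

    Each trace is the model signal B(t)/alpha plus i.i.d. Gaussian noise,
    sampled every ``noise.sampling_dt`` seconds over ``duration`` minutes
    and clipped at zero (the reference-subtracted signal cannot be
    meaningfully negative at the plotted scale).  Fully deterministic
    given ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    dt_min = noise.sampling_dt / 60.0
    t = np.arange(0.0, duration + 0.5 * dt_min, dt_min)
    traces: list[KineticTrace] = []
    for c in profile.concentrations:
        params = profile.params_at(c)
        clean = predict_signal(simulate(params, init, t), cal)
        for rep in range(noise.n_replicates):
            y = clean + rng.normal(0.0, noise.sigma, size=len(t)) if noise.sigma > 0 else clean.copy()
            traces.append(
                KineticTrace(
                    t=t,
                    dlambda=np.maximum(y, 0.0),
                    enzyme_conc=c,
                    replicate_id=f"r{rep + 1}",
                    Q=50.0,
                )
            )
    return traces


def generate_saturation_dataset(
    kd2d: float,
    amplitude: float,
    q_grid=None,
    noise: NoiseSpec = NoiseSpec(),
    coating: CoatingSpec | None = None,
    enzyme_conc: float = 0.0,
) -> SaturationDataset:
    """Saturation signal vs RGD density over a coating-composition grid.

    Ligand densities come from the copolymer recipe via
    :func:`rwgkinetics.calibration.rgd_surface_density`; the clean signal
    is the binding isotherm amplitude·L0/(L0 + kd2d).  Per density,
    ``noise.n_replicates`` noisy readings are generated and summarized
    as mean ± SD.
    """
    if q_grid is None:
        q_grid = (0, 1, 10, 25, 38, 50, 58, 66, 75, 80, 85, 90, 95, 100)
    rng = np.random.default_rng(noise.seed)
    from dataclasses import replace

    l0 = []
    for q in q_grid:
        spec = CoatingSpec(Q=float(q)) if coating is None else replace(coating, Q=float(q))
        l0.append(rgd_surface_density(spec).L0_per_um2)
    l0 = np.array(l0)
    clean = isotherm(l0, amplitude, kd2d)
    reps = clean[:, None] + rng.normal(0.0, noise.sigma, size=(len(l0), noise.n_replicates))
    if noise.sigma == 0:
        reps = np.repeat(clean[:, None], noise.n_replicates, axis=1)
    return SaturationDataset(
        L0=l0,
        dlambda_max=reps.mean(axis=1),
        sd=reps.std(axis=1, ddof=1) if noise.n_replicates > 1 else None,
        enzyme_conc=enzyme_conc,
    )
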