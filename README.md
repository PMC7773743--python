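# rwgkinetics

Quantitative analysis of label-free cell-adhesion kinetics measured on
resonant waveguide grating (RWG) biosensors, built around the question of
how enzymatic digestion of the cancer-cell glycocalyx regulates
integrin–RGD adhesion.

An RWG plate reader reports cell adhesion as a resonant-wavelength shift
Δλ(t) (pm) proportional to the surface density of integrin–ligand
complexes in the ~100 nm evanescent zone above the sensor. This package
turns such sigmoidal adhesion curves — and saturation signals measured on
surfaces with tuned RGD ligand density — into receptor-level rate and
equilibrium constants. It is aimed at biophysicists and biosensor users
who want receptor–ligand kinetics from live, label-free cell adhesion
rather than from isolated proteins.

## Models

**Logistic adhesion kinetics.** Each adhesion curve is summarized by the
logistic growth ODE

    dΔλ/dt = r·Δλ·(1 − Δλ/Δλ_max),

giving the saturation signal Δλ_max (pm) and adhesion rate constant r
(min⁻¹) per well and time window (a 4-parameter logistic variant is also
available).

**Three-state adhesion-zone model.** Surface densities (µm⁻²) of free
ligand L, free integrin I and bound complex B in the contact zone obey

    dB/dt =  k₁LI − k₂B
    dL/dt = −k₁LI + k₂B
    dI/dt = −k₁LI + k₂B + k₃B(I_max − I)

with association/dissociation rates k₁, k₂, a recruitment rate k₃ and a
free-integrin ceiling I_max. Fitting Δλ(t) = B(t)/α (α = 1/200 µm⁻² per
pm) to replicate traces yields the kinetic 2D dissociation constant
²ᴰK_d = k₂/k₁, the saturation density B_max = (L₀+B₀)I_max/(²ᴰK_d+I_max),
and — dividing by the cell–substrate separation d_c ≈ 100 nm — the molar
constant K_d = ²ᴰK_d/d_c.

**Static isotherm.** On surfaces with RGD density L₀ set by the
PLL-g-PEG : PLL-g-PEG-RGD mixing ratio Q (L₀ = (Γ/M)·(Q/100)·(N_Lys/g)·(P/100)),
the saturation signal follows the monovalent isotherm
Δλ_max = A·L₀/(L₀ + ²ᴰK_d), giving an independent "static" dissociation
constant.

A synthetic-data module generates triplicate noisy plates whose
parameters vary with enzyme (chondroitinase ABC) dose the way digestion
experiments show: constant k₂, monotonically falling k₃, a mild-dose k₁
bump, and a doubling of I_max at strong digestion.

## Worked example

```python
import numpy as np
from rwgkinetics import *

# 1. RGD density of a 50% mixed coating
res = rgd_surface_density(CoatingSpec(Q=50))
print(f"L0 = {res.L0_pmol_cm2:.2f} pmol/cm2 = {res.L0_per_um2:.0f} um^-2, "
      f"spacing {res.d_rgd:.2f} nm")

# 2. simulate a noisy triplicate at the untreated baseline and refit it
true = AdhesionKineticParams(k1=0.1/600, k2=0.1, k3=0.7, I_max=0.3)
init, cal = InitialState(), SignalCalibration()
t = np.arange(0, 100.05, 0.5)
clean = predict_signal(simulate(true, init, t), cal)
rng = np.random.default_rng(0)
traces = [KineticTrace(t=t, dlambda=np.maximum(clean + rng.normal(0, 15, len(t)), 0),
                       replicate_id=f"r{i}") for i in range(3)]
fit = fit_kinetics(traces, init, cal, n_starts=4)
dq = derived_quantities(fit.params, init, cal)
print(f"kd2d = {dq.kd2d_kinetic:.0f} um^-2, kd3d = {dq.kd3d_kinetic:.1f} uM, "
      f"B_max = {dq.B_max:.2f} um^-2, R2 = {fit.r_squared:.4f}")
```

prints

```
L0 = 2.59 pmol/cm2 = 15575 um^-2, spacing 8.61 nm
kd2d = 557 um^-2, kd3d = 9.3 uM, B_max = 7.50 um^-2, R2 = 0.9992
```

i.e. the 50% coating carries 2.59 pmol/cm² of RGD (8.6 nm spacing), and
the refit recovers the generating saturation density (7.50 µm⁻² ≙
~1500 pm) exactly and the dissociation constant (true 600 µm⁻² ≙
9.96 µM) to within the ~±50% identifiability width that K_d inherits
from the weakly determined k₁ (see `docs/methods.md`).

The same analyses are scriptable from the shell:

```
rwgkinetics simulate --out-dir plate/
rwgkinetics fit-kinetic plate/traces.csv --out plate/kinetic_fits.csv
rwgkinetics fit-static plate/saturation.csv --out plate/static_fit.json
rwgkinetics coating-table --out plate/coating_table.csv
rwgkinetics full --out-dir plate/   # everything, reproducibly
```

## Layout

- `rwgkinetics.calibration` — pm ↔ µm⁻² signal conversion, 2D→3D K_d,
  coating densities/spacings, Smoluchowski zeta potential
- `rwgkinetics.logistic` — logistic/4PL fits of adhesion curves
- `rwgkinetics.kinetic_model` — three-state ODE model: simulation,
  closed-form equilibria, fitting, identifiability diagnostics
- `rwgkinetics.static_model` — saturation-vs-density isotherm fits
- `rwgkinetics.synthetic` — dose-dependent synthetic plate generator
- `rwgkinetics.io`, `rwgkinetics.cli`, `rwgkinetics.plots` — CSV dialects,
  command line, optional figures

See `docs/methods.md` for model assumptions, parameter defaults and
numerical choices.
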