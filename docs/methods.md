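# Methods

## Signal calibration

RWG biosensors sense refractive-index changes within ~150 nm of the
surface; for adherent cells the wavelength shift is taken proportional to
the surface density of integrin–ligand complexes B in the adhesion zone.
The default factor α = 1/200 µm⁻² per pm comes from the estimate that a
saturation shift of 1200 pm corresponds to ~6000 bound integrins on a
~1000 µm² cell footprint, i.e. 6 µm⁻². Both α and the cell–substrate
separation d_c are fields of `SignalCalibration`; d_c defaults to 100 nm,
the middle of the 40–160 nm range reported by surface-sensitive
microscopies, and conversions are linear in both, so any recalibration
rescales results without refitting.

Areal ("2D") dissociation constants (µm⁻²) are converted to molar ones by
treating the contact zone as a slab of thickness d_c: K_d[M] =
(K_d²ᴰ/d_c)/N_A with N_A fixed at 6.02214076×10²³ mol⁻¹. All unit
handling lives in `calibration`.

## Coating densities and ligand spacing

For mixed PLL-g-PEG / PLL-g-PEG-RGD coatings the RGD surface density is
L₀ = (Γ/M_PPR)(Q/100)(N_Lys/g)(P/100), with defaults Γ = 97 ng/cm²,
M_PPR = 107.76 kDa, N_Lys = 136.82, g = 3.5, P = 14.7%. Since ng/kDa =
pmol, the expression evaluates directly in pmol/cm². The mean
nearest-neighbour spacing assumes hexagonal packing (area per molecule
(√3/2)d², so d = √(2/(√3 L₀))); this convention reproduces published
spacing tables for these coatings to ≤0.3%, where a square-lattice
convention deviates by >5%. The molecules/µm² column of such tables is
derived from the pmol/cm² column via N_A; where a published table is
internally inconsistent between the two columns (~1.7%), the pmol/cm²
column — which the recipe formula reproduces exactly — is treated as
authoritative.

The zeta potential is computed in SI form ζ = µη/(ε₀ε_r) (the Gaussian
4πµη/ε form differs only by unit convention); it is linear in mobility
and provided for completeness of the calibration chain.

## Logistic fits

The logistic ODE dΔλ/dt = rΔλ(1 − Δλ/Δλ_max) has the closed form
Δλ(t) = Δλ_max / (1 + ((Δλ_max − Δλ₀)/Δλ₀)e^(−rt)), fitted by bounded
nonlinear least squares with three free parameters (Δλ₀, Δλ_max, r).
Initial guesses: Δλ_max ← max Δλ, Δλ₀ ← max(first sample, 1 pm),
r ← 4·max slope/Δλ_max (the logistic's peak slope is rΔλ_max/4). Time is
minutes throughout and r is reported per minute: curves that saturate
over tens of minutes are incompatible with per-second rates of order
0.1. Two standard windows, 0–60 and 0–100 min, are fitted by default; on
noiseless logistic data they give identical parameters. Traces whose
dynamic range is below a configurable noise floor (default 5 pm) raise an
explicit fit failure instead of returning numbers. A four-parameter
logistic (bottom, top, t_half, Hill slope) is available as `model="4pl"`
for comparison with spreadsheet/plotting-software fits.

## Three-state kinetic model

States are surface densities in the adhesion zone: free ligand L, free
integrin I, bound complex B, with mass-action binding (k₁, k₂) and
complex-catalyzed integrin recruitment k₃B(I_max − I) that stops when I
reaches I_max. Ligand is conserved (L + B constant); integrins are not,
because recruitment draws from the cell body. Initial conditions default
to L₀ = 15000 µm⁻² (a 50% RGD coating), I₀ = 0.1 µm⁻², B₀ = 0.

Unit convention: densities µm⁻², time min, hence k₂ in min⁻¹ and k₁, k₃
in µm² min⁻¹ per molecule; `k1_2d_to_kon3d` converts a 2D on-rate to the
familiar M⁻¹s⁻¹ given d_c.

Closed-form anchors used as oracles for the integrator and fitter:

* k₃ = 0 (no recruitment): both species conserved; B_eq is the smaller
  root of B² − (L_tot + I_tot + K_d)B + L_tot I_tot = 0, evaluated in the
  cancellation-free form 2LI/(S + √(S² − 4LI)).
* k₃ > 0: the fixed point forces I = I_max, giving
  B_max = (L₀ + B₀)I_max/(K_d + I_max).

Simulation uses LSODA with rtol 1e-8 / atol 1e-10 and dense output
evaluated at the sample times; tiny negative excursions within tolerance
are clipped to zero.

### Fitting and identifiability

`fit_kinetics` minimizes pooled squared residuals between B(t)/α and all
replicates, each truncated at the maximum of a moving-median-smoothed
(width 5) copy of itself so a noise spike cannot end the window early.
Optimization runs in log-parameter space (positivity by construction)
with bounded trust-region least squares. The finite-difference step for
the Jacobian is 1e-4 in log space — far above the integrator's noise
floor; with the default √ε step the Jacobian is dominated by solver noise
and the optimizer stalls partway down the shallow valley described next.
A data-driven start (saturation level → K_d·I_max trade-off, coarse k₃
scan for rise timing) plus seeded random restarts (default 8) guard
against local minima; the spread of parameters across near-optimal starts
is reported.

The model is sloppy in k₁: increasing k₁ while decreasing I_max (and
adjusting k₃) leaves the predicted signal almost unchanged, because only
the products k₁L·I and the saturation level are strongly constrained once
I₀ is fixed. Two diagnostics expose this: `identifiability_scan` refits
from initial guesses with one parameter scaled across orders of
magnitude, and `profile_scan` fixes a parameter at a factor of its
best-fit value and re-optimizes the rest. On synthetic data with 1%
noise, fixing k₁ at ±50% of its fitted value raises the SSR by only a few
percent (R² stays above 0.99) — k₁ is not determined tighter than about
±50% by such data, while k₂, k₃ and I_max are determined to a few
percent. Derived constants that involve k₁ (K_d = k₂/k₁) inherit this
uncertainty; dose-to-dose *trends* survive it, absolute values should be
quoted with the profile width.

Derived quantities: K_d²ᴰ = k₂/k₁ and its molar equivalent; B_max from
the closed form; I_total at saturation = B_max + 2·I_max, reading I_max
as the integrin reservoir just outside the zone (at saturation the zone
holds I = I_max free integrins and the reservoir holds another I_max).

## Static isotherm

At equilibrium with ligand in excess (L₀ ≫ B_eq), B_eq = L₀I₀/(L₀ +
K_d²ᴰ). The fit uses two parameters — an amplitude A (pm) absorbing
I₀·(1/α), and K_d²ᴰ — so the fitted constant is independent of the signal
calibration; I₀ in µm⁻² is derived afterwards as A·α. Weighted least
squares is used when replicate SDs are supplied. The ligand-excess
assumption is checked post hoc (warn when min L₀ < 10·B_eq), as are
parameter-at-bound conditions; an all-equal signal vector is rejected as
degenerate.

## Synthetic plates

The generator emulates a ChrABC dilution-series experiment on a 50% RGD
surface: 11 doses (0 plus a 2×/5×-alternating series, 6.25×10⁻⁵ to 1.25
U/ml), triplicate wells, 0–100 min sampled at the instrument's 3 s
resolution, additive i.i.d. Gaussian noise on Δλ. Dose dependence of the
true parameters is smooth on the log-dose axis and anchored at the
untreated baseline K_d²ᴰ = 600 µm⁻², I_max = 0.3 µm⁻², k₂ = 0.1 min⁻¹,
with k₃ = 0.7 µm²/min chosen so the baseline curve half-rises at ~30 min.
The dose shapes encode the observed digestion signature: k₂ constant; k₃
monotonically decreasing (to ~25% at the top dose); k₁ ~25–30% above
baseline at the two mildest doses, then declining so that K_d²ᴰ reaches
~1700 µm⁻² at 1.25 U/ml; I_max stepping from 0.3 to 0.6 µm⁻² between 0.01
and 0.1 U/ml.

The noise SD defaults to 10 pm (roughly 0.7% of a 1500 pm saturation
signal), an order of magnitude consistent with replicate scatter in such
measurements; the true noise of any given instrument should be measured,
not assumed. What the generator does *not* emulate: reference-well
drift, temperature transients, cell-count variability between wells,
single-cell heterogeneity, and any model mismatch — so recovery tests on
synthetic plates demonstrate the estimator's correctness and precision
under the model's own assumptions, not robustness to real-data artifacts.
All randomness is seeded and recorded in the dataset manifest.

## Problem sizes and numerical defaults

Analysis-grade fits use the full 3 s sampling; the test suite and the
reproduction script sample synthetic traces at 0.5 min (201 points per
100 min trace, ×3 replicates) and use 1–4 optimizer starts, which gives
recovery indistinguishable from the dense sampling for these smooth
curves. Monte-Carlo checks use 20 random parameter sets (kinetics) and
200 noise realizations (isotherm). Optimizer tolerances are ftol = xtol =
1e-14 (kinetics; the shallow valley needs tight stopping rules),
lmfit/MINPACK defaults elsewhere. Equilibrium oracle comparisons run the
ODE to t = 600–2000 min, where the analytic fixed point is approached to
better than 1e-6 relative.

## Known limitations

* Monovalent binding only: no integrin clustering, cooperativity,
  multivalency or spatial transport; k₃ lumps all recruitment mechanics.
* I₀ (initial zone integrin density) is fixed, not fitted; it anchors the
  overall scale and its miscalibration propagates into k₁ and I_max.
* The kinetic and static dissociation constants are reported side by
  side; reconciling their difference is interpretation, not computation.
* The logistic and three-state fits assume reference-subtracted,
  drift-free traces; no baseline correction is applied.
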