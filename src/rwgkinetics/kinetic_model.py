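"""Three-state integrin-recruitment/binding model of adhesion kinetics.

State variables are surface concentrations (µm⁻²) inside the cell's
adhesion zone — free RGD ligand L, free integrin I, and bound
integrin--ligand complex B — obeying

    dB/dt =  k1·L·I − k2·B
    dL/dt = −k1·L·I + k2·B
    dI/dt = −k1·L·I + k2·B + k3·B·(I_max − I)

k1 and k2 are the on/off rates of integrin--RGD binding, k3 the rate at
which bound complexes recruit further integrins into the zone, and I_max
the free-integrin ceiling at which recruitment stops.  The biosensor
signal is proportional to B, so fitting the model to triplicate
wavelength-shift curves estimates (k1, k2, k3, I_max) and the derived
kinetic dissociation constant K_d^2D = k2/k1.

Units: densities µm⁻², time minutes, hence k2 and k3·(density) in min⁻¹
and k1, k3 in µm²·min⁻¹ per molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .calibration import AVOGADRO, SignalCalibration, kd2d_to_kd3d
from .logistic import FitFailure, KineticTrace

__all__ = [
    "AdhesionKineticParams",
    "InitialState",
    "StateTrajectory",
    "DerivedQuantities",
    "KineticFitResult",
    "SimulationError",
    "simulate",
    "equilibrium_B_no_recruitment",
    "steady_state_B",
    "predict_signal",
    "fit_kinetics",
    "identifiability_scan",
    "profile_scan",
    "derived_quantities",
    "k1_2d_to_kon3d",
]


class SimulationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


@dataclass(frozen=True)
class AdhesionKineticParams:
    """Rate constants and recruitment ceiling of the three-state model."""

    k1: float  # µm²/min per molecule, integrin-RGD association
    k2: float  # 1/min, dissociation
    k3: float  # µm²/min per molecule, recruitment
    I_max: float  # µm⁻², free-integrin ceiling in the zone

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "I_max"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def kd2d(self) -> float:
        """Kinetic 2D dissociation constant k2/k1 (µm⁻²)."""
        if self.k1 == 0:
            raise ZeroDivisionError("kd2d undefined for k1 = 0")
        return self.k2 / self.k1

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.I_max])


@dataclass(frozen=True)
class InitialState:
    """Surface concentrations at first cell--surface contact (t = 0)."""

    L0: float = 15000.0
    I0: float = 0.1
    B0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("L0", "I0", "B0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class StateTrajectory:
    """Simulated L(t), I(t), B(t) on a time grid (minutes, µm⁻²)."""

    t: np.ndarray
    L: np.ndarray
    I: np.ndarray
    B: np.ndarray


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities computed from fitted rate constants.

    kd2d_kinetic = k2/k1 (µm⁻²); kd3d_kinetic its molar equivalent (µM);
    B_max the bound-complex density at saturation; I_total_sat = B + I +
    I_max evaluated at saturation (where I = I_max, reading I_max as the
    reservoir of integrins outside the adhesion zone).
    """

    kd2d_kinetic: float
    kd3d_kinetic: float
    B_max: float
    I_total_sat: float


def _rhs(t, y, k1, k2, k3, I_max):
    L, I, B = y
    flux = k1 * L * I - k2 * B
    return (-flux, -flux + k3 * B * (I_max - I), flux)


def simulate(
    params: AdhesionKineticParams,
    init: InitialState,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StateTrajectory:
    """Integrate the three-state model on ``t_grid`` (minutes, increasing).

    Uses an adaptive, stiffness-switching solver (LSODA) with dense
    output interpolated to the grid.  Ligand is conserved exactly by the
    equations (dL/dt + dB/dt = 0), so L + B stays at L0 + B0 to within
    solver tolerance — a useful internal consistency check.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D, increasing, length >= 2")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after 0")
    y0 = (init.L0, init.I0, init.B0)
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_grid[-1])),
        y0,
        method="LSODA",
        t_eval=t_grid,
        args=(params.k1, params.k2, params.k3, params.I_max),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    L, I, B = sol.y
    # clip tiny negative excursions within solver tolerance
    return StateTrajectory(
        t=t_grid, L=np.maximum(L, 0.0), I=np.maximum(I, 0.0), B=np.maximum(B, 0.0)
    )


def equilibrium_B_no_recruitment(L_tot: float, I_tot: float, kd2d: float) -> float:
    """Equilibrium bound density for pure binding (k3 = 0).

    With ligand and integrin both conserved, B solves
    B² − (L_tot + I_tot + kd2d)·B + L_tot·I_tot = 0; the physical root is
    the smaller one, computed in a cancellation-free form.
    """
    for name, v in (("L_tot", L_tot), ("I_tot", I_tot), ("kd2d", kd2d)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if L_tot == 0 or I_tot == 0:
        return 0.0
    s = L_tot + I_tot + kd2d
    disc = s * s - 4.0 * L_tot * I_tot
    # disc >= (L_tot - I_tot)^2 >= 0 always
    return 2.0 * L_tot * I_tot / (s + math.sqrt(max(disc, 0.0)))


def steady_state_B(params: AdhesionKineticParams, init: InitialState) -> float:
    """Saturation bound-complex density when recruitment is active (k3 > 0).

    At the fixed point the recruitment term forces I = I_max, and the
    binding balance k1·L·I_max = k2·B with L = L0 + B0 − B gives

        B_max = (L0 + B0)·I_max / (K_d^2D + I_max).
    """
    if params.k1 <= 0 or params.k2 <= 0 or params.k3 <= 0:
        raise ValueError("steady_state_B requires k1, k2, k3 > 0")
    kd = params.kd2d
    l_tot = init.L0 + init.B0
    return l_tot * params.I_max / (kd + params.I_max)


def predict_signal(
    traj: StateTrajectory, cal: SignalCalibration = SignalCalibration()
) -> np.ndarray:
    """Wavelength-shift trace (pm) implied by a trajectory: Δλ = B/alpha."""
    return traj.B / cal.alpha


def k1_2d_to_kon3d(k1: float, d_c: float = 100.0) -> float:
    """Convert a 2D association rate (µm²/min per molecule) to a solution
    on-rate in M⁻¹s⁻¹, assuming reactants confined to a zone of thickness
    ``d_c`` nm."""
    if k1 < 0:
        raise ValueError("k1 must be >= 0")
    if not (d_c > 0):
        raise ValueError("d_c must be positive")
    vol_um3_per_min = k1 * d_c * 1e-3  # µm³/min per molecule
    litres_per_min = vol_um3_per_min * 1e-15
    return litres_per_min / 60.0 * AVOGADRO


# --------------------------------------------------------------------------
# fitting


def _smoothed_argmax(y: np.ndarray, width: int = 5) -> int:
    """Index of the maximum of a moving-median-smoothed copy of ``y``.

    Smoothing keeps a single noise spike from truncating the fit window
    early.
    """
    if len(y) <= width:
        return int(np.argmax(y))
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, width)
    smooth = np.median(windows, axis=1)
    return int(np.argmax(smooth))


@dataclass(frozen=True)
class KineticFitResult:
    """Best-fit parameters plus pooled goodness-of-fit diagnostics."""

    params: AdhesionKineticParams
    r_squared: float
    residual_sd: float  # pm
    ssr: float
    n_points: int
    at_bounds: dict = field(default_factory=dict)
    n_starts: int = 1
    start_spread: dict = field(default_factory=dict)


_DEFAULT_BOUNDS = {
    "k1": (1e-8, 1.0),
    "k2": (1e-4, 10.0),
    "k3": (1e-4, 100.0),
    "I_max": (1e-3, 10.0),
}


def _prepare_traces(traces, cal, noise_floor):
    """Truncate each replicate at its (smoothed) maximum; pool times/values."""
    prepared = []
    for tr in traces:
        y = tr.dlambda
        if float(np.max(y) - np.min(y)) < noise_floor:
            raise FitFailure(
                f"replicate {tr.replicate_id!r} is flat (range below "
                f"{noise_floor} pm); cannot fit kinetics"
            )
        imax = _smoothed_argmax(y)
        if imax + 1 < 10:
            raise ValueError(
                f"replicate {tr.replicate_id!r} has fewer than 10 samples "
                "before its maximum"
            )
        prepared.append((tr.t[: imax + 1], y[: imax + 1]))
    return prepared


def _pooled_residuals(theta, prepared, init, cal, t_end):
    params = AdhesionKineticParams(*np.exp(theta))
    grid = np.array([0.0, t_end])
    try:
        sol = solve_ivp(
            _rhs,
            (0.0, t_end),
            (init.L0, init.I0, init.B0),
            method="LSODA",
            dense_output=True,
            args=(params.k1, params.k2, params.k3, params.I_max),
            rtol=1e-8,
            atol=1e-10,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise SimulationError(str(exc)) from exc
    if not sol.success:
        return np.full(sum(len(t) for t, _ in prepared), 1e6)
    res = []
    for t, y in prepared:
        B = sol.sol(t)[2]
        res.append(B / cal.alpha - y)
    return np.concatenate(res)


def _data_driven_guess(prepared, init, cal, guess):
    """Initial parameter vector from the traces themselves.

    Anchors: the saturation signal fixes B_max, which with an I_max guess
    fixes K_d^2D through the steady state; a coarse 1-D scan sets the
    recruitment rate to match the observed rise time.
    """
    b_sat = np.median([np.max(y) for _, y in prepared]) * cal.alpha
    if guess is not None:
        return np.log(guess.as_array())
    i_max0 = 0.3
    l_tot = init.L0 + init.B0
    kd0 = max(l_tot * i_max0 / max(b_sat, 1e-9) - i_max0, 1.0)
    k2_0 = 0.1
    k1_0 = k2_0 / kd0
    # coarse scan over k3 to match rise timing
    t_end = max(t[-1] for t, _ in prepared)
    best = (np.inf, 0.5)
    for k3 in np.logspace(-2, 1.5, 8):
        theta = np.log([k1_0, k2_0, k3, i_max0])
        try:
            r = _pooled_residuals(theta, prepared, init, cal, t_end)
        except SimulationError:
            continue
        ssr = float(r @ r)
        if ssr < best[0]:
            best = (ssr, k3)
    return np.log([k1_0, k2_0, best[1], i_max0])


def fit_kinetics(
    traces,
    init: InitialState = InitialState(),
    cal: SignalCalibration = SignalCalibration(),
    guess: AdhesionKineticParams | None = None,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    noise_floor: float = 5.0,
    multi_start: bool = True,
) -> KineticFitResult:
    """Fit (k1, k2, k3, I_max) to one or more replicate adhesion traces.

    Each replicate is truncated at its own (lightly smoothed) maximum and
    residuals are pooled across replicates — the signal model is
    Δλ(t) = B(t)/alpha with B from :func:`simulate`.  Optimization runs
    in log-parameter space (positivity for free) with bounded
    trust-region least squares and, by default, several seeded restarts
    around a data-driven initial guess: the association rate k1 sits in a
    shallow valley of the cost surface, so restarts both guard against
    local minima and report the spread of each parameter across starts.

    Returns a :class:`KineticFitResult`; parameters pinned at their
    bounds are flagged in ``at_bounds``.
    """
    if isinstance(traces, KineticTrace):
        traces = [traces]
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    prepared = _prepare_traces(traces, cal, noise_floor)
    t_end = float(max(t[-1] for t, _ in prepared))

    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.log([b["k1"][0], b["k2"][0], b["k3"][0], b["I_max"][0]])
    hi = np.log([b["k1"][1], b["k2"][1], b["k3"][1], b["I_max"][1]])

    theta0 = np.clip(_data_driven_guess(prepared, init, cal, guess), lo, hi)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    if multi_start and n_starts > 1:
        for _ in range(n_starts - 1):
            starts.append(np.clip(theta0 + rng.uniform(-1.5, 1.5, 4), lo, hi))

    def run(theta_start):
        return least_squares(
            _pooled_residuals,
            theta_start,
            bounds=(lo, hi),
            args=(prepared, init, cal, t_end),
            method="trf",
            x_scale="jac",
            # diff_step well above the ODE-solver noise floor keeps the
            # finite-difference Jacobian usable in the shallow k1 valley
            diff_step=1e-4,
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-12,
        )

    results = []
    for theta_start in starts:
        try:
            results.append(run(theta_start))
        except SimulationError:
            continue
    if not results:
        raise FitFailure("all optimization starts failed")
    results.sort(key=lambda r: r.cost)
    best = results[0]
    theta_hat = best.x
    params = AdhesionKineticParams(*np.exp(theta_hat))

    y_all = np.concatenate([y for _, y in prepared])
    r = _pooled_residuals(theta_hat, prepared, init, cal, t_end)
    ssr = float(r @ r)
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r_squared = 1.0 - ssr / ss_tot if ss_tot > 0 else 0.0

    at_bounds = {}
    for i, name in enumerate(("k1", "k2", "k3", "I_max")):
        if theta_hat[i] - lo[i] < 1e-6 or hi[i] - theta_hat[i] < 1e-6:
            at_bounds[name] = True
    spread = {}
    if len(results) > 1:
        # spread of each parameter over starts whose cost is within 1% of best
        good = np.array(
            [np.exp(res.x) for res in results if res.cost <= 1.01 * best.cost]
        )
        for i, name in enumerate(("k1", "k2", "k3", "I_max")):
            spread[name] = float(good[:, i].max() / good[:, i].min())

    return KineticFitResult(
        params=params,
        r_squared=r_squared,
        residual_sd=math.sqrt(ssr / len(y_all)),
        ssr=ssr,
        n_points=len(y_all),
        at_bounds=at_bounds,
        n_starts=len(results),
        start_spread=spread,
    )


def identifiability_scan(
    traces,
    init: InitialState = InitialState(),
    cal: SignalCalibration = SignalCalibration(),
    base: AdhesionKineticParams | None = None,
    param: str = "k1",
    factors=None,
    bounds: dict | None = None,
):
    """Guess-sensitivity scan: refit with one initial guess scaled.

    Mirrors the diagnostic of varying the starting value of one rate
    (typically k1) over orders of magnitude and recording how much the
    fitted parameters move while the residual stays flat.  Each scaled
    guess launches a single optimization (no restarts — the point is to
    see where each start settles).

    Returns a list of dicts with the scale factor, fitted parameters,
    SSR and R² per start.
    """
    if factors is None:
        factors = np.logspace(-1, 1, 7)
    if base is None:
        fit0 = fit_kinetics(traces, init, cal, bounds=bounds, n_starts=1,
                            multi_start=False)
        base = fit0.params
    out = []
    for f in factors:
        kwargs = {k: getattr(base, k) for k in ("k1", "k2", "k3", "I_max")}
        kwargs[param] = kwargs[param] * float(f)
        g = AdhesionKineticParams(**kwargs)
        fit = fit_kinetics(
            traces, init, cal, guess=g, bounds=bounds, n_starts=1,
            multi_start=False,
        )
        out.append(
            {
                "factor": float(f),
                "k1": fit.params.k1,
                "k2": fit.params.k2,
                "k3": fit.params.k3,
                "I_max": fit.params.I_max,
                "ssr": fit.ssr,
                "r_squared": fit.r_squared,
            }
        )
    return out


def profile_scan(
    traces,
    best: AdhesionKineticParams,
    init: InitialState = InitialState(),
    cal: SignalCalibration = SignalCalibration(),
    param: str = "k1",
    factors=(0.5, 1.5),
    bounds: dict | None = None,
    noise_floor: float = 5.0,
):
    """Profile-likelihood scan of one parameter.

    Fixes ``param`` at ``factor``×its best-fit value, re-optimizes the
    remaining three, and reports the sum of squared residuals relative
    to the full fit.  A shallow profile (small SSR excess across a wide
    factor range) is the signature of a weakly identified parameter —
    for this model, the association rate k1, which trades off against
    I_max with little effect on the predicted signal.
    """
    if isinstance(traces, KineticTrace):
        traces = [traces]
    prepared = _prepare_traces(traces, cal, noise_floor)
    t_end = float(max(t[-1] for t, _ in prepared))
    names = ["k1", "k2", "k3", "I_max"]
    if param not in names:
        raise ValueError(f"unknown parameter {param!r}")
    idx = names.index(param)
    free = [i for i in range(4) if i != idx]

    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.log([b[names[i]][0] for i in free])
    hi = np.log([b[names[i]][1] for i in free])

    r0 = _pooled_residuals(np.log(best.as_array()), prepared, init, cal, t_end)
    ssr0 = float(r0 @ r0)
    y_all = np.concatenate([y for _, y in prepared])
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))

    out = []
    for f in factors:
        fixed_log = math.log(getattr(best, param) * float(f))

        def res(theta_free):
            full = np.empty(4)
            full[idx] = fixed_log
            full[free] = theta_free
            return _pooled_residuals(full, prepared, init, cal, t_end)

        theta_free0 = np.clip(np.log(best.as_array()[free]), lo, hi)
        r = least_squares(
            res, theta_free0, bounds=(lo, hi), method="trf", x_scale="jac",
            diff_step=1e-4, ftol=1e-12, xtol=1e-12,
        )
        ssr = 2.0 * float(r.cost)
        refit = np.exp(r.x)
        row = {"factor": float(f), "ssr": ssr,
               "ssr_excess": ssr / ssr0 - 1.0,
               "r_squared": 1.0 - ssr / ss_tot if ss_tot > 0 else 0.0}
        for i, j in enumerate(free):
            row[names[j]] = float(refit[i])
        out.append(row)
    return out


def derived_quantities(
    params: AdhesionKineticParams,
    init: InitialState = InitialState(),
    cal: SignalCalibration = SignalCalibration(),
) -> DerivedQuantities:
    """Dissociation constants and saturation densities implied by a fit."""
    if params.k1 <= 0:
        raise ValueError("kd2d undefined: k1 must be positive")
    kd2d = params.kd2d
    kd3d = kd2d_to_kd3d(kd2d, cal.d_c)
    b_max = steady_state_B(params, init)
    # at saturation I = I_max inside the zone and I_outside = I_max
    i_total = b_max + 2.0 * params.I_max
    return DerivedQuantities(
        kd2d_kinetic=kd2d,
        kd3d_kinetic=kd3d,
        B_max=b_max,
        I_total_sat=i_total,
    )
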