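"""Optional diagnostic plots (requires matplotlib; never needed for analysis).

Overlay figures in the style of the standard views of this experiment:
measured vs fitted adhesion curves, dose dependence of fitted parameters,
and the saturation isotherm.
"""

from __future__ import annotations

import numpy as np

from .calibration import SignalCalibration
from .kinetic_model import InitialState, predict_signal, simulate
from .static_model import isotherm


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting; install the 'plot' extra"
        ) from exc
    return plt


def plot_traces_with_fit(traces, params_by_conc, init=None, cal=None, ax=None):
    """Measured traces (dots) with model curves (lines), one color per dose."""
    plt = _plt()
    init = init or InitialState()
    cal = cal or SignalCalibration()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    colors = plt.cm.viridis(np.linspace(0, 1, len(params_by_conc)))
    for color, (conc, params) in zip(colors, sorted(params_by_conc.items())):
        for tr in traces:
            if tr.enzyme_conc == conc:
                ax.plot(tr.t, tr.dlambda, ".", ms=1, color=color, alpha=0.4)
        t = np.linspace(0, max(tr.t[-1] for tr in traces), 400)
        y = predict_signal(simulate(params, init, t), cal)
        ax.plot(t, y, "-", color=color, lw=1.5, label=f"{conc:g} U/ml")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("wavelength shift (pm)")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_dose_response(fit_table, columns=("k1", "k2", "k3", "I_max"), axes=None):
    """Fitted parameter vs enzyme dose, log-x, one panel per parameter."""
    plt = _plt()
    if axes is None:
        _, axes = plt.subplots(1, len(columns), figsize=(3.2 * len(columns), 3))
    conc = np.asarray(fit_table["enzyme_U_per_ml"], dtype=float)
    floor = conc[conc > 0].min() / 3 if np.any(conc > 0) else 1e-5
    x = np.where(conc > 0, conc, floor)
    for ax, col in zip(np.atleast_1d(axes), columns):
        ax.semilogx(x, fit_table[col], "o-")
        ax.set_xlabel("ChrABC (U/ml)")
        ax.set_ylabel(col)
    return axes


def plot_isotherm_fit(data, fit, ax=None):
    """Saturation signal vs ligand density with the fitted isotherm."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if data.sd is not None:
        ax.errorbar(data.L0, data.dlambda_max, yerr=data.sd, fmt="o", ms=4)
    else:
        ax.plot(data.L0, data.dlambda_max, "o", ms=4)
    grid = np.linspace(0, data.L0.max() * 1.05, 300)
    ax.plot(grid, isotherm(grid, fit.amplitude, fit.kd2d_static), "-")
    ax.set_xlabel("RGD density (µm$^{-2}$)")
    ax.set_ylabel("$\\Delta\\lambda_{max}$ (pm)")
    return ax
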