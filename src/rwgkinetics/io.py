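"""Delimited-text input/output for traces, saturation data and fit tables.

Column dialects
---------------
kinetic traces : ``time_min, dlambda_pm, enzyme_U_per_ml, replicate, q_percent``
saturation data: ``q_percent`` or ``L0_per_um2``, ``dlambda_max_pm``,
                 ``sd_pm`` (optional), ``enzyme_U_per_ml``
coating table  : ``Q, L0_pmol_cm2, d_rgd_nm, L0_per_um2``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CoatingSpec, rgd_surface_density
from .logistic import KineticTrace
from .static_model import SaturationDataset

__all__ = [
    "read_traces",
    "write_traces",
    "read_saturation",
    "write_saturation",
    "write_manifest",
]

TRACE_COLUMNS = ["time_min", "dlambda_pm", "enzyme_U_per_ml", "replicate", "q_percent"]


def read_traces(path) -> list[KineticTrace]:
    """Read long-format kinetic traces; one trace per
    (enzyme_U_per_ml, replicate) group."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if "q_percent" not in df.columns:
        df["q_percent"] = 50.0
    bad = df[TRACE_COLUMNS[:2]].apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        row = int(bad.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric value near row {row + 2}")
    traces = []
    for (conc, rep), grp in df.groupby(["enzyme_U_per_ml", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            KineticTrace(
                t=grp["time_min"].to_numpy(float),
                dlambda=grp["dlambda_pm"].to_numpy(float),
                enzyme_conc=float(conc),
                replicate_id=str(rep),
                Q=float(grp["q_percent"].iloc[0]),
            )
        )
    return traces


def write_traces(traces, path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_min": tr.t,
                    "dlambda_pm": tr.dlambda,
                    "enzyme_U_per_ml": tr.enzyme_conc,
                    "replicate": tr.replicate_id,
                    "q_percent": tr.Q,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_saturation(path, coating: CoatingSpec | None = None) -> list[SaturationDataset]:
    """Read saturation datasets, one per enzyme concentration.

    Densities are taken from ``L0_per_um2`` when present, otherwise
    computed from ``q_percent`` through the coating recipe.
    """
    df = pd.read_csv(path)
    if "dlambda_max_pm" not in df.columns:
        raise ValueError(f"{path}: missing column 'dlambda_max_pm'")
    if "L0_per_um2" not in df.columns:
        if "q_percent" not in df.columns:
            raise ValueError(
                f"{path}: need either 'L0_per_um2' or 'q_percent' column"
            )
        from dataclasses import replace

        def q_to_l0(q):
            spec = CoatingSpec(Q=float(q)) if coating is None else replace(
                coating, Q=float(q)
            )
            return rgd_surface_density(spec).L0_per_um2

        df["L0_per_um2"] = df["q_percent"].map(q_to_l0)
    if "enzyme_U_per_ml" not in df.columns:
        df["enzyme_U_per_ml"] = 0.0
    out = []
    for conc, grp in df.groupby("enzyme_U_per_ml", sort=True):
        sd = grp["sd_pm"].to_numpy(float) if "sd_pm" in grp.columns else None
        out.append(
            SaturationDataset(
                L0=grp["L0_per_um2"].to_numpy(float),
                dlambda_max=grp["dlambda_max_pm"].to_numpy(float),
                sd=sd,
                enzyme_conc=float(conc),
            )
        )
    return out


def write_saturation(data: SaturationDataset, path) -> None:
    df = pd.DataFrame(
        {
            "L0_per_um2": data.L0,
            "dlambda_max_pm": data.dlambda_max,
            "enzyme_U_per_ml": data.enzyme_conc,
        }
    )
    if data.sd is not None:
        df.insert(2, "sd_pm", data.sd)
    df.to_csv(path, index=False)


def write_manifest(profile, noise, path) -> None:
    """Record the true generator parameters of a synthetic dataset."""
    payload = {
        "seed": noise.seed,
        "sigma_pm": noise.sigma,
        "n_replicates": noise.n_replicates,
        "sampling_dt_s": noise.sampling_dt,
        "true_params": {
            str(c): {
                "k1": profile.params_at(c).k1,
                "k2": profile.params_at(c).k2,
                "k3": profile.params_at(c).k3,
                "I_max": profile.params_at(c).I_max,
            }
            for c in profile.concentrations
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
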