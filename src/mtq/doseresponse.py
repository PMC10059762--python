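"""MTT viability percentages and Hill dose-response fitting.

Viability (%) = 100 x OD_treated / OD_control, where OD_control is the mean
optical density of that plate-and-timepoint's vehicle (dose 0) wells. The
optional Hill fit recovers (IC50, slope, floor) from the four-parameter
logistic form used by the plate simulator:

    viability(d) = 100 * [floor + (1 - floor) / (1 + (d / IC50)^h)]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthdata import hill_viability

__all__ = ["HillFit", "viability_percent", "build_viability_table", "fit_hill"]


def viability_percent(od_treated: float, od_control: float) -> float:
    """100 x OD_treated / OD_control; negative ODs are clipped to 0."""
    if od_control <= 0:
        raise ValueError("od_control must be positive")
    if od_treated < 0:
        warnings.warn(
            "negative od_treated (blank over-subtraction?); clipping to 0",
            stacklevel=2,
        )
        od_treated = 0.0
    return 100.0 * od_treated / od_control


def build_viability_table(
    od: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    group: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-well viability percentages from OD readings.

    ``od`` needs columns well, od; dose/timepoint either come with it or are
    merged from ``layout`` (columns well, dose_uM, timepoint, and optionally
    group/treatment). Control OD is the mean of dose-0 wells per timepoint;
    a timepoint without controls is an error, as is a well assigned twice.
    Returns (per-well table, per-condition mean +/- SEM summary).
    """
    df = od.copy()
    if layout is not None:
        if layout["well"].duplicated().any():
            dup = layout.loc[layout["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate well assignment in layout: {dup}")
        df = df.merge(layout, on=[c for c in ("well", "timepoint") if c in layout], how="left")
    required = {"well", "od", "dose_uM", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.duplicated(subset=["well", "timepoint"]).any():
        raise ValueError("duplicate well readings for the same timepoint")
    out = []
    for tp, sub in df.groupby("timepoint", sort=False):
        controls = sub.loc[sub["dose_uM"] == 0, "od"]
        if controls.empty:
            raise ValueError(f"timepoint {tp!r} has no dose-0 control wells")
        od_control = float(controls.mean())
        sub = sub.copy()
        sub["od_control"] = od_control
        sub["viability_percent"] = [
            viability_percent(v, od_control) for v in sub["od"]
        ]
        out.append(sub)
    per_well = pd.concat(out, ignore_index=True)
    if group:
        per_well["group"] = group
    keys = [c for c in ("group", "treatment", "timepoint", "dose_uM") if c in per_well]
    summary = (
        per_well.groupby(keys, sort=False)["viability_percent"]
        .agg(["mean", "sem", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    return per_well, summary


@dataclass
class HillFit:
    ic50_uM: float
    hill_slope: float
    floor: float
    se_ic50_uM: float
    se_hill_slope: float
    se_floor: float
    converged: bool
    message: str = ""


def fit_hill(per_well: pd.DataFrame, group: str | None = None) -> HillFit:
    """Least-squares Hill fit of viability vs dose.

    Requires >= 4 distinct doses. IC50 is fitted on the log scale for
    conditioning. A monotone-increasing dose-viability relationship violates
    the model and is flagged (``converged=False``) rather than raised, as is
    optimizer non-convergence.
    """
    df = per_well
    if group is not None and "group" in df:
        df = df[df["group"] == group]
    dose = df["dose_uM"].to_numpy(float)
    via = df["viability_percent"].to_numpy(float)
    if len(np.unique(dose)) < 4:
        raise ValueError("need at least 4 distinct doses to fit a Hill curve")

    pos = dose > 0
    if pos.sum() >= 2:
        rho = stats.spearmanr(dose[pos], via[pos]).statistic
        if rho > 0.5:
            return HillFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           False, "viability increases with dose; Hill model violated")

    def model(d, log_ic50, h, floor):
        return 100.0 * hill_viability(d, np.exp(log_ic50), h, floor)

    geo_mid = np.exp(np.mean(np.log(dose[pos]))) if pos.any() else 1.0
    try:
        popt, pcov = optimize.curve_fit(
            model,
            dose,
            via,
            p0=[np.log(geo_mid), 1.0, 0.0],
            bounds=([np.log(1e-6), 0.05, 0.0], [np.log(1e9), 20.0, 1.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # non-convergence is reported, not raised
        return HillFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, str(exc))
    se = np.sqrt(np.diag(pcov))
    ic50 = float(np.exp(popt[0]))
    return HillFit(
        ic50_uM=ic50,
        hill_slope=float(popt[1]),
        floor=float(popt[2]),
        se_ic50_uM=float(ic50 * se[0]),  # delta method on the log scale
        se_hill_slope=float(se[1]),
        se_floor=float(se[2]),
        converged=True,
    )
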