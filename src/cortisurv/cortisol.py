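"""Per-patient diurnal cortisol slope estimation.

Each patient collects saliva samples at fixed times after waking on several
days; the diurnal slope is the ordinary-least-squares slope of
log-transformed cortisol concentration on hours since waking, pooling all
days into one regression. A flatter (less negative) slope indicates a
blunted circadian cortisol rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CortisolSlope", "fit_cortisol_slope", "fit_all_slopes", "summarize_slopes"]


@dataclass(frozen=True)
class CortisolSlope:
    patient_id: str
    slope: float  # log-cortisol per hour
    intercept: float  # log-cortisol at waking (t = 0)
    n_used: int
    r2: float
    missing: bool = False  # too few usable samples; excluded downstream


def fit_cortisol_slope(
    samples: pd.DataFrame,
    patient_id: str | None = None,
    log_base: float = np.e,
    exclude_waking_response: bool = False,
) -> CortisolSlope:
    """OLS regression of log cortisol on hours since waking for one patient.

    Parameters
    ----------
    samples
        Rows for a single patient with columns ``t`` (hours since waking,
        >= 0) and ``cortisol`` (concentration, > 0). A ``patient_id`` column
        is used if the argument is not given.
    log_base
        Base of the log transform (natural log by default; only rescales
        the slope).
    exclude_waking_response
        Drop the +45-minute awakening sample (``sample_index == 2``) if a
        ``sample_index`` column is present.

    Patients with fewer than 3 usable samples, or with all samples at the
    same time, are flagged ``missing`` rather than raising, mirroring the
    complete-saliva-subset policy of cohort analyses.
    """
    if patient_id is None:
        ids = samples["patient_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"samples must belong to one patient, got {ids}")
        patient_id = str(ids[0])
    df = samples
    if exclude_waking_response and "sample_index" in df.columns:
        df = df[df["sample_index"] != 2]
    t = np.asarray(df["t"], dtype=float)
    c = np.asarray(df["cortisol"], dtype=float)
    if np.any(c <= 0):
        raise ValueError(f"patient {patient_id}: cortisol concentrations must be > 0")
    if np.any(t < 0):
        raise ValueError(f"patient {patient_id}: times since waking must be >= 0")
    if len(t) < 3 or np.unique(t).size < 2:
        return CortisolSlope(patient_id, np.nan, np.nan, len(t), np.nan, missing=True)
    y = np.log(c) / np.log(log_base)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CortisolSlope(patient_id, float(slope), float(intercept), len(t), r2)


def fit_all_slopes(saliva: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit one pooled diurnal slope per patient; returns a tidy table.

    Patients flagged missing keep NaN slope and ``missing=True`` so callers
    can apply a complete-case filter explicitly.
    """
    rows = []
    for pid, grp in saliva.groupby("patient_id", sort=True):
        s = fit_cortisol_slope(grp, patient_id=str(pid), **kwargs)
        rows.append(
            {
                "patient_id": s.patient_id,
                "slope": s.slope,
                "intercept": s.intercept,
                "n_used": s.n_used,
                "r2": s.r2,
                "missing": s.missing,
            }
        )
    return pd.DataFrame(rows)


def summarize_slopes(slopes) -> dict[str, float]:
    """Mean, SD (n−1 denominator), and mean±SD reference values of slopes.

    The ±1 SD references are the profiles at which adjusted survival curves
    are conventionally drawn for a continuous predictor.
    """
    arr = np.asarray(slopes, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 non-missing slopes to summarise")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return {
        "mean": mean,
        "sd": sd,
        "n": int(arr.size),
        "minus_1sd": mean - sd,
        "plus_1sd": mean + sd,
    }
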