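"""Slope-based signal extraction from kinetic multi-exposure intensities.

Each reporter peptide in each sample is imaged at several CCD exposure
times on every kinetic cycle. The analysis unit downstream is one scalar
"slope signal" per peptide x sample:

1. *Exposure collapse* — within each cycle, the four exposure channels
   are fused by a through-origin regression of intensity on exposure time,
   projected to the 100 ms channel: scaled = 100 * sum(e*I) / sum(e^2).
   (Alternatively a single exposure can be selected and rescaled.)
2. *Kinetic slope* — ordinary least squares of the scaled intensity on
   cycle time; the slope is the phosphorylation velocity estimate and the
   regression's R^2 measures how linear (hence detectable) the signal is.
3. *QC filter* — peptides with R^2 < 0.80 are treated as undetectable /
   nonlinear and flagged; 0.80 itself passes. Non-positive slopes are
   floored at a small positive value so downstream fold-change ratios are
   always defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

R2_MIN_DEFAULT = 0.80
SLOPE_FLOOR_DEFAULT = 1e-6
PROJECTION_EXPOSURE_MS = 100.0


class DegenerateExposureError(ValueError):
    """All exposure times in a cycle are zero; the through-origin fit is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than two distinct cycle times; no kinetic slope can be fit."""


@dataclass(frozen=True)
class SlopeFit:
    peptide_id: str
    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def exposure_collapse(
    exposures_ms: Sequence[float], intensities: Sequence[float]
) -> float:
    """Fuse one cycle's multi-exposure intensities into a projected 100 ms value.

    Through-origin least squares of intensity on exposure time (the
    physically expected proportionality), evaluated at 100 ms:
    ``100 * sum(e_i * I_i) / sum(e_i^2)``. With a single exposure e this
    reduces to ``I * 100 / e``.
    """
    e = np.asarray(exposures_ms, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if e.size == 0:
        raise DegenerateExposureError("no exposures supplied")
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise DegenerateExposureError("all exposure times are zero")
    return PROJECTION_EXPOSURE_MS * float(np.sum(e * y)) / denom


def collapse_exposures(kinetics: pd.DataFrame, exposure: float | None = None) -> pd.DataFrame:
    """Collapse a long kinetic table to one scaled intensity per peptide/sample/cycle.

    ``exposure`` selects a single exposure channel (rescaled to 100 ms)
    instead of the default all-exposure through-origin fit.
    """
    df = kinetics
    if exposure is not None:
        df = df[df["exposure_ms"] == exposure]
        if df.empty:
            raise DegenerateExposureError(f"no rows with exposure_ms == {exposure}")
        out = df.assign(
            scaled_intensity=df["intensity"] * (PROJECTION_EXPOSURE_MS / exposure)
        )[["peptide_id", "sample_id", "cycle_time_min", "scaled_intensity"]]
        return out.reset_index(drop=True)
    e = df["exposure_ms"].to_numpy(dtype=float)
    if np.all(e == 0):
        raise DegenerateExposureError("all exposure times are zero")
    work = df.assign(_ey=e * df["intensity"].to_numpy(dtype=float), _ee=e * e)
    grouped = (
        work.groupby(["peptide_id", "sample_id", "cycle_time_min"], sort=True)[["_ey", "_ee"]]
        .sum()
        .reset_index()
    )
    if (grouped["_ee"] == 0).any():
        raise DegenerateExposureError("a cycle has only zero exposure times")
    grouped["scaled_intensity"] = PROJECTION_EXPOSURE_MS * grouped["_ey"] / grouped["_ee"]
    return grouped[["peptide_id", "sample_id", "cycle_time_min", "scaled_intensity"]]


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of y on t with the degenerate-variance conventions.

    R^2 is 1 when the residual variance is 0 (and total variance > 0) and
    0 when the total variance is 0 (constant series).
    """
    n = t.size
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    if sxx == 0.0:
        raise InsufficientDataError("need >= 2 distinct cycle times")
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    sstot = float(np.sum((y - ybar) ** 2))
    if sstot == 0.0:
        return slope, intercept, 0.0
    ssres = float(np.sum((y - (intercept + slope * t)) ** 2))
    r2 = 1.0 - ssres / sstot
    return slope, intercept, float(np.clip(r2, 0.0, 1.0))


def fit_slope(
    times_min: Sequence[float],
    scaled_intensities: Sequence[float],
    peptide_id: str = "",
    sample_id: str = "",
) -> SlopeFit:
    """OLS kinetic fit of one collapsed series; see `_ols` for R^2 conventions."""
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(scaled_intensities, dtype=float)
    if np.unique(t).size < 2:
        raise InsufficientDataError("need >= 2 distinct cycle times")
    slope, intercept, r2 = _ols(t, y)
    return SlopeFit(peptide_id, sample_id, slope, intercept, r2, int(t.size))


def fit_slopes(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Vectorized kinetic OLS per peptide x sample over a collapsed table."""
    g = collapsed.assign(
        _t=collapsed["cycle_time_min"].astype(float),
        _y=collapsed["scaled_intensity"].astype(float),
    )
    g["_tt"] = g["_t"] ** 2
    g["_ty"] = g["_t"] * g["_y"]
    g["_yy"] = g["_y"] ** 2
    agg = g.groupby(["peptide_id", "sample_id"], sort=True).agg(
        n=("_t", "size"),
        n_times=("_t", "nunique"),
        st=("_t", "sum"),
        sy=("_y", "sum"),
        stt=("_tt", "sum"),
        sty=("_ty", "sum"),
        syy=("_yy", "sum"),
    )
    if (agg["n_times"] < 2).any():
        bad = agg.index[agg["n_times"] < 2].tolist()
        raise InsufficientDataError(f"series with < 2 distinct cycle times: {bad[:5]}")
    n = agg["n"].to_numpy(dtype=float)
    sxx = agg["stt"] - agg["st"] ** 2 / n
    sxy = agg["sty"] - agg["st"] * agg["sy"] / n
    sstot = agg["syy"] - agg["sy"] ** 2 / n
    slope = sxy / sxx
    intercept = (agg["sy"] - slope * agg["st"]) / n
    ssres = sstot - slope * sxy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ssres / sstot
    r2 = np.where(sstot <= 0, 0.0, np.clip(r2, 0.0, 1.0))
    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
            "n_points": agg["n"].astype(int),
        },
        index=agg.index,
    ).reset_index()
    return out


def qc_filter(
    fits: pd.DataFrame,
    r2_min: float = R2_MIN_DEFAULT,
    slope_floor: float = SLOPE_FLOOR_DEFAULT,
) -> pd.DataFrame:
    """Turn slope fits into a signal table with the R^2 quality flag.

    ``qc_pass`` is True when r_squared >= r2_min (inclusive boundary) and
    the floored signal is positive. ``signal`` is the slope floored at
    ``slope_floor`` so fold-change ratios are always defined. The
    per-comparison exclusion (a peptide failing QC in any sample of a
    comparison drops from that comparison) is applied downstream where
    comparisons are formed.
    """
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must lie in [0, 1]")
    if slope_floor <= 0:
        raise ValueError("slope_floor must be > 0")
    out = fits.copy()
    out["signal"] = np.maximum(out["slope"].to_numpy(dtype=float), slope_floor)
    out["qc_pass"] = (out["r_squared"] >= r2_min) & (out["signal"] > 0)
    return out


def extract_signals(
    kinetics: pd.DataFrame,
    r2_min: float = R2_MIN_DEFAULT,
    slope_floor: float = SLOPE_FLOOR_DEFAULT,
    exposure: float | None = None,
) -> pd.DataFrame:
    """Full stage: exposure collapse -> kinetic OLS -> QC flagging.

    Returns one row per peptide x sample with columns
    peptide_id, sample_id, slope, intercept, r_squared, n_points,
    signal, qc_pass.
    """
    collapsed = collapse_exposures(kinetics, exposure=exposure)
    fits = fit_slopes(collapsed)
    return qc_filter(fits, r2_min=r2_min, slope_floor=slope_floor)
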