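"""Trait QC and normalisation.

Quantile normalisation across traits (per replicate batch), replicate-CV
consistency filtering against two technical-control segregants, the
low-cell-count measurement filter, replicate aggregation, and growth-rate
extraction from microplate OD curves with robust locally weighted
positional-bias correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import GrowthCurveSet, TraitPanel

__all__ = [
    "quantile_normalize",
    "normalize_panel",
    "assess_trait_consistency",
    "filter_low_cell_count",
    "extract_growth_rate",
    "aggregate_replicates",
    "loess_2d",
]


def quantile_normalize(raw: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Map every trait column onto a common reference distribution.

    The reference is the across-trait mean of the per-trait sorted value
    vectors (partially missing columns contribute by interpolation onto the
    common quantile grid).  Ranks within a trait are preserved; tied values
    receive the mean reference value of their tied rank positions.  All-missing
    columns are excluded from the reference and returned as all-NaN.
    """
    df = isinstance(raw, pd.DataFrame)
    X = np.asarray(raw, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two trait columns")
    n, p = X.shape
    grid = np.linspace(0.0, 1.0, n)

    cols = []
    for j in range(p):
        v = X[:, j]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        if v.size == n:
            cols.append(np.sort(v))
        else:
            q = np.linspace(0.0, 1.0, v.size)
            cols.append(np.interp(grid, q, np.sort(v)))
    if not cols:
        raise ValueError("all trait columns are entirely missing")
    ref = np.mean(cols, axis=0)

    out = np.full_like(X, np.nan)
    for j in range(p):
        v = X[:, j]
        ok = np.isfinite(v)
        k = int(ok.sum())
        if k == 0:
            warnings.warn(f"column {j} is all-missing; left as NaN")
            continue
        ranks = rankdata(v[ok], method="average")  # 1..k, ties averaged
        q = (ranks - 1.0) / max(k - 1.0, 1.0)
        out[ok, j] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns) if df else out


def normalize_panel(panel: TraitPanel) -> TraitPanel:
    """Quantile-normalise each replicate batch of a trait panel in place order.

    Normalisation happens per replicate batch, before any replicate averaging.
    """
    out = panel.copy()
    for r in range(panel.n_replicates):
        out.values[:, :, r] = quantile_normalize(panel.values[:, :, r])
    return out


def _cv(values: np.ndarray) -> np.ndarray:
    """Coefficient of variation per trait column; NaN where the mean is ~0."""
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) > 1e-12, sd / mean, np.nan)
    return cv


def assess_trait_consistency(
    control1: np.ndarray,
    control2: np.ndarray,
    trait_names=None,
    cv_max: float = 0.4,
    dist_max: float = 0.2,
) -> pd.DataFrame:
    """Per-trait measurement-CV consistency between two control segregants.

    ``control1`` / ``control2`` are (replicates x traits) blocks of *raw*
    repeated measurements of the two technical controls.  CV = SD/mean per
    trait per control.  Traits with CV > ``cv_max`` in either control are
    excluded (``high_cv``); among the rest, traits whose CV distance index
    |CV1-CV2|/(CV1+CV2) exceeds ``dist_max`` are excluded (``inconsistent``).
    Zero-mean traits have undefined CV and are excluded (``undefined_cv``).
    For included traits the mean CV and 1-CV are reported.
    """
    c1 = np.atleast_2d(np.asarray(control1, dtype=float))
    c2 = np.atleast_2d(np.asarray(control2, dtype=float))
    if c1.shape[0] < 2 or c2.shape[0] < 2:
        raise ValueError("need >=2 replicates per control")
    if c1.shape[1] != c2.shape[1]:
        raise ValueError("controls must cover the same traits")
    p = c1.shape[1]
    if trait_names is None:
        trait_names = [f"trait{j}" for j in range(p)]

    cv1, cv2 = _cv(c1), _cv(c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.abs(cv1 - cv2) / (cv1 + cv2)
    dist = np.where((cv1 + cv2) > 0, dist, 0.0)

    reason = np.full(p, "none", dtype=object)
    undef = ~np.isfinite(cv1) | ~np.isfinite(cv2)
    reason[undef] = "undefined_cv"
    high = ~undef & ((cv1 > cv_max) | (cv2 > cv_max))
    reason[high] = "high_cv"
    incons = ~undef & ~high & (dist > dist_max)
    reason[incons] = "inconsistent"
    included = reason == "none"

    mean_cv = np.where(included, (cv1 + cv2) / 2.0, np.nan)
    return pd.DataFrame({
        "trait": trait_names,
        "cv_control1": cv1, "cv_control2": cv2, "cv_distance": dist,
        "included": included, "exclusion_reason": reason,
        "mean_cv": mean_cv, "one_minus_cv": 1.0 - mean_cv,
    })


def filter_low_cell_count(panel: TraitPanel, min_cells: int = 80
                          ) -> tuple[TraitPanel, pd.DataFrame]:
    """Drop measurements derived from too few cells.

    A replicate measurement with cell_count < ``min_cells`` is masked; a
    segregant is removed only when *all* of its replicates fall below the
    threshold (the boundary is strict: exactly ``min_cells`` cells passes).
    Returns the filtered panel and a per-segregant retention table.
    """
    low = panel.cell_counts < min_cells
    keep_seg = ~low.all(axis=1)
    values = panel.values.copy()
    values[low[:, None, :].repeat(panel.values.shape[1], axis=1)] = np.nan
    report = pd.DataFrame({
        "segregant": panel.segregant_ids,
        "n_replicates_kept": (~low).sum(axis=1),
        "retained": keep_seg,
    })
    out = TraitPanel(panel.segregant_ids[keep_seg], panel.trait_names.copy(),
                     values[keep_seg], panel.cell_counts[keep_seg])
    return out, report


def aggregate_replicates(panel: TraitPanel) -> pd.DataFrame:
    """Per (segregant, trait) mean over available replicate values.

    Single-replicate segregants pass through unchanged; missing replicate
    values are simply left out of the mean.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(panel.values, axis=2)
    return pd.DataFrame(means, index=panel.segregant_ids, columns=panel.trait_names)


# ---------------------------------------------------------------------------
# growth-rate extraction
# ---------------------------------------------------------------------------

def loess_2d(x: np.ndarray, y: np.ndarray, z: np.ndarray,
             span: float = 0.7, robustness_iters: int = 2, degree: int = 2,
             eval_x: np.ndarray | None = None,
             eval_y: np.ndarray | None = None) -> np.ndarray:
    """Robust locally weighted polynomial regression of z on two coordinates.

    Tricube distance weights over the ``span`` fraction of nearest points,
    local degree-1 or degree-2 fit (quadratic by default, which tracks smooth
    curved bias surfaces), with ``robustness_iters`` bisquare reweighting
    passes.
    """
    x = np.asarray(x, float); y = np.asarray(y, float); z = np.asarray(z, float)
    n = z.size
    if eval_x is None:
        eval_x, eval_y = x, y
    k = max(int(np.ceil(span * n)), 6 if degree == 2 else 3)
    robust = np.ones(n)
    pts = np.column_stack([x, y])
    fitted_at_data = z.copy()

    for it in range(robustness_iters + 1):
        if it > 0:
            resid = z - fitted_at_data
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = resid / (6.0 * s)
            robust = np.clip(1.0 - u ** 2, 0.0, None) ** 2
        fitted_at_data = _loess_2d_pass(pts, z, robust, k, pts, degree)
    return _loess_2d_pass(pts, z, robust, k,
                          np.column_stack([eval_x, eval_y]), degree)


def _loess_2d_pass(pts, z, robust, k, eval_pts, degree):
    out = np.empty(len(eval_pts))
    for i, q in enumerate(eval_pts):
        dx = pts[:, 0] - q[0]
        dy = pts[:, 1] - q[1]
        d = np.hypot(dx, dy)
        dk = np.partition(d, k - 1)[k - 1]
        w = np.clip(1.0 - (d / max(dk, 1e-12)) ** 3, 0.0, None) ** 3 * robust
        cols = [np.ones(len(pts)), dx, dy]
        if degree == 2:
            cols += [dx * dx, dy * dy, dx * dy]
        X = np.column_stack(cols)
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
        out[i] = beta[0]
    return out


def extract_growth_rate(
    curves: GrowthCurveSet,
    smoothing_window: int = 1,
    span: float = 0.7,
    robustness_iters: int = 2,
    correct_bias: bool = True,
    artifact_drop: float = 0.05,
) -> pd.DataFrame:
    """Vmax per well with positional-bias correction, averaged per segregant.

    Raw Vmax is the maximum slope over a sliding window of ``smoothing_window``
    reading intervals.  Positional bias is removed per plate by a robust
    locally weighted regression of Vmax on (row, column); the raw fitted
    surface is divided out, so corrected values are *relative* (normalised)
    growth rates and any constant bias cancels exactly.  The plate mean of the
    fitted surface is recorded per well.  Wells with gross non-monotone
    artifacts (an OD drop larger than ``artifact_drop``) are flagged, not
    dropped.

    Returns a well-level table; the per-segregant growth rate is the mean of
    corrected replicate values (column ``vmax_corrected`` grouped by
    ``segregant``; see :func:`growth_rate_per_segregant`).
    """
    od = curves.od
    if od.shape[1] < smoothing_window + 1:
        raise ValueError("need at least smoothing_window+1 time points")
    dt = curves.times[1] - curves.times[0]
    w = smoothing_window
    slopes = (od[:, w:] - od[:, :-w]) / (w * dt)
    vmax = slopes.max(axis=1)
    artifact = (np.diff(od, axis=1).min(axis=1) < -artifact_drop)
    if artifact.any():
        warnings.warn(f"{int(artifact.sum())} wells show non-monotone OD artifacts")

    tab = curves.wells.copy()
    tab["vmax_raw"] = vmax
    tab["artifact"] = artifact
    if correct_bias:
        factor = np.ones(len(tab))
        plate_mean = np.ones(len(tab))
        for plate, idx in tab.groupby("plate").groups.items():
            idx = np.asarray(idx)
            fit = loess_2d(tab.loc[idx, "row"].to_numpy(float),
                           tab.loc[idx, "column"].to_numpy(float),
                           vmax[idx], span=span,
                           robustness_iters=robustness_iters)
            factor[idx] = fit
            plate_mean[idx] = fit.mean()
        tab["bias_factor"] = factor
        tab["plate_mean_vmax"] = plate_mean
        tab["vmax_corrected"] = vmax / factor
    else:
        tab["bias_factor"] = 1.0
        tab["plate_mean_vmax"] = vmax.mean()
        tab["vmax_corrected"] = vmax
    return tab


def growth_rate_per_segregant(well_table: pd.DataFrame) -> pd.Series:
    """Mean bias-corrected Vmax per segregant (the fitness estimate)."""
    return well_table.groupby("segregant")["vmax_corrected"].mean()
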