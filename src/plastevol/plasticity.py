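"""Degree of plasticity and its hierarchical bootstrap inference.

A line's degree of plasticity on a given assay day is the Euclidean
distance between the multivariate means of its bead-corrected cell
morphologies (FSC, SSC, Red-B, log-scale units) at low (0.8 M) and high
(4.0 M) salinity.  Evolution of plasticity is tested by regressing this
distance, across the fluctuating-regime lines, on the environmental
predictability rho^2 each line experienced.

Significance is assessed by a hierarchical nonparametric bootstrap that
mirrors the nesting of the data: lines are resampled with replacement
among the lines, then within each drawn line and salinity a fixed number
of cells (n = 150) is resampled with replacement; distances and the
regression slope are recomputed, the whole process iterated B = 1000
times.  The one-sided p-value reported is the proportion of replicate
slopes <= 0, so that small p supports a positive slope (higher plasticity
under higher predictability).  Lines with fewer than n cells are upsampled
with replacement, which is what a fixed resampling size forces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import CORRECTED

LOW_SALINITY = 0.8
HIGH_SALINITY = 4.0


@dataclass
class PlasticityRecord:
    line_id: str
    day: int
    distance: float
    se: float = np.nan


@dataclass
class BootstrapResult:
    """Observed regression and its bootstrap slope distribution."""

    slope_obs: float
    intercept_obs: float
    r2_obs: float
    slopes: np.ndarray
    p_one_sided: float  # proportion of replicate slopes <= 0
    B: int
    seed: int | None
    day: int | None = None
    distances: pd.DataFrame | None = None  # per-line observed distance + bootstrap SE
    degenerate: bool = False

    @property
    def slope_se(self) -> float:
        return float(np.std(self.slopes, ddof=1)) if len(self.slopes) > 1 else np.nan


@dataclass
class GroupComparison:
    difference: float  # mean distance of group A minus group B
    p_two_sided: float
    diffs: np.ndarray
    B: int


def plasticity_distance(low_cells, high_cells) -> float:
    """Euclidean distance between low- and high-salinity mean morphologies."""
    low = np.asarray(low_cells, float)
    high = np.asarray(high_cells, float)
    if low.size == 0 or high.size == 0:
        raise ValueError("both cell sets must be nonempty")
    return float(np.linalg.norm(high.mean(axis=0) - low.mean(axis=0)))


def _ols(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS: slope, intercept, r^2."""
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in the predictor")
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = ((y - ym) ** 2).sum()
    r2 = 0.0 if syy == 0 else float(sxy**2 / (sxx * syy))
    return float(slope), float(intercept), r2


def _rowwise_slopes(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS slope of each row of Y on the matching row of X."""
    xm = X.mean(axis=1, keepdims=True)
    ym = Y.mean(axis=1, keepdims=True)
    sxx = ((X - xm) ** 2).sum(axis=1)
    sxy = ((X - xm) * (Y - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sxx > 0, sxy / sxx, np.nan)


def _cells_by_line(cells: pd.DataFrame, lines, day: int, value_cols):
    """dict (line, salinity) -> (n_i, k) array of cell morphologies."""
    sel = cells.loc[cells["day"] == day]
    out = {}
    for line in lines:
        for sal in (LOW_SALINITY, HIGH_SALINITY):
            sub = sel.loc[
                (sel["line_id"] == line) & np.isclose(sel["salinity_M"], sal), value_cols
            ].to_numpy(float)
            if len(sub) == 0:
                raise ValueError(f"line {line!r} has no cells at {sal} M on day {day}")
            out[(line, sal)] = sub
    return out


def line_distances(cells: pd.DataFrame, lines, day: int, value_cols=CORRECTED) -> pd.DataFrame:
    """Observed per-line distance between salinity means on one day."""
    value_cols = list(value_cols)
    arrs = _cells_by_line(cells, lines, day, value_cols)
    rows = [
        {
            "line_id": line,
            "day": day,
            "distance": plasticity_distance(arrs[(line, LOW_SALINITY)], arrs[(line, HIGH_SALINITY)]),
        }
        for line in lines
    ]
    return pd.DataFrame(rows)


def regress_on_predictability(records: pd.DataFrame, design: pd.DataFrame):
    """OLS of distance on rho^2 across fluctuating lines.

    ``records`` has columns ``line_id, distance``; ``design`` columns
    ``line_id, regime, predictability``.  Constant-regime lines are
    excluded (rho^2 undefined for them).  Returns (slope, intercept, r2).
    """
    merged = records.merge(design[["line_id", "regime", "predictability"]], on="line_id")
    fl = merged.loc[merged["regime"] == "fluctuating"]
    if len(fl) < 3 or fl["predictability"].nunique() < 2:
        raise ValueError("need >= 3 fluctuating lines with distinct predictability")
    return _ols(fl["predictability"].to_numpy(float), fl["distance"].to_numpy(float))


def hierarchical_bootstrap(
    cells: pd.DataFrame,
    design: pd.DataFrame,
    day: int,
    B: int = 1000,
    n_cells: int = 150,
    seed: int | None = None,
    value_cols=CORRECTED,
) -> BootstrapResult:
    """Nested bootstrap of the distance-vs-predictability regression.

    Each replicate draws the fluctuating lines with replacement, then
    ``n_cells`` cells with replacement per drawn line and salinity,
    recomputes the per-line distances and refits the OLS slope on rho^2.
    """
    value_cols = list(value_cols)
    fl = design.loc[design["regime"] == "fluctuating"]
    lines = fl["line_id"].to_numpy()
    rho2 = fl["predictability"].to_numpy(float)
    n_lines = len(lines)
    if n_lines < 3:
        raise ValueError("need >= 3 fluctuating lines")
    arrs = _cells_by_line(cells, lines, day, value_cols)

    d_obs = np.array(
        [
            plasticity_distance(arrs[(l, LOW_SALINITY)], arrs[(l, HIGH_SALINITY)])
            for l in lines
        ]
    )
    slope_obs, intercept_obs, r2_obs = _ols(rho2, d_obs)

    rng = np.random.default_rng(seed)
    L = rng.integers(0, n_lines, size=(B, n_lines))
    k = len(value_cols)
    means = np.empty((B, n_lines, 2, k))
    for i, line in enumerate(lines):
        mask = L == i
        m = int(mask.sum())
        if m == 0:
            continue
        for j, sal in enumerate((LOW_SALINITY, HIGH_SALINITY)):
            X = arrs[(line, sal)]
            idx = rng.integers(0, len(X), size=(m, n_cells))
            means[mask, j, :] = X[idx].mean(axis=1)
    d = np.linalg.norm(means[:, :, 1, :] - means[:, :, 0, :], axis=-1)  # (B, n_lines)
    slopes = _rowwise_slopes(rho2[L], d)
    degenerate = bool(len(slopes) > 1 and np.nanstd(slopes) == 0)
    if degenerate:
        warnings.warn("bootstrap slope distribution is degenerate (zero spread)")
    p_one = float(np.mean(slopes[np.isfinite(slopes)] <= 0.0))

    se = np.array([np.std(d[L == i], ddof=1) if (L == i).sum() > 1 else np.nan
                   for i in range(n_lines)])
    dist = pd.DataFrame({"line_id": lines, "day": day, "distance": d_obs, "se": se})
    return BootstrapResult(slope_obs, intercept_obs, r2_obs, slopes, p_one, B, seed,
                           day=day, distances=dist, degenerate=degenerate)


def slope_profile_by_day(
    cells: pd.DataFrame,
    design: pd.DataFrame,
    days=range(1, 11),
    B: int = 1000,
    n_cells: int = 150,
    seed: int | None = None,
    value_cols=CORRECTED,
) -> dict[int, BootstrapResult]:
    """The hierarchical bootstrap applied independently to each assay day."""
    ss = np.random.SeedSequence(seed)
    out = {}
    for day in days:
        child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        out[day] = hierarchical_bootstrap(
            cells, design, day, B=B, n_cells=n_cells, seed=child, value_cols=value_cols
        )
    return out


def profile_frame(profile: dict[int, BootstrapResult]) -> pd.DataFrame:
    """Per-day regression table (day, slope, intercept, r2, p_one_sided)."""
    return pd.DataFrame(
        {
            "day": list(profile),
            "slope": [r.slope_obs for r in profile.values()],
            "slope_se": [r.slope_se for r in profile.values()],
            "slope_boot_mean": [float(np.nanmean(r.slopes)) for r in profile.values()],
            "intercept": [r.intercept_obs for r in profile.values()],
            "r2": [r.r2_obs for r in profile.values()],
            "p_one_sided": [r.p_one_sided for r in profile.values()],
        }
    )


def compare_groups(
    cells: pd.DataFrame,
    design: pd.DataFrame,
    group_a,
    group_b,
    day: int,
    B: int = 1000,
    n_cells: int = 150,
    seed: int | None = None,
    value_cols=CORRECTED,
) -> GroupComparison:
    """Two-sided bootstrap comparison of mean plasticity between line sets.

    Resamples lines within each group, then cells within drawn lines, as
    in :func:`hierarchical_bootstrap`; the statistic is the difference of
    group mean distances (A minus B).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    value_cols = list(value_cols)
    rng = np.random.default_rng(seed)

    def group_stats(lines):
        arrs = _cells_by_line(cells, lines, day, value_cols)
        d_obs = np.array(
            [plasticity_distance(arrs[(l, LOW_SALINITY)], arrs[(l, HIGH_SALINITY)]) for l in lines]
        )
        n = len(lines)
        L = rng.integers(0, n, size=(B, n))
        k = len(value_cols)
        means = np.empty((B, n, 2, k))
        for i, line in enumerate(lines):
            mask = L == i
            m = int(mask.sum())
            if m == 0:
                continue
            for j, sal in enumerate((LOW_SALINITY, HIGH_SALINITY)):
                X = arrs[(line, sal)]
                idx = rng.integers(0, len(X), size=(m, n_cells))
                means[mask, j, :] = X[idx].mean(axis=1)
        d = np.linalg.norm(means[:, :, 1, :] - means[:, :, 0, :], axis=-1)
        return float(d_obs.mean()), d.mean(axis=1)

    mean_a, boot_a = group_stats(group_a)
    mean_b, boot_b = group_stats(group_b)
    diffs = boot_a - boot_b
    frac_le = float(np.mean(diffs <= 0))
    frac_ge = float(np.mean(diffs >= 0))
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return GroupComparison(mean_a - mean_b, p, diffs, B)
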