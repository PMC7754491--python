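"""Batch-culture growth rates and growth-phase labels.

The per-capita growth rate per day is the discrete relative change in
population density, r_t = (N_t - N_{t-1}) / N_{t-1}.  Days on which r is
highest form the exponential phase; slower positive growth before and after
it is labelled lag and stationary respectively.  The verbal definition is
operationalised as: the exponential phase is the contiguous block of days
around the (earliest) maximal rate whose rates are at least a fraction
``f`` (default 0.8) of the maximum.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PHASES = ("lag", "exponential", "stationary")


def per_capita_growth(densities) -> np.ndarray:
    """Daily per-capita growth rates from a density series.

    ``rates[t-1]`` corresponds to day ``t`` (1-based); a rate is NaN
    (flagged with a warning) wherever the previous density is zero.
    """
    n = np.asarray(densities, float)
    if np.any(n < 0):
        raise ValueError("densities must be >= 0")
    prev, cur = n[:-1], n[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = (cur - prev) / prev
    rates = np.where(prev == 0, np.nan, rates)
    if np.any(prev == 0):
        warnings.warn("zero density encountered; growth rate undefined on those days")
    return rates


def classify_phases(rates, f: float = 0.8) -> list[str]:
    """Label each day's rate as lag, exponential or stationary.

    The exponential block is the maximal contiguous run of days with
    ``rate >= f * max(rate)`` that contains the earliest maximum.  Days
    before the block are lag, days after are stationary.  If no rate is
    positive, every day is stationary (with a warning).
    """
    r = np.asarray(rates, float)
    if len(r) < 3:
        raise ValueError("need at least 3 rates to classify phases")
    if not (0.0 < f <= 1.0):
        raise ValueError("f must be in (0, 1]")
    finite = np.isfinite(r)
    if not finite.any() or np.nanmax(r) <= 0:
        warnings.warn("no positive growth rate; all days labelled stationary")
        return ["stationary"] * len(r)
    rmax = np.nanmax(r)
    peak = int(np.nanargmax(r))  # earliest maximum wins ties
    above = finite & (r >= f * rmax)
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak
    while end < len(r) - 1 and above[end + 1]:
        end += 1
    labels = []
    for i in range(len(r)):
        if i < start:
            labels.append("lag")
        elif i <= end:
            labels.append("exponential")
        else:
            labels.append("stationary")
    return labels


def growth_table(densities: pd.DataFrame, f: float = 0.8) -> pd.DataFrame:
    """Add per-capita rate and phase columns to a long density table.

    ``densities`` must have columns ``line_id, salinity_M, day,
    cells_per_ml``; rates and phases are computed within each
    (line, salinity) series ordered by day.  Day 0 (pre-transfer) has no
    rate and is labelled lag.
    """
    required = {"line_id", "salinity_M", "day", "cells_per_ml"}
    missing = required - set(densities.columns)
    if missing:
        raise ValueError(f"density table missing columns: {sorted(missing)}")
    out = []
    for (line, sal), grp in densities.groupby(["line_id", "salinity_M"], sort=True):
        grp = grp.sort_values("day").copy()
        rates = per_capita_growth(grp["cells_per_ml"].to_numpy())
        phases = classify_phases(rates, f=f)
        grp["r"] = np.concatenate([[np.nan], rates])
        grp["phase"] = ["lag"] + phases
        out.append(grp)
    return pd.concat(out, ignore_index=True)
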