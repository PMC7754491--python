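"""Stochastic salinity environments for experimental evolution.

Each selection line experiences a salinity time series generated by a
stationary first-order autoregressive (AR1) process.  All treatments share
the same long-term mean ``mu`` and standard deviation ``sigma`` of salinity
and differ only in the lag-1 autocorrelation ``rho``, so that the
*predictability* of the environment -- the proportion of temporal variance
in salinity explained by the previous salinity -- equals ``rho**2``.
Treatments with rho = -0.5 and rho = +0.5 therefore have identical
predictability (0.25) but opposite patterns of change.

The module also translates a target salinity series into the bench recipe
used at each twice-weekly transfer: a fixed fraction of the culture is
retained and diluted into fresh medium mixed from a hypo-saline (0 M NaCl)
and a hyper-saline (4.8 M NaCl) stock.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

#: Salinity of the hypo-saline stock medium (M NaCl).
HYPO_STOCK = 0.0
#: Salinity of the hyper-saline stock medium (M NaCl).
HYPER_STOCK = 4.8

#: The four fluctuating-treatment target autocorrelations.
TREATMENT_RHOS = (-0.5, 0.0, 0.5, 0.9)


class DegenerateSeriesError(ValueError):
    """Raised when a statistic is requested on a zero-variance series."""


@dataclass(frozen=True)
class AR1Params:
    """Parameters of a stationary AR1 salinity process.

    Parameters
    ----------
    mu : float
        Stationary mean salinity (M NaCl).
    sigma : float
        Stationary standard deviation of salinity (M NaCl).
    rho : float
        Lag-1 autocorrelation, in (-1, 1).
    n_transfers : int
        Number of transfers (series length), >= 2.
    seed : int or None
        Seed for reproducible generation.
    """

    mu: float = 2.4
    sigma: float = 1.0
    rho: float = 0.0
    n_transfers: int = 139
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_transfers < 2:
            raise ValueError(f"n_transfers must be >= 2, got {self.n_transfers}")


@dataclass
class SalinitySeries:
    """One line's salinity trajectory across transfers.

    ``realized_rho`` is the sample lag-1 Pearson correlation of the series
    and ``predictability`` its square; both are NaN for a degenerate
    (zero-variance) series.
    """

    values: np.ndarray
    treatment_label: str
    realized_rho: float
    predictability: float
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TransferRecipe:
    """Volumes of stock media realizing one salinity transfer."""

    retained_fraction: float
    fresh_volume: float
    v_hypo: float
    v_hyper: float
    medium_salinity: float
    achieved_salinity: float
    feasible: bool


def simulate_ar1(params: AR1Params, treatment_label: str | None = None) -> SalinitySeries:
    """Simulate a stationary AR1 salinity series.

    The first value is drawn from the stationary distribution
    N(mu, sigma^2); subsequent values follow
    ``x[t+1] = mu + rho * (x[t] - mu) + eps`` with innovation variance
    ``sigma^2 * (1 - rho^2)``, so every treatment shares the same
    stationary variance.  The series is returned unclipped; physical
    feasibility is the business of :func:`transfer_recipe`.
    """
    rng = np.random.default_rng(params.seed)
    label = treatment_label if treatment_label is not None else format(params.rho, "g")
    n = params.n_transfers
    if params.sigma == 0.0:
        values = np.full(n, params.mu)
        return SalinitySeries(values, label, np.nan, np.nan, degenerate=True)
    d0 = params.sigma * rng.standard_normal()
    innov_sd = params.sigma * np.sqrt(1.0 - params.rho**2)
    eps = innov_sd * rng.standard_normal(n - 1)
    # deviations d[t] = rho d[t-1] + eps[t] via an IIR filter
    dev, _ = signal.lfilter([1.0], [1.0, -params.rho], eps, zi=[params.rho * d0])
    values = params.mu + np.concatenate([[d0], dev])
    rho_hat = realized_autocorrelation(values)
    return SalinitySeries(values, label, rho_hat, rho_hat**2)


def realized_autocorrelation(series: SalinitySeries | np.ndarray) -> float:
    """Pearson correlation between salinities at consecutive transfers."""
    values = np.asarray(series.values if isinstance(series, SalinitySeries) else series, float)
    if len(values) < 3:
        raise DegenerateSeriesError("need at least 3 values for a lag-1 correlation")
    a, b = values[:-1], values[1:]
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise DegenerateSeriesError("zero variance in a lagged subseries")
    return float(stats.pearsonr(a, b).statistic)


def predictability(rho: float) -> float:
    """Environmental predictability: the squared lag-1 autocorrelation."""
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    return float(rho) ** 2


def transfer_recipe(
    s_pre: float,
    s_target: float,
    retained_fraction: float = 0.2,
    fresh_volume: float = 800.0,
) -> TransferRecipe:
    """Stock-mixing recipe achieving ``s_target`` after a serial transfer.

    A fraction ``retained_fraction`` of the total post-transfer volume is
    carried-over culture at salinity ``s_pre``; the rest is ``fresh_volume``
    ul of medium mixed from the 0 M and 4.8 M stocks.  If the required
    medium salinity falls outside the stock range it is clamped to the
    nearest bound, the achieved salinity recomputed, and the recipe flagged
    infeasible.
    """
    if s_pre < 0:
        raise ValueError(f"pre-transfer salinity must be >= 0, got {s_pre}")
    if not (0.0 < retained_fraction < 1.0):
        raise ValueError("retained_fraction must be in (0, 1)")
    f = retained_fraction
    medium = (s_target - f * s_pre) / (1.0 - f)
    feasible = True
    if medium < HYPO_STOCK or medium > HYPER_STOCK:
        medium = min(max(medium, HYPO_STOCK), HYPER_STOCK)
        feasible = False
    v_hyper = fresh_volume * medium / HYPER_STOCK
    v_hypo = fresh_volume - v_hyper
    achieved = f * s_pre + (1.0 - f) * medium
    return TransferRecipe(f, fresh_volume, v_hypo, v_hyper, medium, achieved, feasible)


def series_recipes(series, retained_fraction: float = 0.2, fresh_volume: float = 800.0):
    """Per-transfer recipe table for a salinity series.

    Returns a :class:`pandas.DataFrame` with columns ``transfer_index,
    salinity_M, v_hypo_ul, v_hyper_ul, feasible``.  The first row is the
    initial salinity (no transfer, volumes NaN).  ``salinity_M`` is the
    *achieved* salinity: each transfer targets the raw series value but
    starts from the previously achieved state, so out-of-range targets are
    clamped to what the stocks allow and flagged infeasible.
    """
    import pandas as pd

    values = np.asarray(series.values if isinstance(series, SalinitySeries) else series, float)
    achieved = float(np.clip(values[0], HYPO_STOCK, HYPER_STOCK))
    rows = [
        {
            "transfer_index": 0,
            "salinity_M": achieved,
            "v_hypo_ul": np.nan,
            "v_hyper_ul": np.nan,
            "feasible": bool(achieved == values[0]),
        }
    ]
    for t in range(1, len(values)):
        rec = transfer_recipe(achieved, values[t], retained_fraction, fresh_volume)
        achieved = rec.achieved_salinity
        rows.append(
            {
                "transfer_index": t,
                "salinity_M": rec.achieved_salinity,
                "v_hypo_ul": rec.v_hypo,
                "v_hyper_ul": rec.v_hyper,
                "feasible": rec.feasible,
            }
        )
    return pd.DataFrame(rows)
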