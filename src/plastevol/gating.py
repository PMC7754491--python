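"""Cytometry event gating, bead correction, subsampling and densities.

Raw list-mode events (log-scale channel values) are reduced to
bead-corrected morphology vectors for alive singlet cells:

1. ``gate_alive`` -- keep events with high chlorophyll autofluorescence
   (Red-B above a floor and sufficiently above Yellow-B), excluding dead
   cells and debris;
2. ``remove_doublets`` -- keep events whose pulse width (FSC-W) is below a
   cut-off;
3. ``bead_correct`` -- subtract, per channel, the mean of calibration
   beads measured in medium at the same salinity, removing the
   medium-density optical effect;
4. ``subsample_events`` -- draw up to a fixed number of events per
   condition for a balanced design.

The instrument's visual cytogram gate is formalised here as two log-scale
thresholds; the default values are calibrated on the synthetic generator
(not taken from any instrument) and are explicit configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CHANNELS = ("fsc", "ssc", "red_b")
CORRECTED = ("fsc_c", "ssc_c", "red_b_c")


@dataclass(frozen=True)
class GateThresholds:
    """Alive/singlet gate: log-scale channel thresholds."""

    min_red: float = 4.5
    min_red_minus_yellow: float = 1.0
    fsc_w_max: float = 3.0


def gate_alive(
    events: pd.DataFrame,
    min_red: float = GateThresholds.min_red,
    min_red_minus_yellow: float = GateThresholds.min_red_minus_yellow,
) -> pd.DataFrame:
    """Retain events gated alive on the Red-B / Yellow-B cytogram."""
    if events.empty:
        warnings.warn("gate_alive called on an empty event table")
        return events.copy()
    keep = (events["red_b"] >= min_red) & (
        events["red_b"] - events["yellow_b"] >= min_red_minus_yellow
    )
    out = events.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("no events passed the alive gate")
    return out


def remove_doublets(events: pd.DataFrame, fsc_w_max: float = GateThresholds.fsc_w_max) -> pd.DataFrame:
    """Retain singlet events (pulse width at or below the cut-off)."""
    if not np.isfinite(fsc_w_max):
        if fsc_w_max > 0:  # +inf keeps everything
            return events.copy()
        raise ValueError("fsc_w_max must be finite or +inf")
    if events.empty:
        return events.copy()
    out = events.loc[events["fsc_w"] <= fsc_w_max].reset_index(drop=True)
    if out.empty:
        warnings.warn("no events below the doublet cut-off")
    return out


def retention_fraction(before: pd.DataFrame, after: pd.DataFrame) -> float:
    """Fraction of events retained by a gating step."""
    return len(after) / len(before) if len(before) else float("nan")


def bead_correct(events: pd.DataFrame, beads: pd.DataFrame) -> pd.DataFrame:
    """Subtract salinity-matched bead channel means from each event.

    ``beads`` must contain rows for the (single) salinity of ``events``.
    Returns a frame with corrected channels ``fsc_c, ssc_c, red_b_c``
    alongside the condition metadata.
    """
    if beads.empty:
        raise ValueError("bead table is empty")
    sals = events["salinity_M"].unique()
    if len(sals) != 1:
        raise ValueError("bead_correct expects a single-salinity event table; "
                         "use bead_correct_table for mixed tables")
    sal = sals[0]
    bsel = beads.loc[np.isclose(beads["salinity_M"], sal)]
    if bsel.empty:
        raise ValueError(f"no beads measured at salinity {sal} M")
    means = bsel[list(CHANNELS)].mean()
    out = events[["line_id", "salinity_M", "day"]].copy()
    for raw, cor in zip(CHANNELS, CORRECTED):
        out[cor] = events[raw].to_numpy() - means[raw]
    return out.reset_index(drop=True)


def bead_correct_table(events: pd.DataFrame, beads: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`bead_correct` per assay salinity of a mixed table."""
    parts = [
        bead_correct(grp, beads)
        for _, grp in events.groupby("salinity_M", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def subsample_events(events: pd.DataFrame, cap: int = 150, seed: int | None = None) -> pd.DataFrame:
    """Uniform subsample without replacement of up to ``cap`` events."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(events) <= cap:
        return events.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(events), size=cap, replace=False)
    return events.iloc[np.sort(idx)].reset_index(drop=True)


def subsample_by_condition(
    events: pd.DataFrame,
    cap: int = 150,
    seed: int | None = None,
    by=("line_id", "salinity_M", "day"),
) -> pd.DataFrame:
    """Balanced design: subsample each condition independently."""
    ss = np.random.SeedSequence(seed)
    parts = []
    for _, grp in events.groupby(list(by), sort=True):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        parts.append(subsample_events(grp, cap=cap, seed=sub_seed))
    return pd.concat(parts, ignore_index=True)


def estimate_density(n_alive: int, acquisition_volume_ul: float = 35.4) -> float:
    """Population density (cells/ml) from an alive-event count.

    The default acquisition volume corresponds to 30 s at 1.18 ul/s.
    """
    if acquisition_volume_ul <= 0:
        raise ValueError("acquisition volume must be > 0")
    if n_alive < 0:
        raise ValueError("count must be >= 0")
    return n_alive / (acquisition_volume_ul / 1000.0)


def read_events(path) -> pd.DataFrame:
    """Read the standard event CSV (header line_id,salinity_M,day,fsc,...)."""
    df = pd.read_csv(path)
    missing = {"line_id", "salinity_M", "day", "fsc", "ssc", "red_b", "yellow_b", "fsc_w"} - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    return df


def read_beads(path) -> pd.DataFrame:
    """Read the bead CSV (header salinity_M,fsc,ssc,red_b)."""
    df = pd.read_csv(path)
    missing = {"salinity_M", "fsc", "ssc", "red_b"} - set(df.columns)
    if missing:
        raise ValueError(f"bead CSV missing columns: {sorted(missing)}")
    return df
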