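"""Synthetic flow-cytometry study generator.

Emulates the structure of a salinity-plasticity selection experiment on the
halotolerant microalga *Dunaliella salina*: 32 lines evolved under randomly
fluctuating salinity (four AR1 autocorrelation treatments) plus 4 lines
evolved at constant 2.4 M, founded from two ancestral strains.  Each line
is assayed over an 11-day time course (day 0 = end of acclimation) at up to
three salinities; a cytometer records per-event FSC, SSC, Red-B, Yellow-B
and FSC-W on a logarithmic scale.

The generator encodes, by construction, the statistical structure the
downstream analysis is meant to detect:

* alive singlet cells have a 3-channel morphology (FSC, SSC, Red-B) whose
  mean separates between low and high assay salinity along a fixed
  size/chlorophyll axis, with magnitude ``a + b * rho^2`` for a line with
  realized predictability rho^2 -- so the expected Euclidean distance
  between salinity means on a given day is
  ``(a + b * rho^2) * phase_gain[phase(day)] * ||salinity_effect||``;
* a day-indexed loop-shaped ontogenic offset shared by all conditions;
* plasticity damped during the exponential growth phase (``phase_gain``);
* contaminating debris, dead cells (low chlorophyll, i.e. low Red-B
  relative to Yellow-B) and doublets (high FSC-W);
* a salinity-dependent optical offset on all channels, shared with the
  calibration beads so that bead correction cancels it.

Defaults give unit-norm ``salinity_effect`` so that the expected distance
on an undamped day is exactly ``a + b * rho^2`` log-units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth as growth_mod
from .environment import AR1Params, SalinitySeries, simulate_ar1

#: Target autocorrelations of the four fluctuating treatments.
TREATMENTS = (-0.5, 0.0, 0.5, 0.9)
#: Assay salinities (M NaCl): low / acclimation / high.
ASSAY_SALINITIES = (0.8, 2.4, 4.0)
LOW_SALINITY, MID_SALINITY, HIGH_SALINITY = ASSAY_SALINITIES

EVENT_COLUMNS = ["line_id", "salinity_M", "day", "fsc", "ssc", "red_b", "yellow_b", "fsc_w"]


@dataclass
class LineMeta:
    """Metadata of one evolved line."""

    line_id: str
    strain: str  # "A" or "B"
    regime: str  # "fluctuating" or "constant"
    treatment_rho_bar: float | None
    realized_rho: float
    predictability: float
    isogenic: bool = False


@dataclass
class GeneratorParams:
    """Free parameters of the synthetic study.

    Channel units are log-scale cytometer units throughout.  ``bead_offsets``
    are the salinity-dependent medium-density optical shifts applied both to
    cell events and to calibration beads; ``bead_base`` is the intrinsic
    bead brightness (common to all salinities).
    """

    baseline_mean: tuple[float, float, float] = (5.0, 4.5, 6.2)  # FSC, SSC, Red-B
    #: Unit-norm direction of the plastic response: high salinity makes
    #: cells smaller (lower FSC) with less chlorophyll (lower Red-B).
    salinity_effect: tuple[float, float, float] = (-0.6, 0.0, -0.8)
    plasticity_intercept: float = 0.5  # a
    plasticity_slope: float = 2.0  # b, per unit rho^2
    #: Between-line biological scatter of the plasticity magnitude around
    #: the a + b * rho^2 trend (lines are independently evolved genotypes;
    #: their scatter dominates cell-sampling noise, as in the assay data).
    line_effect_sd: float = 0.12
    #: Effective predictability assigned to constant-regime lines
    #: (their plasticity matches high-predictability lines).
    constant_line_rho2: float = 0.7
    #: Loop-shaped ontogeny: offset(day) = amp1*sin(pi d/10)*u1 + amp2*sin(2 pi d/10)*u2.
    ontogeny_amp1: float = 0.8
    ontogeny_amp2: float = 0.4
    ontogeny_u1: tuple[float, float, float] = (0.89, 0.45, 0.0)
    ontogeny_u2: tuple[float, float, float] = (0.0, 0.45, 0.89)
    phase_gain: dict = field(
        default_factory=lambda: {"lag": 1.0, "exponential": 0.3, "stationary": 1.0}
    )
    within_cell_sd: tuple[float, float, float] = (0.3, 0.3, 0.3)
    debris_fraction: float = 0.05
    dead_fraction: float = 0.05
    doublet_fraction: float = 0.05
    #: Yellow-B means: alive cells have high Red-B relative to Yellow-B.
    yellow_alive: float = 3.0
    red_dead: float = 2.0
    red_debris: float = 1.5
    contaminant_sd: float = 0.4
    fsc_w_singlet: float = 2.0
    fsc_w_doublet: float = 4.0
    fsc_w_sd: float = 0.25
    bead_base: tuple[float, float, float] = (2.0, 2.0, 1.5)
    bead_offsets: dict = field(
        default_factory=lambda: {
            0.8: (0.10, 0.05, 0.02),
            2.4: (0.20, 0.10, 0.05),
            4.0: (0.30, 0.16, 0.08),
        }
    )
    bead_sd: float = 0.05
    # logistic growth of the assay cultures
    r_max: float = 1.2
    carrying_capacity: float = 1.0e6
    n0: float = 2.0e4  # inoculation density, cells/ml
    growth_lag_days: float = 2.0
    growth_noise_sd: float = 0.05
    acquisition_volume_ul: float = 35.4  # 1.18 ul/s for 30 s
    #: Fraction of cells in the acquired volume actually recorded as events.
    detection_efficiency: float = 0.25
    max_events: int = 5000
    min_events: int = 40

    def __post_init__(self) -> None:
        fr = (self.debris_fraction, self.dead_fraction, self.doublet_fraction)
        if any(f < 0 or f >= 1 for f in fr) or sum(fr) >= 1:
            raise ValueError("contaminant fractions must be in [0,1) and sum < 1")
        if any(g < 0 for g in self.phase_gain.values()):
            raise ValueError("phase_gain must be >= 0")

    def ontogeny_offset(self, day: int) -> np.ndarray:
        t = np.pi * day / 10.0
        u1 = np.asarray(self.ontogeny_u1)
        u2 = np.asarray(self.ontogeny_u2)
        return self.ontogeny_amp1 * np.sin(t) * u1 + self.ontogeny_amp2 * np.sin(2 * t) * u2

    def phase_by_day(self) -> dict[int, str]:
        """Growth phase of each assay day from the noiseless growth curve."""
        dens = generate_growth_curve(self, days=np.arange(11), noise_sd=0.0)
        rates = growth_mod.per_capita_growth(dens)
        labels = growth_mod.classify_phases(rates)
        out = {0: "lag"}
        out.update({d: labels[d - 1] for d in range(1, 11)})
        return out


def generate_design(
    n_fluct: int = 32,
    n_const: int = 4,
    seed: int | None = None,
    n_transfers: int = 139,
) -> list[LineMeta]:
    """Assign lines evenly to treatments and strains.

    Every fluctuating line is paired with its own simulated AR1 salinity
    series, from which the realized autocorrelation and predictability are
    computed -- yielding a continuum of rho^2 values around the treatment
    targets.  Constant-regime lines have no autocorrelation treatment and
    NaN predictability.
    """
    if n_fluct % len(TREATMENTS) != 0:
        raise ValueError(f"n_fluct must be divisible by {len(TREATMENTS)}")
    ss = np.random.SeedSequence(seed)
    per_treatment = n_fluct // len(TREATMENTS)
    lines: list[LineMeta] = []
    children = ss.spawn(n_fluct)
    i = 0
    for rho_bar in TREATMENTS:
        for j in range(per_treatment):
            child_seed = int(children[i].generate_state(1)[0] % 2**31)
            series = simulate_ar1(
                AR1Params(rho=rho_bar, n_transfers=n_transfers, seed=child_seed)
            )
            lines.append(
                LineMeta(
                    line_id=f"F{i:02d}",
                    strain="A" if j < per_treatment / 2 else "B",
                    regime="fluctuating",
                    treatment_rho_bar=rho_bar,
                    realized_rho=series.realized_rho,
                    predictability=series.predictability,
                )
            )
            i += 1
    for k in range(n_const):
        lines.append(
            LineMeta(
                line_id=f"C{k:02d}",
                strain="A" if k < n_const / 2 else "B",
                regime="constant",
                treatment_rho_bar=None,
                realized_rho=np.nan,
                predictability=np.nan,
            )
        )
    return lines


def line_series(line_index: int, rho_bar: float, seed: int | None, n_transfers: int = 139) -> SalinitySeries:
    """Regenerate the salinity series of fluctuating line ``line_index``.

    Uses the same seed-spawning scheme as :func:`generate_design`, so the
    series matches the design generated from the same root seed.
    """
    children = np.random.SeedSequence(seed).spawn(line_index + 1)
    child_seed = int(children[line_index].generate_state(1)[0] % 2**31)
    return simulate_ar1(AR1Params(rho=rho_bar, n_transfers=n_transfers, seed=child_seed))


def design_frame(lines: list[LineMeta]) -> pd.DataFrame:
    """Design table: one row per line."""
    return pd.DataFrame(
        {
            "line_id": [l.line_id for l in lines],
            "strain": [l.strain for l in lines],
            "regime": [l.regime for l in lines],
            "rho_bar": [np.nan if l.treatment_rho_bar is None else l.treatment_rho_bar for l in lines],
            "realized_rho": [l.realized_rho for l in lines],
            "predictability": [l.predictability for l in lines],
        }
    )


def generate_growth_curve(
    params: GeneratorParams,
    days=None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Logistic density trajectory with an initial lag.

    N(t) = K N0 e^{r t'} / (K + N0 (e^{r t'} - 1)) with effective time
    t' = max(0, t - lag); multiplicative lognormal day-to-day noise of the
    given log-sd is applied to days > 0.  With ``growth_lag_days = 0`` this
    is the plain logistic closed form.
    """
    if params.n0 <= 0:
        raise ValueError("N0 must be > 0")
    if days is None:
        days = np.arange(11)
    days = np.asarray(days, float)
    sd = params.growth_noise_sd if noise_sd is None else noise_sd
    t_eff = np.maximum(0.0, days - params.growth_lag_days)
    k, n0 = params.carrying_capacity, params.n0
    e = np.exp(params.r_max * t_eff)
    dens = k * n0 * e / (k + n0 * (e - 1.0))
    if sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(sd * rng.standard_normal(len(days)))
        noise[days == 0] = 1.0
        dens = dens * noise
    return dens


def _effective_rho2(line: LineMeta, params: GeneratorParams) -> float:
    if line.regime == "constant":
        return params.constant_line_rho2
    return line.predictability


def expected_salinity_shift(line: LineMeta, day: int, params: GeneratorParams,
                            assay_salinity: float, phase_lookup: dict | None = None,
                            line_effect: float = 0.0) -> np.ndarray:
    """Expected 3-channel mean offset of alive singlets vs. the acclimated state.

    ``line_effect`` is the line's biological deviation from the
    ``a + b * rho^2`` plasticity trend (drawn per line in
    :func:`generate_study`).
    """
    if day == 0:
        return np.zeros(3)
    phases = phase_lookup if phase_lookup is not None else params.phase_by_day()
    gain = params.phase_gain[phases[day]]
    magnitude = max(
        0.0,
        params.plasticity_intercept
        + params.plasticity_slope * _effective_rho2(line, params)
        + line_effect,
    )
    direction = np.asarray(params.salinity_effect)
    return np.sign(assay_salinity - MID_SALINITY) * magnitude * gain * direction / 2.0


def generate_events(
    line: LineMeta,
    assay_salinity: float,
    day: int,
    n_events: int,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    keep_truth: bool = False,
    phase_lookup: dict | None = None,
    line_effect: float = 0.0,
) -> pd.DataFrame:
    """Generate one acquisition's event table.

    Events are a mixture of alive singlets, dead cells, debris and
    doublets; all channels are then shifted by the salinity-specific
    optical offset.  With ``keep_truth`` a ``true_class`` column records
    the mixture component of each event.
    """
    params = params or GeneratorParams()
    if assay_salinity not in params.bead_offsets:
        raise ValueError(f"unknown assay salinity {assay_salinity}")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)

    p_debris, p_dead, p_doub = params.debris_fraction, params.dead_fraction, params.doublet_fraction
    p_alive = 1.0 - p_debris - p_dead - p_doub
    counts = rng.multinomial(n_events, [p_alive, p_dead, p_debris, p_doub])
    n_alive, n_dead, n_debris, n_doub = counts

    base = np.asarray(params.baseline_mean)
    sd3 = np.asarray(params.within_cell_sd)
    alive_mean = base + params.ontogeny_offset(day) + expected_salinity_shift(
        line, day, params, assay_salinity, phase_lookup, line_effect
    )

    def alive_block(n):
        m = alive_mean + sd3 * rng.standard_normal((n, 3))
        yellow = params.yellow_alive + 0.3 * rng.standard_normal(n)
        return m, yellow

    frames = []
    if n_alive:
        m, yellow = alive_block(n_alive)
        fsc_w = params.fsc_w_singlet + params.fsc_w_sd * rng.standard_normal(n_alive)
        frames.append((m, yellow, fsc_w, "alive"))
    if n_dead:
        csd = params.contaminant_sd
        m = np.column_stack(
            [
                base[0] + csd * rng.standard_normal(n_dead),
                base[1] + csd * rng.standard_normal(n_dead),
                params.red_dead + csd * rng.standard_normal(n_dead),
            ]
        )
        yellow = params.yellow_alive + csd * rng.standard_normal(n_dead)
        fsc_w = params.fsc_w_singlet + params.fsc_w_sd * rng.standard_normal(n_dead)
        frames.append((m, yellow, fsc_w, "dead"))
    if n_debris:
        csd = params.contaminant_sd
        m = np.column_stack(
            [
                base[0] - 2.0 + csd * rng.standard_normal(n_debris),
                base[1] - 1.5 + csd * rng.standard_normal(n_debris),
                params.red_debris + csd * rng.standard_normal(n_debris),
            ]
        )
        yellow = params.yellow_alive - 0.5 + csd * rng.standard_normal(n_debris)
        fsc_w = params.fsc_w_singlet + params.fsc_w_sd * rng.standard_normal(n_debris)
        frames.append((m, yellow, fsc_w, "debris"))
    if n_doub:
        m, yellow = alive_block(n_doub)
        m[:, 0] += 0.3  # two cells scatter slightly more light
        fsc_w = params.fsc_w_doublet + params.fsc_w_sd * rng.standard_normal(n_doub)
        frames.append((m, yellow, fsc_w, "doublet"))

    morph = np.vstack([f[0] for f in frames])
    yellow_b = np.concatenate([f[1] for f in frames])
    fsc_w = np.concatenate([f[2] for f in frames])
    classes = np.concatenate([[f[3]] * len(f[1]) for f in frames])

    offset = np.asarray(params.bead_offsets[assay_salinity]) + np.asarray(params.bead_base)
    morph = morph + offset  # medium-density optical shift (beads carry the same)

    order = rng.permutation(len(morph))
    table = pd.DataFrame(
        {
            "line_id": line.line_id,
            "salinity_M": assay_salinity,
            "day": day,
            "fsc": morph[order, 0],
            "ssc": morph[order, 1],
            "red_b": morph[order, 2],
            "yellow_b": yellow_b[order],
            "fsc_w": fsc_w[order],
        }
    )
    if keep_truth:
        table["true_class"] = classes[order]
    return table


def generate_beads(
    assay_salinity: float,
    n_beads: int = 1000,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Calibration-bead table for one assay salinity.

    Bead channels are centred at the intrinsic bead brightness plus the
    same salinity-dependent optical offset applied to cell events, so
    subtracting bead means cancels the offset.
    """
    params = params or GeneratorParams()
    if assay_salinity not in params.bead_offsets:
        raise ValueError(f"unknown assay salinity {assay_salinity}")
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    rng = np.random.default_rng(seed)
    centre = np.asarray(params.bead_base) + np.asarray(params.bead_offsets[assay_salinity])
    draws = centre + params.bead_sd * rng.standard_normal((n_beads, 3))
    return pd.DataFrame(
        {
            "salinity_M": assay_salinity,
            "fsc": draws[:, 0],
            "ssc": draws[:, 1],
            "red_b": draws[:, 2],
        }
    )


def events_for_density(density: float, params: GeneratorParams) -> int:
    """Number of recorded events at a given culture density (cells/ml)."""
    vol_ml = params.acquisition_volume_ul / 1000.0
    n = int(round(density * vol_ml * params.detection_efficiency))
    return int(np.clip(n, params.min_events, params.max_events))


def generate_study(
    lines: list[LineMeta],
    params: GeneratorParams | None = None,
    days=range(11),
    salinities_fluct=(0.8, 2.4, 4.0),
    salinities_const=(0.8, 4.0),
    seed: int | None = None,
    n_events: int | None = None,
    keep_truth: bool = False,
):
    """Generate the full synthetic assay: events, beads and densities.

    Fluctuating lines are assayed at three salinities, constant lines at
    the two extremes (matching the factorial structure of the variation
    partitioning).  Event counts per condition track the (noisy) logistic
    density unless ``n_events`` fixes them.

    Returns ``(events, beads, densities)`` data frames; densities have
    columns ``line_id, salinity_M, day, cells_per_ml``.
    """
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    phase_lookup = params.phase_by_day()
    days = list(days)
    # biological deviation of each line's plasticity from the rho^2 trend,
    # one draw per line per study realization
    eff_rng = np.random.default_rng(ss.spawn(1)[0])
    effects = {l.line_id: params.line_effect_sd * eff_rng.standard_normal() for l in lines}
    ev_frames, dens_rows = [], []
    for li, line in enumerate(lines):
        sals = salinities_fluct if line.regime == "fluctuating" else salinities_const
        for sj, sal in enumerate(sals):
            gseed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            dens = generate_growth_curve(params, days=np.asarray(days, float), seed=gseed)
            for dk, day in enumerate(days):
                n = n_events if n_events is not None else events_for_density(dens[dk], params)
                eseed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                ev_frames.append(
                    generate_events(
                        line, sal, day, n, params, seed=eseed,
                        keep_truth=keep_truth, phase_lookup=phase_lookup,
                        line_effect=effects[line.line_id],
                    )
                )
                dens_rows.append(
                    {"line_id": line.line_id, "salinity_M": sal, "day": day, "cells_per_ml": dens[dk]}
                )
    bead_frames = []
    for sal in sorted({s for l in lines for s in (salinities_fluct if l.regime == "fluctuating" else salinities_const)}):
        bseed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        bead_frames.append(generate_beads(sal, 1000, params, seed=bseed))
    events = pd.concat(ev_frames, ignore_index=True)
    beads = pd.concat(bead_frames, ignore_index=True)
    densities = pd.DataFrame(dens_rows)
    return events, beads, densities
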