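# Methods

This note documents the models, parameter choices and numerical decisions
behind `plastevol`, and what its synthetic-data tests do and do not show
about real assay data.

## Environment model

Salinity regimes are stationary AR1 processes with shared mean
`mu = 2.4` M NaCl and standard deviation `sigma = 1` M.  We parameterise
the innovation variance as `sigma^2 (1 - rho^2)` so that every
autocorrelation treatment (`rho_bar` in −0.5, 0, 0.5, 0.9) has the same
*stationary* variance — treatments differ only in predictability
`rho^2`, not in long-run variability.  The first value is drawn from the
stationary distribution rather than pinned at `mu`, so sample moments of
finite series are unbiased.

Series are generated unbounded.  Physical feasibility — what a 20 %
serial transfer into 800 µl of medium mixed from 0 M and 4.8 M stocks can
actually reach — is enforced only when a series is turned into bench
recipes: an out-of-range required medium salinity is clamped to the
nearest stock bound, the achieved salinity recomputed from the mass
balance, and the transfer flagged infeasible.  Clamping at recipe time
(rather than truncating the process) keeps the statistical targets of the
simulation undistorted; in the recipe table each transfer starts from the
previously *achieved* salinity, so infeasible excursions decay rather
than accumulate.  Alternatives (redraw, reflect) would change the
stationary law and were not adopted.

Realized autocorrelation is the lag-1 Pearson correlation of the series;
predictability is its square.  Both are undefined (NaN, with a degenerate
flag) for zero-variance series.

Seeding: every study descends from one root seed through
`numpy.random.SeedSequence` spawning in a fixed order (design, study,
gating, RDA, plasticity; per-line children in line order), so reruns are
byte-identical and any stage can be reproduced in isolation.

## Synthetic assay generator

The generator emulates the statistical structure the analysis is meant to
detect, with effect sizes that are free parameters (no channel-level
effect sizes exist to copy, so downstream validation is *parameter
recovery*, not value matching).

* **Morphology.**  Alive singlets are Gaussian in (FSC, SSC, Red-B)
  log-units around `baseline_mean = (5.0, 4.5, 6.2)`, within-cell sd 0.3
  per channel.
* **Plastic response.**  Low- and high-salinity means separate along a
  fixed unit axis `(-0.6, 0, -0.8)` — high salinity means smaller cells
  with less chlorophyll — with magnitude
  `max(0, a + b rho^2 + e_i) * phase_gain[phase(day)]`, defaults
  `a = 0.5`, `b = 2.0` log-units.  The expected day-10 distance between
  salinity means is therefore exactly `a + b rho^2 + e_i`.
* **Line effects.**  `e_i ~ N(0, 0.12^2)` is each line's biological
  deviation from the trend, redrawn per study realization.  Independently
  evolved lines are genetically distinct, and in assay data of this kind
  the between-line scatter of plasticity dominates cell-sampling noise
  (bootstrap SEs are small relative to the spread of line distances
  around the regression).  This term matters for inference: the
  hierarchical bootstrap resamples both lines and cells, and is
  calibrated when line-level variance dominates; with `e_i = 0` all
  between-line scatter is resampling noise, the bootstrap double-counts
  it, and the slope test becomes arbitrarily conservative.
* **Ontogeny.**  A loop-shaped day-indexed offset
  `0.8 sin(pi d/10) u1 + 0.4 sin(2 pi d/10) u2` shared by all
  conditions: start (day 0) and end (day 10) morphologies coincide while
  mid-days excurse, as cell size/granularity change early in the culture
  cycle and chlorophyll later.
* **Growth and phases.**  Densities follow a logistic
  `N(t) = K N0 e^{r t'} / (K + N0 (e^{r t'} - 1))` with effective time
  `t' = max(0, t - lag)`.  The lag (default 2 days) is needed because a
  plain logistic has its maximal daily ratio on day 1, which cannot
  produce the observed lag → exponential (days 3–4) → stationary
  sequence; with `lag = 0` the plain closed form is recovered.  Defaults
  `r = 1.2 d^-1`, `K = 10^6 cells ml^-1`, `N0 = 2 x 10^4 cells ml^-1`
  place the exponential phase on days 3–4.  Plasticity is damped during
  the exponential phase (`phase_gain` defaults: lag 1.0, exponential 0.3,
  stationary 1.0), emulating the rapid-division morphology that masks
  salinity effects.
* **Contaminants.**  Events are a mixture of alive singlets, dead cells
  (low Red-B relative to Yellow-B), debris (low scatter and fluorescence)
  and doublets (alive morphology, FSC-W ≈ 4 vs ≈ 2 for singlets), default
  5 % each.
* **Optics.**  A salinity-dependent offset (medium density affects the
  light signal) shifts all morphology channels of both cells and beads;
  beads additionally carry an intrinsic brightness.  Bead correction —
  subtracting per-channel bead means at the matching salinity — cancels
  both exactly in expectation.
* **Event counts.**  Per condition, counts track density:
  `clip(density * 35.4 µl * 0.25, 40, 5000)`, giving ~150–200 events on
  the low-density days 1–2 and the 5000-event instrument cap late —
  the density-limited sampling that motivates the balanced 150-event
  subsample.
* **Constant-regime lines** are generated with effective predictability
  0.7 (the midpoint of the 0.6–0.8 band their plasticity empirically
  matches), so group comparisons against high-predictability lines are
  null by construction.

**What the generator does not emulate:** genetic polymorphism within
lines, selection during the assay, instrument drift or day effects,
non-Gaussian channel noise, density-dependent morphology beyond the phase
gains, and any mechanistic osmotic physiology.  Passing tests therefore
demonstrate that the *analysis chain* is correct and calibrated under the
assumed data-generating structure — not that real cytometry data satisfy
that structure.

## Gating

The visual cytogram gate is formalised as two log-scale thresholds:
`red_b >= 4.5` and `red_b - yellow_b >= 1.0`; doublets are removed at
`fsc_w <= 3.0`.  These defaults are calibrated against the generator's
class geometry to ≥ 99 % separation and are explicit configuration — they
are not instrument values and should be re-tuned for real data.  Gating
operators commute and are idempotent.  Subsampling to ≤ 150 events per
condition is uniform without replacement.  All analysis stays on the
log-scale instrument units; nothing is linearised.

## RDA variation partitioning

RDA is implemented as multivariate least squares on centred responses
with incremental Gram–Schmidt orthonormalisation of centred term blocks
(re-orthogonalised twice; columns with residual singular value below
`1e-9` of the design scale are dropped as rank-deficient, reducing the
term's df with a warning).  Sequential attribution credits term *k* with
the fitted sum of squares it adds given terms 1..k−1, in the printed
order (strain, growth rate, day, salinity, predictability, then the
interactions); a marginal mode (full model minus drop-one model) backs
statements about effects "given everything else".  Sequential R² plus the
residual sum to 1 to 1e−10 by construction; this and exact agreement with
brute-force cumulative least squares are tested.

Permutation tests freely permute rows of Y (999 randomizations by
default), recomputing every pseudo-F against the same design; the p-value
`(1 + #{F* >= F}) / (1 + n_perm)` has minimum `1/(n_perm+1)`.  Free
row permutation is the simplest exchangeability assumption; residual
permutation under a reduced model is not implemented.  Day 0 (the
pre-transfer acclimation measurement) is excluded from partitioning, so
day contributes 9 df (days 1–10); assay salinity contributes 2 df for
fluctuating-regime lines (three assay salinities) and 1 df for
constant-regime lines (extremes only).  Growth rate enters as the
condition-level per-capita rate broadcast to that condition's cells.
Channels are not standardised: they are already bead-corrected on a
common log scale.

## Growth phases

Daily per-capita rate is `(N_t - N_{t-1}) / N_{t-1}`, with `N(0)` the
inoculation density.  Phases are labelled by a contiguous-block rule: the
exponential phase is the maximal contiguous run of days with rate at
least `f = 0.8` of the maximum that contains the earliest maximum; days
before are lag, after are stationary.  `f` is configurable — the verbal
definition ("days when r is highest") does not pin down day 2, which
under the defaults falls in the lag phase.  Labels are invariant to
rescaling all densities (so the detection-efficiency factor between true
and event-estimated densities cancels).

## Plasticity inference

Distances use bead-corrected raw channels (not PCA scores, not
standardised): bead correction is the only per-cell transformation the
assay carries forward, and the distance is invariant to the common shift
correction applies.  The one-sided bootstrap p is the proportion of
replicate slopes ≤ 0 (the complement of "proportion > 0" is printable
from the same replicates).  Per-line SEs are the spread of that line's
bootstrap distances across the replicates in which it was drawn.
Constant-regime lines never enter the rho² regression; they are compared
to high-predictability lines by the same two-stage resampling with a
two-sided p (twice the smaller tail proportion).  The group comparison
between equal-predictability treatments (rho_bar = ±0.5) uses the same
machinery.  Degenerate inputs (zero spread of replicate slopes) are
flagged rather than erroring.

## Problem sizes

The shipped tests validate at sizes chosen for tight Monte Carlo error at
desk scale: AR1 moments at 10^5 steps (tolerance ±0.02 ≈ 1.5 standard
errors at rho = 0.9), permutation calibration over 200 datasets × 999
permutations, bootstrap type-I calibration over 200 end-to-end studies of
8 lines × 150 cells with B = 1000, parameter recovery over 20 studies of
32 lines, and the day-profile check on 16 lines with B = 400.  The
default `StudyConfig` reproduces the full 36-line, 11-day,
three-salinity design.

## Known limitations

* The permutation test assumes exchangeable cell rows; with strong
  within-condition correlation its p-values for condition-level
  predictors are anticonservative (cells are pseudo-replicates there, as
  in any cell-level RDA).
* The two-stage bootstrap mildly over-counts within-line noise; its
  calibration relies on line-level variance dominating (see above).
* `transfer_recipe` ignores evaporation and pipetting error.
* FCS binary ingest is out of scope: the package reads the plain CSV
  event dialect only.
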