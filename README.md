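# plastevol

Analysis toolkit for a question in evolutionary ecology: **does phenotypic
plasticity evolve to lower levels in environments that fluctuate less
predictably?**  The package implements the full analysis chain of a
long-term selection experiment on the halotolerant microalga *Dunaliella
salina*, in which replicate lines evolved under randomly fluctuating
salinity regimes that shared the same mean and variance but differed in
their temporal autocorrelation — and therefore in how predictable each
salinity change was.

It is aimed at experimental-evolution and quantitative-ecology researchers
who want to simulate such regimes, process flow-cytometry phenotyping data,
and quantify the evolution of plasticity with resampling-based inference —
or to prototype the whole design on synthetic data first.

## The model and statistics

**Environment.**  Each line's salinity series follows a stationary AR1
process

    x[t+1] = mu + rho (x[t] - mu) + eps[t],   eps[t] ~ N(0, sigma^2 (1 - rho^2)),

with mu = 2.4 M NaCl, sigma = 1 M, and treatment autocorrelations
rho_bar in {-0.5, 0, 0.5, 0.9}.  The *predictability* of the environment is
rho^2, the share of temporal variance explained by the previous salinity;
the realized rho of each finite series is its lag-1 Pearson correlation.
Each target salinity is achieved by 20 % serial dilution into 800 µl of
fresh medium mixed from 0 M and 4.8 M stocks.

**Phenotyping.**  Cytometer events are gated alive on a Red-B/Yellow-B
chlorophyll cytogram, doublets removed by pulse width (FSC-W), and each
cell's (FSC, SSC, Red-B) log-scale morphology corrected by subtracting the
mean of 1000 calibration beads measured in medium at the same salinity.

**Degree of plasticity.**  For line *i* on assay day *d*,

    D_i(d) = || mean_morph(4.0 M) - mean_morph(0.8 M) ||_2 ,

the Euclidean distance between its multivariate morphology means at high
vs. low assay salinity.  Evolution of plasticity is the OLS regression of
D_i on the line's realized predictability rho_i^2.  Significance comes from
a hierarchical nonparametric bootstrap mirroring the data's nesting:
resample the lines with replacement, then n = 150 cells with replacement
per drawn line and salinity, recompute all distances and the slope; repeat
B = 1000 times and report the proportion of replicate slopes <= 0.

**Variation partitioning.**  Morphological variation is decomposed by
redundancy analysis (RDA): multivariate least squares of cell morphology on
strain, growth rate, day, assay salinity, predictability and their
interactions, each term's share quantified by a multivariate R² and tested
by ANOVA-like permutation (999 randomizations).

A synthetic-data module generates a full study — lines, AR1 environments,
logistic growth with lag, per-cell events with debris/dead/doublet
contamination, loop-shaped ontogeny, growth-phase-dependent plasticity and
salinity-dependent bead offsets — with known ground truth, so every stage
is testable end to end.

## Worked example

Simulate eight evolved lines, assay them at day 10, and test whether
plasticity increased with the predictability each line experienced:

```python
import plastevol as pv

lines = pv.generate_design(n_fluct=8, n_const=0, seed=3)
cells, design = pv.make_assay_dataset(lines, days=(10,), seed=5, n_events=250)
res = pv.hierarchical_bootstrap(cells, design, day=10, B=1000, seed=7)
print(f"slope = {res.slope_obs:.3f} +/- {res.slope_se:.3f} (bootstrap SE)")
print(f"one-sided p (slopes <= 0) = {res.p_one_sided:.3f}")
```

prints

```
slope = 2.123 +/- 0.179 (bootstrap SE)
one-sided p (slopes <= 0) = 0.000
```

The generator's true plasticity trend is `0.5 + 2.0 * rho^2` log-units, so
the estimated slope of 2.12 ± 0.18 recovers the construction, and the
bootstrap p-value ≈ 0 says no replicate produced a non-positive slope:
lines from more predictable environments are reliably more plastic.
`res.distances` holds the per-line distances with their bootstrap SEs.

The full pipeline (environment → synthetic assay → gating → growth phases →
RDA partitioning → plasticity inference) runs from one config:

```sh
plastevol run --out study_out --seed 1
```

and writes the design, per-line environments, corrected cells, growth
rates, two partition tables, the per-day slope profile and a manifest with
file hashes; `plastevol --help` lists the per-stage subcommands.

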