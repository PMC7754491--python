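"""End-to-end orchestration of the synthetic plasticity-evolution study.

``run_all`` chains the stages -- environment simulation, synthetic assay
generation, gating/bead correction, growth-phase labelling, RDA variation
partitioning, and plasticity regression with hierarchical bootstrap --
into one reproducible run driven by a single :class:`StudyConfig`.  All
randomness descends from one root seed through a fixed spawning order, so
identical configs give byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import gating, growth, multivariate, plasticity, synthdata
from .environment import series_recipes
from .gating import GateThresholds
from .synthdata import GeneratorParams, LineMeta

STAGES = ("environment", "synthdata", "gating", "growth", "rda", "plasticity")


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    seed: int = 0
    n_fluct: int = 32
    n_const: int = 4
    n_transfers: int = 139
    days: tuple = tuple(range(11))
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    gate: GateThresholds = field(default_factory=GateThresholds)
    subsample_cap: int = 150
    n_perm: int = 999
    B: int = 1000
    n_cells: int = 150
    regression_day: int = 10
    #: fixed events per condition; None lets counts track culture density
    events_per_condition: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorParams(**raw.pop("generator", {}))
        gate = GateThresholds(**raw.pop("gate", {}))
        if "days" in raw:
            raw["days"] = tuple(raw["days"])
        return cls(generator=gen, gate=gate, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        return d


@dataclass
class RunResult:
    out_dir: Path
    design: pd.DataFrame
    partition_fluct: pd.DataFrame | None
    partition_const: pd.DataFrame | None
    profile: pd.DataFrame | None
    day_regression: dict | None
    comparison: dict | None
    manifest: dict


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_assay_dataset(
    lines: list[LineMeta],
    params: GeneratorParams | None = None,
    days=(10,),
    gate: GateThresholds | None = None,
    seed: int | None = None,
    n_events: int | None = None,
    salinities=(0.8, 4.0),
):
    """Simulate, gate and bead-correct an assay: the cell-level input of
    the plasticity analysis.

    Returns ``(cells, design)`` where ``cells`` has the corrected channels
    ``fsc_c, ssc_c, red_b_c`` per alive singlet and ``design`` is the line
    table.
    """
    params = params or GeneratorParams()
    gate = gate or GateThresholds()
    events, beads, _ = synthdata.generate_study(
        lines, params, days=days, salinities_fluct=salinities,
        salinities_const=salinities, seed=seed, n_events=n_events,
    )
    alive = gating.gate_alive(events, gate.min_red, gate.min_red_minus_yellow)
    singlets = gating.remove_doublets(alive, gate.fsc_w_max)
    cells = gating.bead_correct_table(singlets, beads)
    return cells, synthdata.design_frame(lines)


def run_all(config: StudyConfig, out_dir) -> RunResult:
    """Execute every stage and write the result bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: _child_seed(ss) for name in
             ("design", "study", "gating", "rda_fluct", "rda_const", "plasticity")}
    completed, files = [], {}
    stage = "environment"
    try:
        # -- environment + design ------------------------------------------
        lines = synthdata.generate_design(
            config.n_fluct, config.n_const, seed=seeds["design"],
            n_transfers=config.n_transfers,
        )
        design = synthdata.design_frame(lines)
        design.to_csv(out / "design.csv", index=False)
        files["design.csv"] = out / "design.csv"
        env_rows = []
        for i, line in enumerate(lines):
            if line.regime != "fluctuating":
                continue
            series = synthdata.line_series(
                i, line.treatment_rho_bar, seeds["design"], config.n_transfers
            )
            rec = series_recipes(series)
            rec.insert(0, "line_id", line.line_id)
            env_rows.append(rec)
        if env_rows:
            env = pd.concat(env_rows, ignore_index=True)
            env.to_csv(out / "environment.csv", index=False)
            files["environment.csv"] = out / "environment.csv"
        completed.append(stage)

        # -- synthetic assay ----------------------------------------------
        stage = "synthdata"
        events, beads, densities = synthdata.generate_study(
            lines, config.generator, days=config.days,
            seed=seeds["study"], n_events=config.events_per_condition,
        )
        beads.to_csv(out / "beads.csv", index=False)
        files["beads.csv"] = out / "beads.csv"
        completed.append(stage)

        # -- gating ---------------------------------------------------------
        stage = "gating"
        alive = gating.gate_alive(events, config.gate.min_red, config.gate.min_red_minus_yellow)
        singlets = gating.remove_doublets(alive, config.gate.fsc_w_max)
        cells = gating.bead_correct_table(singlets, beads)
        counts = (
            singlets.groupby(["line_id", "salinity_M", "day"], sort=True)
            .size()
            .reset_index(name="n_alive")
        )
        counts["cells_per_ml"] = [
            gating.estimate_density(n, config.generator.acquisition_volume_ul)
            for n in counts["n_alive"]
        ]
        counts.to_csv(out / "densities.csv", index=False)
        files["densities.csv"] = out / "densities.csv"
        balanced = gating.subsample_by_condition(
            cells, cap=config.subsample_cap, seed=seeds["gating"]
        )
        balanced.to_csv(out / "corrected.csv", index=False)
        files["corrected.csv"] = out / "corrected.csv"
        completed.append(stage)

        # -- growth ---------------------------------------------------------
        stage = "growth"
        rates = growth.growth_table(counts[["line_id", "salinity_M", "day", "cells_per_ml"]])
        rates.to_csv(out / "rates.csv", index=False)
        files["rates.csv"] = out / "rates.csv"
        completed.append(stage)

        # -- RDA variation partitioning -------------------------------------
        stage = "rda"
        meta_cols = rates[["line_id", "salinity_M", "day", "r"]]
        rda_rows = balanced.loc[balanced["day"] > 0].merge(
            meta_cols, on=["line_id", "salinity_M", "day"]
        ).merge(design[["line_id", "strain", "regime", "predictability"]], on="line_id")
        rda_rows = rda_rows.rename(columns={"r": "growth_rate"})
        partitions = {}
        for regime, pname, seed_key in (
            ("fluctuating", "partition_fluctuating.tsv", "rda_fluct"),
            ("constant", "partition_constant.tsv", "rda_const"),
        ):
            sub = rda_rows.loc[rda_rows["regime"] == regime]
            if sub.empty:
                partitions[regime] = None
                continue
            terms = multivariate.build_design(sub, regime=regime)
            parts = multivariate.rda_partition(
                sub[list(gating.CORRECTED)].to_numpy(float), terms,
                n_perm=config.n_perm, seed=seeds[seed_key],
            )
            tab = multivariate.partition_frame(parts)
            tab.to_csv(out / pname, sep="\t", index=False)
            files[pname] = out / pname
            partitions[regime] = tab
        completed.append(stage)

        # -- plasticity ------------------------------------------------------
        stage = "plasticity"
        assay_days = [d for d in config.days if d > 0]
        profile = plasticity.slope_profile_by_day(
            cells, design, days=assay_days, B=config.B,
            n_cells=config.n_cells, seed=seeds["plasticity"],
        )
        prof = plasticity.profile_frame(profile)
        prof.to_csv(out / "regression.tsv", sep="\t", index=False)
        files["regression.tsv"] = out / "regression.tsv"
        dist = pd.concat([r.distances for r in profile.values()], ignore_index=True)
        dist.to_csv(out / "plasticity.tsv", sep="\t", index=False)
        files["plasticity.tsv"] = out / "plasticity.tsv"

        day_reg = None
        if config.regression_day in profile:
            r = profile[config.regression_day]
            day_reg = {
                "day": config.regression_day, "slope": r.slope_obs,
                "intercept": r.intercept_obs, "r2": r.r2_obs,
                "p_one_sided": r.p_one_sided, "B": r.B,
            }

        comparison = None
        const_lines = design.loc[design["regime"] == "constant", "line_id"].tolist()
        high_pred = design.loc[
            (design["regime"] == "fluctuating")
            & design["predictability"].between(0.6, 0.8),
            "line_id",
        ].tolist()
        if const_lines and high_pred:
            cmp_res = plasticity.compare_groups(
                cells, design, const_lines, high_pred,
                day=config.regression_day, B=config.B,
                n_cells=config.n_cells, seed=seeds["plasticity"],
            )
            comparison = {
                "group_a": "constant", "group_b": "rho2 in [0.6, 0.8]",
                "difference": cmp_res.difference, "p_two_sided": cmp_res.p_two_sided,
                "B": cmp_res.B, "day": config.regression_day,
            }
        completed.append(stage)
    except Exception as exc:  # annotate which stage failed
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": seeds,
        "stages": completed,
        "day_regression": day_reg,
        "comparison": comparison,
        "files": {name: _sha256(path) for name, path in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return RunResult(out, design, partitions.get("fluctuating"), partitions.get("constant"),
                     prof, day_reg, comparison, manifest)


def report(result: RunResult | None) -> str:
    """Human-readable markdown summary of a completed run."""
    if result is None or not result.manifest.get("stages"):
        return "# Study report\n\nno stages completed\n"
    lines = ["# Study report", ""]
    lines.append(f"Completed stages: {', '.join(result.manifest['stages'])}")
    lines.append("")
    for title, tab in (
        ("Variation partitioning (fluctuating-regime lines)", result.partition_fluct),
        ("Variation partitioning (constant-regime lines)", result.partition_const),
    ):
        lines.append(f"## {title}")
        if tab is None:
            lines.append("(not computed)")
        else:
            lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    if result.day_regression:
        d = result.day_regression
        lines.append(f"## Plasticity vs. predictability at day {d['day']}")
        lines.append(
            f"slope = {d['slope']:.4g}, intercept = {d['intercept']:.4g}, "
            f"R2 = {d['r2']:.3f}, one-sided p = {d['p_one_sided']:.4g} "
            f"({d['B']} bootstrap replicates)"
        )
        lines.append("")
    if result.profile is not None:
        lines.append("## Per-day slope profile")
        lines.append(result.profile.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    if result.comparison:
        c = result.comparison
        lines.append("## Group comparison")
        lines.append(
            f"{c['group_a']} vs {c['group_b']} at day {c['day']}: "
            f"difference = {c['difference']:.4g}, two-sided p = {c['p_two_sided']:.4g} "
            f"({c['B']} bootstrap replicates)"
        )
        lines.append("")
    return "\n".join(lines)
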