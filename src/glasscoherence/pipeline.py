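"""End-to-end orchestration: seed -> stimuli, design, cohort, GLM,
trend inference, behavioral analysis -> report bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import glm as glm_mod
from . import inference, io, stimulus
from ._rng import substream
from .design import CONDITION_COHERENCE
from .simulate import CohortConfig, simulate_behavior_run, simulate_cohort

log = logging.getLogger("glasscoherence")


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of the whole pipeline."""

    seed: int = 0
    stimulus: stimulus.GlassPatternSpec = field(
        default_factory=stimulus.GlassPatternSpec)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fdr_q: float = 0.001
    n_permutations: int = 10_000
    whiten: bool = True
    behavior_lag: float = 0.5
    hit_rate: float = 0.9
    false_alarm_rate: float = 0.02
    render_stimuli: bool = True
    write_cohort: bool = False
    output_dir: str = "glasscoherence_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = io.config_to_dict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stimulus" in d:
            d["stimulus"] = stimulus.GlassPatternSpec(**d["stimulus"])
        if "cohort" in d:
            d["cohort"] = io.config_from_dict(d["cohort"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage(name):
    log.info("stage %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to output_dir.

    Deterministic given the config: each stage draws from its own named
    substream of the config seed.  Returns the report dictionary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report = {"seed": config.seed, "stages": {}}

    if config.render_stimuli:
        t0 = _stage("make-stimuli")
        rng = substream(config.seed, "stimulus")
        sdir = out / "stimuli"
        sdir.mkdir(exist_ok=True)
        for label, coh in CONDITION_COHERENCE.items():
            form = "circular" if coh > 0 else "random"
            spec = dataclasses.replace(config.stimulus, coherence=coh,
                                       form=form)
            dip = stimulus.sample_dipole_field(spec, rng)
            stimulus.render_pattern(dip, spec).save_png(sdir / f"{label}.png")
            dip.save_tsv(sdir / f"{label}_dipoles.tsv")
        report["stages"]["stimuli"] = {"seconds": round(time.time() - t0, 2)}

    t0 = _stage("simulate-cohort")
    cohort = simulate_cohort(config.cohort, substream(config.seed, "cohort"))
    ddir = out / "design"
    ddir.mkdir(exist_ok=True)
    for r, tl in enumerate(cohort.participants[0].timelines):
        tl.save_tsv(ddir / f"p0_run{r:02d}_events.tsv")
    if config.write_cohort:
        io.write_cohort(cohort, out / "cohort")
    report["stages"]["simulate"] = {
        "seconds": round(time.time() - t0, 2),
        "n_runs_total": cohort.n_runs_total}

    t0 = _stage("fit-glm")
    fit = glm_mod.fit_cohort(cohort, whiten=config.whiten, q=config.fdr_q)
    gdir = out / "glm"
    gdir.mkdir(exist_ok=True)
    fit.node_table.to_csv(gdir / "node_table.tsv", sep="\t", index=False)
    for area, mat in fit.area_matrices.items():
        mat.values.to_csv(gdir / f"area_{io._safe(area)}_matrix.tsv", sep="\t")
    report["stages"]["glm"] = {
        "seconds": round(time.time() - t0, 2),
        "design_shape": list(fit.design_shape),
        "n_selected": {a: int(m.n_nodes_selected.sum())
                       for a, m in fit.area_matrices.items()}}

    t0 = _stage("trend-test")
    rng = substream(config.seed, "permutation")
    table = inference.trend_table(fit.area_matrices, config.n_permutations,
                                  rng)
    table.to_csv(out / "trend_table.tsv", sep="\t", index=False)
    report["stages"]["inference"] = {"seconds": round(time.time() - t0, 2)}
    report["trend_table"] = table.to_dict(orient="records")

    if "V3" in fit.area_matrices:
        sel = fit.node_table[(fit.node_table["area"] == "V3")
                             & fit.node_table["selected"]]
        binned = inference.binned_trend_analysis(
            sel, inference.orthogonal_contrasts(4).linear,
            n_iterations=config.n_permutations, rng=rng)
        report["v3_binned"] = {
            f"{lo}-{hi}": (None if res is None else
                           {"coefficient": res.coefficient,
                            "p_two_tailed": res.p_two_tailed})
            for (lo, hi), res in binned.items()}

    t0 = _stage("behavior-analysis")
    rng = substream(config.seed, "behavior")
    trains = {}
    for part in cohort.participants:
        trains[part.participant_id] = [
            simulate_behavior_run(tl, config.behavior_lag, config.hit_rate,
                                  config.false_alarm_rate, rng)
            for tl in part.timelines]
    corr, anova = beh.analyze_behavior(trains)
    bdir = out / "behavior"
    bdir.mkdir(exist_ok=True)
    corr.correlations.to_csv(bdir / "correlations.tsv", sep="\t", index=False)
    anova_dict = {"effects": anova.effects.to_dict(orient="records"),
                  "pooled_lag": anova.pooled_lag,
                  "ss_total": anova.ss_total}
    with open(bdir / "anova.json", "w") as fh:
        json.dump(anova_dict, fh, indent=1, sort_keys=True)
    report["stages"]["behavior"] = {"seconds": round(time.time() - t0, 2)}
    report["anova"] = anova_dict

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
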