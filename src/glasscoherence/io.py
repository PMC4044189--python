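"""Plain-text (TSV/JSON) serialization of cohorts and configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import BlockProtocol, RunTimeline
from .hemo import HemoParams
from .simulate import Cohort, CohortConfig, NoiseParams, Participant


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("areas", "drift_sd"):
        d[key] = list(d[key])
    d["noise"]["drift_coefficients"] = list(d["noise"]["drift_coefficients"])
    d["noise"]["motion_coupling"] = list(d["noise"]["motion_coupling"])
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["protocol"] = BlockProtocol(**d["protocol"])
    d["hemo"] = HemoParams(**d["hemo"])
    noise = dict(d["noise"])
    noise["drift_coefficients"] = tuple(noise["drift_coefficients"])
    noise["motion_coupling"] = tuple(noise["motion_coupling"])
    d["noise"] = NoiseParams(**noise)
    d["areas"] = tuple(d["areas"])
    d["drift_sd"] = tuple(d["drift_sd"])
    return CohortConfig(**d)


def timeline_from_events(frame: pd.DataFrame, tr: float) -> RunTimeline:
    blocks = [(float(r.onset), float(r.duration), str(r.trial_type))
              for r in frame.itertuples()]
    total = blocks[-1][0] + blocks[-1][1] if blocks else 0.0
    return RunTimeline(blocks=blocks, total_duration=total,
                       n_volumes=int(round(total / tr)))


def _safe(area: str) -> str:
    return area.replace("+", "plus")


def write_cohort(cohort: Cohort, path) -> None:
    """One directory per participant: events/motion/data TSVs + node table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.json", "w") as fh:
        json.dump(config_to_dict(cohort.config), fh, indent=1, sort_keys=True)
    conditions = list(cohort.config.protocol.labels)
    for part in cohort.participants:
        pdir = path / part.participant_id
        pdir.mkdir(exist_ok=True)
        nodes = part.nodes.copy()
        for j, c in enumerate(conditions):
            nodes[f"truth_{c}"] = part.truth[:, j]
        nodes.to_csv(pdir / "nodes.tsv", sep="\t", index=False)
        for r, tl in enumerate(part.timelines):
            tl.save_tsv(pdir / f"run{r:02d}_events.tsv")
            pd.DataFrame(part.motion[r],
                         columns=[f"motion{j}" for j in range(6)]
                         ).to_csv(pdir / f"run{r:02d}_motion.tsv",
                                  sep="\t", index=False)
            for area in cohort.config.areas:
                mask = (part.nodes["area"] == area).to_numpy()
                frame = pd.DataFrame(part.data[mask, r, :].T,
                                     columns=part.nodes.loc[mask, "node_id"])
                frame.to_csv(pdir / f"run{r:02d}_{_safe(area)}.tsv",
                             sep="\t", index=False)


def read_cohort(path) -> Cohort:
    path = Path(path)
    with open(path / "config.json") as fh:
        config = config_from_dict(json.load(fh))
    conditions = list(config.protocol.labels)
    participants = []
    for p_idx in range(config.n_participants):
        pdir = path / f"p{p_idx}"
        nodes = pd.read_csv(pdir / "nodes.tsv", sep="\t")
        truth = nodes[[f"truth_{c}" for c in conditions]].to_numpy()
        nodes = nodes.drop(columns=[f"truth_{c}" for c in conditions])
        timelines, motion, runs = [], [], []
        for r in range(config.protocol.n_runs):
            ev = pd.read_csv(pdir / f"run{r:02d}_events.tsv", sep="\t")
            timelines.append(timeline_from_events(ev, config.protocol.tr))
            motion.append(pd.read_csv(pdir / f"run{r:02d}_motion.tsv",
                                      sep="\t").to_numpy())
            blocks = []
            for area in config.areas:
                frame = pd.read_csv(pdir / f"run{r:02d}_{_safe(area)}.tsv",
                                    sep="\t")
                blocks.append(frame.to_numpy().T)
            runs.append(np.vstack(blocks))
        # node order: data rows were written grouped by area
        order = np.concatenate([np.flatnonzero((nodes["area"] == a).to_numpy())
                                for a in config.areas])
        nodes = nodes.iloc[order].reset_index(drop=True)
        truth = truth[order]
        data = np.stack(runs, axis=1)  # (n_nodes, n_runs, n_vol)
        participants.append(Participant(f"p{p_idx}", timelines,
                                        np.stack(motion), nodes, data, truth))
    return Cohort(config=config, participants=participants)
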