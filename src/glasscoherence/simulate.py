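"""Synthetic BOLD cohort generator.

Produces per-node cortical-surface timecourses with the statistical
structure the analysis assumes: condition boxcars convolved with the
canonical hemodynamic response and scaled as percent signal change of a
baseline, per-run cubic Legendre drift, optional motion-coupled
nuisance, and ARMA(1,1) temporal noise.  Also generates binary
target/response event trains for the fixation digit task.

Default effect profiles encode the study's ground truth: flat coherence
response functions in V1/V2 and linear ones in V3, hMT+, DRA and VRA
with full-versus-zero differences of 0.153, 0.101, 0.185 and 0.246
percent signal change respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._rng import as_rng
from .design import (BLANK, BlockProtocol, RunTimeline, build_run_timeline,
                     counterbalanced_orders)
from .hemo import HemoParams, canonical_hrf, condition_regressor, condition_regressors

AREAS = ("V1", "V2", "V3", "hMT+", "DRA", "VRA")


@dataclass(frozen=True)
class NoiseParams:
    """ARMA(1,1) noise, Legendre drift and motion-coupling parameters."""

    ar: float = 0.4
    ma: float = -0.2
    innovation_sd: float = 5.0
    drift_coefficients: tuple = (0.0, 0.0, 0.0, 0.0)  # P0..P3 weights, one run
    motion_coupling: tuple = (0.0,) * 6

    def __post_init__(self):
        if not (abs(self.ar) < 1 and abs(self.ma) < 1):
            raise ValueError("ARMA(1,1) requires |ar| < 1 and |ma| < 1")


@dataclass(frozen=True)
class AreaEffectProfile:
    """Per-condition response amplitudes (psc of baseline) for one area."""

    area: str
    condition_amplitudes: tuple  # psc at coherence 0, 33, 66, 100 %

    @property
    def full_minus_zero(self) -> float:
        return self.condition_amplitudes[-1] - self.condition_amplitudes[0]


def _linear_profile(area: str, base: float, diff: float) -> AreaEffectProfile:
    amps = tuple(base + diff * f for f in (0.0, 1 / 3, 2 / 3, 1.0))
    return AreaEffectProfile(area, amps)


#: ground-truth coherence response profiles, on a 1.0 psc visual response
DEFAULT_PROFILES = {
    "V1": AreaEffectProfile("V1", (1.0, 1.0, 1.0, 1.0)),
    "V2": AreaEffectProfile("V2", (1.0, 1.0, 1.0, 1.0)),
    "V3": _linear_profile("V3", 1.0, 0.153),
    "hMT+": _linear_profile("hMT+", 1.0, 0.101),
    "DRA": _linear_profile("DRA", 1.0, 0.185),
    "VRA": _linear_profile("VRA", 1.0, 0.246),
}


@dataclass
class NodeTimeseries:
    """One node's signal for one run, with its generating amplitudes."""

    values: np.ndarray
    run_id: int
    participant_id: str
    area: str
    node_id: str
    meridian_distance: float
    hemisphere: str
    truth: np.ndarray | None = None


def arma11_noise(shape, ar: float, ma: float, sd: float, rng,
                 burn: int = 200) -> np.ndarray:
    """Stationary-ish ARMA(1,1) noise via filtered innovations + burn-in."""
    rng = as_rng(rng)
    if np.isscalar(shape):
        shape = (int(shape),)
    e = rng.normal(0.0, sd, size=shape[:-1] + (shape[-1] + burn,))
    x = lfilter([1.0, ma], [1.0, -ar], e, axis=-1)
    return x[..., burn:]


def simulate_node(timeline: RunTimeline, profile: AreaEffectProfile,
                  noise: NoiseParams, baseline: float, rng, *,
                  hemo: HemoParams = HemoParams(), tr: float | None = None,
                  motion: np.ndarray | None = None,
                  regressors: np.ndarray | None = None,
                  conditions=None,
                  run_id: int = 0, participant_id: str = "p0",
                  node_id: str = "n0", meridian_distance: float = 45.0,
                  hemisphere: str = "L") -> NodeTimeseries:
    """Forward-model one node for one run.

    values = baseline * (1 + sum_c amp_c/100 * regressor_c)
             + Legendre drift + motion_coupling . motion + ARMA(1,1) noise
    """
    from .glm import legendre_regressors

    rng = as_rng(rng)
    tr = 2.0 if tr is None else tr
    if conditions is None:
        conditions = [lab for lab in
                      ("c0", "c33", "c66", "c100")
                      if lab in timeline.labels_present()] or sorted(
                          timeline.labels_present() - {BLANK})
    if regressors is None:
        regressors = condition_regressors(timeline, conditions, hemo, tr)
    amps = np.asarray(profile.condition_amplitudes, dtype=float)
    if regressors.shape[1] != amps.size:
        raise ValueError("regressor/amplitude count mismatch")
    n_vol = timeline.n_volumes
    values = baseline * (1.0 + regressors @ (amps / 100.0))
    coeffs = np.asarray(noise.drift_coefficients, dtype=float)
    if np.any(coeffs):
        L = legendre_regressors(n_vol, coeffs.size - 1)
        values = values + L @ coeffs
    if motion is not None and np.any(noise.motion_coupling):
        values = values + motion @ np.asarray(noise.motion_coupling)
    if noise.innovation_sd > 0:
        values = values + arma11_noise(n_vol, noise.ar, noise.ma,
                                       noise.innovation_sd, rng)
    return NodeTimeseries(values=values, run_id=run_id,
                          participant_id=participant_id, area=profile.area,
                          node_id=node_id, meridian_distance=meridian_distance,
                          hemisphere=hemisphere, truth=amps.copy())


def random_walk_motion(n_volumes: int, rng, n_params: int = 6) -> np.ndarray:
    """Six smooth low-frequency nuisance series, standardized per run."""
    rng = as_rng(rng)
    steps = rng.normal(0.0, 1.0, size=(n_volumes, n_params))
    walk = np.cumsum(steps, axis=0)
    walk = walk - walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return walk / sd


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale configuration of the synthetic cohort."""

    n_participants: int = 6
    protocol: BlockProtocol = field(default_factory=BlockProtocol)
    hemo: HemoParams = field(default_factory=HemoParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    areas: tuple = AREAS
    nodes_per_area_hemi: int = 50          # responsive nodes
    nonresponsive_per_area_hemi: int = 10  # zero-amplitude nodes
    participant_sd: float = 0.08           # psc jitter per condition
    drift_sd: tuple = (0.0, 4.0, 2.0, 1.0)  # per-run Legendre coefficient sds
    baseline: float = 1000.0

    def profiles(self) -> dict:
        return {a: DEFAULT_PROFILES[a] for a in self.areas}


@dataclass
class Participant:
    """All simulated data for one participant."""

    participant_id: str
    timelines: list            # one RunTimeline per run
    motion: np.ndarray         # (n_runs, n_volumes, 6)
    nodes: pd.DataFrame        # node_id, area, hemisphere, meridian_distance, responsive
    data: np.ndarray           # (n_nodes, n_runs, n_volumes)
    truth: np.ndarray          # (n_nodes, 4) generating amplitudes (psc)


@dataclass
class Cohort:
    config: CohortConfig
    participants: list

    @property
    def n_runs_total(self) -> int:
        return sum(len(p.timelines) for p in self.participants)


def simulate_cohort(config: CohortConfig = CohortConfig(), rng=0,
                    profiles: dict | None = None) -> Cohort:
    """Simulate the full cohort (defaults: 6 participants x 12 runs).

    Responsive nodes share their area's effect profile plus a
    per-participant, per-condition Normal(0, participant_sd) amplitude
    jitter; a complement of non-responsive (zero-amplitude) nodes
    exercises downstream node selection.  Node visual-field meridian
    distances are uniform on [0, 90] degrees.
    """
    from .glm import legendre_regressors

    rng = as_rng(rng)
    protocol = config.protocol
    profiles = config.profiles() if profiles is None else profiles
    conditions = list(protocol.labels)
    participants = []
    for p_idx in range(config.n_participants):
        pid = f"p{p_idx}"
        timelines, motions, regs = [], [], []
        for _ in range(protocol.n_runs):
            orders = counterbalanced_orders(protocol.n_conditions, rng)
            tl = build_run_timeline(protocol, orders)
            timelines.append(tl)
            motions.append(random_walk_motion(tl.n_volumes, rng))
            regs.append(condition_regressors(tl, conditions, config.hemo,
                                             protocol.tr))
        n_vol = timelines[0].n_volumes
        motion = np.stack(motions)
        L = legendre_regressors(n_vol, 3)

        rows, amp_rows, run_signals = [], [], []
        for area in profiles:
            base = np.asarray(profiles[area].condition_amplitudes, float)
            jitter = rng.normal(0.0, config.participant_sd, size=base.size)
            for hemi in ("L", "R"):
                for kind, count in (("resp", config.nodes_per_area_hemi),
                                    ("null", config.nonresponsive_per_area_hemi)):
                    for j in range(count):
                        amps = base + jitter if kind == "resp" else np.zeros_like(base)
                        rows.append({
                            "node_id": f"{pid}_{area}_{hemi}_{kind}{j}",
                            "area": area, "hemisphere": hemi,
                            "meridian_distance": rng.uniform(0.0, 90.0),
                            "responsive": kind == "resp",
                        })
                        amp_rows.append(amps)
        nodes = pd.DataFrame(rows)
        truth = np.array(amp_rows)
        n_nodes = len(nodes)

        data = np.empty((n_nodes, protocol.n_runs, n_vol))
        drift_sd = np.asarray(config.drift_sd, float)
        for r in range(protocol.n_runs):
            signal = config.baseline * (1.0 + (regs[r] @ truth.T / 100.0).T)
            coeffs = rng.normal(0.0, 1.0, size=(n_nodes, drift_sd.size)) * drift_sd
            drift = coeffs @ L.T
            noise = arma11_noise((n_nodes, n_vol), config.noise.ar,
                                 config.noise.ma, config.noise.innovation_sd,
                                 rng)
            mc = np.asarray(config.noise.motion_coupling)
            extra = motion[r] @ mc if np.any(mc) else 0.0
            data[:, r, :] = signal + drift + noise + extra
        participants.append(Participant(pid, timelines, motion, nodes, data,
                                        truth))
    return Cohort(config=config, participants=participants)


@dataclass
class BehaviorTrain:
    """Binary target/response series and block labels at 100 ms resolution."""

    target_bins: np.ndarray
    response_bins: np.ndarray
    condition_bins: np.ndarray  # condition label per bin
    bin_width: float = 0.1


def condition_bin_labels(timeline: RunTimeline, bin_width: float = 0.1) -> np.ndarray:
    n_bins = int(round(timeline.total_duration / bin_width))
    labels = np.array([BLANK] * n_bins, dtype=object)
    for onset, duration, lab in timeline.blocks:
        i0 = int(round(onset / bin_width))
        i1 = int(round((onset + duration) / bin_width))
        labels[i0:i1] = lab
    return labels


def simulate_behavior_run(timeline: RunTimeline, lag: float = 0.5,
                          hit_rate: float = 0.9,
                          false_alarm_rate: float = 0.02, rng=0, *,
                          bin_width: float = 0.1, digit_rate: float = 3.0,
                          p_target: float = 1.0 / 20.0) -> BehaviorTrain:
    """Simulate the fixation digit task for one run.

    Digits update at 3 Hz; each presentation matches the (digit,
    polarity) target with probability 1/20.  A target elicits a response
    at ``target time + lag`` with probability ``hit_rate``; each
    non-target presentation elicits a spurious response with probability
    ``false_alarm_rate``.  All trains are discretized into 100 ms bins.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= false_alarm_rate <= 1.0):
        raise ValueError("hit_rate and false_alarm_rate must be in [0, 1]")
    rng = as_rng(rng)
    duration = timeline.total_duration
    n_bins = int(round(duration / bin_width))
    n_digits = int(np.floor(duration * digit_rate))
    times = np.arange(n_digits) / digit_rate
    is_target = rng.random(n_digits) < p_target
    hit = is_target & (rng.random(n_digits) < hit_rate)
    fa = ~is_target & (rng.random(n_digits) < false_alarm_rate)
    resp_times = times[hit | fa] + lag
    resp_times = resp_times[resp_times < duration]

    target_bins = np.zeros(n_bins, dtype=np.uint8)
    response_bins = np.zeros(n_bins, dtype=np.uint8)
    target_bins[np.floor(times[is_target] / bin_width).astype(int)] = 1
    response_bins[np.floor(resp_times / bin_width).astype(int)] = 1
    return BehaviorTrain(target_bins, response_bins,
                         condition_bin_labels(timeline, bin_width), bin_width)
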