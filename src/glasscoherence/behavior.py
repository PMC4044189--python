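"""Fixation-task behavioral analysis.

Performance on the fixation digit task is quantified as the Pearson
correlation between the binary target and response trains (100 ms
bins), computed separately for bins belonging to each stimulus
condition and for response lags of 0-1.4 s (15 levels).  The resulting
participant x condition x lag correlations are submitted to a two-way
repeated-measures ANOVA with participants as a random factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LAGS = tuple(np.round(np.arange(15) * 0.1, 10))  # 0.0 .. 1.4 s


def bin_events(event_times, duration: float, bin_width: float = 0.1) -> np.ndarray:
    """Discretize event times into a binary series of 100 ms bins."""
    times = np.asarray(event_times, dtype=float)
    if times.size and (times.min() < 0 or times.max() >= duration):
        raise ValueError("event times must lie in [0, duration)")
    n_bins = int(np.ceil(duration / bin_width))
    out = np.zeros(n_bins, dtype=np.uint8)
    if times.size:
        out[np.floor(times / bin_width).astype(int)] = 1
    return out


@dataclass
class LagCorrelationResult:
    """Per-participant condition x lag Pearson (phi) correlations."""

    correlations: pd.DataFrame  # columns: participant, condition, lag, r
    lags: tuple
    bin_width: float = 0.1

    def to_array(self, participants, conditions) -> np.ndarray:
        """(participant, condition, lag) array in the given orders."""
        wide = self.correlations.set_index(["participant", "condition", "lag"])["r"]
        out = np.empty((len(participants), len(conditions), len(self.lags)))
        for i, p in enumerate(participants):
            for j, c in enumerate(conditions):
                for k, L in enumerate(self.lags):
                    out[i, j, k] = wide.loc[(p, c, L)]
        return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def lagged_correlation(target: np.ndarray, response: np.ndarray,
                       condition_labels: np.ndarray,
                       lags=DEFAULT_LAGS, bin_width: float = 0.1,
                       conditions=None, participant="p0") -> LagCorrelationResult:
    """Correlate target with lagged response within each condition's bins.

    For condition c and lag L, the Pearson correlation between
    ``target[t]`` and ``response[t + L/bin_width]`` is computed over
    bins whose condition label (at the *target* bin) is c; lagged
    indices past the series end are clipped.  Zero-variance
    restrictions yield NaN (missing).
    """
    target = np.asarray(target, dtype=float)
    response = np.asarray(response, dtype=float)
    condition_labels = np.asarray(condition_labels)
    if not (len(target) == len(response) == len(condition_labels)):
        raise ValueError("target, response and labels must have equal length")
    if conditions is None:
        conditions = [c for c in ("c0", "c33", "c66", "c100")
                      if c in set(condition_labels)]
    n = len(target)
    rows = []
    for c in conditions:
        cond_idx = np.flatnonzero(condition_labels == c)
        for L in lags:
            shift = int(round(L / bin_width))
            idx = cond_idx[cond_idx + shift < n]
            r = _pearson(target[idx], response[idx + shift])
            rows.append({"participant": participant, "condition": c,
                         "lag": float(L), "r": r})
    return LagCorrelationResult(correlations=pd.DataFrame(rows),
                                lags=tuple(float(L) for L in lags),
                                bin_width=bin_width)


@dataclass
class AnovaTable:
    """Two-way repeated-measures ANOVA partition.

    ``effects`` rows: condition, lag, condition x lag, each tested
    against its interaction with the random participant factor;
    ``pooled_lag`` reports the lag effect against the pooled
    (lag x participant within condition) error term.
    """

    effects: pd.DataFrame
    strata: pd.DataFrame        # participant and error-term SS/df
    pooled_lag: dict
    ss_total: float


def two_way_rm_anova(data: np.ndarray) -> AnovaTable:
    """Partition sums of squares for a (participant, A, B) data cube.

    Factor A is stimulus condition, factor B response lag; both fixed,
    participants random.  F for each fixed effect uses its interaction
    with participants as the error term; F_AB uses the three-way
    residual.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be participant x condition x lag")
    if np.isnan(data).any():
        raise ValueError("unbalanced data: missing cells are not supported")
    P, A, B = data.shape
    if P < 2:
        raise ValueError("need at least 2 participants")
    g = data.mean()
    m_p = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_pa = data.mean(axis=2)
    m_pb = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_p = A * B * np.sum((m_p - g) ** 2)
    ss_a = P * B * np.sum((m_a - g) ** 2)
    ss_b = P * A * np.sum((m_b - g) ** 2)
    ss_ab = P * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_pa = B * np.sum((m_pa - m_p[:, None] - m_a[None, :] + g) ** 2)
    ss_pb = A * np.sum((m_pb - m_p[:, None] - m_b[None, :] + g) ** 2)
    ss_total = np.sum((data - g) ** 2)
    ss_pab = ss_total - (ss_p + ss_a + ss_b + ss_ab + ss_pa + ss_pb)

    df = {"participant": P - 1, "condition": A - 1, "lag": B - 1,
          "condition x lag": (A - 1) * (B - 1),
          "condition x participant": (A - 1) * (P - 1),
          "lag x participant": (B - 1) * (P - 1),
          "residual": (A - 1) * (B - 1) * (P - 1)}

    def f_and_p(ss_num, df_num, ss_err, df_err):
        if ss_err <= 0 or df_err <= 0:
            return np.nan, np.nan
        F = (ss_num / df_num) / (ss_err / df_err)
        return F, float(stats.f.sf(F, df_num, df_err))

    rows = []
    for name, ss, err_name, ss_err in (
            ("condition", ss_a, "condition x participant", ss_pa),
            ("lag", ss_b, "lag x participant", ss_pb),
            ("condition x lag", ss_ab, "residual", ss_pab)):
        F, p = f_and_p(ss, df[name], ss_err, df[err_name])
        rows.append({"effect": name, "ss": ss, "df": df[name],
                     "error_term": err_name, "error_ss": ss_err,
                     "error_df": df[err_name], "F": F, "p": p})
    effects = pd.DataFrame(rows)

    strata = pd.DataFrame([
        {"term": "participant", "ss": ss_p, "df": df["participant"]},
        {"term": "condition x participant", "ss": ss_pa,
         "df": df["condition x participant"]},
        {"term": "lag x participant", "ss": ss_pb,
         "df": df["lag x participant"]},
        {"term": "residual", "ss": ss_pab, "df": df["residual"]},
    ])

    # pooled error for the lag effect: lag x participant within each
    # condition = (lag x participant) + residual strata combined
    ss_pooled = ss_pb + ss_pab
    df_pooled = df["lag x participant"] + df["residual"]
    F_pool, p_pool = f_and_p(ss_b, df["lag"], ss_pooled, df_pooled)
    pooled_lag = {"ss": ss_b, "df": df["lag"], "error_ss": ss_pooled,
                  "error_df": df_pooled, "F": F_pool, "p": p_pool}
    return AnovaTable(effects=effects, strata=strata, pooled_lag=pooled_lag,
                      ss_total=float(ss_total))


def analyze_behavior(trains_per_participant: dict, lags=DEFAULT_LAGS,
                     conditions=("c0", "c33", "c66", "c100")):
    """Full behavioral analysis from per-participant lists of trains.

    Concatenates each participant's runs, computes condition x lag
    correlations, and runs the two-way RM ANOVA.  Returns
    (LagCorrelationResult, AnovaTable).
    """
    frames = []
    participants = sorted(trains_per_participant)
    for pid in participants:
        trains = trains_per_participant[pid]
        target = np.concatenate([t.target_bins for t in trains])
        response = np.concatenate([t.response_bins for t in trains])
        labels = np.concatenate([t.condition_bins for t in trains])
        res = lagged_correlation(target, response, labels, lags=lags,
                                 conditions=list(conditions), participant=pid)
        frames.append(res.correlations)
    corr = LagCorrelationResult(
        correlations=pd.concat(frames, ignore_index=True),
        lags=tuple(float(L) for L in lags))
    cube = corr.to_array(participants, list(conditions))
    return corr, two_way_rm_anova(cube)
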