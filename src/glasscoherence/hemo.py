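"""Canonical hemodynamic response and block regressors.

The canonical double-gamma response (peak ~5 s, undershoot ~15 s) is the
difference of two gamma densities; condition regressors are unit-height
boxcars over a condition's blocks convolved with this kernel at fine
temporal resolution and sampled at the volume acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import BLANK, RunTimeline


@dataclass(frozen=True)
class HemoParams:
    """Double-gamma kernel parameters (defaults: the canonical response)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0


def canonical_hrf(t, params: HemoParams = HemoParams()) -> np.ndarray:
    """Evaluate the double-gamma response at times ``t`` (seconds >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hemodynamic response is defined for t >= 0 only")
    peak = stats.gamma.pdf(t, a=params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, a=params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - params.undershoot_ratio * under
    return np.where(t <= params.kernel_length, h, 0.0)


def condition_regressor(timeline: RunTimeline, condition: str,
                        params: HemoParams = HemoParams(),
                        tr: float = 2.0, dt: float = 0.1) -> np.ndarray:
    """Per-volume regressor for one condition of one run.

    Unit-height boxcar over the condition's blocks, convolved with the
    canonical kernel on a ``dt`` grid, sampled at volume onsets
    ``0, tr, 2 tr, ...``.  A known label with no blocks yields zeros.
    """
    known = timeline.labels_present() | {BLANK}
    if condition not in known:
        raise ValueError(f"condition {condition!r} not in timeline")
    n_fine = int(round(timeline.total_duration / dt))
    box = np.zeros(n_fine)
    for onset, duration, lab in timeline.blocks:
        if lab == condition:
            i0 = int(round(onset / dt))
            i1 = int(round((onset + duration) / dt))
            box[i0:i1] = 1.0
    kernel = canonical_hrf(np.arange(0.0, params.kernel_length + dt, dt), params)
    fine = np.convolve(box, kernel * dt)[:n_fine]
    vol_idx = np.round(np.arange(timeline.n_volumes) * tr / dt).astype(int)
    return fine[vol_idx]


def condition_regressors(timeline: RunTimeline, conditions,
                         params: HemoParams = HemoParams(),
                         tr: float = 2.0, dt: float = 0.1) -> np.ndarray:
    """Stack regressors for several conditions: shape (n_volumes, k)."""
    return np.column_stack([
        condition_regressor(timeline, c, params, tr, dt) for c in conditions])
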