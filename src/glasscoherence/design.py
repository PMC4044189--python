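"""Block-design protocol: counterbalanced sequences and run timelines.

One run is a 6 s blank lead-in, four sequences of (four 16 s stimulus
blocks + one 16 s blank), and one appended 16 s blank: 342 s = 171
volumes at TR = 2 s.  Within a run, the stimulus blocks are arranged so
that every condition immediately follows every other condition exactly
once (a row-complete / Williams arrangement); blank blocks break the
adjacency chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng

BLANK = "blank"
COHERENCE_LABELS = ("c0", "c33", "c66", "c100")
#: nominal coherence proportion for each condition label
CONDITION_COHERENCE = {"c0": 0.0, "c33": 0.33, "c66": 0.66, "c100": 1.0}


def condition_labels(n_conditions: int) -> tuple[str, ...]:
    if n_conditions == 4:
        return COHERENCE_LABELS
    return tuple(f"cond{i}" for i in range(n_conditions))


@dataclass(frozen=True)
class BlockProtocol:
    """Timing parameters of the block design (defaults: the experiment)."""

    n_conditions: int = 4
    block_duration: float = 16.0
    sequences_per_run: int = 4
    pre_blank: float = 6.0
    blank_appended: bool = True
    tr: float = 2.0
    n_runs: int = 12
    censor_volumes_per_run: int = 3

    def __post_init__(self):
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        for name in ("block_duration", "pre_blank"):
            dur = getattr(self, name)
            if dur < 0 or abs(dur / self.tr - round(dur / self.tr)) > 1e-9:
                raise ValueError(f"{name} must be a non-negative integer "
                                 f"multiple of tr")

    @property
    def labels(self) -> tuple[str, ...]:
        return condition_labels(self.n_conditions)


@dataclass
class RunTimeline:
    """Ordered blocks of one run: (onset s, duration s, condition label)."""

    blocks: list
    total_duration: float
    n_volumes: int

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table: onset, duration, trial_type."""
        return pd.DataFrame(self.blocks,
                            columns=["onset", "duration", "trial_type"])

    def save_tsv(self, path) -> None:
        self.to_events_frame().to_csv(path, sep="\t", index=False)

    def labels_present(self) -> set:
        return {b[2] for b in self.blocks}


def _williams_square(n: int) -> np.ndarray:
    """Row-complete Latin square for even n (Williams construction)."""
    first = np.empty(n, dtype=int)
    first[0] = 0
    lo, hi = 1, n - 1
    for j in range(1, n):
        first[j] = hi if j % 2 else lo
        if j % 2:
            hi -= 1
        else:
            lo += 1
    return np.mod(first[None, :] + np.arange(n)[:, None], n)


def counterbalanced_orders(n_conditions: int, rng) -> list[list[int]]:
    """n sequences (permutations of 0..n-1) whose within-sequence adjacent
    ordered pairs cover every ordered pair of distinct conditions exactly
    once.

    Exists for every even n (Williams squares); for odd n no single set
    of n sequences has the property (e.g. n = 3, by exhaustive
    enumeration), so ``ValueError`` is raised.  The returned solution is
    randomized via symbol relabeling, row shuffling and global reversal.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    if n_conditions % 2:
        raise ValueError(f"no first-order counterbalanced set of "
                         f"{n_conditions} sequences exists for odd "
                         f"n_conditions")
    rng = as_rng(rng)
    square = _williams_square(n_conditions)
    relabel = rng.permutation(n_conditions)
    square = relabel[square]
    square = square[rng.permutation(n_conditions)]
    if rng.integers(0, 2):
        square = square[:, ::-1]  # reversal maps (x,y)->(y,x): still complete
    return [[int(v) for v in row] for row in square]


def transition_counts(orders) -> np.ndarray:
    """Matrix of within-sequence adjacent ordered-pair counts."""
    n = max(max(seq) for seq in orders) + 1
    counts = np.zeros((n, n), dtype=int)
    for seq in orders:
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
    return counts


def build_run_timeline(protocol: BlockProtocol, orders) -> RunTimeline:
    """Assemble one run: pre-blank, then per sequence the stimulus blocks
    followed by a blank block, then an optional appended blank."""
    labels = protocol.labels
    for seq in orders:
        if sorted(seq) != list(range(protocol.n_conditions)):
            raise ValueError("each order must be a permutation of all "
                             "conditions")
    if len(orders) != protocol.sequences_per_run:
        raise ValueError(f"expected {protocol.sequences_per_run} sequences, "
                         f"got {len(orders)}")
    blocks = []
    t = protocol.pre_blank
    bd = protocol.block_duration
    for seq in orders:
        for cond in seq:
            blocks.append((t, bd, labels[cond]))
            t += bd
        blocks.append((t, bd, BLANK))
        t += bd
    if protocol.blank_appended:
        blocks.append((t, bd, BLANK))
        t += bd
    total = t
    n_vol = total / protocol.tr
    if abs(n_vol - round(n_vol)) > 1e-9:
        raise ValueError("total duration is not a whole number of volumes")
    return RunTimeline(blocks=blocks, total_duration=total,
                       n_volumes=int(round(n_vol)))


def condition_onsets(timeline: RunTimeline, condition: str) -> list[float]:
    """Onsets of all blocks carrying ``condition``, in temporal order."""
    known = timeline.labels_present() | set(COHERENCE_LABELS) | {BLANK}
    if condition not in known:
        raise ValueError(f"unknown condition label {condition!r}")
    return [onset for onset, _, lab in timeline.blocks if lab == condition]
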