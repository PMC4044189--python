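"""Named random substreams derived from a single pipeline seed.

Each pipeline stage draws from its own child of the root ``SeedSequence``
so that adding or removing draws in one stage does not perturb the others.
"""

from __future__ import annotations

import numpy as np

#: fixed substream indices; appending new names keeps old streams stable
STREAMS = {
    "stimulus": 0,
    "design": 1,
    "cohort": 2,
    "behavior": 3,
    "permutation": 4,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    if name not in STREAMS:
        raise KeyError(f"unknown random substream {name!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[name],))
    return np.random.default_rng(ss)


def as_rng(rng) -> np.random.Generator:
    """Coerce an int seed or Generator to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
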