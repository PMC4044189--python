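"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_complete_sets(n):
    """All n-tuples of permutations whose within-sequence adjacencies cover
    every ordered pair of distinct conditions exactly once."""
    perms = list(itertools.permutations(range(n)))
    pair_id = {}
    for a in range(n):
        for b in range(n):
            if a != b:
                pair_id[(a, b)] = len(pair_id)
    masks = []
    for p in perms:
        m = 0
        for a, b in zip(p[:-1], p[1:]):
            m |= 1 << pair_id[(a, b)]
        masks.append(m)
    full = (1 << len(pair_id)) - 1
    found = []
    for combo in itertools.combinations_with_replacement(range(len(perms)), n):
        m = 0
        for i in combo:
            m |= masks[i]
        if m == full and sum(bin(masks[i]).count("1")
                             for i in combo) == n * (n - 1):
            found.append(tuple(perms[i] for i in combo))
    return found


def exhaustive_two_participant_p(values, weights):
    """Exact directional tail probability over all 24^2 joint permutations
    of two participants' four condition values."""
    w = np.asarray(weights, float)
    obs = float((values @ w).mean())
    perms = list(itertools.permutations(range(4)))
    null = []
    for p0 in perms:
        for p1 in perms:
            stat = 0.5 * (values[0, list(p0)] @ w + values[1, list(p1)] @ w)
            null.append(stat)
    null = np.asarray(null)
    direction = np.sign(obs)
    if direction == 0:
        return 1.0
    return float(np.mean(direction * null >= direction * obs))
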