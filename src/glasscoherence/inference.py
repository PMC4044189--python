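"""Trend analysis of coherence response functions.

The shape of each area's coherence response function is summarized by
orthogonal-polynomial contrasts over the four ordered coherence levels
(linear [-3,-1,+1,+3], quadratic [+1,-1,-1,+1], cubic [-1,+3,-3,+1]).
Significance is assessed by a permutation test: each participant's
condition labels are independently shuffled each iteration, the group
contrast recomputed, and the directional tail probability doubled
(two-tailed).  A meridian-distance binned variant subdivides an area's
nodes by their angular distance from the vertical meridian.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

import numpy as np
import pandas as pd

from ._rng import as_rng
from .glm import AreaResponseMatrix, area_coherence_response


@dataclass(frozen=True)
class ContrastSet:
    """Integer orthogonal polynomial contrast vectors for k ordered levels."""

    linear: tuple
    quadratic: tuple | None = None
    cubic: tuple | None = None

    def as_dict(self) -> dict:
        out = {"linear": self.linear}
        if self.quadratic is not None:
            out["quadratic"] = self.quadratic
        if self.cubic is not None:
            out["cubic"] = self.cubic
        return out


def _integer_contrast(vec) -> tuple:
    """Scale a rational vector to the smallest integer form, last entry > 0."""
    denoms = [f.denominator for f in vec]
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(f * lcm) for f in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    ints = [v // g for v in ints]
    last = next((v for v in reversed(ints) if v != 0), 1)
    if last < 0:
        ints = [-v for v in ints]
    return tuple(ints)


def orthogonal_contrasts(k: int) -> ContrastSet:
    """Orthogonal polynomial contrasts for k equally spaced levels.

    Gram-Schmidt over exact rationals on levels 0..k-1, reduced to
    primitive integer vectors, up to degree min(3, k-1).
    """
    if k < 2:
        raise ValueError("need at least 2 levels for trend contrasts")
    x = [Fraction(i) for i in range(k)]
    basis = [[Fraction(1)] * k]
    out = {}
    for deg in range(1, min(3, k - 1) + 1):
        v = [xi ** deg for xi in x]
        for b in basis:
            num = sum(vi * bi for vi, bi in zip(v, b))
            den = sum(bi * bi for bi in b)
            coef = num / den
            v = [vi - coef * bi for vi, bi in zip(v, b)]
        basis.append(v)
        out[deg] = _integer_contrast(v)
    return ContrastSet(linear=out[1], quadratic=out.get(2), cubic=out.get(3))


@dataclass
class TrendResult:
    """Group contrast coefficient with its permutation p-value."""

    coefficient: float
    p_two_tailed: float
    n_iterations: int
    observed_direction: int


def _matrix_values(matrix) -> np.ndarray:
    if isinstance(matrix, AreaResponseMatrix):
        return matrix.values.to_numpy(dtype=float)
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)


def trend_coefficient(matrix, weights) -> float:
    """Mean over participants of the per-participant contrast value."""
    vals = _matrix_values(matrix)
    w = np.asarray(weights, dtype=float)
    if vals.shape[1] != w.size:
        raise ValueError("contrast length must match number of conditions")
    return float((vals @ w).mean())


def permutation_trend_test(matrix, weights, n_iterations: int = 10_000,
                           rng=0) -> TrendResult:
    """Permutation test of a trend contrast.

    Null distribution: each participant's condition values are
    independently and uniformly permuted each iteration and the group
    coefficient recomputed.  One-tailed p = (1 + #{null at least as
    extreme in the observed direction}) / (n_iterations + 1), doubled
    for the two-tailed value (capped at 1).
    """
    rng = as_rng(rng)
    vals = _matrix_values(matrix)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    w = np.asarray(weights, dtype=float)
    if vals.shape[1] != w.size:
        raise ValueError("contrast length must match number of conditions")
    obs = float((vals @ w).mean())
    n_part, k = vals.shape

    # iterate in chunks to bound memory at ~n_chunk * n_part * k floats
    direction = int(np.sign(obs))
    count = 0
    remaining = n_iterations
    while remaining > 0:
        m = min(remaining, 2000)
        order = np.argsort(rng.random((m, n_part, k)), axis=-1)
        permuted = np.take_along_axis(vals[None, :, :], order, axis=-1)
        null = (permuted @ w).mean(axis=1)
        if direction >= 0:
            count += int(np.sum(null >= obs)) if direction > 0 else m
        else:
            count += int(np.sum(null <= obs))
        remaining -= m
    p_one = (1 + count) / (n_iterations + 1)
    return TrendResult(coefficient=obs,
                       p_two_tailed=min(1.0, 2.0 * p_one),
                       n_iterations=n_iterations,
                       observed_direction=direction)


DEFAULT_MERIDIAN_EDGES = (0.0, 22.5, 45.0, 67.5, 90.0)


def binned_trend_analysis(node_psc: pd.DataFrame, weights,
                          bin_edges=DEFAULT_MERIDIAN_EDGES,
                          n_iterations: int = 10_000, rng=0,
                          conditions=("c0", "c33", "c66", "c100")) -> dict:
    """Trend test within meridian-distance bins of an area's nodes.

    ``node_psc`` needs participant, meridian_distance and per-condition
    psc columns.  Nodes are grouped by ``bin_edges`` (which must
    partition [0, 90]); each bin gets the area averaging/normalization
    then the permutation test.  A bin empty for any participant maps to
    ``None`` (missing).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 90.0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must increase from 0 to 90")
    rng = as_rng(rng)
    participants = sorted(node_psc["participant"].unique())
    results = {}
    d = node_psc["meridian_distance"].to_numpy(dtype=float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (d >= lo) & (d < hi) if hi < 90 else (d >= lo) & (d <= hi)
        sub = node_psc[in_bin]
        key = (float(lo), float(hi))
        try:
            mat = area_coherence_response(sub, area=f"bin[{lo},{hi})",
                                          conditions=conditions,
                                          participants=participants)
        except ValueError:
            results[key] = None
            continue
        results[key] = permutation_trend_test(mat, weights, n_iterations, rng)
    return results


def trend_table(area_matrices: dict, n_iterations: int = 10_000,
                rng=0) -> pd.DataFrame:
    """Area x {linear, quadratic, cubic} coefficient/p table."""
    rng = as_rng(rng)
    contrasts = orthogonal_contrasts(4).as_dict()
    rows = []
    for area, matrix in area_matrices.items():
        row = {"area": area}
        for name, w in contrasts.items():
            res = permutation_trend_test(matrix, w, n_iterations, rng)
            row[f"{name}_coeff"] = res.coefficient
            row[f"{name}_p"] = res.p_two_tailed
        rows.append(row)
    return pd.DataFrame(rows)
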