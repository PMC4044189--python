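"""Design matrix construction and prewhitened GLM fitting.

The design holds one regressor per stimulus condition spanning all runs,
per-run Legendre drift polynomials up to degree 3, and six motion
nuisance columns (for the experimental protocol: 2016 retained volumes x
58 regressors after censoring the first three volumes of each run).
Noise temporal correlation is handled per node with an ARMA(1,1) model:
ordinary least squares, conditional maximum-likelihood (a, b) estimation
on the residuals, then generalized least squares via innovation
filtering of data and design.  Condition betas are converted to percent
signal change of the fitted drift baseline; stimulus-responsive nodes
are selected by a one-sided all-stimulus > 0 contrast with
Benjamini-Hochberg correction within each hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import optimize, stats
from scipy.signal import lfilter
from statsmodels.stats.multitest import multipletests

from .design import BlockProtocol, RunTimeline
from .hemo import HemoParams, condition_regressors


def legendre_regressors(n_volumes: int, max_degree: int) -> np.ndarray:
    """Legendre polynomials P0..Pmax on n equally spaced points in [-1, 1]."""
    if n_volumes < max_degree + 1:
        raise ValueError("need at least max_degree + 1 points")
    x = np.linspace(-1.0, 1.0, n_volumes)
    return npleg.legvander(x, max_degree)


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list
    condition_idx: np.ndarray
    drift_idx: np.ndarray
    motion_idx: np.ndarray
    run_slices: list          # row ranges of retained volumes, per run
    condition_names: list

    @property
    def shape(self):
        return self.matrix.shape


def build_design_matrix(timelines, motion, protocol: BlockProtocol,
                        params: HemoParams = HemoParams()) -> DesignMatrix:
    """Assemble the censored multi-run design matrix.

    ``timelines``: one RunTimeline per run; ``motion``: one
    (n_volumes, 6) array per run, standardized per run here.  Condition
    and drift regressors are built on the full run grid, then the first
    ``censor_volumes_per_run`` rows of each run are dropped.
    """
    if len(timelines) != len(motion):
        raise ValueError("need one motion table per timeline")
    n_runs = len(timelines)
    c = protocol.censor_volumes_per_run
    conditions = list(protocol.labels)
    cond_blocks, leg_blocks, mot_blocks, run_slices = [], [], [], []
    row = 0
    for tl, mot in zip(timelines, motion):
        mot = np.asarray(mot, dtype=float)
        if mot.shape[0] != tl.n_volumes:
            raise ValueError("motion rows must match run volume count")
        regs = condition_regressors(tl, conditions, params, protocol.tr)
        L = legendre_regressors(tl.n_volumes, 3)
        keep = slice(c, tl.n_volumes)
        cond_blocks.append(regs[keep])
        leg_blocks.append(L[keep])
        m = mot[keep]
        mu, sd = m.mean(axis=0), m.std(axis=0)
        sd[sd == 0] = 1.0
        mot_blocks.append((m - mu) / sd)
        n_keep = tl.n_volumes - c
        run_slices.append(slice(row, row + n_keep))
        row += n_keep

    n_rows = row
    cond = np.vstack(cond_blocks)
    drift = np.zeros((n_rows, 4 * n_runs))
    for r, (blk, sl) in enumerate(zip(leg_blocks, run_slices)):
        drift[sl, 4 * r:4 * r + 4] = blk
    mot = np.vstack(mot_blocks)
    X = np.hstack([cond, drift, mot])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    names = (conditions
             + [f"run{r}_P{d}" for r in range(n_runs) for d in range(4)]
             + [f"motion{j}" for j in range(mot.shape[1])])
    k = len(conditions)
    return DesignMatrix(
        matrix=X, names=names,
        condition_idx=np.arange(k),
        drift_idx=np.arange(k, k + 4 * n_runs),
        motion_idx=np.arange(k + 4 * n_runs, X.shape[1]),
        run_slices=run_slices, condition_names=conditions)


def censor_concat(data_runs: np.ndarray, protocol: BlockProtocol) -> np.ndarray:
    """Drop the first censored volumes of each run and concatenate.

    ``data_runs``: (..., n_runs, n_volumes) -> (..., total retained).
    """
    c = protocol.censor_volumes_per_run
    return np.concatenate(
        [data_runs[..., r, c:] for r in range(data_runs.shape[-2])], axis=-1)


# ---------------------------------------------------------------------------
# ARMA(1,1) estimation and whitening

def _arma11_css(x_runs, a: float, b: float) -> float:
    """Conditional sum of squared innovations of pooled within-run series."""
    total = 0.0
    for x in x_runs:
        e = lfilter([1.0, -a], [1.0, b], x)
        total += float(e @ e)
    return total


def _rho1(a: float, b: float) -> float:
    return (1 + a * b) * (a + b) / (1 + 2 * a * b + b * b)


def estimate_arma11(residuals: np.ndarray, run_slices=None) -> tuple[float, float]:
    """Estimate ARMA(1,1) (a, b) from GLM residuals.

    Maximizes the conditional Gaussian likelihood (sum of squared
    innovations) of the per-run demeaned residuals, initialized by
    moment matching on the lag-1/lag-2 autocorrelations and constrained
    to the stationary/invertible region.  Degenerate (near-constant)
    residuals fall back to (0, 0) with a warning.
    """
    residuals = np.asarray(residuals, dtype=float)
    if run_slices is None:
        run_slices = [slice(0, len(residuals))]
    x_runs = [residuals[sl] - residuals[sl].mean() for sl in run_slices]
    var = sum(float(x @ x) for x in x_runs)
    n = sum(len(x) for x in x_runs)
    if n < 50:
        raise ValueError("need at least 50 residual points")
    if var / n < 1e-12:
        warnings.warn("near-constant residuals; ARMA(1,1) falls back to (0, 0)",
                      RuntimeWarning)
        return 0.0, 0.0

    def acov(k):
        return sum(float(x[k:] @ x[:-k]) for x in x_runs if len(x) > k) / var

    r1, r2 = acov(1), acov(2)
    # negligible autocorrelation: start at white noise (r2/r1 is unstable)
    if abs(r1) < 2.0 / np.sqrt(n):
        a0, b0 = 0.0, 0.0
    else:
        a0 = float(np.clip(r2 / r1, -0.9, 0.9))
        bgrid = np.linspace(-0.9, 0.9, 37)
        b0 = float(bgrid[np.argmin([(_rho1(a0, b) - r1) ** 2 for b in bgrid])])

    # small ridge toward (0, 0): the CSS surface is exactly flat along the
    # common-factor line b = -a, so white-ish noise is otherwise unidentified
    lam = 3e-3 * var

    def objective(theta):
        a, b = theta
        if abs(a) >= 0.97 or abs(b) >= 0.97:
            return 1e12
        return _arma11_css(x_runs, a, b) + lam * (a * a + b * b)

    res = optimize.minimize(objective, x0=[a0, b0], method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-8 * var,
                                     "maxiter": 150})
    a, b = res.x
    return float(np.clip(a, -0.97, 0.97)), float(np.clip(b, -0.97, 0.97))


def whiten_series(arr: np.ndarray, run_slices, a: float, b: float) -> np.ndarray:
    """Apply the ARMA(1,1) innovation filter per run (rows = time)."""
    out = np.empty_like(arr, dtype=float)
    for sl in run_slices:
        out[sl] = lfilter([1.0, -a], [1.0, b], arr[sl], axis=0)
    return out


# ---------------------------------------------------------------------------
# GLM fit

@dataclass
class GlmFit:
    betas: np.ndarray
    residuals: np.ndarray       # raw-scale residuals y - X @ betas
    arma: tuple                 # (a, b), (0, 0) for plain OLS
    baseline_mean: float        # mean fitted drift-only timecourse
    sigma2: float               # innovation variance of the (whitened) fit
    cov_scale: np.ndarray       # (X'X)^-1 of the (whitened) design
    dof: int
    design: DesignMatrix

    @property
    def condition_betas(self) -> np.ndarray:
        return self.betas[self.design.condition_idx]


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    return beta


def fit_glm(y: np.ndarray, X: DesignMatrix, whiten: bool = True) -> GlmFit:
    """Fit one node's censored, concatenated series.

    With ``whiten``: OLS, ARMA(1,1) estimation on the residuals, then
    generalized least squares by innovation-filtering data and design.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.matrix.shape[0]:
        raise ValueError("y length must match design rows (censored volumes)")
    beta = _ols(X.matrix, y)
    resid = y - X.matrix @ beta
    a = b = 0.0
    Xw, yw = X.matrix, y
    if whiten:
        a, b = estimate_arma11(resid, X.run_slices)
        if (a, b) != (0.0, 0.0):
            Xw = whiten_series(X.matrix, X.run_slices, a, b)
            yw = whiten_series(y, X.run_slices, a, b)
            beta = _ols(Xw, yw)
            resid = y - X.matrix @ beta
    rw = yw - Xw @ beta
    dof = X.matrix.shape[0] - X.matrix.shape[1]
    sigma2 = float(rw @ rw) / dof
    cov_scale = np.linalg.inv(Xw.T @ Xw)
    baseline = float((X.matrix[:, X.drift_idx] @ beta[X.drift_idx]).mean())
    return GlmFit(betas=beta, residuals=resid, arma=(a, b),
                  baseline_mean=baseline, sigma2=sigma2, cov_scale=cov_scale,
                  dof=dof, design=X)


def betas_to_psc(fit: GlmFit) -> np.ndarray:
    """Condition betas as percent signal change of the drift baseline."""
    if fit.baseline_mean <= 0:
        raise ValueError("baseline mean must be positive for psc conversion")
    return 100.0 * fit.condition_betas / fit.baseline_mean


def responsiveness_test(fit: GlmFit) -> tuple[float, float]:
    """One-sided t-test of the all-stimulus > 0 contrast (sum of betas)."""
    k = len(fit.design.condition_idx)
    c = np.zeros(len(fit.betas))
    c[fit.design.condition_idx] = 1.0
    se = float(np.sqrt(fit.sigma2 * c @ fit.cov_scale @ c))
    t = float(c @ fit.betas) / se if se > 0 else 0.0
    p = float(stats.t.sf(t, fit.dof))
    return t, p


def select_responsive_nodes(pvalues: np.ndarray, groups, q: float = 0.001) -> np.ndarray:
    """Benjamini-Hochberg selection at level q, separately per group.

    ``groups`` are e.g. hemisphere labels; returns a boolean mask.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    groups = np.asarray(groups)
    selected = np.zeros(len(pvalues), dtype=bool)
    for g in np.unique(groups):
        mask = groups == g
        if not mask.any():
            continue
        rej = multipletests(pvalues[mask], alpha=q, method="fdr_bh")[0]
        selected[mask] = rej
    return selected


# ---------------------------------------------------------------------------
# Area-level response matrices

@dataclass
class AreaResponseMatrix:
    """Participant x condition normalized psc for one visual area."""

    values: pd.DataFrame        # index participant, columns conditions
    area: str
    n_nodes_selected: pd.Series


def area_coherence_response(node_psc: pd.DataFrame, area: str,
                            conditions=("c0", "c33", "c66", "c100"),
                            participants=None) -> AreaResponseMatrix:
    """Average selected-node psc per participant, then normalize.

    ``node_psc`` needs a ``participant`` column and one column per
    condition; every participant must contribute at least one node.
    Each participant's mean across the conditions is subtracted, so rows
    of the result sum to zero.
    """
    conditions = list(conditions)
    if participants is None:
        participants = sorted(node_psc["participant"].unique())
    rows, counts = [], []
    for p in participants:
        sub = node_psc[node_psc["participant"] == p]
        if len(sub) == 0:
            raise ValueError(f"no selected nodes for participant {p!r} "
                             f"in area {area!r}")
        rows.append(sub[conditions].mean(axis=0).to_numpy())
        counts.append(len(sub))
    vals = np.array(rows)
    vals = vals - vals.mean(axis=1, keepdims=True)
    values = pd.DataFrame(vals, index=pd.Index(participants, name="participant"),
                          columns=conditions)
    return AreaResponseMatrix(values=values, area=area,
                              n_nodes_selected=pd.Series(counts, index=participants))


# ---------------------------------------------------------------------------
# Cohort-level orchestration

@dataclass
class CohortFit:
    node_table: pd.DataFrame
    area_matrices: dict
    design_shape: tuple


def fit_cohort(cohort, whiten: bool = True, q: float = 0.001,
               hemo: HemoParams | None = None) -> CohortFit:
    """Fit every node of a simulated cohort and assemble area matrices.

    Per participant the design is built once (identical across that
    participant's nodes); node selection runs per participant per
    hemisphere; area matrices average selected nodes only.
    """
    protocol = cohort.config.protocol
    hemo = cohort.config.hemo if hemo is None else hemo
    conditions = list(protocol.labels)
    records = []
    design_shape = None
    for part in cohort.participants:
        X = build_design_matrix(part.timelines, list(part.motion), protocol,
                                hemo)
        design_shape = X.shape
        Y = censor_concat(part.data, protocol)  # (n_nodes, rows)
        for i in range(Y.shape[0]):
            fit = fit_glm(Y[i], X, whiten=whiten)
            psc = betas_to_psc(fit)
            t, p = responsiveness_test(fit)
            meta = part.nodes.iloc[i]
            rec = {"participant": part.participant_id,
                   "node_id": meta["node_id"], "area": meta["area"],
                   "hemisphere": meta["hemisphere"],
                   "meridian_distance": meta["meridian_distance"],
                   "truth_responsive": bool(meta["responsive"]),
                   "t": t, "p": p, "ar": fit.arma[0], "ma": fit.arma[1],
                   "baseline_mean": fit.baseline_mean}
            rec.update({c: v for c, v in zip(conditions, psc)})
            records.append(rec)
    table = pd.DataFrame(records)

    table["selected"] = False
    for (pid, _), idx in table.groupby(["participant", "hemisphere"]).groups.items():
        sub = table.loc[idx]
        table.loc[idx, "selected"] = select_responsive_nodes(
            sub["p"].to_numpy(), np.zeros(len(sub)), q=q)

    matrices = {}
    for area in table["area"].unique():
        sel = table[(table["area"] == area) & table["selected"]]
        matrices[area] = area_coherence_response(sel, area, conditions)
    return CohortFit(node_table=table, area_matrices=matrices,
                     design_shape=design_shape)
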