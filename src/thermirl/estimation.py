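"""Regularized maximum-likelihood estimation of the value function (OptV).

Observed state transitions {s_t, s_{t+1}} are assumed to be draws from the
stationary optimal LMDP policy π*(s'|s; v).  The value function is the
maximizer of the smoothness-penalized log-likelihood

    v̂ = argmax_v [ Σ_t log π*(s_{t+1}|s_t; v)
                    − λ Σ_s Σ_{s'∈χ(s)} |v(s) − v(s')|² ],

where χ(s) is the 4-neighborhood of s on the state mesh.  The sum over s
then s'∈χ(s) counts each unordered neighbor pair twice; that double
counting is kept (it is absorbed into λ).  The objective is concave in v,
so a deterministic quasi-Newton ascent from v = 0 finds the global optimum.

λ and the passive-noise scales (σ_T, σ_dT) are chosen by k-fold
cross-validation over contiguous blocks of the transition sequence
(nine folds by default), maximizing the mean held-out log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import logsumexp

from .exceptions import DataError, NumericalError
from .grid import StateGrid
from .lmdp import PassiveKernel, ValueFunction, as_values, gaussian_passive_kernel

__all__ = [
    "TransitionData", "FitConfig", "CVResult", "ModelComparison",
    "transition_loglik", "smoothness_penalty", "estimate_value",
    "penalized_objective", "cross_validate", "compare_models",
]


@dataclass(frozen=True)
class TransitionData:
    """Ordered (from-state, to-state) pairs observed at the Δt cadence.

    Pairs are emitted only between consecutive resampled time points of the
    same worm track segment — never across worms or across tracking gaps.
    The order of ``pairs`` is the temporal order used for contiguous
    cross-validation folds.
    """

    pairs: np.ndarray                 # (M, 2) int
    worm_ids: np.ndarray              # (M,) label per pair
    n_states: int
    n_clipped: int = 0                # samples clipped into boundary bins
    n_rejected: int = 0               # samples rejected out of range
    _counts: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "worm_ids", np.asarray(self.worm_ids))
        if len(self.worm_ids) != len(pairs):
            raise DataError("worm_ids and pairs must have equal length")
        if len(pairs) and (pairs.min() < 0 or pairs.max() >= self.n_states):
            raise DataError("state index outside [0, n_states)")

    def __len__(self) -> int:
        return len(self.pairs)

    def counts(self) -> np.ndarray:
        """Dense (N, N) matrix C(s, s') of observed transition counts (cached)."""
        if self._counts is None:
            C = np.zeros((self.n_states, self.n_states))
            np.add.at(C, (self.pairs[:, 0], self.pairs[:, 1]), 1.0)
            object.__setattr__(self, "_counts", C)
        return self._counts

    def subset(self, index) -> "TransitionData":
        """A new TransitionData over ``pairs[index]`` (order preserved)."""
        return TransitionData(self.pairs[index], self.worm_ids[index],
                              self.n_states, self.n_clipped, self.n_rejected)

    def folds(self, n_folds: int):
        """Contiguous equal blocks of the pair sequence, as (train, test) pairs."""
        if len(self) < n_folds:
            raise DataError(
                f"{len(self)} transitions cannot be split into {n_folds} folds")
        blocks = np.array_split(np.arange(len(self)), n_folds)
        out = []
        for i in range(n_folds):
            test = blocks[i]
            train = np.concatenate([blocks[j] for j in range(n_folds) if j != i])
            out.append((self.subset(train), self.subset(test)))
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "worm_id": self.worm_ids,
            "t_index": np.arange(len(self)),
            "from_k": self.pairs[:, 0],
            "to_k": self.pairs[:, 1],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_states: int) -> "TransitionData":
        df = pd.read_csv(path)
        need = {"worm_id", "from_k", "to_k"}
        if not need <= set(df.columns):
            raise DataError(f"transition CSV missing columns {need - set(df.columns)}")
        return cls(df[["from_k", "to_k"]].to_numpy(), df["worm_id"].to_numpy(),
                   n_states)


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of the penalized fit.

    ``lam`` is the smoothness-penalty weight λ; ``value_floor`` bounds v
    from below so unvisited states cannot run away; ``p_floor`` drops
    observed transitions whose passive probability underflows the finite
    grid's Gaussian tail (they are counted, not allowed to contribute −∞).
    """

    lam: float = 0.1
    tol: float = 1e-9
    max_iter: int = 2000
    value_floor: float = -30.0
    p_floor: float = 1e-12

    def __post_init__(self):
        if self.lam < 0:
            raise DataError(f"lambda must be >= 0 (got {self.lam})")
        if not self.tol > 0:
            raise DataError("tolerance must be > 0")


def _supported_counts(data: TransitionData, kernel: PassiveKernel,
                      p_floor: float):
    """Counts restricted to transitions the kernel supports, plus the tally."""
    C = data.counts()
    ok = kernel.matrix > p_floor
    excluded = int(C[~ok].sum())
    if excluded:
        C = np.where(ok, C, 0.0)
    return C, excluded


def transition_loglik(v, kernel: PassiveKernel, data: TransitionData,
                      p_floor: float = 1e-12) -> float:
    """Log-likelihood Σ_t log π*(s_{t+1} | s_t; v) in nats.

    Computed from the transition-count matrix:
    Σ_{s,s'} C(s,s') [log p(s'|s) + v(s')] − Σ_s C(s,·) logΣ_y p(y|s)e^{v(y)}.
    Pairs with p(s'|s) <= p_floor are excluded (the caller can tally them
    via :func:`estimate_value`'s metadata).
    """
    if len(data) == 0:
        raise DataError("transition_loglik: empty transition data")
    v = as_values(v)
    C, _ = _supported_counts(data, kernel, p_floor)
    logp = kernel.log_matrix
    row_tot = C.sum(axis=1)
    lse = logsumexp(logp + v[None, :], axis=1)
    fixed = float(np.sum(C * np.where(np.isfinite(logp), logp, 0.0)))
    return fixed + float(C.sum(axis=0) @ v) - float(row_tot @ lse)


def smoothness_penalty(v, grid: StateGrid) -> float:
    """Σ_s Σ_{s'∈χ(s)} (v(s) − v(s'))², each unordered pair counted twice.

    Equals 2 vᵀLv for the neighbor-graph Laplacian L; invariant under
    v → v + c.
    """
    v = as_values(v)
    return float(2.0 * v @ (grid.laplacian @ v))


def _make_neg_objective(data: TransitionData, kernel: PassiveKernel,
                        grid: StateGrid, cfg: FitConfig):
    """Closure computing (−objective, −gradient) of the penalized fit."""
    C, excluded = _supported_counts(data, kernel, cfg.p_floor)
    if C.sum() == 0:
        raise DataError("no transitions supported by the kernel")
    logp = kernel.log_matrix
    in_counts = C.sum(axis=0)
    row_tot = C.sum(axis=1)
    fixed = float(np.sum(C * np.where(np.isfinite(logp), logp, 0.0)))
    L = grid.laplacian.tocsr()
    lam = cfg.lam
    buf = np.empty_like(logp)

    def neg_obj_and_grad(v):
        # fused objective + gradient with a reused buffer: the row-wise
        # log-sum-exp dominates the fit cost on dense kernels
        np.add(logp, v[None, :], out=buf)
        m = buf.max(axis=1)
        np.subtract(buf, m[:, None], out=buf)
        np.exp(buf, out=buf)
        s = buf.sum(axis=1)
        lse = m + np.log(s)
        Lv = L @ v
        ll = fixed + in_counts @ v - row_tot @ lse
        g_ll = in_counts - (row_tot / s) @ buf
        return -(ll - lam * 2.0 * (v @ Lv)), -(g_ll - lam * 4.0 * Lv)

    meta = {"excluded": excluded,
            "unvisited": np.flatnonzero((in_counts == 0) & (row_tot == 0))}
    return neg_obj_and_grad, meta


def penalized_objective(v, data: TransitionData, kernel: PassiveKernel,
                        grid: StateGrid, cfg: FitConfig = FitConfig()):
    """Penalized log-likelihood objective and its analytic gradient at v.

    Returns ``(objective, gradient)`` of
    ``log L(v) − λ Σ_s Σ_{s'∈χ(s)} (v(s) − v(s'))²`` — the quantity
    :func:`estimate_value` maximizes.  Exposed for diagnostics (gradient
    checks, concavity probes along line segments).
    """
    from .lmdp import as_values
    neg, _ = _make_neg_objective(data, kernel, grid, cfg)
    f, g = neg(as_values(v))
    return -f, -g


def estimate_value(data: TransitionData, kernel: PassiveKernel,
                   grid: StateGrid, cfg: FitConfig = FitConfig()) -> ValueFunction:
    """Maximize the penalized transition log-likelihood over v.

    Deterministic L-BFGS-B ascent from v = 0 with the analytic gradient
    (the objective is concave, so the start only affects arithmetic, not
    the optimum).  The result is gauge-normalized to max(v) = 0.  The
    returned value function carries an ``info`` dict with the convergence
    status, final objective, excluded-transition count, and the states the
    data never touched (their values are shaped by the penalty alone).

    Raises
    ------
    NumericalError
        If the optimizer stops without satisfying its convergence test and
        the projected gradient is still large.
    """
    if len(data) == 0:
        raise DataError("estimate_value: empty transition data")
    neg_obj_and_grad, meta = _make_neg_objective(data, kernel, grid, cfg)
    n = grid.n_states
    res = scipy.optimize.minimize(
        neg_obj_and_grad, np.zeros(n), jac=True, method="L-BFGS-B",
        bounds=[(cfg.value_floor, None)] * n,
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-7})
    gnorm = float(np.abs(res.jac).max())
    if not res.success and gnorm > 1e-3:
        raise NumericalError(
            f"estimate_value did not converge: {res.message} "
            f"(max |projected gradient| = {gnorm:.3g})")
    v = res.x - res.x.max()
    return ValueFunction(v, gauge_normalized=True, info={
        "converged": bool(res.success),
        "objective": -float(res.fun),
        "n_iter": int(res.nit),
        "grad_norm": gnorm,
        "n_excluded_transitions": meta["excluded"],
        "unvisited_states": meta["unvisited"],
    })


@dataclass(frozen=True)
class CVResult:
    """Grid-search cross-validation table and the selected combination."""

    table: pd.DataFrame          # lam, sigma_T, sigma_dT, fold, heldout_loglik
    selected: dict               # {"lam", "sigma_T", "sigma_dT"}
    n_folds: int

    def mean_scores(self) -> pd.DataFrame:
        return (self.table.groupby(["lam", "sigma_T", "sigma_dT"])
                ["heldout_loglik"].mean().reset_index())

    def fold_scores(self, lam=None, sigma_T=None, sigma_dT=None) -> np.ndarray:
        """Held-out log-likelihoods per fold for one combination (default: selected)."""
        sel = dict(self.selected)
        for key, val in (("lam", lam), ("sigma_T", sigma_T), ("sigma_dT", sigma_dT)):
            if val is not None:
                sel[key] = val
        t = self.table
        m = ((t["lam"] == sel["lam"]) & (t["sigma_T"] == sel["sigma_T"])
             & (t["sigma_dT"] == sel["sigma_dT"]))
        if not m.any():
            raise DataError(f"combination {sel} not in the CV table")
        return t.loc[m].sort_values("fold")["heldout_loglik"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def cross_validate(data: TransitionData, grid: StateGrid, lambda_grid,
                   sigma_T_grid, sigma_dT_grid, n_folds: int = 9,
                   fit_config: FitConfig = FitConfig(tol=1e-7)) -> CVResult:
    """Exhaustive grid search over (λ, σ_T, σ_dT) by contiguous k-fold CV.

    The transition sequence is divided into ``n_folds`` contiguous, equal
    parts (respecting temporal dependence — folds are blocks, not shuffled
    singletons).  For every hyperparameter combination the value function
    is fitted on all-but-one part and scored by the held-out transition
    log-likelihood, rotating through the folds; the combination with the
    highest mean held-out log-likelihood is selected (ties broken by the
    first combination in iteration order: λ, σ_T, σ_dT ascending).
    """
    lambda_grid = sorted(set(float(x) for x in np.atleast_1d(lambda_grid)))
    sigma_T_grid = sorted(set(float(x) for x in np.atleast_1d(sigma_T_grid)))
    sigma_dT_grid = sorted(set(float(x) for x in np.atleast_1d(sigma_dT_grid)))
    folds = data.folds(n_folds)
    rows = []
    for sT in sigma_T_grid:
        for sD in sigma_dT_grid:
            kernel = gaussian_passive_kernel(grid, sT, sD)
            for lam in lambda_grid:
                cfg = replace(fit_config, lam=lam)
                for i, (train, test) in enumerate(folds):
                    v = estimate_value(train, kernel, grid, cfg)
                    score = transition_loglik(v, kernel, test,
                                              p_floor=cfg.p_floor)
                    rows.append({"lam": lam, "sigma_T": sT, "sigma_dT": sD,
                                 "fold": i, "heldout_loglik": score})
    table = pd.DataFrame(rows)
    means = (table.groupby(["lam", "sigma_T", "sigma_dT"], sort=True)
             ["heldout_loglik"].mean())
    best = means.idxmax()
    selected = {"lam": best[0], "sigma_T": best[1], "sigma_dT": best[2]}
    return CVResult(table, selected, n_folds)


@dataclass(frozen=True)
class ModelComparison:
    """Two-sided Mann–Whitney U comparison of per-fold held-out scores."""

    u_statistic: float
    p_value: float
    direction: str               # "a", "b", or "none"
    n_folds: int


def compare_models(folds_a, folds_b) -> ModelComparison:
    """Mann–Whitney U test between two models' per-fold held-out log-likelihoods.

    ``direction`` names the model whose scores rank higher ("a" or "b"),
    or "none" when the rank sums tie exactly.
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if len(a) != len(b):
        raise DataError("fold score vectors must have equal length")
    if len(a) < 2:
        raise DataError("need at least 2 folds to compare models")
    if np.array_equal(np.sort(a), np.sort(b)) and np.all(a == a[0]) and np.all(b == a[0]):
        # degenerate: every score identical — no evidence either way
        return ModelComparison(len(a) * len(b) / 2.0, 1.0, "none", len(a))
    method = "exact" if (len(np.unique(np.concatenate([a, b])))
                         == len(a) + len(b)) else "auto"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    mid = len(a) * len(b) / 2.0
    if res.statistic > mid:
        direction = "a"
    elif res.statistic < mid:
        direction = "b"
    else:
        direction = "none"
    return ModelComparison(float(res.statistic), float(res.pvalue),
                           direction, len(a))
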