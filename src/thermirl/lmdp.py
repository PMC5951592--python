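"""Linearly-solvable MDP machinery.

In a linearly-solvable MDP the agent does not pick discrete actions: it
directly reshapes the state-transition distribution, paying a KL control
cost relative to uncontrolled *passive dynamics* ``p(s'|s)``.  The net
reward at state s under policy π is

    l(s, π) = r(s) − KL[π(·|s) || p(·|s)],

and the optimal policy has the closed form

    π*(s'|s) = p(s'|s) exp(v(s')) / Σ_y p(y|s) exp(v(y)),

where v is the value function (expected cumulative net reward).  The
desirability function z = exp(v) is the standard visualization of the
strategy.  v is identifiable only up to an additive constant; this module
fixes the gauge as max(v) = 0, so desirability peaks at 1.

Value and reward are interconvertible through the Bellman self-consistency
relation  exp(v(s)) = exp(r(s)) Σ_{s'} p(s'|s) exp(v(s')).

All policy arithmetic is done in log space with log-sum-exp: exp(v) across
hundreds of states underflows otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, rel_entr
from scipy.stats import norm

from .exceptions import ConfigurationError, ModelError, NumericalError
from .grid import StateGrid

__all__ = [
    "PassiveKernel", "Policy", "ValueFunction", "DesirabilityFunction",
    "RewardFunction", "gaussian_passive_kernel", "optimal_policy",
    "control_cost", "reward_from_value", "value_from_reward",
    "desirability_of",
]

_ROW_SUM_TOL = 1e-9


def as_values(v) -> np.ndarray:
    """Accept a per-state vector as ndarray or any of the function wrappers."""
    if hasattr(v, "values"):
        v = v.values
    return np.asarray(v, dtype=float)


@dataclass(frozen=True)
class ValueFunction:
    """Per-state value v(s) (log-desirability), gauge max(v) = 0 when normalized."""

    values: np.ndarray
    gauge_normalized: bool = False
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ModelError("value function entries must be finite")
        if self.gauge_normalized and abs(self.values.max()) > 1e-9:
            raise ModelError("gauge-normalized value function must have max 0")

    def gauged(self) -> "ValueFunction":
        """Shift to the max-zero gauge."""
        return ValueFunction(self.values - self.values.max(), True, dict(self.info))

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class DesirabilityFunction:
    """z(s) = exp(v(s)); max 1 under the max-zero gauge."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not (self.values > 0).all():
            raise ModelError("desirability entries must be positive")

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class RewardFunction:
    """Per-step state reward r(s)."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ModelError("reward entries must be finite")

    def __len__(self):
        return len(self.values)


def _check_row_stochastic(matrix: np.ndarray, what: str) -> None:
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ModelError(f"{what} must be square (got shape {matrix.shape})")
    if (matrix < 0).any():
        raise ModelError(f"{what} has negative entries")
    err = np.abs(matrix.sum(axis=1) - 1.0).max()
    if err > _ROW_SUM_TOL:
        raise ModelError(f"{what} rows must sum to 1 (max deviation {err:.3g})")


@dataclass(frozen=True)
class PassiveKernel:
    """Row-stochastic transition matrix p(s'|s); row index = from-state."""

    matrix: np.ndarray
    grid: StateGrid | None = None
    _log: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        _check_row_stochastic(self.matrix, "passive kernel")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_matrix(self) -> np.ndarray:
        """log p(s'|s), with -inf where p = 0 (cached)."""
        if self._log is None:
            with np.errstate(divide="ignore"):
                object.__setattr__(self, "_log", np.log(self.matrix))
        return self._log


@dataclass(frozen=True)
class Policy:
    """Controlled transition matrix π(s'|s)."""

    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        _check_row_stochastic(self.matrix, "policy")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def gaussian_passive_kernel(grid: StateGrid, sigma_T: float,
                            sigma_dT: float) -> PassiveKernel:
    """Discretize the Gaussian passive dynamics onto the grid.

    The uncontrolled transition law is inertial persistence with white
    noise: from state (T, dT) the next temperature is distributed
    N(T + dT·Δt, σ_T²) and the next derivative N(dT, σ_dT²).  The
    probability of landing in a destination bin is the product of Gaussian
    CDF differences over that bin's edges (exact mass, not density at the
    center); each row is renormalized to absorb the mass truncated beyond
    the grid boundary.

    Parameters
    ----------
    sigma_T : float
        Temperature noise per step (°C, standard deviation).
    sigma_dT : float
        Derivative noise per step (°C/s, standard deviation).
    """
    if not (sigma_T > 0 and sigma_dT > 0):
        raise ConfigurationError(
            f"sigma_T and sigma_dT must be > 0 (got {sigma_T}, {sigma_dT})")
    spec = grid.spec
    # temperature part: mean depends on the from-state's (T, dT) center
    meanT = grid.T_centers[:, None] + grid.dT_centers[None, :] * spec.delta_t
    cdfT = norm.cdf((grid.T_edges[None, None, :] - meanT[:, :, None]) / sigma_T)
    pT = np.diff(cdfT, axis=2)                       # (n_T, n_dT, n_T')
    # derivative part: mean is the from-state's dT center
    cdfD = norm.cdf((grid.dT_edges[None, :] - grid.dT_centers[:, None]) / sigma_dT)
    pD = np.diff(cdfD, axis=1)                       # (n_dT, n_dT')
    P = np.einsum("ade,df->adef", pT, pD).reshape(grid.n_states, grid.n_states)
    rows = P.sum(axis=1, keepdims=True)
    if (rows <= 0).any():
        raise ModelError("passive kernel row with zero mass on the grid")
    return PassiveKernel(P / rows, grid)


def optimal_policy(kernel: PassiveKernel, v) -> Policy:
    """Closed-form optimal LMDP policy π* ∝ p(s'|s)·exp(v(s'))."""
    v = as_values(v)
    logp = kernel.log_matrix
    if not np.isfinite(logp).any(axis=1).all():
        raise ModelError("passive kernel has an all-zero row")
    a = logp + v[None, :]
    log_pi = a - logsumexp(a, axis=1, keepdims=True)
    return Policy(np.exp(log_pi))


def control_cost(policy_row, passive_row) -> float:
    """KL[π(·|s) || p(·|s)] in nats — the resistance to passive dynamics.

    Nonnegative, zero iff the rows coincide; 0·log 0 = 0 by convention.
    """
    q = np.asarray(policy_row, dtype=float)
    p = np.asarray(passive_row, dtype=float)
    if ((q > 0) & (p == 0)).any():
        raise ModelError("policy places mass where passive dynamics has none")
    return float(rel_entr(q, p).sum())


def reward_from_value(v, kernel: PassiveKernel) -> RewardFunction:
    """State reward consistent with v under Bellman self-consistency.

    r(s) = v(s) − log Σ_{s'} p(s'|s) exp(v(s')); invariant under v → v + c.
    """
    v = as_values(v)
    return RewardFunction(v - logsumexp(kernel.log_matrix + v[None, :], axis=1))


def value_from_reward(r, kernel: PassiveKernel, tol: float = 1e-10,
                      max_iter: int = 100_000) -> ValueFunction:
    """Solve the Bellman self-consistency relation for v given r.

    Fixed-point (power) iteration on the desirability:
    z ← exp(r) ∘ (P z), renormalized to max 1 every sweep (the gauge makes
    the dominant-eigenvector scale irrelevant).  Performed in log space.

    Raises
    ------
    NumericalError
        If max |Δv| has not fallen below ``tol`` within ``max_iter`` sweeps.
    """
    r = as_values(r)
    logp = kernel.log_matrix
    v = np.zeros_like(r)
    for _ in range(max_iter):
        v_new = r + logsumexp(logp + v[None, :], axis=1)
        v_new -= v_new.max()
        resid = np.abs(v_new - v).max()
        v = v_new
        if resid < tol:
            return ValueFunction(v, gauge_normalized=True)
    raise NumericalError(
        f"value_from_reward: no convergence in {max_iter} sweeps "
        f"(residual {resid:.3g} > tol {tol:.3g})")


def desirability_of(v) -> DesirabilityFunction:
    """z(s) = exp(v(s)); a gauge-normalized v yields max(z) = 1."""
    return DesirabilityFunction(np.exp(as_values(v)))
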