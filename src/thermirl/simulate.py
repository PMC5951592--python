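"""Forward simulation and designed ground-truth strategies.

Two uses: (i) sample state trajectories from the optimal LMDP policy
implied by a value function — the forward check that an identified
strategy actually produces thermotaxis; and (ii) build parametric
ground-truth value landscapes (mixtures of ridges on the (T, dT) plane)
for estimator validation and parameter-recovery studies.

Ground-truth variants, named after their control-theoretic reading:

``pd_diagonal``
    A diagonal Gaussian ridge through (T*, 0) — below the target
    temperature positive dT is desirable, above it negative dT — plus a
    horizontal ridge at dT ≈ 0 (isothermal migration).  Proportional-
    derivative-like control toward the cultivation temperature T*.
``bang_bang``
    Desirability saturates at the most positive dT below T* and the most
    negative dT above it (switching control).
``p_only``
    Desirability depends on T alone (a Gaussian bump at T*): proportional
    control, no derivative information.
``starved_p``
    Desirability depressed near T* and higher away from it — the
    temperature-only avoidance profile of starved animals.

Simulated series live on the grid: emitted (T, dT) are bin centers at the
Δt cadence.  Everything stochastic is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import TransitionData
from .exceptions import ConfigurationError, DataError
from .grid import StateGrid, discretize
from .lmdp import PassiveKernel, ValueFunction, as_values, optimal_policy
from .tracks import StateSeries, series_to_transitions

__all__ = [
    "GroundTruthSpec", "SimConfig", "make_ground_truth", "simulate_states",
    "simulate_population_summary", "generate_training_set", "TrainingSet",
]

_VARIANTS = ("pd_diagonal", "bang_bang", "p_only", "starved_p")


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parametric family of designed value landscapes.

    The desirability is a baseline plus ridge terms and the value is its
    logarithm (gauge-normalized on the grid).

    Parameters
    ----------
    variant : str
        One of ``pd_diagonal``, ``bang_bang``, ``p_only``, ``starved_p``.
    T_star : float
        Target (cultivation) temperature, °C.
    dm_amplitude, dm_slope, dm_width :
        Diagonal ridge: amplitude (dimensionless), slope of the ridge line
        ``dT = −dm_slope · (T − T*)`` in (°C/s) per °C, and Gaussian width
        of the ridge measured along dT (°C/s).  For the temperature-only
        variants ``dm_amplitude`` scales the T-bump and ``t_width`` is its
        width in °C.
    im_amplitude, im_width :
        Horizontal (isothermal) ridge at dT = 0: amplitude and Gaussian
        dT-width (°C/s).
    baseline : float
        Desirability floor away from all ridges (> 0).
    """

    variant: str = "pd_diagonal"
    T_star: float = 20.0
    dm_amplitude: float = 1.0
    dm_slope: float = 1.0 / 300.0
    dm_width: float = 0.005
    im_amplitude: float = 0.5
    im_width: float = 0.003
    t_width: float = 2.0
    baseline: float = 0.05

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ConfigurationError(
                f"unknown ground-truth variant {self.variant!r}; "
                f"expected one of {_VARIANTS}")
        for name in ("dm_width", "im_width", "t_width", "baseline"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("dm_amplitude", "im_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def make_ground_truth(spec: GroundTruthSpec, grid: StateGrid) -> ValueFunction:
    """Evaluate the designed desirability on the grid and return log of it."""
    T, dT = grid.all_centers()
    base = spec.baseline
    if spec.variant == "pd_diagonal":
        off = dT + spec.dm_slope * (T - spec.T_star)   # distance from ridge, °C/s
        dm = spec.dm_amplitude * np.exp(-0.5 * (off / spec.dm_width) ** 2)
        im = spec.im_amplitude * np.exp(-0.5 * (dT / spec.im_width) ** 2)
        z = base + dm + im
    elif spec.variant == "bang_bang":
        s = np.sign(spec.T_star - T)
        z = base + spec.dm_amplitude / (1.0 + np.exp(-s * dT / spec.dm_width))
    elif spec.variant == "p_only":
        z = base + spec.dm_amplitude * np.exp(
            -0.5 * ((T - spec.T_star) / spec.t_width) ** 2)
    else:  # starved_p
        z = base + spec.dm_amplitude * (
            1.0 - np.exp(-0.5 * ((T - spec.T_star) / spec.t_width) ** 2))
    v = np.log(z)
    return ValueFunction(v - v.max(), gauge_normalized=True)


@dataclass(frozen=True)
class SimConfig:
    """Forward-simulation settings.

    Defaults mirror the population protocol: 100 worms started with
    dT₀ = 0 from temperatures cycling through {15, 20, 25} °C, stepped for
    one hour at Δt = 1 s.
    """

    n_worms: int = 100
    n_steps: int = 3600
    start_T: tuple = (15.0, 20.0, 25.0)
    start_dT: float = 0.0
    seed: int = 0
    burn_in: int = 0     # steps discarded before recording (stationary sampling)

    def __post_init__(self):
        if self.n_worms < 1 or self.n_steps < 1:
            raise ConfigurationError("n_worms and n_steps must be >= 1")
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")
        if len(np.atleast_1d(self.start_T)) < 1:
            raise ConfigurationError("need at least one start temperature")


def simulate_states(kernel: PassiveKernel, v, cfg: SimConfig) -> list:
    """Sample worm trajectories from the optimal policy π*(·|s; v).

    Each worm is an independent Markov chain on the grid started at its
    assigned (start_T, start_dT) bin; the emitted series hold bin-center
    coordinates at the Δt cadence.  With ``cfg.burn_in > 0`` the first
    ``burn_in`` steps are discarded, so the recorded stretch samples the
    chain near its stationary distribution.  Fully reproducible from
    ``cfg.seed``.
    """
    grid = kernel.grid
    if grid is None:
        raise ConfigurationError("simulate_states needs a grid-aware kernel")
    v = as_values(v)
    if len(v) != kernel.n_states:
        raise ConfigurationError("value function does not match the kernel grid")
    rng = np.random.default_rng(cfg.seed)
    cum = np.cumsum(optimal_policy(kernel, v).matrix, axis=1)
    cum[:, -1] = 1.0   # guard against round-off at the top
    starts = np.resize(np.atleast_1d(np.asarray(cfg.start_T, float)), cfg.n_worms)
    k0, _ = discretize(starts, np.full(cfg.n_worms, cfg.start_dT), grid)
    total = cfg.burn_in + cfg.n_steps
    states = np.empty((total, cfg.n_worms), dtype=np.intp)
    states[0] = k0
    cur = k0
    for t in range(1, total):
        u = rng.random(cfg.n_worms)
        cur = (cum[cur] < u[:, None]).sum(axis=1)
        states[t] = cur
    states = states[cfg.burn_in:]
    tt = grid.delta_t * np.arange(cfg.n_steps)
    out = []
    for w in range(cfg.n_worms):
        T, dT = grid.state_center(states[:, w])
        out.append(StateSeries(f"sim{w:04d}", tt, T, dT,
                               np.zeros(cfg.n_steps, dtype=int), grid.delta_t))
    return out


def simulate_population_summary(series_list, time_points,
                                bin_edges=None) -> pd.DataFrame:
    """Histogram of worm temperatures at each requested time point.

    Returns a DataFrame indexed by temperature-bin center with one column
    per time point (in seconds), holding worm counts.
    """
    if not series_list:
        raise DataError("no series to summarize")
    dt = series_list[0].delta_t
    if bin_edges is None:
        lo = min(s.T.min() for s in series_list)
        hi = max(s.T.max() for s in series_list)
        bin_edges = np.linspace(lo, hi + 1e-9, 25)
    bin_edges = np.asarray(bin_edges, dtype=float)
    cols = {}
    for tp in np.atleast_1d(time_points):
        idx = int(round(tp / dt))
        if idx < 0 or any(idx >= len(s) for s in series_list):
            raise DataError(f"time point {tp} s beyond the simulated series")
        temps = np.array([s.T[idx] for s in series_list])
        counts, _ = np.histogram(temps, bins=bin_edges)
        cols[float(tp)] = counts
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return pd.DataFrame(cols, index=pd.Index(centers, name="T_center"))


def median_final_temperature(series_list) -> float:
    """Median worm temperature at the last simulated step."""
    return float(np.median([s.T[-1] for s in series_list]))


@dataclass(frozen=True)
class TrainingSet:
    """Simulated transitions plus everything needed to score recovery."""

    train: TransitionData
    test: TransitionData
    truth: ValueFunction
    kernel: PassiveKernel
    grid: StateGrid
    spec: GroundTruthSpec
    sim_config: SimConfig
    series: list = field(repr=False, default=None)


def generate_training_set(spec: GroundTruthSpec, grid: StateGrid, sigma_T: float,
                          sigma_dT: float, cfg: SimConfig,
                          test_fraction: float = 0.2) -> TrainingSet:
    """Simulate from a designed strategy and split worms into train/test.

    Builds the Gaussian passive kernel and the ground-truth value, samples
    ``cfg.n_worms`` trajectories from the optimal policy, converts them to
    transition data, and holds out the last ``test_fraction`` of worms as
    the test set.  The generating value function and kernel are returned
    for recovery scoring.
    """
    from .lmdp import gaussian_passive_kernel
    if not 0 <= test_fraction < 1:
        raise ConfigurationError("test_fraction must be in [0, 1)")
    kernel = gaussian_passive_kernel(grid, sigma_T, sigma_dT)
    truth = make_ground_truth(spec, grid)
    series = simulate_states(kernel, truth, cfg)
    n_test = int(round(test_fraction * len(series)))
    train_series = series[:len(series) - n_test]
    test_series = series[len(series) - n_test:]
    train = series_to_transitions(train_series, grid)
    test = (series_to_transitions(test_series, grid) if test_series
            else TransitionData(np.empty((0, 2), dtype=np.intp),
                                np.empty(0), grid.n_states))
    return TrainingSet(train, test, truth, kernel, grid, spec, cfg, series)
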