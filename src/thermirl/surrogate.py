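"""Surrogate-data hypothesis tests for the identified strategy components.

Null hypothesis: the worms migrate with no behavioral strategy, i.e. the
observed temperature series could equally have arisen from dynamics with
the same value distribution and autocorrelation but no state-dependent
control.  Surrogate temperature series are produced by the iterated
amplitude-adjusted Fourier transform (IAAFT), which preserves the original
amplitude distribution exactly and the power spectrum approximately; the
whole identification pipeline (derivative, discretization, penalized fit)
is re-run on each surrogate with the hyperparameters fixed in advance, and
the sums of the fitted desirability over the diagonal (DM) and horizontal
(IM) regions serve as test statistics.  Empirical p-values use the add-one
rule, p = (1 + #{null >= observed}) / (1 + n_surrogates), so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitConfig, estimate_value
from .exceptions import ConfigurationError, DataError
from .grid import StateGrid
from .lmdp import PassiveKernel, desirability_of
from .tracks import StateSeries, sg_derivative, sg_smooth, series_to_transitions

__all__ = [
    "RegionMask", "SurrogateResult", "iaaft_surrogate", "build_region_masks",
    "region_statistic", "surrogate_strategy_test",
]


@dataclass(frozen=True)
class RegionMask:
    """A labelled set of grid states over which desirability is summed."""

    label: str                     # "DM" or "IM"
    indices: np.ndarray            # flat state indices
    params: dict

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ConfigurationError(f"{self.label} region mask is empty")

    def __len__(self):
        return len(self.indices)

    def overlap(self, other: "RegionMask") -> int:
        """Number of states shared with another mask (DM and IM meet near (T*, 0))."""
        return len(np.intersect1d(self.indices, other.indices))


def iaaft_surrogate(series, max_iter: int = 100, rng=None) -> np.ndarray:
    """Iterated amplitude-adjusted Fourier transform surrogate of a series.

    Alternates imposing the original Fourier amplitude spectrum (magnitude
    substitution, phases kept) and the original value distribution
    (rank-order remapping) until the rank permutation stabilizes or
    ``max_iter`` is reached.  The surrogate's sorted values equal the
    original's sorted values exactly; its autocorrelation matches to the
    convergence tolerance of the spectrum step.

    A constant series has a degenerate spectrum and is returned unchanged
    with a warning.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 8:
        raise DataError(f"series of length {len(x)} too short for IAAFT (< 8)")
    if not np.isfinite(x).all():
        raise DataError("IAAFT input must be finite")
    if np.ptp(x) == 0:
        warnings.warn("IAAFT: constant series, returning it unchanged")
        return x.copy()
    rng = np.random.default_rng(rng)
    sorted_x = np.sort(x)
    amplitudes = np.abs(np.fft.rfft(x))
    s = rng.permutation(x)
    prev_ranks = None
    for _ in range(max_iter):
        phases = np.angle(np.fft.rfft(s))
        s = np.fft.irfft(amplitudes * np.exp(1j * phases), n=len(x))
        ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[ranks]
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    return s


def build_region_masks(grid: StateGrid, T_star: float, dm_slope: float,
                       dm_width: float, im_halfwidth: float):
    """Construct the DM (diagonal) and IM (horizontal) region masks.

    DM collects states within ``dm_width`` (measured along dT, °C/s) of
    the ridge line ``dT = −dm_slope · (T − T_star)``; IM collects states
    with ``|dT| <= im_halfwidth``.  With ``dm_slope = 0`` the DM band
    degenerates into a horizontal band at dT = 0.

    Returns ``(dm_mask, im_mask)``; the masks may overlap near (T*, 0) —
    use :meth:`RegionMask.overlap` to report the shared states.
    """
    T, dT = grid.all_centers()
    dm_idx = np.flatnonzero(np.abs(dT + dm_slope * (T - T_star)) <= dm_width)
    im_idx = np.flatnonzero(np.abs(dT) <= im_halfwidth)
    dm = RegionMask("DM", dm_idx, {"T_star": T_star, "slope": dm_slope,
                                   "width": dm_width})
    im = RegionMask("IM", im_idx, {"halfwidth": im_halfwidth})
    return dm, im


def region_statistic(z, mask: RegionMask) -> float:
    """Sum of the desirability over the mask's states."""
    values = z.values if hasattr(z, "values") else np.asarray(z, dtype=float)
    return float(values[mask.indices].sum())


@dataclass(frozen=True)
class SurrogateResult:
    """Observed statistics, empirical nulls and add-one p-values."""

    observed: dict                 # {"DM": float, "IM": float}
    null: pd.DataFrame             # columns replicate, DM_stat, IM_stat
    p_values: dict                 # {"DM": float, "IM": float}
    n_surrogates: int
    seed: int

    def summary(self) -> dict:
        """JSON-compatible record of the test."""
        return {
            "observed_DM": self.observed["DM"],
            "observed_IM": self.observed["IM"],
            "p_DM": self.p_values["DM"],
            "p_IM": self.p_values["IM"],
            "n_surrogates": self.n_surrogates,
            "seed": self.seed,
        }

    def to_csv(self, path) -> None:
        self.null.to_csv(path, index=False)


def _refit_desirability(series_list, grid, kernel, fit_config, sg_window,
                        sg_order):
    """Identical preprocessing + fit for observed and surrogate data.

    dT is always recomputed from the temperature series through the same
    Savitzky–Golay filter, so the observed statistic and the null pass
    through one pipeline.
    """
    processed = []
    for s in series_list:
        T = np.empty_like(s.T)
        dT = np.empty_like(s.T)
        for seg in np.unique(s.segment):
            m = s.segment == seg
            T[m] = sg_smooth(s.T[m], sg_window, sg_order)
            dT[m] = sg_derivative(s.T[m], sg_window, sg_order, s.delta_t)
        processed.append(StateSeries(s.worm_id, s.time, T, dT, s.segment,
                                     s.delta_t))
    data = series_to_transitions(processed, grid)
    v = estimate_value(data, kernel, grid, fit_config)
    return desirability_of(v)


def _grid_mean_normalized(z):
    """Desirability rescaled to unit mean over the grid.

    The value function is identified only up to its gauge, so the absolute
    scale of z carries no information; summing the max-gauged z over a
    region would reward *diffuse* fits (many mid-level states) over
    *concentrated* ridges.  Rescaling to unit grid mean makes the region
    sum measure the share of desirability concentrated in the region:
    a flat z of any height scores exactly the region's state count.
    """
    values = z.values if hasattr(z, "values") else np.asarray(z, dtype=float)
    return values * (len(values) / values.sum())


def surrogate_strategy_test(series_list, grid: StateGrid,
                            kernel: PassiveKernel, fit_config: FitConfig,
                            masks, n_surrogates: int = 99, seed: int = 0,
                            sg_window: int = 7, sg_order: int = 2,
                            iaaft_max_iter: int = 100,
                            normalize: bool = True) -> SurrogateResult:
    """Test the DM and IM strategy components against an IAAFT null.

    Each surrogate replicate IAAFT-shuffles every worm's temperature series
    independently (per segment), recomputes dT, re-fits the desirability
    function with the *same, pre-selected* hyperparameters, and records the
    two region statistics.  Hyperparameter selection must happen before
    this test — no per-surrogate cross-validation.

    With ``normalize=True`` (default) region sums are taken over the
    desirability rescaled to unit grid mean, so the statistic measures
    concentration of desirability in the region rather than its
    gauge-dependent absolute level; ``normalize=False`` sums the raw
    max-gauged desirability.
    """
    if n_surrogates < 1:
        raise ConfigurationError("n_surrogates must be >= 1")
    # canonical worm order: the test result must not depend on how the
    # caller happened to order the series
    series_list = sorted(series_list, key=lambda s: str(s.worm_id))
    dm_mask, im_mask = masks
    prep = _grid_mean_normalized if normalize else (lambda z: z)
    rng = np.random.default_rng(seed)
    z_obs = _refit_desirability(series_list, grid, kernel, fit_config,
                                sg_window, sg_order)
    observed = {"DM": region_statistic(prep(z_obs), dm_mask),
                "IM": region_statistic(prep(z_obs), im_mask)}
    rows = []
    for rep in range(n_surrogates):
        surr = []
        for s in series_list:
            T = np.empty_like(s.T)
            for seg in np.unique(s.segment):
                m = s.segment == seg
                T[m] = iaaft_surrogate(s.T[m], iaaft_max_iter, rng)
            surr.append(StateSeries(s.worm_id, s.time, T, np.zeros_like(T),
                                    s.segment, s.delta_t))
        z = _refit_desirability(surr, grid, kernel, fit_config, sg_window,
                                sg_order)
        rows.append({"replicate": rep,
                     "DM_stat": region_statistic(prep(z), dm_mask),
                     "IM_stat": region_statistic(prep(z), im_mask)})
    null = pd.DataFrame(rows)
    p_values = {
        "DM": (1 + int((null["DM_stat"].to_numpy() >= observed["DM"]).sum()))
              / (1 + n_surrogates),
        "IM": (1 + int((null["IM_stat"].to_numpy() >= observed["IM"]).sum()))
              / (1 + n_surrogates),
    }
    return SurrogateResult(observed, null, p_values, n_surrogates, seed)
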