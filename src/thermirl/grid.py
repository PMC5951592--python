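"""Tabular state space over the (T, dT) thermosensory plane.

The worm's sensory state is the pair ``s = (T, dT)`` of the temperature it
currently experiences and that temperature's temporal derivative.  The state
space is a regular mesh over a rectangle of this plane: ``n_T`` bins along T
and ``n_dT`` bins along dT, flattened to indices ``k = i_T * n_dT + i_dT``.
Bins are half-open ``[lo, hi)`` except the topmost bin on each axis, which is
closed, so the rectangle is covered exactly once.

A one-dimensional variant (temperature only) is expressed as ``n_dT = 1``
with a degenerate dT range; it is used to ask whether the derivative carries
strategy information at all.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from .exceptions import ConfigurationError, DataError

__all__ = ["GridSpec", "StateGrid", "build_grid", "discretize", "neighbors"]

#: nominal half-width (°C/s) given to the single dT bin of a 1-D grid whose
#: dT range is degenerate, so edges/centers stay well defined.
_DEGENERATE_HALFWIDTH = 0.5


@dataclass(frozen=True)
class GridSpec:
    """Parameters of the state mesh.

    Parameters
    ----------
    T_min, T_max : float
        Temperature range covered by the grid (°C).
    n_T : int
        Number of temperature bins (>= 2).
    dT_min, dT_max : float
        Range of the temperature derivative (°C/s).  May be degenerate
        (equal) only when ``n_dT == 1`` (1-D, temperature-only grid).
    n_dT : int
        Number of derivative bins; odd when > 1 so that dT = 0 is a bin
        center (the identified strategies peak there).
    delta_t : float
        State-transition interval Δt in seconds; the time step at which
        transitions are counted and at which the passive dynamics act.
    """

    T_min: float
    T_max: float
    n_T: int
    dT_min: float
    dT_max: float
    n_dT: int
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.T_min, self.T_max, self.dT_min, self.dT_max,
                            self.delta_t]).all():
            raise ConfigurationError("GridSpec fields must be finite")
        if not self.T_min < self.T_max:
            raise ConfigurationError(
                f"T_min must be < T_max (got {self.T_min} >= {self.T_max})")
        if self.n_T < 2:
            raise ConfigurationError(f"n_T must be >= 2 (got {self.n_T})")
        if self.n_dT < 1:
            raise ConfigurationError(f"n_dT must be >= 1 (got {self.n_dT})")
        if self.n_dT > 1 and self.n_dT % 2 == 0:
            raise ConfigurationError(
                f"n_dT must be odd when > 1 so dT = 0 is a bin center "
                f"(got {self.n_dT})")
        if self.n_dT == 1:
            if self.dT_min > self.dT_max:
                raise ConfigurationError("dT_min must be <= dT_max")
        elif not self.dT_min < self.dT_max:
            raise ConfigurationError(
                f"dT_min must be < dT_max (got {self.dT_min} >= {self.dT_max})")
        if not self.delta_t > 0:
            raise ConfigurationError(f"delta_t must be > 0 (got {self.delta_t})")

    @property
    def n_states(self) -> int:
        return self.n_T * self.n_dT

    @property
    def is_1d(self) -> bool:
        """True for a temperature-only grid (single dT bin)."""
        return self.n_dT == 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GridSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class StateGrid:
    """Realized mesh: edges, centers and the flat-index maps."""

    spec: GridSpec
    T_edges: np.ndarray
    T_centers: np.ndarray
    dT_edges: np.ndarray
    dT_centers: np.ndarray
    _adjacency: sp.csr_matrix = field(repr=False, compare=False, default=None)

    @property
    def n_states(self) -> int:
        return self.spec.n_states

    @property
    def delta_t(self) -> float:
        return self.spec.delta_t

    # -- flat index <-> (i_T, i_dT) ------------------------------------
    def flat_index(self, i_T, i_dT):
        return np.asarray(i_T) * self.spec.n_dT + np.asarray(i_dT)

    def unravel(self, k):
        k = np.asarray(k)
        return k // self.spec.n_dT, k % self.spec.n_dT

    def state_center(self, k):
        """Bin-center coordinates (T, dT) of flat state ``k`` (vectorized)."""
        i_T, i_dT = self.unravel(k)
        return self.T_centers[i_T], self.dT_centers[i_dT]

    def all_centers(self):
        """(N,) arrays of T and dT at every state's bin center, in flat order."""
        k = np.arange(self.n_states)
        return self.state_center(k)

    # -- neighborhood ---------------------------------------------------
    @property
    def adjacency(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 matrix of the 4-neighborhood graph."""
        if self._adjacency is None:
            object.__setattr__(self, "_adjacency", _build_adjacency(self.spec))
        return self._adjacency

    @property
    def laplacian(self) -> sp.csr_matrix:
        """Combinatorial graph Laplacian D - A of the neighbor graph."""
        adj = self.adjacency
        deg = np.asarray(adj.sum(axis=1)).ravel()
        return sp.diags(deg) - adj

    def neighbor_pairs(self) -> np.ndarray:
        """(E, 2) array of all *directed* neighbor pairs (each edge twice)."""
        coo = self.adjacency.tocoo()
        return np.column_stack([coo.row, coo.col])


def _build_adjacency(spec: GridSpec) -> sp.csr_matrix:
    n_T, n_dT = spec.n_T, spec.n_dT
    rows, cols = [], []
    for i in range(n_T):
        for j in range(n_dT):
            k = i * n_dT + j
            if i > 0:
                rows.append(k); cols.append(k - n_dT)
            if i < n_T - 1:
                rows.append(k); cols.append(k + n_dT)
            if j > 0:
                rows.append(k); cols.append(k - 1)
            if j < n_dT - 1:
                rows.append(k); cols.append(k + 1)
    data = np.ones(len(rows))
    n = spec.n_states
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_grid(spec: GridSpec) -> StateGrid:
    """Construct the mesh for a :class:`GridSpec`.

    Edges are uniformly spaced; centers are exact bin midpoints.  A 1-D grid
    with a degenerate dT range receives a single dT bin of nominal width
    ``2 * 0.5`` °C/s centered on the degenerate value.
    """
    T_edges = np.linspace(spec.T_min, spec.T_max, spec.n_T + 1)
    if spec.n_dT == 1 and spec.dT_min == spec.dT_max:
        c = spec.dT_min
        dT_edges = np.array([c - _DEGENERATE_HALFWIDTH, c + _DEGENERATE_HALFWIDTH])
    else:
        dT_edges = np.linspace(spec.dT_min, spec.dT_max, spec.n_dT + 1)
    T_centers = 0.5 * (T_edges[:-1] + T_edges[1:])
    dT_centers = 0.5 * (dT_edges[:-1] + dT_edges[1:])
    return StateGrid(spec, T_edges, T_centers, dT_edges, dT_centers)


def _bin_1d(x: np.ndarray, edges: np.ndarray, clip: bool):
    """Half-open binning with a closed top bin.

    Returns (indices, out_of_range_mask).  In clip mode out-of-range values
    are mapped to the boundary bin; indices for out-of-range values in
    reject mode are still clipped but flagged by the mask.
    """
    idx = np.searchsorted(edges, x, side="right") - 1
    # a value exactly at the top edge belongs to the last (closed) bin
    idx = np.where(x == edges[-1], len(edges) - 2, idx)
    out = (x < edges[0]) | (x > edges[-1])
    idx = np.clip(idx, 0, len(edges) - 2)
    return idx, out


def discretize(T, dT, grid: StateGrid, mode: str = "clip"):
    """Map (T, dT) samples to flat state indices.

    Values exactly on an interior bin edge fall in the right-hand bin
    (half-open convention); values at the top of the range fall in the last
    bin (closed top bin).

    Parameters
    ----------
    T, dT : array_like
        Sample coordinates (scalars or equal-length arrays).
    mode : {"clip", "reject"}
        ``clip`` maps out-of-range samples to the boundary bin and counts
        them; ``reject`` marks them with index ``-1``.

    Returns
    -------
    k : ndarray of int
        Flat state indices (``-1`` for rejected samples in reject mode).
    n_out : int
        Number of out-of-range samples (clipped or rejected).
    """
    if mode not in ("clip", "reject"):
        raise ConfigurationError(f"unknown discretize mode {mode!r}")
    T = np.atleast_1d(np.asarray(T, dtype=float))
    dT = np.atleast_1d(np.asarray(dT, dtype=float))
    if not (np.isfinite(T).all() and np.isfinite(dT).all()):
        raise DataError("discretize: non-finite T or dT sample")
    i_T, out_T = _bin_1d(T, grid.T_edges, clip=True)
    i_dT, out_dT = _bin_1d(dT, grid.dT_edges, clip=True)
    out = out_T | out_dT
    k = grid.flat_index(i_T, i_dT)
    if mode == "reject":
        k = np.where(out, -1, k)
    return k, int(out.sum())


def neighbors(k: int, grid: StateGrid) -> np.ndarray:
    """Flat indices of the 4-neighborhood χ(s) of state ``k`` (sorted).

    Neighbors are ±1 steps along i_T and i_dT, truncated at grid
    boundaries; the state itself is never included.
    """
    if not 0 <= k < grid.n_states:
        raise ConfigurationError(f"state index {k} outside [0, {grid.n_states})")
    return np.sort(grid.adjacency.indices[
        grid.adjacency.indptr[k]:grid.adjacency.indptr[k + 1]])
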