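"""Plain-text interchange formats.

Per-state vectors (value, desirability, reward) are written as TSV grids:
the first row holds the dT bin centers, the first column the T bin centers,
and the body holds the vector reshaped to (n_T, n_dT).  Floats are printed
with 17 significant digits so round trips are bit-exact.
"""

from __future__ import annotations

import numpy as np

from .exceptions import FormatError
from .grid import StateGrid

__all__ = ["write_grid_tsv", "read_grid_tsv"]

_FMT = "%.17g"


def write_grid_tsv(path, values, grid: StateGrid, label: str = "T\\dT") -> None:
    """Write a per-state vector as a TSV grid (rows = T bins, cols = dT bins)."""
    values = np.asarray(values, dtype=float)
    if hasattr(values, "shape") and values.ndim == 1:
        if values.size != grid.n_states:
            raise FormatError(
                f"vector length {values.size} != grid size {grid.n_states}")
        mat = values.reshape(grid.spec.n_T, grid.spec.n_dT)
    else:
        mat = values
    with open(path, "w") as fh:
        fh.write(label + "\t" + "\t".join(_FMT % c for c in grid.dT_centers) + "\n")
        for i, Tc in enumerate(grid.T_centers):
            fh.write(_FMT % Tc + "\t"
                     + "\t".join(_FMT % x for x in mat[i]) + "\n")


def read_grid_tsv(path):
    """Read a TSV grid.

    Returns
    -------
    values : (N,) ndarray in flat state order (k = i_T * n_dT + i_dT)
    T_centers : (n_T,) ndarray
    dT_centers : (n_dT,) ndarray
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: not a TSV grid (header too short)")
        dT_centers = np.array([float(x) for x in header[1:]])
        T_centers, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(dT_centers) + 1:
                raise FormatError(f"{path}: ragged row with {len(parts)} fields")
            T_centers.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    mat = np.array(rows)
    return mat.ravel(), np.array(T_centers), dT_centers
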