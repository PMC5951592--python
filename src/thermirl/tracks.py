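"""Trajectory preprocessing: centroid tracks → (T, dT) state series.

The assay records worm centroids on a plate held at a linear thermal
gradient (about 0.45 °C/cm in the original assay), so the temperature a
worm experiences is an affine function of its position.  This module maps
positions through the gradient, resamples each track to the transition
interval Δt, smooths the temperature with a Savitzky–Golay filter and takes
the filter's first derivative, then discretizes the resulting (T, dT)
series into transition pairs for the likelihood.

Two CSV dialects are accepted: positional tracks
(``worm_id,time_s,x_mm,y_mm``) and pre-mapped temperature series
(``worm_id,time_s,T_celsius``) for data whose gradient lookup already
happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .estimation import TransitionData
from .exceptions import DataError, FormatError
from .grid import StateGrid, discretize

__all__ = [
    "WormTrack", "GradientMap", "StateSeries", "read_tracks",
    "temperature_at", "sg_derivative", "sg_smooth", "extract_state_series",
    "series_to_transitions",
]


@dataclass(frozen=True)
class WormTrack:
    """One worm's raw samples, time-sorted; either positional or pre-mapped."""

    worm_id: str
    time: np.ndarray                        # s
    x: np.ndarray | None = None             # mm
    y: np.ndarray | None = None             # mm
    temperature: np.ndarray | None = None   # °C, pre-mapped dialect

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", t)
        if len(t) and (np.diff(t) <= 0).any():
            raise DataError(f"worm {self.worm_id!r}: time not strictly increasing")
        for name in ("x", "y", "temperature"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, dtype=float))

    @property
    def premapped(self) -> bool:
        return self.temperature is not None

    def __len__(self):
        return len(self.time)


@dataclass(frozen=True)
class GradientMap:
    """Linear thermal gradient on the assay plate.

    ``T(x, y) = center_temperature + slope · proj`` where ``proj`` is the
    displacement of (x, y) from the plate center projected onto the
    gradient axis, in cm (positions are in mm).
    """

    center_temperature: float              # °C at the plate center
    slope: float = 0.45                    # °C per cm along the axis
    axis: tuple = (1.0, 0.0)               # gradient direction, normalized
    plate_center: tuple = (0.0, 0.0)       # mm

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise DataError("gradient slope must be finite")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise DataError("gradient axis must be nonzero")
        object.__setattr__(self, "axis", tuple(ax / n))


@dataclass(frozen=True)
class StateSeries:
    """Uniformly resampled (T, dT) series for one worm.

    ``segment`` labels gap-free stretches; transitions are never formed
    across a segment boundary.  ``dropped_segments`` counts raw segments
    too short for the smoothing window.
    """

    worm_id: str
    time: np.ndarray       # s, uniform Δt within a segment
    T: np.ndarray          # °C
    dT: np.ndarray         # °C/s
    segment: np.ndarray    # int label per sample
    delta_t: float = 1.0
    dropped_segments: int = 0

    def __post_init__(self):
        for name in ("time", "T", "dT"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "segment",
                           np.asarray(self.segment, dtype=int))
        if not np.isfinite(self.dT).all():
            raise DataError("state series has non-finite dT")

    def __len__(self):
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"worm_id": self.worm_id, "time_s": self.time,
                             "T": self.T, "dT": self.dT,
                             "segment": self.segment})


def series_to_csv(series_list, path) -> None:
    pd.concat([s.to_frame() for s in series_list]).to_csv(path, index=False)


def series_from_csv(path, delta_t: float = 1.0):
    df = pd.read_csv(path)
    need = {"worm_id", "time_s", "T", "dT", "segment"}
    if not need <= set(df.columns):
        raise FormatError(f"series CSV missing columns {sorted(need - set(df.columns))}")
    out = []
    for wid, g in df.groupby("worm_id", sort=False):
        out.append(StateSeries(str(wid), g["time_s"].to_numpy(),
                               g["T"].to_numpy(), g["dT"].to_numpy(),
                               g["segment"].to_numpy(), delta_t))
    return out


def read_tracks(path) -> list:
    """Read centroid tracks (or pre-mapped temperature series) from CSV.

    Rows must be grouped by worm with strictly increasing time within each
    worm; duplicates and reversals raise :class:`DataError` naming the
    offending row, and rows with missing/non-numeric fields raise with
    their line numbers.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"worm_id", "time_s", "x_mm", "y_mm"} <= cols:
        value_cols = ["time_s", "x_mm", "y_mm"]
        premapped = False
    elif {"worm_id", "time_s", "T_celsius"} <= cols:
        value_cols = ["time_s", "T_celsius"]
        premapped = True
    else:
        raise FormatError(
            f"{path}: expected columns worm_id,time_s,x_mm,y_mm or "
            f"worm_id,time_s,T_celsius; found {sorted(cols)}")
    numeric = df[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = df.index[numeric.isna().any(axis=1)
                   | ~np.isfinite(numeric).all(axis=1)]
    if len(bad):
        # +2: 1-based line numbers counting the header line
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise DataError(f"{path}: malformed rows at lines {lines}"
                        + (" ..." if len(bad) > 10 else ""))
    df[value_cols] = numeric
    tracks = []
    for wid, g in df.groupby("worm_id", sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if len(dup):
            row = g.index[dup[0] + 1] + 2
            raise DataError(f"{path}: duplicate (worm_id, time) at line {row}")
        if (np.diff(t) < 0).any():
            row = g.index[int(np.flatnonzero(np.diff(t) < 0)[0]) + 1] + 2
            raise DataError(f"{path}: non-monotone time for worm {wid!r} "
                            f"at line {row}")
        if premapped:
            tracks.append(WormTrack(str(wid), t,
                                    temperature=g["T_celsius"].to_numpy(float)))
        else:
            tracks.append(WormTrack(str(wid), t, x=g["x_mm"].to_numpy(float),
                                    y=g["y_mm"].to_numpy(float)))
    return tracks


def temperature_at(x, y, gmap: GradientMap):
    """Temperature (°C) at plate position(s) (x, y) in mm."""
    dx = np.asarray(x, dtype=float) - gmap.plate_center[0]
    dy = np.asarray(y, dtype=float) - gmap.plate_center[1]
    proj_cm = (dx * gmap.axis[0] + dy * gmap.axis[1]) / 10.0
    return gmap.center_temperature + gmap.slope * proj_cm


def _check_sg(window: int, order: int, n: int):
    if window % 2 == 0 or window <= order or order < 1:
        raise DataError(
            f"Savitzky-Golay window must be odd and > order >= 1 "
            f"(got window={window}, order={order})")
    if n < window:
        raise DataError(f"series of length {n} shorter than SG window {window}")


def sg_derivative(values, window: int, order: int, dt: float) -> np.ndarray:
    """Savitzky–Golay first derivative of a uniformly sampled series.

    Local least-squares polynomial fit of the given order over ``window``
    samples; endpoints use the filter's one-sided polynomial extension, so
    the output has the input's length.  Exact (to round-off) for
    polynomials of degree <= order.
    """
    values = np.asarray(values, dtype=float)
    _check_sg(window, order, len(values))
    return scipy.signal.savgol_filter(values, window, order, deriv=1,
                                      delta=dt, mode="interp")


def sg_smooth(values, window: int, order: int) -> np.ndarray:
    """Savitzky–Golay smoothing (zeroth derivative) with the same contract."""
    values = np.asarray(values, dtype=float)
    _check_sg(window, order, len(values))
    return scipy.signal.savgol_filter(values, window, order, mode="interp")


def _raw_segments(time: np.ndarray, max_gap: float):
    """Split raw sample indices wherever the sampling gap exceeds max_gap."""
    breaks = np.flatnonzero(np.diff(time) > max_gap)
    starts = np.r_[0, breaks + 1]
    stops = np.r_[breaks + 1, len(time)]
    return [(a, b) for a, b in zip(starts, stops) if b > a]


def extract_state_series(track: WormTrack, gmap: GradientMap | None = None,
                         delta_t: float = 1.0, sg_window: int = 7,
                         sg_order: int = 2) -> StateSeries:
    """Turn a raw track into a uniform-Δt (T, dT) series.

    Positions are mapped through the gradient (skipped for pre-mapped
    tracks), each gap-free stretch is linearly interpolated onto a uniform
    Δt time base, the temperature is Savitzky–Golay smoothed and its first
    derivative taken with the same filter.  Tracking gaps longer than 2Δt
    break the track into segments; resampled segments shorter than the
    smoothing window are dropped and counted.
    """
    if track.premapped:
        T_raw = track.temperature
    else:
        if gmap is None:
            raise DataError("positional track needs a GradientMap")
        T_raw = temperature_at(track.x, track.y, gmap)
    if len(track) == 0:
        raise DataError(f"worm {track.worm_id!r}: empty track")
    times, Ts, dTs, segs = [], [], [], []
    dropped = 0
    seg_id = 0
    for a, b in _raw_segments(track.time, 2.0 * delta_t):
        t0, t1 = track.time[a], track.time[b - 1]
        n = int(np.floor((t1 - t0) / delta_t)) + 1
        if n < sg_window:
            dropped += 1
            continue
        tt = t0 + delta_t * np.arange(n)
        T = np.interp(tt, track.time[a:b], T_raw[a:b])
        times.append(tt)
        Ts.append(sg_smooth(T, sg_window, sg_order))
        dTs.append(sg_derivative(T, sg_window, sg_order, delta_t))
        segs.append(np.full(n, seg_id))
        seg_id += 1
    if not times:
        raise DataError(
            f"worm {track.worm_id!r}: no usable segment (all shorter than "
            f"the SG window after resampling)")
    return StateSeries(track.worm_id, np.concatenate(times),
                       np.concatenate(Ts), np.concatenate(dTs),
                       np.concatenate(segs), delta_t, dropped)


def series_to_transitions(series_list, grid: StateGrid,
                          mode: str = "clip") -> TransitionData:
    """Discretize state series and emit consecutive-sample transition pairs.

    Pairs are formed only between consecutive samples of the same segment
    of the same worm.  Out-of-range samples are clipped (and tallied) or,
    in reject mode, remove every pair they touch (tallied as rejections).
    """
    if isinstance(series_list, StateSeries):
        series_list = [series_list]
    from_k, to_k, wids = [], [], []
    n_clipped = 0
    n_rejected = 0
    for s in series_list:
        k, n_out = discretize(s.T, s.dT, grid, mode=mode)
        same_seg = s.segment[1:] == s.segment[:-1]
        if mode == "reject":
            ok = (k[:-1] >= 0) & (k[1:] >= 0) & same_seg
            n_rejected += n_out
        else:
            ok = same_seg
            n_clipped += n_out
        from_k.append(k[:-1][ok])
        to_k.append(k[1:][ok])
        wids.append(np.full(int(ok.sum()), s.worm_id, dtype=object))
    pairs = np.column_stack([np.concatenate(from_k), np.concatenate(to_k)]) \
        if from_k else np.empty((0, 2), dtype=np.intp)
    return TransitionData(pairs, np.concatenate(wids) if wids else np.empty(0),
                          grid.n_states, n_clipped=n_clipped,
                          n_rejected=n_rejected)
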