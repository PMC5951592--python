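"""Track preprocessing: gradient lookup, SG derivative, state series."""

import io

import numpy as np
import pytest

from thermirl import (DataError, FormatError, GradientMap, GridSpec,
                      WormTrack, build_grid, extract_state_series,
                      read_tracks, series_to_transitions, sg_derivative,
                      temperature_at)
from thermirl.tracks import StateSeries, series_from_csv, series_to_csv


def _csv(tmp_path, text, name="tracks.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTracks:
    def test_positional_dialect(self, tmp_path):
        p = _csv(tmp_path, "worm_id,time_s,x_mm,y_mm\n"
                           "w1,0.0,1.0,2.0\nw1,0.5,1.1,2.0\nw1,1.0,1.2,2.1\n")
        tracks = read_tracks(p)
        assert len(tracks) == 1 and len(tracks[0]) == 3
        assert not tracks[0].premapped

    def test_premapped_dialect(self, tmp_path):
        p = _csv(tmp_path, "worm_id,time_s,T_celsius\n"
                           "w1,0.0,20.0\nw1,1.0,20.1\n")
        tracks = read_tracks(p)
        assert tracks[0].premapped
        assert np.allclose(tracks[0].temperature, [20.0, 20.1])

    def test_missing_columns_is_format_error(self, tmp_path):
        p = _csv(tmp_path, "worm,when\na,0\n")
        with pytest.raises(FormatError):
            read_tracks(p)

    def test_duplicate_time_names_the_row(self, tmp_path):
        p = _csv(tmp_path, "worm_id,time_s,T_celsius\n"
                           "w1,0.0,20.0\nw1,0.0,20.1\n")
        with pytest.raises(DataError, match="line 3"):
            read_tracks(p)

    def test_non_monotone_time_rejected(self, tmp_path):
        p = _csv(tmp_path, "worm_id,time_s,T_celsius\n"
                           "w1,1.0,20.0\nw1,0.5,20.1\n")
        with pytest.raises(DataError):
            read_tracks(p)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        p = _csv(tmp_path, "worm_id,time_s,T_celsius\n"
                           "w1,0.0,20.0\nw1,1.0,oops\n")
        with pytest.raises(DataError, match="lines 3"):
            read_tracks(p)


class TestTemperatureAt:
    def test_plate_center(self):
        g = GradientMap(20.0)
        assert temperature_at(0.0, 0.0, g) == 20.0

    def test_two_cm_up_gradient(self):
        g = GradientMap(20.0, slope=0.45, axis=(1.0, 0.0))
        assert temperature_at(20.0, 0.0, g) == pytest.approx(20.9)

    def test_orthogonal_displacement_is_isothermal(self):
        g = GradientMap(20.0, slope=0.45, axis=(1.0, 0.0))
        assert temperature_at(0.0, 37.0, g) == 20.0

    def test_affine_superposition(self, rng):
        g = GradientMap(20.0, slope=0.45, axis=(0.6, 0.8),
                        plate_center=(3.0, -2.0))
        a = rng.normal(size=2) * 10
        b = rng.normal(size=2) * 10
        base = temperature_at(*g.plate_center, g)
        da = temperature_at(*(g.plate_center + a), g) - base
        db = temperature_at(*(g.plate_center + b), g) - base
        dab = temperature_at(*(g.plate_center + a + b), g) - base
        assert dab == pytest.approx(da + db)


class TestSGDerivative:
    def test_exact_on_linear_ramp(self):
        t = np.arange(50) * 0.5
        d = sg_derivative(2.0 + 0.5 * t, window=7, order=2, dt=0.5)
        assert np.abs(d - 0.5).max() < 1e-10

    def test_exact_on_cubic_at_order_three(self):
        t = np.arange(60) * 0.2
        y = 1.0 - 0.3 * t + 0.02 * t ** 2 + 0.005 * t ** 3
        dy = -0.3 + 0.04 * t + 0.015 * t ** 2
        d = sg_derivative(y, window=9, order=3, dt=0.2)
        assert np.abs(d - dy).max() < 1e-9

    def test_constant_series_has_zero_derivative(self):
        d = sg_derivative(np.full(20, 19.5), window=7, order=2, dt=1.0)
        assert np.abs(d).max() < 1e-12

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            sg_derivative(np.arange(5.0), window=7, order=2, dt=1.0)


class TestExtractStateSeries:
    def test_stationary_worm_is_isothermal(self):
        t = np.arange(0.0, 30.0, 0.074)  # ~13.5 Hz
        track = WormTrack("w", t, x=np.full_like(t, 5.0),
                          y=np.full_like(t, 5.0))
        s = extract_state_series(track, GradientMap(20.0), delta_t=1.0)
        assert np.allclose(s.dT, 0.0, atol=1e-12)
        assert np.allclose(s.T, temperature_at(5.0, 5.0, GradientMap(20.0)))

    def test_straight_run_matches_chain_rule(self):
        # 0.2 mm/s up a 0.45 C/cm (0.045 C/mm) gradient -> 0.009 C/s
        t = np.arange(0.0, 60.0, 0.074)
        track = WormTrack("w", t, x=0.2 * t, y=np.zeros_like(t))
        s = extract_state_series(track, GradientMap(20.0, slope=0.45),
                                 delta_t=1.0)
        interior = s.dT[3:-3]
        assert np.abs(interior - 0.009).max() < 1e-6

    def test_gap_splits_segments_and_blocks_transitions(self):
        t = np.concatenate([np.arange(0.0, 10.0, 0.5),
                            np.arange(40.0, 50.0, 0.5)])
        track = WormTrack("w", t, temperature=np.full_like(t, 20.0))
        s = extract_state_series(track, delta_t=1.0)
        assert len(np.unique(s.segment)) == 2
        grid = build_grid(GridSpec(18.0, 22.0, 4, -0.01, 0.01, 3))
        data = series_to_transitions(s, grid)
        seg_lengths = [int((s.segment == i).sum()) for i in np.unique(s.segment)]
        assert len(data) == sum(seg_lengths) - 2

    def test_short_segments_dropped_and_counted(self):
        t = np.concatenate([np.arange(0.0, 3.0, 0.5),       # < SG window
                            np.arange(100.0, 120.0, 0.5)])
        track = WormTrack("w", t, temperature=np.full_like(t, 20.0))
        s = extract_state_series(track, delta_t=1.0, sg_window=7)
        assert s.dropped_segments == 1


class TestSeriesToTransitions:
    def test_transition_count(self, tiny_grid):
        s = StateSeries("w", np.arange(10.0), np.full(10, 20.0),
                        np.zeros(10), np.zeros(10, dtype=int))
        data = series_to_transitions(s, tiny_grid)
        assert len(data) == 9

    def test_single_bin_series_gives_self_transitions(self, tiny_grid):
        s = StateSeries("w", np.arange(8.0), np.full(8, 20.1),
                        np.zeros(8), np.zeros(8, dtype=int))
        data = series_to_transitions(s, tiny_grid)
        assert np.all(data.pairs[:, 0] == data.pairs[:, 1])

    def test_determinism_byte_identical(self, tmp_path, rng):
        t = np.arange(0.0, 40.0, 0.074)
        x = np.cumsum(rng.normal(0, 0.02, len(t)))
        body = "\n".join(f"w1,{ti:.3f},{xi:.5f},0.0" for ti, xi in zip(t, x))
        p = tmp_path / "in.csv"
        p.write_text("worm_id,time_s,x_mm,y_mm\n" + body + "\n")
        grid = build_grid(GridSpec(18.0, 22.0, 8, -0.01, 0.01, 5))

        def run():
            tracks = read_tracks(p)
            series = [extract_state_series(tr, GradientMap(20.0), 1.0)
                      for tr in tracks]
            out = tmp_path / "out.csv"
            series_to_transitions(series, grid).to_csv(out)
            return out.read_bytes()

        assert run() == run()

    def test_series_csv_round_trip(self, tmp_path):
        s = StateSeries("w9", np.arange(8.0), np.linspace(19, 20, 8),
                        np.full(8, 0.001), np.zeros(8, dtype=int))
        path = tmp_path / "series.csv"
        series_to_csv([s], path)
        back = series_from_csv(path)
        assert back[0].worm_id == "w9"
        assert np.allclose(back[0].T, s.T)


def test_band_limited_derivative_within_5pct_rms():
    """SG derivative of a slow sinusoidal temperature recovers the analytic
    derivative within 5% RMS."""
    dt = 1.0
    t = np.arange(0.0, 600.0, dt)
    T = 20.0 + 0.8 * np.sin(2 * np.pi * t / 120.0)   # period 2 min
    dT_true = 0.8 * (2 * np.pi / 120.0) * np.cos(2 * np.pi * t / 120.0)
    d = sg_derivative(T, window=7, order=2, dt=dt)
    rms = np.sqrt(np.mean((d - dT_true) ** 2))
    assert rms < 0.05 * np.sqrt(np.mean(dT_true ** 2))
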