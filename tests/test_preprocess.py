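"""Framewise displacement, FD filtering, scrubbing and nuisance regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from netbgc.preprocess import (
    DESIGN_COLUMNS,
    ParcellatedTimeSeries,
    framewise_displacement,
    lowpass_filter_fd,
    regress_nuisance,
    scrub_mask,
)

TR = 0.785


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert np.all(framewise_displacement(np.zeros((20, 6))) == 0)

    def test_translation_step(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 0.3
        fd = framewise_displacement(m)
        assert fd[5] == pytest.approx(0.3)
        assert np.all(np.delete(fd, 5) == 0)

    def test_rotation_arc_length(self):
        # 0.01 rad about one axis on a 50 mm sphere is 0.5 mm of arc
        m = np.zeros((10, 6))
        m[4:, 4] = 0.01
        fd = framewise_displacement(m, rotation_radius=50.0)
        assert fd[4] == pytest.approx(0.5)

    def test_first_frame_zero_convention(self, rng):
        fd = framewise_displacement(rng.standard_normal((30, 6)))
        assert fd[0] == 0.0

    @given(st.integers(0, 5), st.floats(-10, 10, allow_nan=False))
    @settings(deadline=None, max_examples=25)
    def test_column_offset_invariance(self, col, offset):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((15, 6)) * 0.1
        shifted = m.copy()
        shifted[:, col] += offset
        assert np.allclose(
            framewise_displacement(m), framewise_displacement(shifted)
        )

    def test_wrong_column_count(self):
        with pytest.raises(ValueError, match="6"):
            framewise_displacement(np.zeros((10, 5)))


class TestLowpassFD:
    def test_constant_passthrough(self):
        out = lowpass_filter_fd(np.full(100, 0.17), 0.3, TR)
        assert np.allclose(out, 0.17, atol=1e-9)

    def test_nyquist_attenuation(self):
        # alternating +-1 sits exactly at Nyquist; the designed filter must
        # attenuate it at least tenfold (checked against its own response)
        x = np.resize([1.0, -1.0], 400)
        out = lowpass_filter_fd(x, 0.3, TR)
        mid = out[50:-50]
        assert np.abs(mid).max() < 0.1
        b, a = signal.butter(2, 0.3, btype="low", fs=1 / TR)
        _, h = signal.freqz(b, a, worN=[np.pi])
        assert np.abs(h[0]) ** 2 < 0.1  # filtfilt applies |H|^2

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter_fd(np.zeros(100), 0.8, TR)

    def test_too_short_for_warmup(self):
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_filter_fd(np.zeros(5), 0.3, TR)


class TestScrubMask:
    def test_window_toy(self):
        fd = np.array([0.1, 0.1, 0.4, 0.1, 0.1, 0.1])
        keep = scrub_mask(fd, 0.3)
        assert list(np.flatnonzero(~keep)) == [1, 2, 3, 4]

    def test_all_below_threshold(self):
        assert scrub_mask(np.full(10, 0.05), 0.3).all()

    def test_boundary_clipping_first_frame(self):
        fd = np.array([0.5, 0.1, 0.1, 0.1, 0.1])
        keep = scrub_mask(fd, 0.3)
        assert list(np.flatnonzero(~keep)) == [0, 1, 2]

    def test_boundary_clipping_last_frame(self):
        fd = np.array([0.1, 0.1, 0.1, 0.1, 0.5])
        keep = scrub_mask(fd, 0.3)
        assert list(np.flatnonzero(~keep)) == [3, 4]

    def test_threshold_exclusive(self):
        # a frame exactly at threshold is not flagged
        assert scrub_mask(np.array([0.1, 0.3, 0.1, 0.1]), 0.3).all()

    @given(st.floats(0.05, 1.0), st.floats(0.0, 0.5))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_threshold(self, thr, delta):
        rng = np.random.default_rng(11)
        fd = rng.uniform(0, 1.2, 60)
        low = scrub_mask(fd, thr)
        high = scrub_mask(fd, thr + delta)
        # every frame kept at the low threshold stays kept at the high one
        assert np.all(high[low])


def _toy_inputs(rng, n_frames=60, n_regions=4):
    data = rng.standard_normal((n_regions, n_frames))
    ts = ParcellatedTimeSeries(
        "sub-toy", data, TR, tuple(f"r{i}" for i in range(n_regions))
    )
    motion = rng.standard_normal((n_frames, 6)) * 0.01
    vent = rng.standard_normal(n_frames)
    wm = rng.standard_normal(n_frames)
    gs = rng.standard_normal(n_frames)
    return ts, motion, vent, wm, gs


class TestRegressNuisance:
    def test_global_series_removed(self, rng):
        ts, motion, vent, wm, gs = _toy_inputs(rng)
        data = ts.data.copy()
        data[0] = 3.0 * gs - 1.0
        ts2 = ParcellatedTimeSeries(ts.subject_id, data, TR, ts.region_ids)
        out = regress_nuisance(ts2, motion, vent, wm, gs)
        assert np.abs(out.data[0]).max() < 1e-8

    def test_orthogonal_series_demeaned(self, rng):
        # a series orthogonal to every regressor only loses its mean
        ts, motion, vent, wm, gs = _toy_inputs(rng, n_frames=80)
        design = np.column_stack(
            [
                np.ones(80), motion,
                np.diff(motion, axis=0, prepend=motion[:1]),
                vent, wm,
                np.diff(vent, prepend=vent[:1]),
                np.diff(wm, prepend=wm[:1]),
                gs,
            ]
        )
        q, _ = np.linalg.qr(design)
        y = ts.data[1] - q @ (q.T @ ts.data[1])
        data = ts.data.copy()
        data[1] = y + 5.0  # shift; regression must remove only the mean part
        ts2 = ParcellatedTimeSeries(ts.subject_id, data, TR, ts.region_ids)
        out = regress_nuisance(ts2, motion, vent, wm, gs)
        assert np.allclose(out.data[1], y - y.mean(), atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        ts, motion, vent, wm, gs = _toy_inputs(rng)
        keep = np.ones(60, dtype=bool)
        keep[10:15] = False
        out = regress_nuisance(ts, motion, vent, wm, gs, keep)
        design = np.column_stack(
            [
                np.ones(60), motion,
                np.diff(motion, axis=0, prepend=motion[:1]),
                vent, wm,
                np.diff(vent, prepend=vent[:1]),
                np.diff(wm, prepend=wm[:1]),
                gs,
            ]
        )[keep]
        inner = out.data @ design
        scale = np.linalg.norm(out.data) * np.linalg.norm(design)
        assert np.abs(inner).max() / scale < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        # independent projection with an explicit (X'X)^-1 X'y solve
        ts, motion, vent, wm, gs = _toy_inputs(rng)
        out = regress_nuisance(ts, motion, vent, wm, gs)
        x = np.column_stack(
            [
                np.ones(60), motion,
                np.diff(motion, axis=0, prepend=motion[:1]),
                vent, wm,
                np.diff(vent, prepend=vent[:1]),
                np.diff(wm, prepend=wm[:1]),
                gs,
            ]
        )
        for r in range(ts.n_regions):
            beta = np.linalg.solve(x.T @ x, x.T @ ts.data[r])
            resid = ts.data[r] - x @ beta
            assert np.allclose(out.data[r], resid - resid.mean(), atol=1e-8)

    def test_collinear_design_names_columns(self, rng):
        ts, motion, vent, wm, gs = _toy_inputs(rng)
        with pytest.raises(ValueError, match="white_matter"):
            regress_nuisance(ts, motion, vent, vent, gs)

    def test_too_few_retained_frames(self, rng):
        ts, motion, vent, wm, gs = _toy_inputs(rng)
        keep = np.zeros(60, dtype=bool)
        keep[:10] = True
        with pytest.raises(ValueError, match="retained"):
            regress_nuisance(ts, motion, vent, wm, gs, keep)

    def test_residuals_zero_mean(self, rng):
        ts, motion, vent, wm, gs = _toy_inputs(rng)
        out = regress_nuisance(ts, motion, vent, wm, gs)
        assert np.allclose(out.data.mean(axis=1), 0, atol=1e-12)


def test_design_column_names_cover_17_regressors_plus_intercept():
    assert len(DESIGN_COLUMNS) == 18
    assert DESIGN_COLUMNS[0] == "intercept"
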