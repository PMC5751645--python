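import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microexp.descriptors import (DescriptorParams, FrameSequence,
                                  cell_mean, compute_cell_signals,
                                  displacement_features, motion_magnitude,
                                  resample_window, weighted_centroid)
from microexp.errors import ParameterError
from microexp.geometry import CELL_NAMES, Cell
from tests.conftest import constant_sequence


def _single_pixel_sequence(values_by_index: dict[int, float], n: int = 40):
    """1x1-pixel sequence whose frame t has the given value (default 0)."""
    frames = np.zeros((n, 1, 1))
    for t, v in values_by_index.items():
        frames[t, 0, 0] = v
    return FrameSequence(frames=frames, fps=100.0)


class TestMotionMagnitude:
    def test_constant_sequence_gives_one(self, default_params):
        seq = constant_sequence(77.0)
        mm = motion_magnitude(seq, 30, default_params)
        assert np.array_equal(mm, np.ones((32, 32)))

    def test_single_pixel_large_motion(self, default_params):
        # frame_t = 10, frame_{t-floor(tau/2)} = 4, frame_{t-eps} = 10
        t = 30
        seq = _single_pixel_sequence({t: 10.0, t - 18: 4.0, t - 3: 10.0})
        assert motion_magnitude(seq, t, default_params)[0, 0] == pytest.approx(7.0)

    def test_single_pixel_noise_suppression(self, default_params):
        # frame_t = 4, frame_{t-floor(tau/2)} = 4, frame_{t-eps} = 9
        t = 30
        seq = _single_pixel_sequence({t: 4.0, t - 18: 4.0, t - 3: 9.0})
        assert motion_magnitude(seq, t, default_params)[0, 0] == pytest.approx(1 / 6)

    def test_reference_indices_clamp_to_zero(self, default_params):
        seq = _single_pixel_sequence({0: 5.0, 1: 11.0}, n=10)
        # t=1: both references clamp to frame 0
        mm = motion_magnitude(seq, 1, default_params)
        assert mm[0, 0] == pytest.approx((6 + 1) / (6 + 1))

    def test_strictly_positive_everywhere(self, default_params):
        rng = np.random.default_rng(3)
        seq = FrameSequence(frames=rng.uniform(0, 255, (40, 8, 8)))
        for t in (0, 5, 20, 39):
            assert (motion_magnitude(seq, t, default_params) > 0).all()

    def test_invariant_under_global_intensity_offset(self, default_params):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 200, (40, 8, 8)).astype(np.float64)
        seq1 = FrameSequence(frames=base)
        seq2 = FrameSequence(frames=base + 55.0)
        mm1 = motion_magnitude(seq1, 25, default_params)
        mm2 = motion_magnitude(seq2, 25, default_params)
        assert np.array_equal(mm1, mm2)


class TestCellMean:
    def test_uniform_image(self):
        cell = Cell(name="probe", center=(8.0, 8.0), side=6.0)
        assert cell_mean(np.ones((16, 16)), cell) == 1.0

    def test_two_by_two_values(self):
        mm = np.zeros((4, 4))
        mm[0:2, 0:2] = [[1.0, 3.0], [5.0, 7.0]]
        cell = Cell(name="probe", center=(1.0, 1.0), side=2.0)
        assert cell_mean(mm, cell) == pytest.approx(4.0)

    def test_clipped_cell_uses_inside_pixels_only(self):
        mm = np.full((10, 10), 3.5)
        cell = Cell(name="probe", center=(0.0, 5.0), side=8.0)
        assert cell_mean(mm, cell) == pytest.approx(3.5)

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mm = rng.uniform(0.1, 9.0, (16, 16))
            cx, cy = rng.uniform(2, 14, 2)
            side = rng.uniform(2, 8)
            cell = Cell(name="probe", center=(cx, cy), side=side)
            x0, x1, y0, y1 = cell.bounds((16, 16))
            total, count = 0.0, 0
            for y in range(y0, y1):
                for x in range(x0, x1):
                    total += mm[y, x]
                    count += 1
            assert cell_mean(mm, cell) == pytest.approx(total / count, abs=1e-12)


class TestWeightedCentroid:
    def test_uniform_mass_gives_geometric_center(self):
        cell = Cell(name="probe", center=(8.0, 6.0), side=4.0)
        cx, cy = weighted_centroid(np.ones((16, 16)), cell)
        x0, x1, y0, y1 = cell.bounds((16, 16))
        assert cx == pytest.approx((x0 + x1 - 1) / 2)
        assert cy == pytest.approx((y0 + y1 - 1) / 2)

    def test_concentrated_mass(self):
        mm = np.full((16, 16), 1e-6)
        mm[10, 7] = 1e6
        cell = Cell(name="probe", center=(8.0, 8.0), side=10.0)
        cx, cy = weighted_centroid(mm, cell)
        assert abs(cx - 7) < 1e-3 and abs(cy - 10) < 1e-3

    def test_two_equal_masses(self):
        mm = np.full((20, 20), 1e-9)
        mm[10, 10] = 5.0
        mm[10, 14] = 5.0
        cell = Cell(name="probe", center=(12.0, 10.0), side=12.0)
        cx, cy = weighted_centroid(mm, cell)
        assert cx == pytest.approx(12.0, abs=1e-6)
        assert cy == pytest.approx(10.0, abs=1e-6)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_centroid_inside_clipped_bounding_box(self, seed):
        rng = np.random.default_rng(seed)
        mm = rng.uniform(0.01, 10.0, (16, 16))
        cell = Cell(name="probe",
                    center=tuple(rng.uniform(0, 16, 2)), side=rng.uniform(2, 12))
        try:
            x0, x1, y0, y1 = cell.bounds((16, 16))
        except Exception:
            return
        cx, cy = weighted_centroid(mm, cell)
        assert x0 - 0.5 <= cx <= x1 - 0.5
        assert y0 - 0.5 <= cy <= y1 - 0.5


class TestResampleWindow:
    def test_identity_sampling(self):
        assert resample_window(0, 10, 11).tolist() == list(range(11))

    def test_rounded_spread(self):
        expected = [0, 4, 7, 11, 14, 18, 22, 25, 29, 32, 36]
        assert resample_window(0, 36, 11).tolist() == expected

    def test_degenerate_window_repeats(self):
        assert resample_window(5, 5, 3).tolist() == [5, 5, 5]

    def test_full_window_is_permutation_free(self):
        idx = resample_window(10, 30, 21)
        assert idx.tolist() == list(range(10, 31))

    def test_monotone_and_endpoints(self):
        idx = resample_window(3, 200, 11)
        assert idx[0] == 3 and idx[-1] == 200
        assert (np.diff(idx) >= 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            resample_window(5, 4, 3)
        with pytest.raises(ParameterError):
            resample_window(0, 10, 1)


class TestCellSignals:
    def test_constant_sequence_prefix_and_ones(self, template_grid,
                                               default_params):
        seq = FrameSequence(frames=np.full((60, 160, 160), 90.0))
        signals = compute_cell_signals(seq, template_grid, default_params)
        start = default_params.signal_start
        for name in CELL_NAMES:
            s = signals.series[name]
            assert len(s) == 60
            assert np.array_equal(s[:start], np.zeros(start))
            assert np.array_equal(s[start:], np.ones(60 - start))

    def test_blink_like_brightening_peaks_after_event(self, template_grid,
                                                      default_params):
        # ramp brightening of one isolated cell over [a, a + tau/2]: the
        # signal peaks once the short-lag difference goes quiet, i.e. at
        # a + tau/2 + eps (numerator maximal, denominator back to zero)
        a, tau_half = 60, default_params.half_tau
        frames = np.full((140, 160, 160), 100.0)
        cell = template_grid["mentalis"]  # overlaps no other cell
        x0, x1, y0, y1 = cell.bounds((160, 160))
        for t in range(a, 140):
            ramp = min((t - a) / tau_half, 1.0)
            frames[t, y0:y1, x0:x1] += 40.0 * ramp
        seq = FrameSequence(frames=frames)
        signals = compute_cell_signals(seq, template_grid, default_params)
        peak = int(np.argmax(signals.series["mentalis"]))
        expected = a + tau_half + default_params.eps
        assert expected - 2 <= peak <= expected + 2
        # all other cells stay at 1 (no motion reaches them)
        for name in CELL_NAMES:
            if name != "mentalis":
                assert signals.series[name][default_params.signal_start:].max() \
                    == pytest.approx(1.0)

    def test_matches_per_frame_motion_magnitude(self, template_grid,
                                                default_params):
        rng = np.random.default_rng(9)
        seq = FrameSequence(frames=rng.uniform(0, 255, (45, 160, 160)))
        signals = compute_cell_signals(seq, template_grid, default_params)
        t = 40
        mm = motion_magnitude(seq, t, default_params)
        for name in CELL_NAMES:
            assert signals.series[name][t] == pytest.approx(
                cell_mean(mm, template_grid[name]), abs=1e-9)


class TestDisplacementFeatures:
    def test_constant_sequence_gives_zero_pairs(self, template_grid,
                                                default_params):
        seq = FrameSequence(frames=np.full((80, 160, 160), 50.0))
        feats = displacement_features(seq, template_grid, 40, default_params)
        assert feats.n_pairs == default_params.n_resample - 1
        for name in CELL_NAMES:
            np.testing.assert_allclose(feats.pairs[name], 0.0, atol=1e-12)

    def test_output_shape_contract(self, template_grid, default_params):
        rng = np.random.default_rng(2)
        seq = FrameSequence(frames=rng.uniform(0, 255, (60, 160, 160)))
        feats = displacement_features(seq, template_grid, 30, default_params)
        assert set(feats.pairs) == set(CELL_NAMES)
        for name in CELL_NAMES:
            assert feats.pairs[name].shape == (10, 2)

    def test_translated_blob_recovers_displacement(self, template_grid,
                                                   default_params):
        # a bright blob inside one (isolated) cell moves +4 px in x early in
        # the window and then rests; the MM difference pattern forms two
        # lobes at the old and new positions, so the cell's centroid
        # displacement reports roughly half the translation along +x
        cell = template_grid["mentalis"]
        x0, x1, y0, y1 = cell.bounds((160, 160))
        anchor = ((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0)
        apex = 60
        w0 = apex - default_params.half_tau
        frames = np.full((120, 160, 160), 100.0, dtype=np.float64)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        for t in range(120):
            u = np.clip((t - w0) / 10.0, 0.0, 1.0)
            bx = anchor[0] + 4.0 * u
            frames[t, y0:y1, x0:x1] += 80.0 * np.exp(
                -(((xx - bx) ** 2 + (yy - anchor[1]) ** 2) / (2 * 2.5 ** 2)))
        seq = FrameSequence(frames=frames)
        feats = displacement_features(seq, template_grid, apex, default_params)
        k = np.argmax(np.abs(feats.pairs["mentalis"][:, 0]))
        dx, dy = feats.pairs["mentalis"][k]
        assert 2.0 <= dx <= 6.0
        assert abs(dy) < 1.0
        for name in CELL_NAMES:
            if name != "mentalis":
                norms = np.hypot(*feats.pairs[name].T)
                assert norms.max() < 0.5
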