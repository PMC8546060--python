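import numpy as np
import pytest
from scipy.ndimage import shift as ndshift

from mbkit.io import RoiSpec
from mbkit.tracking import TrackingParams, qc_trace, symmetry_index, track_roi

from conftest import PIXEL_SIZE, center_roi, make_stack


def exhaustive_zncc_argmax(window, template):
    """Spatial-domain zero-normalized cross-correlation oracle.

    Slides the template over every valid position of the window and
    returns the argmax offset (row, col) relative to the window centre,
    computed with nothing but elementwise numpy — independent of the
    FFT-accelerated implementation under test.
    """
    th, tw = template.shape
    t = template - template.mean()
    tn = np.sqrt((t**2).sum())
    best, arg = -np.inf, None
    for r in range(window.shape[0] - th + 1):
        for c in range(window.shape[1] - tw + 1):
            patch = window[r : r + th, c : c + tw]
            p = patch - patch.mean()
            pn = np.sqrt((p**2).sum())
            score = (p * t).sum() / (pn * tn) if pn > 0 else 0.0
            if score > best:
                best, arg = score, (r, c)
    rad_r = (window.shape[0] - th) // 2
    rad_c = (window.shape[1] - tw) // 2
    return arg[0] - rad_r, arg[1] - rad_c, best


class TestTrackRoi:
    def test_static_stack_gives_zero_displacement_and_unit_score(self, texture):
        stack = make_stack([texture] * 5)
        tr = track_roi(stack, center_roi(texture.shape), TrackingParams(search_radius=6))
        np.testing.assert_array_equal(tr.dx_um, 0.0)
        np.testing.assert_array_equal(tr.dy_um, 0.0)
        np.testing.assert_allclose(tr.score, 1.0, atol=1e-9)

    def test_integer_shift_recovered_exactly(self, texture):
        shifted = ndshift(texture, (-2, 3), order=3, mode="nearest")
        stack = make_stack([texture, shifted])
        tr = track_roi(stack, center_roi(texture.shape), TrackingParams(search_radius=8))
        assert tr.dx_um[1] == pytest.approx(3 * PIXEL_SIZE, abs=1e-9)
        assert tr.dy_um[1] == pytest.approx(-2 * PIXEL_SIZE, abs=1e-9)

    def test_fft_peak_equals_exhaustive_zncc_argmax(self, texture):
        """FFT-accelerated integer peak == brute-force spatial ZNCC argmax."""
        rng = np.random.default_rng(42)
        roi = center_roi(texture.shape, half=8)
        rad = 5
        params = TrackingParams(search_radius=rad, subpixel=False)
        for _ in range(10):
            dy, dx = rng.integers(-3, 4, 2)
            noisy = ndshift(texture, (dy, dx), order=3, mode="nearest")
            noisy = noisy + rng.normal(0, 1.5, texture.shape)
            stack = make_stack([texture, noisy])
            tr = track_roi(stack, roi, params)
            r0, r1, c0, c1 = roi.bounds()
            window = noisy[r0 - rad : r1 + rad, c0 - rad : c1 + rad]
            template = texture[r0:r1, c0:c1]
            orow, ocol, _ = exhaustive_zncc_argmax(window, template.astype(float))
            assert tr.dx_um[1] / PIXEL_SIZE == pytest.approx(ocol)
            assert tr.dy_um[1] / PIXEL_SIZE == pytest.approx(orow)

    def test_subpixel_shift_recovered_within_tenth_px(self, texture):
        roi = center_roi(texture.shape)
        params = TrackingParams(search_radius=6)
        for s in np.linspace(-0.5, 0.5, 11):
            shifted = ndshift(texture, (0.0, s), order=3, mode="nearest")
            tr = track_roi(make_stack([texture, shifted]), roi, params)
            assert tr.dx_um[1] / PIXEL_SIZE == pytest.approx(s, abs=0.1)

    def test_subpixel_accuracy_at_snr10(self, texture):
        # contrast sd 30, noise sd 3 -> SNR 10
        rng = np.random.default_rng(11)
        roi = center_roi(texture.shape)
        params = TrackingParams(search_radius=6)
        for s in np.linspace(-0.5, 0.5, 11):
            shifted = ndshift(texture, (0.0, s), order=3, mode="nearest")
            shifted = shifted + rng.normal(0, 3.0, texture.shape)
            tr = track_roi(make_stack([texture, shifted]), roi, params)
            assert tr.dx_um[1] / PIXEL_SIZE == pytest.approx(s, abs=0.1)

    def test_mirror_equivariance(self, texture):
        frames = [texture, ndshift(texture, (1, 2), order=3, mode="nearest")]
        stack = make_stack(frames)
        roi = center_roi(texture.shape)
        tr = track_roi(stack, roi, TrackingParams(search_radius=6))
        flipped = make_stack(np.asarray(frames)[:, :, ::-1].copy())
        w = texture.shape[1]
        roi_f = RoiSpec((w - 1 - roi.center[0], roi.center[1]), roi.half_size, "proximal")
        tr_f = track_roi(flipped, roi_f, TrackingParams(search_radius=6))
        assert tr_f.dx_um[1] == pytest.approx(-tr.dx_um[1], abs=1e-6)
        assert tr_f.dy_um[1] == pytest.approx(tr.dy_um[1], abs=1e-6)

    def test_clipped_search_window_rejected(self, texture):
        stack = make_stack([texture] * 2)
        roi = RoiSpec((12, 12), (10, 10), "proximal")
        with pytest.raises(ValueError, match="clipped"):
            track_roi(stack, roi, TrackingParams(search_radius=8))

    def test_peak_on_border_flagged(self, texture):
        # shift larger than the search radius -> peak pinned to the border
        shifted = ndshift(texture, (0, 5), order=3, mode="nearest")
        stack = make_stack([texture, shifted])
        tr = track_roi(stack, center_roi(texture.shape), TrackingParams(search_radius=3))
        assert tr.border_flags[1]


class TestSymmetryIndex:
    def _trace(self, ax, roi_x=0.0):
        ax = np.asarray(ax, float)
        return_roi = RoiSpec((roi_x, 50.0), (8, 8), "proximal")
        from mbkit.tracking import DisplacementTrace

        return DisplacementTrace(
            dx_um=ax,
            dy_um=np.zeros_like(ax),
            score=np.ones_like(ax),
            ref_index=0,
            roi=return_roi,
            pixel_size=0.5,
            frame_interval=0.02,
        )

    def test_antisymmetric_motion_scores_zero(self):
        s = symmetry_index(self._trace([1.0]), self._trace([-1.0]), 0.0)
        assert s[0] == pytest.approx(0.0)

    def test_common_mode_scores_one(self):
        s = symmetry_index(self._trace([1.0]), self._trace([1.0]), 0.0)
        assert s[0] == pytest.approx(1.0)

    def test_one_sided_motion_scores_one(self):
        s = symmetry_index(self._trace([1.0]), self._trace([0.0]), 0.0)
        assert s[0] == pytest.approx(1.0)

    def test_below_noise_floor_is_nan(self):
        s = symmetry_index(self._trace([0.01]), self._trace([-0.01]), 0.0)
        assert np.isnan(s[0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            symmetry_index(self._trace([1.0, 2.0]), self._trace([1.0]), 0.0)


class TestQc:
    def test_clean_synthetic_pair_accepted(self, tracked_pair):
        prox, dist, record = tracked_pair
        verdict = qc_trace(prox, dist, 0.0, TrackingParams(search_radius=12))
        assert verdict.accepted, verdict.reasons

    def test_noise_frame_rejected_with_frame_number(self, texture):
        rng = np.random.default_rng(2)
        frames = np.array([texture] * 8)
        frames[5] = rng.normal(100, 30, texture.shape)
        stack = make_stack(frames)
        p1 = RoiSpec((30, 48), (8, 8), "proximal")
        p2 = RoiSpec((66, 48), (8, 8), "distal")
        params = TrackingParams(search_radius=8)
        verdict = qc_trace(track_roi(stack, p1, params), track_roi(stack, p2, params), 0.0, params)
        assert not verdict.accepted
        assert any("low correlation at frame 5" in r for r in verdict.reasons)

    def test_rigid_translation_rejected_as_common_mode(self, texture):
        frames = [
            ndshift(texture, (0, 3 * np.sin(2 * np.pi * t / 20)), order=3, mode="nearest")
            for t in range(40)
        ]
        stack = make_stack(frames)
        p1 = RoiSpec((30, 48), (8, 8), "proximal")
        p2 = RoiSpec((66, 48), (8, 8), "distal")
        params = TrackingParams(search_radius=8)
        verdict = qc_trace(track_roi(stack, p1, params), track_roi(stack, p2, params), 0.0, params)
        assert not verdict.accepted
        assert any("common-mode" in r for r in verdict.reasons)
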