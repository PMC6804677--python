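"""Autofocusing and candidate-video extraction."""

import numpy as np
import pytest

from holocyte.focusing import (
    CandidateVideo,
    autofocus_coarse,
    autofocus_refine,
    extract_candidate_video,
    window_sum,
)
from holocyte.motion import Candidate, HologramVideo, MotionContrastVolume
from holocyte.optics import DepthGrid


def volume_with_bumps(n_planes=43, shape=(128, 128), bumps=()):
    """C volume with Gaussian bumps at given (plane, x, y) positions."""
    grid = DepthGrid.regular(800, 800 + 100 * (n_planes - 1), 100)
    values = np.zeros((n_planes,) + shape, dtype=np.float32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for plane, x, y in bumps:
        values[plane] += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 3.0**2))
    return MotionContrastVolume(values=values, grid=grid)


def exhaustive_argmax(volume, cand):
    """Brute-force oracle for the windowed-sum focus criterion."""
    nz, h, w = volume.values.shape
    cx, cy = int(round(cand.x)), int(round(cand.y))
    best, best_j = -np.inf, 0
    for j in range(nz):
        total = 0.0
        for dy in range(-19, 21):
            for dx in range(-19, 21):
                yy, xx = cy + dy, cx + dx
                if 0 <= yy < h and 0 <= xx < w:
                    total += volume.values[j, yy, xx]
        if total > best:
            best, best_j = total, j
    return best_j


class TestCoarse:
    def test_single_bump_plane_found(self):
        vol = volume_with_bumps(bumps=[(17, 64, 64)])
        cand = Candidate(x=64.0, y=64.0, area=9, peak_score=1.0)
        z = autofocus_coarse(vol, cand)
        assert z == vol.grid.z_values[17]
        assert cand.z_coarse == z

    def test_two_candidates_recover_their_planes(self):
        vol = volume_with_bumps(bumps=[(5, 30, 30), (30, 96, 96)])
        c1 = Candidate(x=30.0, y=30.0, area=9, peak_score=1.0)
        c2 = Candidate(x=96.0, y=96.0, area=9, peak_score=1.0)
        assert autofocus_coarse(vol, c1) == vol.grid.z_values[5]
        assert autofocus_coarse(vol, c2) == vol.grid.z_values[30]

    def test_matches_exhaustive_oracle_on_random_volume(self):
        rng = np.random.default_rng(0)
        grid = DepthGrid.regular(800, 1800, 100)
        vol = MotionContrastVolume(
            rng.normal(size=(11, 60, 60)).astype(np.float32), grid)
        for x, y in [(30.0, 30.0), (5.0, 45.0), (58.0, 2.0)]:  # incl. corners
            cand = Candidate(x=x, y=y, area=9, peak_score=1.0)
            got = autofocus_coarse(vol, cand)
            assert got == grid.z_values[exhaustive_argmax(vol, cand)]

    def test_flat_scores_warn_and_return_smallest_z(self):
        grid = DepthGrid.regular(800, 1200, 100)
        vol = MotionContrastVolume(np.ones((5, 64, 64), np.float32), grid)
        cand = Candidate(x=32.0, y=32.0, area=9, peak_score=1.0)
        with pytest.warns(RuntimeWarning):
            assert autofocus_coarse(vol, cand) == 800.0

    def test_centroid_outside_frame_rejected(self):
        vol = volume_with_bumps(n_planes=3, shape=(32, 32))
        with pytest.raises(ValueError):
            autofocus_coarse(vol, Candidate(x=99.0, y=5.0, area=9, peak_score=1.0))

    def test_peak_criterion(self):
        # max-of-C criterion finds the plane holding the highest peak even
        # when a broad weak bump elsewhere wins the summed criterion
        grid = DepthGrid.regular(800, 1200, 100)
        values = np.zeros((5, 64, 64), np.float32)
        yy, xx = np.mgrid[:64, :64]
        values[1] += 0.2 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 12.0**2))
        values[3] += 1.0 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 1.5**2))
        vol = MotionContrastVolume(values, grid)
        cand = Candidate(x=32.0, y=32.0, area=9, peak_score=1.0)
        assert autofocus_coarse(vol, cand, criterion="max") == grid.z_values[1]
        assert autofocus_coarse(vol, cand, criterion="peak") == grid.z_values[3]

    def test_unknown_criterion_rejected(self):
        vol = volume_with_bumps(n_planes=3, shape=(32, 32))
        cand = Candidate(x=16.0, y=16.0, area=9, peak_score=1.0)
        with pytest.raises(ValueError):
            autofocus_coarse(vol, cand, criterion="tamura")


class TestWindowSum:
    def test_window_is_asymmetric_40px(self):
        # offsets -19..+20: a point 20 px right of centre is inside the
        # window, a point 20 px left of centre is not
        values = np.zeros((1, 101, 101), np.float32)
        values[0, 50, 70] = 1.0  # +20
        assert window_sum(values, 50, 50)[0] == 1.0
        values[:] = 0.0
        values[0, 50, 30] = 1.0  # -20
        assert window_sum(values, 50, 50)[0] == 0.0


class TestRefine:
    def _flat_video(self, n=12, shape=(64, 64)):
        rng = np.random.default_rng(0)
        frames = np.full((n,) + shape, 100.0, np.float32)
        frames += rng.normal(0, 1e-6, frames.shape)
        return HologramVideo(frames, frame_rate=2.0)

    def test_flat_neighbourhood_returns_coarse(self):
        video = HologramVideo(np.full((12, 64, 64), 100.0, np.float32),
                              frame_rate=2.0)
        grid = DepthGrid.regular(800, 1600, 100)
        cand = Candidate(x=32.0, y=32.0, area=9, peak_score=1.0)
        with pytest.warns(RuntimeWarning):
            z = autofocus_refine(video, cand, 1200.0, grid, patch_size=64)
        assert z == 1200.0

    def test_out_of_range_span_clamped(self):
        video = self._flat_video()
        grid = DepthGrid.regular(800, 1600, 100)
        cand = Candidate(x=32.0, y=32.0, area=9, peak_score=1.0)
        with pytest.warns(RuntimeWarning):
            autofocus_refine(video, cand, 800.0, grid, patch_size=64,
                             fine_halfspan=300.0)


class TestExtraction:
    def _video(self, n=12, shape=(96, 96)):
        rng = np.random.default_rng(1)
        frames = rng.uniform(80, 120, (n,) + shape).astype(np.float32)
        return HologramVideo(frames, frame_rate=2.0)

    def test_output_shape_and_channels(self):
        video = self._video()
        cand = Candidate(x=48.0, y=48.0, area=9, peak_score=1.0)
        cv = extract_candidate_video(video, cand, 1000.0, crop=64,
                                     patch_size=96, candidate_id=3)
        assert cv.values.shape == (2, 12, 64, 64)
        assert cv.candidate_id == 3
        amplitude, phase = cv.values
        assert np.all(amplitude >= 0)
        assert np.all(phase > -np.pi) and np.all(phase <= np.pi)

    def test_amplitude_normalized_to_unit_99th_percentile(self):
        video = self._video()
        cand = Candidate(x=48.0, y=48.0, area=9, peak_score=1.0)
        cv = extract_candidate_video(video, cand, 1000.0, crop=64, patch_size=96)
        assert np.percentile(cv.values[0], 99.0) == pytest.approx(1.0, rel=1e-5)

    def test_border_candidate_padded_not_rejected(self):
        video = self._video()
        cand = Candidate(x=10.0, y=48.0, area=9, peak_score=1.0)
        cv = extract_candidate_video(video, cand, 1000.0, crop=64, patch_size=96)
        assert cv.values.shape == (2, 12, 64, 64)

    def test_centroid_outside_frame_rejected(self):
        video = self._video()
        with pytest.raises(ValueError):
            extract_candidate_video(video, Candidate(x=500.0, y=48.0, area=9,
                                                     peak_score=1.0), 1000.0)

    def test_candidate_video_shape_validated(self):
        with pytest.raises(ValueError):
            CandidateVideo(values=np.zeros((3, 12, 64, 64)), candidate_id=0,
                           z_refined=1000.0, frame_rate=26.7)


@pytest.fixture(scope="module")
def scene_volume():
    from holocyte.motion import motion_contrast_volume
    from holocyte.simulate import SceneSpec, SimObject, render_hologram_video

    z0 = 1050.0
    scene = SceneSpec(
        fov=(192, 192), n_frames=60, frame_rate=26.7,
        objects=[SimObject(kind="oscillating_cell", x=96, y=96, z=z0,
                           obj_id=0)],
        gaussian_noise=2.0, speckle_density=0.002, seed=3)
    rendered = render_hologram_video(scene, patch_size=192)
    grid = DepthGrid.regular(800, 1600, 100)
    vol = motion_contrast_volume(rendered.video, grid)
    return rendered.video, vol, grid, z0


class TestSimulatedFocus:
    """Axial localization on rendered scenes (pipeline criteria)."""

    def test_peak_coarse_within_one_step(self, scene_volume):
        video, vol, grid, z0 = scene_volume
        cand = Candidate(x=96.0, y=96.0, area=9, peak_score=1.0)
        z_c = autofocus_coarse(vol, cand, criterion="peak")
        assert abs(z_c - z0) <= 100.0

    def test_refined_depth_within_20um(self, scene_volume):
        video, vol, grid, z0 = scene_volume
        cand = Candidate(x=96.0, y=96.0, area=9, peak_score=1.0)
        z_c = autofocus_coarse(vol, cand, criterion="peak")
        z_r = autofocus_refine(video, cand, z_c, grid, patch_size=192)
        assert abs(z_r - z0) <= 20.0

    def test_in_focus_sharpness_exceeds_defocused(self, scene_volume):
        # normalized amplitude variance (var/mean^2, invariant to the
        # per-candidate scaling) peaks at the in-focus plane
        video, vol, grid, z0 = scene_volume
        cand = Candidate(x=96.0, y=96.0, area=9, peak_score=1.0)

        def sharpness(z):
            amp = extract_candidate_video(video, cand, z, crop=64,
                                          patch_size=192).values[0]
            return amp.var() / amp.mean() ** 2

        assert sharpness(z0) > sharpness(z0 + 500.0)
        assert sharpness(z0) > sharpness(z0 - 500.0)
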