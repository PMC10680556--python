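import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimphys.synthetic import SlimfieldSimConfig, simulate_image_stack
from slimphys.tracking import (
    Spot,
    TrackingParams,
    detect_spots,
    filter_candidates,
    link_tracks,
    measure_spot,
    track_stack,
)
from tests.conftest import gaussian_spot_image


def brute_force_maxima(image, radius):
    """Oracle: pixel (i, j) is a maximum iff it strictly dominates every
    other pixel within `radius` (ties broken by scan order)."""
    maxima = []
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            r0, r1 = max(0, i - radius), min(image.shape[0], i + radius + 1)
            c0, c1 = max(0, j - radius), min(image.shape[1], j + radius + 1)
            if image[i, j] == image[r0:r1, c0:c1].max():
                maxima.append((i, j))
    return maxima


def brute_force_measure(image, centroid, params):
    """Oracle: double loop over every pixel, Euclidean distances."""
    r, c = centroid
    disc, annulus = [], []
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            d = np.hypot(i - r, j - c)
            if d <= params.inner_radius:
                disc.append(image[i, j])
            elif params.annulus_inner < d <= params.annulus_outer:
                annulus.append(image[i, j])
    bg = float(np.mean(annulus))
    return float(np.sum(disc) - len(disc) * bg), bg, float(np.std(annulus))


class TestDetectSpots:
    def test_blank_frame_no_spots(self, default_params):
        assert detect_spots(np.zeros((32, 32)), None, default_params) == []

    def test_empty_mask_no_spots(self, default_params):
        image = gaussian_spot_image((32, 32), (16.0, 16.0))
        mask = np.zeros((32, 32), dtype=np.int32)
        assert detect_spots(image, mask, default_params) == []

    def test_single_spot_centroid_accuracy(self, default_params):
        image = gaussian_spot_image((40, 40), (20.0, 20.0), sigma=1.5, amplitude=50)
        spots = detect_spots(image, None, default_params)
        assert len(spots) == 1
        # oracle: analytic image has its argmax and center of mass at (20, 20)
        assert np.unravel_index(np.argmax(image), image.shape) == (20, 20)
        assert spots[0].centroid == pytest.approx((20.0, 20.0), abs=0.3)

    def test_two_spots_resolved(self, default_params):
        image = gaussian_spot_image((40, 40), (14.0, 20.0)) + gaussian_spot_image(
            (40, 40), (26.0, 20.0)
        )
        spots = detect_spots(image, None, default_params)
        assert len(spots) == 2
        oracle = [m for m in brute_force_maxima(image, 5) if image[m] > 10]
        assert len(oracle) == 2

    def test_subpixel_centroid(self, default_params):
        image = gaussian_spot_image((40, 40), (20.4, 19.7), sigma=1.5, amplitude=80)
        spots = detect_spots(image, None, default_params)
        assert len(spots) == 1
        assert spots[0].centroid == pytest.approx((20.4, 19.7), abs=0.3)


class TestMeasureSpot:
    def test_uniform_image_cancels(self, default_params):
        for b in (0.0, 7.0, 123.0):
            image = np.full((32, 32), b)
            summed, bg_mean, bg_sd, valid = measure_spot(
                image, (16.0, 16.0), default_params
            )
            assert valid
            assert summed == pytest.approx(0.0, abs=1e-9)
            assert bg_mean == pytest.approx(b)
            assert bg_sd == 0.0

    def test_delta_source(self, default_params):
        image = np.zeros((32, 32))
        image[16, 16] = 100.0
        summed, _, _, _ = measure_spot(image, (16.0, 16.0), default_params)
        assert summed == pytest.approx(100.0)

    def test_constructed_spot_on_background(self, default_params):
        # oracle: direct pixel-array construction — place 500 photoelectrons
        # inside the disc on a uniform background of 10
        image = np.full((32, 32), 10.0)
        image[15, 15] += 200.0
        image[16, 16] += 150.0
        image[17, 16] += 150.0
        summed, bg_mean, _, _ = measure_spot(image, (16.0, 16.0), default_params)
        assert bg_mean == pytest.approx(10.0)
        assert summed == pytest.approx(500.0, abs=1.0)

    def test_annulus_outside_image_invalid(self, default_params):
        image = np.zeros((4, 4))  # no pixel farther than 5 px from the corner
        *_, valid = measure_spot(image, (0.0, 0.0), default_params)
        assert not valid

    def test_matches_brute_force_on_random_images(self, default_params):
        # >= 100 random cases against the double-loop oracle
        rng = np.random.default_rng(42)
        for _ in range(100):
            image = rng.uniform(0, 100, size=(24, 24))
            centroid = tuple(rng.uniform(9, 15, size=2))
            got = measure_spot(image, centroid, default_params)
            want = brute_force_measure(image, centroid, default_params)
            assert got[0] == pytest.approx(want[0], abs=1e-8)
            assert got[1] == pytest.approx(want[1], abs=1e-10)
            assert got[2] == pytest.approx(want[2], abs=1e-10)


def _spot(summed, bg_sd):
    return Spot(
        frame=0, centroid=(10.0, 10.0), summed_intensity=summed,
        background_mean=0.0, background_sd=bg_sd, roi_label=1,
    )


class TestFilterCandidates:
    def test_below_threshold_discarded(self, default_params):
        assert filter_candidates([_spot(39.0, 100.0)], default_params) == []

    def test_boundary_kept(self, default_params):
        # quoted rule discards strictly below 0.4x; the boundary stays
        kept = filter_candidates([_spot(40.0, 100.0)], default_params)
        assert len(kept) == 1

    def test_zero_sd_keeps_nonnegative(self, default_params):
        spots = [_spot(0.0, 0.0), _spot(5.0, 0.0)]
        assert len(filter_candidates(spots, default_params)) == 2

    @given(factor=st.floats(0.0, 5.0), bump=st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_factor(self, factor, bump):
        rng = np.random.default_rng(0)
        spots = [
            _spot(float(s), float(b))
            for s, b in zip(rng.uniform(0, 100, 30), rng.uniform(0, 100, 30))
        ]
        lo = TrackingParams(candidate_factor=factor)
        hi = TrackingParams(candidate_factor=factor + bump)
        assert len(filter_candidates(spots, hi)) <= len(filter_candidates(spots, lo))


def _immobile(frame, pos, intensity=100.0):
    return Spot(
        frame=frame, centroid=pos, summed_intensity=intensity,
        background_mean=0.0, background_sd=1.0, roi_label=1,
    )


class TestLinkTracks:
    def test_single_immobile_spot(self):
        params = TrackingParams(min_track_length=1)
        frames = [[_immobile(f, (10.0, 10.0))] for f in range(10)]
        df = link_tracks(frames, params)
        assert df["track_id"].nunique() == 1
        assert len(df) == 10

    def test_two_separated_spots_never_merge(self):
        params = TrackingParams(max_link_displacement=5.0, min_track_length=1)
        frames = [
            [_immobile(f, (10.0, 10.0)), _immobile(f, (30.0, 10.0))]
            for f in range(8)
        ]
        df = link_tracks(frames, params)
        assert df["track_id"].nunique() == 2
        for _, grp in df.groupby("track_id"):
            assert grp["row"].nunique() == 1

    def test_stepping_spot_single_track(self):
        # oracle: one particle moving 1 px/frame under a 5 px gate has the
        # unique optimal assignment of all detections to one track
        params = TrackingParams(max_link_displacement=5.0, min_track_length=1)
        frames = [[_immobile(f, (10.0, 10.0 + f))] for f in range(12)]
        df = link_tracks(frames, params)
        assert df["track_id"].nunique() == 1
        np.testing.assert_allclose(df.sort_values("frame")["col"], 10.0 + np.arange(12))

    def test_gate_exceeded_starts_new_track(self):
        params = TrackingParams(max_link_displacement=5.0, min_track_length=1)
        frames = [[_immobile(0, (10.0, 10.0))], [_immobile(1, (10.0, 30.0))]]
        df = link_tracks(frames, params)
        assert df["track_id"].nunique() == 2

    def test_short_tracks_dropped(self):
        params = TrackingParams(min_track_length=5)
        frames = [[_immobile(f, (10.0, 10.0))] for f in range(4)]
        assert link_tracks(frames, params).empty


class TestTrackStackOnSimulations:
    def test_noiseless_recovery(self):
        cfg = SlimfieldSimConfig(
            unit_size=5, multiple_weights={1: 1.0}, maturation_prob=1.0,
            brightness=56.0, bleach_prob=0.0, n_complexes=9,
            diffusion_coeff=0.0, frame_count=5, image_shape=(100, 100),
            roi=(8, 8, 92, 92), background_rate=0.0, read_noise_sd=0.0,
            shot_noise=False, placement="grid", seed=2,
        )
        stack, mask, truth = simulate_image_stack(cfg)
        tracks = track_stack(stack, mask, TrackingParams(min_track_length=5))
        assert tracks["track_id"].nunique() == 9
        # summed intensities equal brightness x live within PSF truncation
        np.testing.assert_allclose(
            tracks["summed_intensity"], 280.0, rtol=0.08
        )

    def test_track_count_matches_complexes_with_noise(self):
        cfg = SlimfieldSimConfig(
            unit_size=5, multiple_weights={2: 1.0}, maturation_prob=1.0,
            brightness=56.0, bleach_prob=0.0, n_complexes=9,
            diffusion_coeff=0.01, frame_count=20, image_shape=(100, 100),
            roi=(8, 8, 92, 92), background_rate=5.0, read_noise_sd=2.0,
            placement="grid", seed=3,
        )
        stack, mask, truth = simulate_image_stack(cfg)
        tracks = track_stack(stack, mask, TrackingParams(min_track_length=15))
        assert tracks["track_id"].nunique() == 9
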