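"""Detection front-end against brute-force image-processing oracles."""

import numpy as np
import pytest
from scipy import ndimage

from chromotion import (ImageStack, auto_threshold_isodata,
                        bleach_correct_histogram_match, count_local_maxima,
                        detect_dog_spots, difference_of_gaussians,
                        extract_mask_spots, track_nucleus)
from chromotion.detection import dog_sigmas_from_radius


def gaussian_blob(shape, cy, cx, sigma, amplitude=100.0):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))


class TestBleachCorrection:
    def test_single_frame_identity(self, rng):
        stack = ImageStack(rng.poisson(50, (1, 16, 16)).astype(float), 0.1, 1.0)
        out = bleach_correct_histogram_match(stack)
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_scaled_frame_recovers_reference_multiset(self, rng):
        """A frame that is frame 0 scaled by 0.5 maps back onto frame 0's
        sorted pixel multiset (quantile-mapping oracle)."""
        f0 = rng.poisson(100, (32, 32)).astype(float)
        stack = ImageStack(np.stack([f0, 0.5 * f0]), 0.1, 1.0)
        out = bleach_correct_histogram_match(stack)
        np.testing.assert_allclose(np.sort(out.frames[1].ravel()),
                                   np.sort(f0.ravel()), atol=1e-8)

    def test_mean_intensity_stabilized(self, rng):
        f0 = rng.poisson(100, (32, 32)).astype(float)
        frames = np.stack([f0 * 0.9 ** m + rng.normal(0, 1, f0.shape).clip(-5, 5)
                           for m in range(5)]).clip(0)
        frames[0] = f0
        out = bleach_correct_histogram_match(ImageStack(frames, 0.1, 1.0))
        means = out.frames.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], rtol=0.02)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.empty((0, 4, 4)), 0.1, 1.0)


class TestDifferenceOfGaussians:
    def test_uniform_image_zero_response(self):
        assert difference_of_gaussians(np.full((16, 16), 7.0), 2, 4).max() == 0

    def test_offset_invariance(self, rng):
        img = rng.random((24, 24))
        r1 = difference_of_gaussians(img, 2, 4)
        r2 = difference_of_gaussians(img + 55.0, 2, 4)
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_blob_peak_at_center(self):
        img = gaussian_blob((33, 33), 16, 16, sigma=2.5)
        resp = difference_of_gaussians(img, 2, 4)
        assert np.unravel_index(resp.argmax(), resp.shape) == (16, 16)

    def test_matches_direct_convolution(self, rng):
        """Equals an explicit two-pass Gaussian convolution."""
        img = rng.random((32, 32))
        resp = difference_of_gaussians(img, 1.5, 3.0)
        lo = ndimage.gaussian_filter(img, 1.5, mode="reflect")
        hi = ndimage.gaussian_filter(img, 3.0, mode="reflect")
        ref = np.clip(lo - hi, 0, None)
        np.testing.assert_allclose(resp, ref, rtol=1e-6)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            difference_of_gaussians(np.zeros((8, 8)), 4, 2)


class TestIsodataThreshold:
    def test_two_valued_image(self):
        img = np.array([[10.0, 10.0, 20.0], [10.0, 20.0, 10.0]])
        mask = auto_threshold_isodata(img)
        np.testing.assert_array_equal(mask, img == 20.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold_isodata(np.full((8, 8), 3.0))

    def test_bimodal_matches_exhaustive_fixed_point(self, rng):
        """Threshold agrees with exhaustive intermeans search over integer
        candidate thresholds on a bimodal mixture."""
        vals = np.concatenate([rng.normal(40, 4, 600),
                               rng.normal(120, 8, 400)]).clip(0).round()
        img = vals.reshape(40, 25)
        mask = auto_threshold_isodata(img)
        # brute force: integer t is an intermeans fixed point when
        # t ~= (mean below + mean above) / 2 rounds back into [t, t+1)
        candidates = []
        for t in np.arange(img.min(), img.max()):
            below, above = img[img <= t], img[img > t]
            if below.size and above.size:
                f = 0.5 * (below.mean() + above.mean())
                if t <= f < t + 1:
                    candidates.append((t, f))
        assert candidates, "oracle found no fixed point"
        t_ref = candidates[0][1]
        np.testing.assert_array_equal(mask, img > t_ref)


class TestExtractMaskSpots:
    def test_empty_mask(self):
        assert extract_mask_spots(np.zeros((8, 8), bool), 1) == []

    def test_two_squares_centroids_and_quality(self):
        mask = np.zeros((12, 12), bool)
        mask[1:4, 1:4] = True
        mask[7:10, 8:11] = True
        spots = extract_mask_spots(mask, 1, pixel_size=0.5)
        assert len(spots) == 2
        assert (spots[0].x, spots[0].y) == (1.0, 1.0)   # (2, 2) px * 0.5
        assert (spots[1].x, spots[1].y) == (4.5, 4.0)   # (9, 8) px * 0.5
        assert all(s.quality == 9 for s in spots)

    def test_area_cut_at_3_9(self):
        """A 3.9 quality cut keeps areas 4 and 10, drops area 2."""
        mask = np.zeros((12, 30), bool)
        mask[1, 1:3] = True          # area 2
        mask[5, 5:9] = True          # area 4
        mask[9:11, 20:25] = True     # area 10
        spots = extract_mask_spots(mask, 3.9)
        assert sorted(s.area for s in spots) == [4, 10]

    def test_diagonal_counts_as_connected(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = True  # 8-connected single component
        spots = extract_mask_spots(mask, 1)
        assert len(spots) == 1
        assert spots[0].area == 2


class TestDetectDogSpots:
    def test_blank_frame(self):
        assert detect_dog_spots(np.zeros((32, 32)), 3.0, 0.5) == []

    def test_single_spot_subpixel(self):
        """Rendered Gaussian spot (sigma ~ radius/2) localized to 0.2 px."""
        radius = 3.0
        for true in [(15.3, 16.7), (14.0, 14.5), (17.25, 13.1)]:
            img = gaussian_blob((32, 32), true[1], true[0], sigma=radius / 2)
            spots = detect_dog_spots(img, radius, quality_threshold=1.0)
            assert len(spots) == 1
            assert abs(spots[0].x - true[0]) < 0.2
            assert abs(spots[0].y - true[1]) < 0.2

    def test_two_separated_spots(self):
        img = (gaussian_blob((40, 40), 10, 10, 1.5)
               + gaussian_blob((40, 40), 10, 20, 1.5))
        spots = detect_dog_spots(img, 3.0, 1.0)
        assert len(spots) == 2

    def test_translation_equivariance(self, rng):
        """Whole-pixel image shifts shift all detections identically."""
        img = np.zeros((48, 48))
        img += gaussian_blob((48, 48), 20, 22, 1.5)
        img += gaussian_blob((48, 48), 31, 12, 1.5)
        s0 = detect_dog_spots(img, 3.0, 1.0)
        shifted = np.roll(np.roll(img, 3, axis=0), 5, axis=1)
        s1 = detect_dog_spots(shifted, 3.0, 1.0)
        assert len(s0) == len(s1) == 2
        for a, b in zip(s0, s1):
            assert b.x - a.x == pytest.approx(5, abs=1e-6)
            assert b.y - a.y == pytest.approx(3, abs=1e-6)

    def test_pixel_size_scaling(self):
        img = gaussian_blob((32, 32), 16, 16, 1.5)
        spots = detect_dog_spots(img, 0.3, 1.0, pixel_size=0.1)
        assert len(spots) == 1
        assert spots[0].x == pytest.approx(1.6, abs=0.02)

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            detect_dog_spots(np.zeros((16, 16)), 0.05, 1.0, pixel_size=0.1)


def prominence_oracle(img, prominence):
    """Flood-based prominence count: for each regional maximum (plateau
    aware), find the highest threshold at which its superlevel component
    touches a higher pixel; prominence = height - that saddle level."""
    from skimage.morphology import local_maxima

    img = np.asarray(img, float)
    w = img.shape[1]
    labels, n = ndimage.label(local_maxima(img, connectivity=2),
                              structure=np.ones((3, 3)))
    if n == 0:
        return 0
    peaks = []  # (value, representative flat index, y, x)
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        peaks.append((img[ys[0], xs[0]], ys[0] * w + xs[0], ys[0], xs[0]))
    levels = np.unique(img)[::-1]
    count = 0
    for v, rep, y, x in peaks:
        # terrain dominating this peak: strictly higher pixels, or equal
        # regional maxima earlier in row-major order (tie-break)
        dominating = img > v
        for v2, rep2, y2, x2 in peaks:
            if v2 == v and rep2 < rep:
                dominating |= labels == labels[y2, x2]
        if not dominating.any():
            prom = v - img.min()  # global (or tied-first) maximum
        else:
            saddle = None
            for t in levels:
                if t > v:
                    continue
                comp_lab, _ = ndimage.label(img >= t,
                                            structure=np.ones((3, 3)))
                comp = comp_lab == comp_lab[y, x]
                if dominating[comp].any():
                    saddle = t
                    break
            prom = v - (saddle if saddle is not None else img.min())
        if prom > prominence:
            count += 1
    return count


class TestCountLocalMaxima:
    def test_constant_frame(self):
        assert count_local_maxima(np.full((8, 8), 5.0), 1.0) == 0

    def test_two_separated_blobs(self):
        img = (gaussian_blob((40, 40), 10, 10, 2, 100)
               + gaussian_blob((40, 40), 28, 30, 2, 100))
        assert count_local_maxima(img, 50) == 2

    def test_shoulder_below_prominence(self):
        img = (gaussian_blob((40, 40), 20, 15, 3, 100)
               + gaussian_blob((40, 40), 20, 22, 3, 20))
        assert count_local_maxima(img, 50) == 1

    def test_matches_flood_oracle_on_random_fields(self, rng):
        for _ in range(5):
            img = ndimage.gaussian_filter(rng.random((20, 20)), 1.2)
            img = np.round(img * 50)  # discrete levels keep the oracle exact
            for prom in (2.0, 5.0, 10.0):
                assert count_local_maxima(img, prom) == \
                    prominence_oracle(img, prom), prom


class TestTrackNucleus:
    def disk_frame(self, shape, cy, cx, r, value=100.0):
        ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
        return value * (((xs - cx) ** 2 + (ys - cy) ** 2) <= r ** 2)

    def test_static_disk_center(self):
        frames = np.stack([self.disk_frame((40, 40), 20, 18, 8)] * 4)
        traj = track_nucleus(ImageStack(frames, 0.1, 1.0), 50.0)
        np.testing.assert_allclose(traj.xy, [[1.8, 2.0]] * 4, atol=1e-9)

    def test_translating_disk(self):
        frames = np.stack([self.disk_frame((40, 40), 15, 10 + m, 6)
                           for m in range(5)])
        traj = track_nucleus(ImageStack(frames, 0.2, 1.0), 50.0)
        steps = np.diff(traj.xy, axis=0)
        np.testing.assert_allclose(steps, [[0.2, 0.0]] * 4, atol=1e-9)

    def test_largest_component_wins(self):
        frame = self.disk_frame((40, 40), 20, 20, 8) + \
            self.disk_frame((40, 40), 5, 5, 2)
        traj = track_nucleus(ImageStack(frame[None], 1.0, 1.0), 50.0)
        np.testing.assert_allclose(traj.xy[0], [20, 20], atol=0.5)

    def test_noisy_disk_centroid_within_half_pixel(self, rng):
        truth = (20.0, 17.0)
        clean = self.disk_frame((40, 40), truth[1], truth[0], 9, 100.0) + 10
        frames = rng.poisson(np.stack([clean] * 6)).astype(float)
        traj = track_nucleus(ImageStack(frames, 1.0, 1.0), 50.0)
        for m in range(6):
            assert abs(traj.xy[m, 0] - truth[0]) < 0.5
            assert abs(traj.xy[m, 1] - truth[1]) < 0.5

    def test_empty_frame_names_frame(self):
        frames = np.stack([self.disk_frame((20, 20), 10, 10, 4),
                           np.zeros((20, 20))])
        with pytest.raises(ValueError, match="frame 1"):
            track_nucleus(ImageStack(frames, 1.0, 1.0), 50.0)
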