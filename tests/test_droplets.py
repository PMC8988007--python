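"""Droplet segmentation and morphometrics against brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from phasequant import droplets as dq
from phasequant.types import DropletRecord


def brute_force_phansalkar(image, radius, k=0.25, r=0.5, p=2.0, q=10.0,
                           circular=True):
    """Literal per-pixel evaluation of the local threshold formula."""
    h, w = image.shape
    out = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    foot = (yy**2 + xx**2 <= radius**2) if circular else np.ones_like(yy, bool)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if not foot[di + radius, dj + radius]:
                        continue
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w:
                        vals.append(image[y, x])
            vals = np.array(vals)
            mu, sd = vals.mean(), vals.std()
            t = mu * (1 + p * np.exp(-q * mu) + k * (sd / r - 1))
            out[i, j] = image[i, j] > t
    return out


class TestPhansalkar:
    def test_constant_zero_image_empty_mask(self):
        assert not dq.phansalkar_threshold(np.zeros((16, 16)), radius=3).any()

    @pytest.mark.parametrize("circular", [True, False])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_images(self, seed, circular):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (20, 20))
        radius = int(rng.integers(2, 6))
        fast = dq.phansalkar_threshold(img, radius=radius, circular=circular)
        slow = brute_force_phansalkar(img, radius, circular=circular)
        assert np.array_equal(fast, slow)

    def test_global_window_equals_single_threshold(self):
        """A window covering the whole image reduces to one global T."""
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (7, 7))
        # radius 6 makes even corner-clipped windows span the whole 7×7 image
        mask = dq.phansalkar_threshold(img, radius=6, circular=False)
        mu, sd = img.mean(), img.std()
        t = mu * (1 + 2 * np.exp(-10 * mu) + 0.25 * (sd / 0.5 - 1))
        assert np.array_equal(mask, img > t)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            dq.phansalkar_threshold(np.zeros((4, 4, 4)), radius=2)
        with pytest.raises(ValueError):
            dq.phansalkar_threshold(np.zeros((8, 8)), radius=100)

    def test_segments_synthetic_field_jaccard(self, noisy_droplet_field):
        stack, gt = noisy_droplet_field
        mask = dq.phansalkar_threshold(dq.normalize_image(stack.data))
        yy, xx = np.mgrid[0:256, 0:256]
        for _, t in gt.truth_table.iterrows():
            disc = (
                np.hypot(yy - t.y_um / 0.106, xx - t.x_um / 0.106) <= t.radius_px
            )
            inter = (mask & disc).sum()
            union = ((mask & ~_other_discs(gt, t, yy, xx)) | disc).sum()
            assert inter / disc.sum() >= 0.8  # recall per droplet


def _other_discs(gt, this, yy, xx):
    out = np.zeros(yy.shape, dtype=bool)
    for _, t in gt.truth_table.iterrows():
        if t.label == this.label:
            continue
        out |= np.hypot(yy - t.y_um / 0.106, xx - t.x_um / 0.106) <= t.radius_px + 2
    return out


class TestLabeling:
    def test_min_area_filters_small_components(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask |= np.hypot(yy - 20, xx - 20) <= 4  # ~50 px
        mask[50:51, 50:55] = True  # 5 px
        _, recs = dq.label_condensates(mask, min_area=10)
        assert len(recs) == 1

    def test_perfect_disc_has_unit_aspect_ratio(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        R = 10
        mask |= np.hypot(yy - 32, xx - 32) <= R
        _, recs = dq.label_condensates(mask, min_area=10)
        a, b = recs[0].semi_axes
        assert a == pytest.approx(R, rel=0.05)
        assert b == pytest.approx(R, rel=0.05)
        assert recs[0].aspect_ratio <= 1.05

    def test_full_mask_single_record(self):
        _, recs = dq.label_condensates(np.ones((32, 32), bool), min_area=10)
        assert len(recs) == 1
        assert recs[0].area_px == 32 * 32

    def test_empty_mask_empty_list(self):
        labels, recs = dq.label_condensates(np.zeros((16, 16), bool))
        assert recs == [] and labels.max() == 0

    def test_count_recovery_on_clean_fields(self):
        """Droplet count equals truth (area >= min) on noise-free fields."""
        from phasequant import synthetic as syn

        for seed in range(8):
            stack, gt = syn.make_droplet_field(
                n_droplets=6, radius_range=(0.5, 1.3), snr=np.inf,
                field_size=256, seed=seed,
            )
            _, recs, _ = dq.segment_field(stack)
            expected = int((gt.truth_table.area_px >= 10).sum())
            assert len(recs) == expected

    def test_centroid_recovery_within_half_pixel(self, clean_droplet_field):
        stack, gt = clean_droplet_field
        _, recs, _ = dq.segment_field(stack)
        assert len(recs) == 3
        truth = gt.truth_table.sort_values(["y_um", "x_um"]).reset_index()
        found = sorted(recs, key=lambda r: (r.centroid[0], r.centroid[1]))
        for rec, (_, t) in zip(found, truth.iterrows()):
            err_px = np.hypot(
                rec.centroid[0] - t.y_um, rec.centroid[1] - t.x_um
            ) / stack.pixel_size
            assert err_px < 0.5


class TestVolume:
    def test_sphere_formula(self):
        rec = DropletRecord(1, (0, 0), 1.0, (1.0, 1.0), 0, 0, 0)
        assert dq.estimate_volume(rec) == pytest.approx(4 / 3 * np.pi)

    def test_geometric_mean_z_axis(self):
        rec = DropletRecord(1, (0, 0), 1.0, (2.0, 0.5), 0, 0, 0)
        assert dq.estimate_volume(rec) == pytest.approx(4 / 3 * np.pi, rel=1e-12)

    def test_swapping_axes_invariant(self):
        r1 = DropletRecord(1, (0, 0), 1.0, (1.7, 0.9), 0, 0, 0)
        # semi-axes are ordered a >= b by contract, so compare the formula
        a, b = 1.7, 0.9
        v = 4 / 3 * np.pi * a * b * np.sqrt(a * b)
        assert dq.estimate_volume(r1) == pytest.approx(v)


class TestFieldSummary:
    def test_empty_records_zero_volume(self):
        s = dq.summarize_field([], field_area=100.0)
        assert s.total_volume_per_area == 0 and s.n_droplets == 0

    def test_single_sphere_per_area(self):
        rec = DropletRecord(1, (0, 0), np.pi, (1.0, 1.0), 0, 0, 0)
        rec.volume = dq.estimate_volume(rec)
        s = dq.summarize_field([rec], field_area=100.0)
        assert s.total_volume_per_area == pytest.approx(4 / 3 * np.pi / 100)

    def test_concatenation_is_area_weighted_mean(self):
        rng = np.random.default_rng(0)
        def mkrec(i, a, b):
            r = DropletRecord(i, (0, 0), 1.0, (max(a, b), min(a, b)), 0, 0, 0)
            r.volume = dq.estimate_volume(r)
            return r
        recs1 = [mkrec(i, *rng.uniform(0.5, 2, 2)) for i in range(4)]
        recs2 = [mkrec(i, *rng.uniform(0.5, 2, 2)) for i in range(7)]
        s1 = dq.summarize_field(recs1, 50.0)
        s2 = dq.summarize_field(recs2, 150.0)
        s12 = dq.summarize_field(recs1 + recs2, 200.0)
        weighted = (s1.total_volume_per_area * 50 + s2.total_volume_per_area * 150) / 200
        assert s12.total_volume_per_area == pytest.approx(weighted)

    def test_dilation_increases_total_volume(self):
        """Growing every droplet strictly increases settled volume per area."""
        from phasequant import synthetic as syn

        stack, _ = syn.make_droplet_field(5, (0.5, 1.0), snr=np.inf, seed=3)
        mask = dq.phansalkar_threshold(dq.normalize_image(stack.data))
        _, recs = dq.label_condensates(mask, stack.data, stack.pixel_size)
        grown = ndimage.binary_dilation(mask, iterations=2)
        _, recs_grown = dq.label_condensates(grown, stack.data, stack.pixel_size)
        v0 = dq.summarize_field(recs, 100.0).total_volume_per_area
        v1 = dq.summarize_field(recs_grown, 100.0).total_volume_per_area
        assert v1 > v0


class TestPartitionCoefficient:
    def _masks(self):
        droplet = np.zeros((32, 32), bool)
        droplet[10:20, 10:20] = True
        background = np.zeros((32, 32), bool)
        background[:5] = True
        return droplet, background

    def test_uniform_image_pc_one(self):
        d, b = self._masks()
        img = np.full((32, 32), 7.0)
        assert dq.partition_coefficient(img, d, b) == pytest.approx(1.0)

    def test_ninefold_enrichment(self):
        d, b = self._masks()
        img = np.ones((32, 32))
        img[d] = 9.0
        assert dq.partition_coefficient(img, d, b) == pytest.approx(9.0)

    def test_scale_invariance(self):
        d, b = self._masks()
        rng = np.random.default_rng(2)
        img = rng.uniform(1, 5, (32, 32))
        pc = dq.partition_coefficient(img, d, b)
        assert dq.partition_coefficient(img * 37.5, d, b) == pytest.approx(pc)

    def test_empty_background_rejected(self):
        d, _ = self._masks()
        with pytest.raises(ValueError):
            dq.partition_coefficient(np.ones((32, 32)), d, np.zeros((32, 32), bool))

    def test_overlapping_masks_rejected(self):
        d, _ = self._masks()
        with pytest.raises(ValueError):
            dq.partition_coefficient(np.ones((32, 32)), d, d)


class TestPartitionTimecourse:
    def test_static_movie_constant_series(self):
        from phasequant.types import ImageStack

        frame = np.ones((32, 32))
        frame[10:20, 10:20] = 5.0
        movie = ImageStack(np.stack([frame] * 4), "tyx", 0.1, frame_interval=2.0)
        d = np.zeros((32, 32), bool)
        d[10:20, 10:20] = True
        b = np.zeros((32, 32), bool)
        b[:5] = True
        series = dq.partition_timecourse(movie, d, b)
        assert series.shape == (4, 2)
        assert np.allclose(series[:, 1], 5.0)
        assert np.allclose(series[:, 0], [0, 2, 4, 6])

    def test_influx_recovers_time_constant(self):
        """PC(t) = 1 + 4(1 − e^{−t/τ}) recovered from a noiseless series."""
        from scipy.optimize import curve_fit

        from phasequant.types import ImageStack

        tau = 30.0
        t = np.arange(40, dtype=float) * 5.0
        d = np.zeros((32, 32), bool)
        d[10:20, 10:20] = True
        b = ~d
        frames = []
        for ti in t:
            pc = 1 + 4 * (1 - np.exp(-ti / tau))
            f = np.ones((32, 32))
            f[d] = pc
            frames.append(f)
        movie = ImageStack(np.array(frames), "tyx", 0.1, frame_interval=5.0)
        series = dq.partition_timecourse(movie, d, b)
        popt, _ = curve_fit(
            lambda tt, tau_: 1 + 4 * (1 - np.exp(-tt / tau_)), series[:, 0],
            series[:, 1], p0=[10.0],
        )
        assert popt[0] == pytest.approx(tau, rel=0.15)

    def test_single_frame_series_length_one(self):
        from phasequant.types import ImageStack

        frame = np.ones((16, 16))
        frame[4:8, 4:8] = 3.0
        movie = ImageStack(frame[None], "tyx", 0.1)
        d = np.zeros((16, 16), bool)
        d[4:8, 4:8] = True
        series = dq.partition_timecourse(movie, d, ~d)
        assert series.shape == (1, 2)
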