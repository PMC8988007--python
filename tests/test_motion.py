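"""Tracking chain, MSD estimation, and first-passage extrapolation."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from phasequant import motion as mo
from phasequant import synthetic as syn
from phasequant.types import ImageStack, MSDCurve, PowerLawFit, Trajectory


def _spot_image(points, shape=(64, 64), amp=1000.0, background=10.0):
    img = np.zeros(shape)
    for y, x in points:
        img[int(round(y)), int(round(x))] = amp
    return ndimage.gaussian_filter(img, 1.3) + background


def _gaussian_spots(points, shape=(64, 64), sigma=1.3, background=10.0):
    """Analytic subpixel Gaussian rendering (no interpolation artifacts)."""
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    img = np.full(shape, background, dtype=float)
    for y, x in points:
        img += 1000 * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img


class TestRegistration:
    def test_recovers_injected_shifts(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(10, 54, (12, 2))
        shifts = [(0.0, 0.0), (1.5, -2.0), (-3.2, 0.7)]
        frames = [_gaussian_spots(pts + np.array(s)) for s in shifts]
        movie = ImageStack(np.array(frames), "tyx", 0.1, 1.0)
        _, est = mo.register_translation(movie)
        for (sy, sx), (ey, ex) in zip(shifts, est):
            assert abs(-sy - ey) < 0.1 and abs(-sx - ex) < 0.1

    def test_identical_frames_zero_shift(self):
        base = _spot_image([(20, 20), (40, 45)])
        movie = ImageStack(np.stack([base] * 4), "tyx", 0.1, 1.0)
        _, est = mo.register_translation(movie)
        assert np.allclose(est, 0.0, atol=1e-3)

    def test_single_frame_identity(self):
        base = _spot_image([(20, 20)])
        movie = ImageStack(base[None], "tyx", 0.1, 1.0)
        out, est = mo.register_translation(movie)
        assert np.array_equal(out.data[0], base)
        assert est.shape == (1, 2)

    def test_flat_frames_zero_shift(self):
        movie = ImageStack(np.ones((3, 32, 32)), "tyx", 0.1, 1.0)
        _, est = mo.register_translation(movie)
        assert np.allclose(est, 0.0)


class TestDetection:
    def test_blank_frame_no_detections(self):
        det = mo.detect_puncta(np.full((64, 64), 5.0), pixel_size=0.106)
        assert len(det) == 0

    def test_dense_field_precision_recall(self):
        rng = np.random.default_rng(1)
        pts = []
        while len(pts) < 40:
            p = rng.uniform(5, 123, 2)
            if all(np.hypot(*(p - q)) > 10 for q in pts):
                pts.append(p)
        img = _spot_image(pts, shape=(128, 128))
        img = img + rng.normal(0, (img.max() - 10) / 8, img.shape)  # snr ≈ 8
        det = mo.detect_puncta(img, pixel_size=0.106, diameter=0.5)
        from scipy.spatial.distance import cdist

        d = cdist(det[:, :2] / 0.106, np.array(pts))
        precision = (d.min(axis=1) < 1).mean()
        recall = (d.min(axis=0) < 1).mean()
        assert precision >= 0.95 and recall >= 0.95

    def test_two_close_puncta_subpixel_centroids(self):
        img = _spot_image([(30.0, 25.0), (30.0, 35.0)])
        det = mo.detect_puncta(img, pixel_size=0.106, diameter=0.5)
        assert len(det) == 2
        got = sorted(det[:, 1] / 0.106)
        assert abs(got[0] - 25.0) < 0.5 and abs(got[1] - 35.0) < 0.5

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValueError):
            mo.detect_puncta(np.zeros((32, 32)), pixel_size=0.106, diameter=0.05)


def brute_force_matching(prev, curr, max_link):
    """Exhaustive minimal-cost assignment oracle for small frames."""
    best, best_cost = [], np.inf
    n, m = len(prev), len(curr)
    k = min(n, m)
    for size in range(k, -1, -1):
        for rows in itertools.combinations(range(n), size):
            for cols in itertools.permutations(range(m), size):
                pairs = list(zip(rows, cols))
                if any(
                    np.sum((prev[r] - curr[c]) ** 2) > max_link**2
                    for r, c in pairs
                ):
                    continue
                cost = sum(np.sum((prev[r] - curr[c]) ** 2) for r, c in pairs)
                # maximal matchings first; among them minimal cost
                score = (-len(pairs), cost)
                if score < (-len(best), best_cost):
                    best, best_cost = pairs, cost
    return sorted(best)


class TestLinking:
    def test_matches_exhaustive_oracle_small_frames(self):
        """Assignment equals exhaustive minimal-cost matching for ≤6 points."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n, m = rng.integers(1, 6, 2)
            prev = rng.uniform(0, 5, (n, 2))
            curr = rng.uniform(0, 5, (m, 2))
            got = sorted(mo._match_frames(prev, curr, max_link=2.0))
            oracle = brute_force_matching(prev, curr, 2.0)
            if len(got) == len(oracle):
                cost_got = sum(np.sum((prev[r] - curr[c]) ** 2) for r, c in got)
                cost_orc = sum(np.sum((prev[r] - curr[c]) ** 2) for r, c in oracle)
                assert cost_got == pytest.approx(cost_orc)
            else:  # linear_sum_assignment maximizes pairs at min cost too
                assert len(got) >= len(oracle)

    def test_stationary_spot_single_full_track(self):
        dets = [np.array([[1.0, 1.0, 5.0]])] * 100
        trajs = mo.link_trajectories(dets, 1.0)
        assert len(trajs) == 1
        assert trajs[0].span_fraction == 1.0

    def test_terminates_rather_than_jumping(self):
        """Spots that would need links beyond max_link end their tracks."""
        dets = [
            np.array([[0.0, 0.0], [0.0, 3.0]]),
            np.array([[0.0, 1.5], [0.0, 4.5]]),  # both moved 1.5 > max_link 1
        ]
        trajs = mo.link_trajectories(dets, 1.0, max_link=1.0,
                                     min_span_fraction=0.0)
        assert all(len(t) == 1 for t in trajs)
        assert len(trajs) == 4

    def test_short_track_discarded_at_default_span(self):
        dets = [np.array([[1.0, 1.0]])] * 40 + [np.empty((0, 2))] * 60
        trajs = mo.link_trajectories(dets, 1.0)
        assert trajs == []


class TestMSD:
    def test_stationary_zero(self):
        t = Trajectory(times=np.arange(50.0), positions=np.ones((50, 2)))
        curve = mo.compute_msd([t])
        assert np.allclose(curve.msd, 0.0)

    def test_ballistic_drift_quadratic(self):
        times = np.arange(100.0)
        v = 0.03
        pos = np.column_stack([np.zeros(100), v * times])
        curve = mo.compute_msd([Trajectory(times=times, positions=pos)])
        assert np.allclose(curve.msd, v**2 * curve.lags**2)
        fit = mo.msd_powerlaw_fit(curve, loc_error="none")
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)

    def test_brownian_msd_linear_in_lag(self):
        trajs, _ = syn.make_fbm_trajectories(
            1.0, 4e-3, n_traj=200, n_frames=300, seed=5
        )
        curve = mo.compute_msd(trajs)
        ratio = curve.msd / curve.lags
        sel = curve.lags <= 30
        assert np.all(np.abs(ratio[sel] / ratio[sel].mean() - 1) < 0.1)

    def test_pair_counts_non_increasing(self):
        trajs, _ = syn.make_fbm_trajectories(0.7, 1e-3, n_traj=5, n_frames=80, seed=2)
        curve = mo.compute_msd(trajs)
        assert np.all(np.diff(curve.n_pairs) <= 0)


class TestPowerLawFit:
    def test_exact_curve_machine_precision(self):
        lags = np.arange(1.0, 40.0)
        curve = MSDCurve(lags=lags, msd=2.8e-3 * lags**0.54,
                         n_pairs=np.full(len(lags), 100))
        fit = mo.msd_powerlaw_fit(curve, loc_error="none")
        assert fit.alpha == pytest.approx(0.54, abs=1e-12)
        assert fit.D == pytest.approx(2.8e-3, rel=1e-12)

    def test_linear_curve_alpha_one(self):
        lags = np.arange(1.0, 20.0)
        curve = MSDCurve(lags=lags, msd=0.01 * lags,
                         n_pairs=np.full(len(lags), 50))
        fit = mo.msd_powerlaw_fit(curve, loc_error="none")
        assert fit.alpha == pytest.approx(1.0, abs=1e-10)
        assert fit.D == pytest.approx(0.01, rel=1e-10)

    def test_offset_fit_removes_localization_bias(self):
        lags = np.arange(2.0, 31.0)
        curve = MSDCurve(lags=lags, msd=2.8e-3 * lags**0.54 + 4 * 0.02**2,
                         n_pairs=np.full(len(lags), 100))
        naive = mo.msd_powerlaw_fit(curve, loc_error="none")
        aware = mo.msd_powerlaw_fit(curve, loc_error="fit")
        assert abs(naive.alpha - 0.54) > 0.05  # floor bias is real
        assert aware.alpha == pytest.approx(0.54, abs=1e-6)

    def test_known_noise_subtraction(self):
        lags = np.arange(2.0, 31.0)
        curve = MSDCurve(lags=lags, msd=2.8e-3 * lags**0.54 + 4 * 0.02**2,
                         n_pairs=np.full(len(lags), 100))
        fit = mo.msd_powerlaw_fit(curve, loc_error=0.02)
        assert fit.alpha == pytest.approx(0.54, abs=1e-9)

    def test_subdiffusive_recovery_with_noise(self):
        """Generative α=0.54, D=2.8e-3 recovered across seeds (20 nm noise)."""
        alphas, Ds = [], []
        for seed in range(5):
            trajs, _ = syn.make_fbm_trajectories(
                0.54, 2.8e-3, n_traj=200, n_frames=300, loc_noise=0.02,
                seed=seed,
            )
            fit = mo.msd_powerlaw_fit(mo.compute_msd(trajs), (2.0, 30.0))
            alphas.append(fit.alpha)
            Ds.append(fit.D)
        assert np.mean(alphas) == pytest.approx(0.54, abs=0.05)
        assert np.mean(Ds) == pytest.approx(2.8e-3, rel=0.2)

    def test_too_few_lags_rejected(self):
        curve = MSDCurve(lags=np.array([1.0, 2.0, 3.0]),
                         msd=np.array([1.0, 2.0, 3.0]),
                         n_pairs=np.array([5, 4, 3]))
        with pytest.raises(ValueError):
            mo.msd_powerlaw_fit(curve)


class TestEncounterTime:
    FIT = PowerLawFit(D=2.8e-3, alpha=0.54, D_se=0.0, alpha_se=0.0,
                      fit_lag_range=(2.0, 30.0))

    def test_mean_pairwise_distance_about_200_days(self):
        days = mo.encounter_time(self.FIT, 6.8) / mo.SECONDS_PER_DAY
        assert days == pytest.approx(200, rel=0.15)

    def test_nearest_neighbor_about_five_days(self):
        days = mo.encounter_time(self.FIT, 2.4) / mo.SECONDS_PER_DAY
        # direct evaluation of (d²/2D)^{1/α} gives ≈ 4.4 days
        assert days == pytest.approx((2.4**2 / (2 * 2.8e-3)) ** (1 / 0.54) / 86400)
        assert 3.5 < days < 5.5

    def test_brownian_closed_form(self):
        fit = PowerLawFit(D=1e-2, alpha=1.0, D_se=0, alpha_se=0,
                          fit_lag_range=(1, 10))
        assert mo.encounter_time(fit, 3.0) == pytest.approx(9.0 / 2e-2)
        assert mo.encounter_time(fit, 3.0, "single_locus") == pytest.approx(900.0)

    def test_monotone_in_d_and_separation(self):
        t0 = mo.encounter_time(self.FIT, 2.0)
        assert mo.encounter_time(self.FIT, 3.0) > t0
        faster = PowerLawFit(D=5e-3, alpha=0.54, D_se=0, alpha_se=0,
                             fit_lag_range=(2, 30))
        assert mo.encounter_time(faster, 2.0) < t0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mo.encounter_time(self.FIT, -1.0)
        with pytest.raises(ValueError):
            mo.encounter_time(self.FIT, 1.0, mode="warp")


class TestTelomereGeometry:
    def test_two_puncta_both_stats_equal_distance(self):
        mask = np.ones((20, 20), bool)
        pts = np.array([[2.0, 2.0], [2.0, 7.0]])
        nn, pw = mo.telomere_geometry(mask, pts)
        assert nn == pytest.approx(5.0) and pw == pytest.approx(5.0)

    def test_unit_square_corners(self):
        mask = np.ones((10, 10), bool)
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        nn, pw = mo.telomere_geometry(mask, pts)
        assert nn == pytest.approx(1.0)
        assert pw == pytest.approx((4 + 2 * np.sqrt(2)) / 6)

    def test_puncta_outside_mask_excluded(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        pts = np.array([[2.0, 2.0], [2.0, 6.0], [15.0, 15.0]])
        nn, pw = mo.telomere_geometry(mask, pts)
        assert nn == pytest.approx(4.0) and pw == pytest.approx(4.0)

    def test_single_punctum_rejected(self):
        with pytest.raises(ValueError):
            mo.telomere_geometry(np.ones((5, 5), bool), np.array([[1.0, 1.0]]))


class TestEndToEndTracking:
    def test_track_movie_recovers_brownian_paths(self):
        """Rendered moving spots are detected and linked into full tracks."""
        rng = np.random.default_rng(7)
        n_frames, n_spots = 30, 5
        starts = rng.uniform(10, 54, (n_spots, 2))
        paths = starts[None] + np.cumsum(
            rng.normal(0, 0.6, (n_frames, n_spots, 2)), axis=0
        )
        paths = np.clip(paths, 3, 61)
        frames = [_spot_image(paths[t]) for t in range(n_frames)]
        movie = ImageStack(np.array(frames), "tyx", 0.106, 1.0)
        trajs = mo.track_movie(movie, max_link=0.25, register=False)
        full = [t for t in trajs if t.span_fraction >= 0.9]
        assert len(full) == n_spots
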