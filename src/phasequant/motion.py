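"""Telomere motion analysis: registration, detection, linking, MSD.

Telomeres move subdiffusively: MSD(τ) = D·τ^α with α < 1 because the loci
are embedded in viscoelastic chromatin and tethered to chromosomes. The
pipeline mirrors the standard single-particle-tracking chain — whole-cell
drift correction, Laplacian-of-Gaussian spot detection with subpixel
refinement, frame-to-frame optimal (linear-assignment) linking with a
maximum link distance and no gap closing — followed by time-averaged MSD
estimation, a log-log power-law fit, and first-passage extrapolation of the
time for two loci to meet by (sub)diffusion.

MSD convention: "MSD" is the two-dimensional squared displacement (x and y
summed), so the fitted D carries units μm² s^−α.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize, spatial
from skimage.registration import phase_cross_correlation

from .types import ImageStack, MSDCurve, PowerLawFit, Trajectory

__all__ = [
    "register_translation",
    "detect_puncta",
    "link_trajectories",
    "compute_msd",
    "msd_powerlaw_fit",
    "encounter_time",
    "telomere_geometry",
]

SECONDS_PER_DAY = 86_400.0


# ---------------------------------------------------------------------------
# registration


def register_translation(
    movie: ImageStack, upsample: int = 20
) -> tuple[ImageStack, np.ndarray]:
    """Drift-correct a movie by per-frame translation to the first frame.

    Shifts are estimated by phase correlation with subpixel refinement and
    applied by spline interpolation. Featureless (flat) frames get zero shift.
    Returns the corrected movie and the (n_frames, 2) array of (dy, dx)
    shifts in pixels.
    """
    if movie.axes != "tyx":
        raise ValueError(f"expected a tyx movie, got axes {movie.axes!r}")
    ref = movie.frame(0).astype(float)
    n = movie.n_frames
    shifts = np.zeros((n, 2))
    corrected = np.empty_like(movie.data, dtype=float)
    corrected[0] = ref
    for t in range(1, n):
        frame = movie.frame(t).astype(float)
        if frame.std() == 0 or ref.std() == 0:
            corrected[t] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample)
        shifts[t] = shift
        corrected[t] = ndimage.shift(frame, shift, order=1, mode="nearest")
    return (
        ImageStack(corrected, "tyx", pixel_size=movie.pixel_size,
                   frame_interval=movie.frame_interval),
        shifts,
    )


# ---------------------------------------------------------------------------
# detection


def _quadratic_subpixel(filtered: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Refine an integer maximum by a 1D quadratic fit along each axis."""
    def refine(m1, m0, p1):
        denom = m1 - 2 * m0 + p1
        if denom >= 0:  # not a concave peak
            return 0.0
        offset = 0.5 * (m1 - p1) / denom
        return float(np.clip(offset, -0.5, 0.5))

    dy = refine(filtered[y - 1, x], filtered[y, x], filtered[y + 1, x])
    dx = refine(filtered[y, x - 1], filtered[y, x], filtered[y, x + 1])
    return y + dy, x + dx


def detect_puncta(
    frame: np.ndarray,
    pixel_size: float,
    diameter: float = 0.5,
    threshold_sigmas: float = 2.0,
) -> np.ndarray:
    """Detect diffraction-limited puncta with a Laplacian-of-Gaussian filter.

    The LoG scale is matched to the expected object ``diameter`` (μm) via
    σ = diameter / (2√2) / pixel_size; local maxima of the (sign-inverted)
    filtered image above mean + ``threshold_sigmas``·SD of the filtered
    image are kept and refined to subpixel by quadratic interpolation.

    Returns an array of shape (n, 3): columns (y μm, x μm, score).
    """
    frame = np.asarray(frame, dtype=float)
    sigma = diameter / (2.0 * np.sqrt(2.0)) / pixel_size
    if sigma < 0.7:
        raise ValueError(
            f"diameter {diameter} μm is below 2 px at pixel size {pixel_size}"
        )
    # bright blobs -> positive response; scale-normalize by σ²
    filtered = -(sigma**2) * ndimage.gaussian_laplace(frame, sigma)
    thresh = filtered.mean() + threshold_sigmas * filtered.std()
    maxima = (
        (filtered == ndimage.maximum_filter(filtered, size=3))
        & (filtered > thresh)
    )
    maxima[0, :] = maxima[-1, :] = False
    maxima[:, 0] = maxima[:, -1] = False
    out = []
    for y, x in np.argwhere(maxima):
        sy, sx = _quadratic_subpixel(filtered, y, x)
        out.append((sy * pixel_size, sx * pixel_size, filtered[y, x]))
    if not out:
        return np.empty((0, 3))
    return np.array(out)


# ---------------------------------------------------------------------------
# linking


def _match_frames(
    prev: np.ndarray, curr: np.ndarray, max_link: float
) -> list[tuple[int, int]]:
    """Optimal assignment between two detection sets.

    Minimizes total squared displacement subject to a hard ``max_link``
    distance; unmatched detections are left free. Ties are resolved by the
    assignment solver deterministically (lowest combined index first).
    """
    if len(prev) == 0 or len(curr) == 0:
        return []
    d2 = spatial.distance.cdist(prev, curr, "sqeuclidean")
    big = 1e12
    cost = np.where(d2 <= max_link**2, d2, big)
    rows, cols = optimize.linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols) if cost[r, c] < big]


def link_trajectories(
    detections: list[np.ndarray],
    frame_interval: float,
    max_link: float = 0.5,
    min_span_fraction: float = 0.5,
) -> list[Trajectory]:
    """Link per-frame detections into gapless trajectories.

    Parameters
    ----------
    detections : list of arrays
        One (n_t, 2+) array of (y μm, x μm[, score]) per frame.
    max_link : float
        Maximum frame-to-frame displacement in μm; candidate links beyond it
        are forbidden, so a particle that jumps terminates its track rather
        than mislinking. No gap closing: a missed detection ends the track.
    min_span_fraction : float
        Tracks covering fewer than this fraction of the movie's frames are
        discarded (default one half).
    """
    if max_link <= 0:
        raise ValueError("max_link must be positive")
    n_frames = len(detections)
    open_tracks: dict[int, list[tuple[int, np.ndarray, float]]] = {}
    closed: list[list[tuple[int, np.ndarray, float]]] = []
    next_id = 0
    prev_pts = np.empty((0, 2))
    prev_ids: list[int] = []
    for t, det in enumerate(detections):
        det = np.asarray(det, dtype=float)
        pts = det[:, :2] if det.size else np.empty((0, 2))
        scores = det[:, 2] if det.size and det.shape[1] > 2 else np.zeros(len(pts))
        matches = _match_frames(prev_pts, pts, max_link)
        matched_prev = {m[0] for m in matches}
        matched_curr = {m[1] for m in matches}
        new_ids: list[int] = [-1] * len(pts)
        for r, c in matches:
            tid = prev_ids[r]
            open_tracks[tid].append((t, pts[c], scores[c]))
            new_ids[c] = tid
        # unmatched previous tracks terminate
        for r, tid in enumerate(prev_ids):
            if r not in matched_prev:
                closed.append(open_tracks.pop(tid))
        # unmatched current detections start new tracks
        for c in range(len(pts)):
            if c not in matched_curr:
                open_tracks[next_id] = [(t, pts[c], scores[c])]
                new_ids[c] = next_id
                next_id += 1
        prev_pts = pts
        prev_ids = new_ids
    closed.extend(open_tracks.values())

    trajectories = []
    tid = 0
    for track in closed:
        span = len(track) / n_frames
        if span < min_span_fraction:
            continue
        frames_idx = np.array([f for f, _, _ in track])
        positions = np.array([p for _, p, _ in track])
        quality = float(np.mean([s for _, _, s in track]))
        trajectories.append(
            Trajectory(
                times=frames_idx * frame_interval,
                positions=positions,
                quality=quality,
                span_fraction=span,
                track_id=tid,
            )
        )
        tid += 1
    return trajectories


def track_movie(
    movie: ImageStack,
    diameter: float = 0.5,
    threshold_sigmas: float = 2.0,
    max_link: float = 0.5,
    min_span_fraction: float = 0.5,
    register: bool = True,
) -> list[Trajectory]:
    """Full chain: register → detect per frame → link."""
    if register:
        movie, _ = register_translation(movie)
    detections = [
        detect_puncta(movie.frame(t), movie.pixel_size, diameter, threshold_sigmas)
        for t in range(movie.n_frames)
    ]
    return link_trajectories(
        detections, movie.frame_interval, max_link, min_span_fraction
    )


# ---------------------------------------------------------------------------
# MSD


def compute_msd(
    trajectories: list[Trajectory],
    max_lag_fraction: float = 0.25,
) -> MSDCurve:
    """Ensemble time-averaged MSD, weighted by displacement-pair counts.

    For each trajectory the time-averaged squared displacement is computed at
    every lag up to ``max_lag_fraction`` of its length; the ensemble curve is
    the pair-count-weighted mean across trajectories.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    dt = None
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for traj in trajectories:
        n = len(traj)
        if n < 2:
            continue
        step = np.min(np.diff(traj.times))
        dt = step if dt is None else min(dt, step)
        max_lag = max(1, int(np.floor(n * max_lag_fraction)))
        for lag in range(1, max_lag + 1):
            disp = traj.positions[lag:] - traj.positions[:-lag]
            sq = np.sum(disp**2, axis=1)
            sums[lag] = sums.get(lag, 0.0) + float(sq.sum())
            counts[lag] = counts.get(lag, 0) + len(sq)
    if not sums:
        raise ValueError("all trajectories too short for MSD")
    lags = np.array(sorted(sums))
    msd = np.array([sums[k] / counts[k] for k in lags])
    n_pairs = np.array([counts[k] for k in lags])
    return MSDCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


def msd_powerlaw_fit(
    curve: MSDCurve,
    fit_range: tuple[float, float] | None = None,
    loc_error: str | float = "fit",
) -> PowerLawFit:
    """Fit MSD(τ) = D·τ^α, accounting for static localization error.

    A localization error of SD σ per coordinate inflates the measured 2D MSD
    by a constant 4σ² at every lag, which flattens a naive log-log fit and
    biases α down. ``loc_error`` controls how that floor is handled:

    - ``"fit"`` (default): nonlinear least squares of D·τ^α + c with c ≥ 0
      free, seeded from the log-log fit;
    - ``"none"``: plain ordinary least squares of log(msd) on log(lag)
      (α = slope, D = exp(intercept)) — correct when localization error is
      negligible relative to the smallest fitted MSD;
    - a float σ (μm): subtract the known 4σ² before the log-log fit.

    Standard errors come from the regression (delta method for D in the
    log-log path). Non-positive MSD values in the range are excluded; at
    least 4 usable lags are required.
    """
    lags, msd = curve.lags, curve.msd
    mask = (msd > 0) & (curve.n_pairs > 0)
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (lags >= lo) & (lags <= hi)
        rng = (float(lo), float(hi))
    else:
        rng = (float(lags[0]), float(lags[-1]))
    if mask.sum() < 4:
        raise ValueError("need >= 4 positive MSD lags in the fit range")
    tau = lags[mask]
    y_lin = msd[mask]
    if isinstance(loc_error, (int, float)):
        y_lin = y_lin - 4.0 * float(loc_error) ** 2
        pos = y_lin > 0
        if pos.sum() < 4:
            raise ValueError("noise-floor subtraction left < 4 positive lags")
        tau, y_lin = tau[pos], y_lin[pos]

    def loglog(tau, y):
        import statsmodels.api as sm

        fit = sm.OLS(np.log(y), sm.add_constant(np.log(tau))).fit()
        (b0, b1), (s0, s1) = fit.params, fit.bse
        return float(np.exp(b0)), float(b1), float(np.exp(b0) * s0), float(s1)

    if loc_error == "fit":
        D0, a0, _, _ = loglog(tau, y_lin)

        def model(t, D, alpha, c):
            return D * t**alpha + c

        try:
            popt, pcov = optimize.curve_fit(
                model, tau, y_lin, p0=[D0, np.clip(a0, 0.05, 1.95), 0.0],
                bounds=([1e-12, 0.01, 0.0], [np.inf, 2.2, np.inf]),
                maxfev=10000,
            )
            perr = np.sqrt(np.diag(pcov))
            return PowerLawFit(
                D=float(popt[0]), alpha=float(popt[1]),
                D_se=float(perr[0]), alpha_se=float(perr[1]),
                fit_lag_range=rng, n_lags=len(tau),
            )
        except RuntimeError:
            pass  # fall back to the log-log estimate
    D, alpha, D_se, alpha_se = loglog(tau, y_lin)
    return PowerLawFit(
        D=D, alpha=alpha, D_se=D_se, alpha_se=alpha_se,
        fit_lag_range=rng, n_lags=len(tau),
    )


# ---------------------------------------------------------------------------
# first passage


def encounter_time(
    fit: PowerLawFit,
    separation: float,
    mode: str = "relative_pair",
) -> float:
    """Extrapolated time (s) for loci a given distance apart to meet.

    ``relative_pair`` (default) treats both loci as independently
    subdiffusing, so their relative MSD is twice the single-locus MSD and the
    first-passage scale solves 2·D·t^α = d², i.e. t = (d²/2D)^{1/α};
    ``single_locus`` solves D·t^α = d². Because this extrapolates a power
    law fitted over seconds-to-minutes out to days, treat the result as an
    order-of-magnitude estimate.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if fit.alpha <= 0:
        raise ValueError("alpha must be positive")
    if mode == "relative_pair":
        return float((separation**2 / (2.0 * fit.D)) ** (1.0 / fit.alpha))
    if mode == "single_locus":
        return float((separation**2 / fit.D) ** (1.0 / fit.alpha))
    raise ValueError(f"unknown mode {mode!r}")


def telomere_geometry(
    nucleus_mask: np.ndarray,
    puncta: np.ndarray,
    pixel_size: float = 1.0,
) -> tuple[float, float]:
    """Mean nearest-neighbor and mean pairwise distance of nuclear puncta.

    ``puncta`` is (n, 2+) in μm as from :func:`detect_puncta`; puncta whose
    (rounded) pixel position falls outside ``nucleus_mask`` are excluded.
    Requires at least two puncta inside the nucleus.
    """
    puncta = np.asarray(puncta, dtype=float)
    pts = puncta[:, :2]
    idx = np.round(pts / pixel_size).astype(int)
    shape = nucleus_mask.shape
    keep = (
        (idx[:, 0] >= 0) & (idx[:, 0] < shape[0])
        & (idx[:, 1] >= 0) & (idx[:, 1] < shape[1])
    )
    keep[keep] &= nucleus_mask[idx[keep, 0], idx[keep, 1]].astype(bool)
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("need >= 2 puncta inside the nucleus")
    dmat = spatial.distance.squareform(spatial.distance.pdist(pts))
    np.fill_diagonal(dmat, np.inf)
    nn_mean = float(dmat.min(axis=1).mean())
    pairwise_mean = float(spatial.distance.pdist(pts).mean())
    return nn_mean, pairwise_mean
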