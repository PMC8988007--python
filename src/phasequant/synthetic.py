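"""Seeded generators for every input the pipeline consumes.

Each generator returns the rendered data together with a :class:`GroundTruth`
carrying the generative parameters and a per-object truth table, so that every
downstream estimator can be tested for parameter recovery without any external
data. All randomness flows from an explicit ``seed`` argument through a local
``numpy.random.Generator``; no global RNG state is touched, and identical
``(params, seed)`` reproduce the output bit-exactly.

Photometry convention: the integrated intensity of a rendered object is
proportional to its true volume, mirroring the proportionality the droplet
and coalescence analyses rely on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import FRAPCurve, GroundTruth, ImageStack, Trajectory

__all__ = [
    "make_droplet_field",
    "make_fbm_trajectories",
    "fractional_gaussian_noise",
    "make_fusion_movie",
    "make_nucleus_stack",
    "make_frap_curve",
    "make_dilute_series",
    "make_coalescence_movie",
    "dilute_model_homotypic",
    "dilute_model_heterotypic",
    "DILUTE_MODELS",
]

# Gaussian edge blur applied to rendered discs, px
_EDGE_SIGMA = 1.0
# default PSF sigma for rendered puncta, px
_PUNCTA_SIGMA = 1.3


def _apply_noise(
    image: np.ndarray, snr: float, background: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-Gaussian noise scaled so peak signal / noise SD = ``snr``.

    ``snr=inf`` leaves the image untouched (noise-free fixtures).
    """
    if np.isinf(snr):
        return image
    signal = float(image.max() - background)
    if signal <= 0:
        signal = max(background, 1.0)
    noise_sd = signal / snr
    # shot-noise-like component (variance ∝ intensity) plus read noise
    shot = rng.normal(0.0, 1.0, image.shape) * np.sqrt(
        np.clip(image, 0, None) / max(image.max(), 1e-12)
    )
    read = rng.normal(0.0, 1.0, image.shape)
    noisy = image + noise_sd * 0.5 * (shot + read)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# droplet fields


def make_droplet_field(
    n_droplets: int,
    radius_range: tuple[float, float],
    pixel_size: float = 0.106,
    snr: float = np.inf,
    field_size: int = 256,
    background: float = 100.0,
    amplitude: float = 1000.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[ImageStack, GroundTruth]:
    """Render a field of settled spherical droplets as bright 2D discs.

    Droplet radii (μm) are drawn uniformly from ``radius_range`` and placed by
    rejection sampling so that no two discs overlap and every disc lies fully
    inside the field. Discs get a Gaussian edge blur (σ = 1 px); peak
    intensity is scaled so each droplet's integrated intensity is proportional
    to the volume of a sphere of its radius. The truth table flags droplets
    whose projected area falls below the 10 px minimum-size cut used by the
    segmentation stage.

    Raises
    ------
    ValueError
        If ``n_droplets`` non-overlapping discs cannot be placed
        (impossible packing) or a radius is below 2 px.
    """
    rng = np.random.default_rng(seed)
    lo, hi = radius_range
    if lo / pixel_size < 1.5:
        raise ValueError(
            f"minimum radius {lo} μm is below 1.5 px at pixel size {pixel_size} μm"
        )
    centers: list[tuple[float, float]] = []
    radii_px: list[float] = []
    tries = 0
    while len(centers) < n_droplets:
        if tries >= max_tries:
            raise ValueError(
                f"impossible packing: placed {len(centers)} of {n_droplets} "
                f"non-overlapping droplets in a {field_size} px field after "
                f"{max_tries} attempts"
            )
        tries += 1
        r_um = rng.uniform(lo, hi)
        r_px = r_um / pixel_size
        margin = r_px + 3 * _EDGE_SIGMA
        y = rng.uniform(margin, field_size - margin)
        x = rng.uniform(margin, field_size - margin)
        # keep a 2 px guard band between discs so blurred edges stay separate
        ok = all(
            np.hypot(y - cy, x - cx) > r_px + rp + 2 + 2 * _EDGE_SIGMA
            for (cy, cx), rp in zip(centers, radii_px)
        )
        if ok:
            centers.append((y, x))
            radii_px.append(r_px)

    image = np.zeros((field_size, field_size), dtype=float)
    yy, xx = np.mgrid[0:field_size, 0:field_size]
    rows = []
    for i, ((cy, cx), r_px) in enumerate(zip(centers, radii_px)):
        disc = (np.hypot(yy - cy, xx - cx) <= r_px).astype(float)
        r_um = r_px * pixel_size
        volume = 4.0 / 3.0 * np.pi * r_um**3
        # peak amplitude ∝ volume / area keeps integrated intensity ∝ volume
        area_px = max(disc.sum(), 1.0)
        peak = amplitude * volume / (area_px * pixel_size**2)
        image += peak * disc
        rows.append(
            {
                "label": i + 1,
                "y_um": cy * pixel_size,
                "x_um": cx * pixel_size,
                "radius_um": r_um,
                "radius_px": r_px,
                "volume_um3": volume,
                "area_px": np.pi * r_px**2,
                "below_min_size": bool(np.pi * r_px**2 < 10),
            }
        )
    image = ndimage.gaussian_filter(image, _EDGE_SIGMA) + background
    image = _apply_noise(image, snr, background, rng)

    truth = pd.DataFrame(
        rows,
        columns=[
            "label", "y_um", "x_um", "radius_um", "radius_px",
            "volume_um3", "area_px", "below_min_size",
        ],
    )
    stack = ImageStack(image, "yx", pixel_size=pixel_size)
    gt = GroundTruth(
        kind="droplet_field",
        params=dict(
            n_droplets=n_droplets, radius_range_um=radius_range,
            pixel_size_um=pixel_size, snr=snr, field_size_px=field_size,
            background=background, seed=seed,
        ),
        truth_table=truth,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# fractional Brownian trajectories


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact sample of fractional Gaussian noise with unit step variance.

    Uses Davies-Harte circulant embedding of the fGn autocovariance
    γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); when the embedding is not
    non-negative (possible for H near 1 at small n) falls back to a Cholesky
    factorization of the exact covariance matrix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    # circulant first row: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) < -1e-8 * np.max(eig):
        cov = np.empty((n, n))
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        cov[:] = gamma[idx]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return chol @ rng.standard_normal(n)
    eig = np.clip(eig, 0.0, None)
    m = len(row)
    # synthesize via rfft of a complex Gaussian spectrum with the right weights
    n_half = m // 2
    z = np.empty(n_half + 1, dtype=complex)
    z[0] = rng.standard_normal() * np.sqrt(m)
    z[-1] = rng.standard_normal() * np.sqrt(m)
    re = rng.standard_normal(n_half - 1)
    im = rng.standard_normal(n_half - 1)
    z[1:-1] = (re + 1j * im) * np.sqrt(m / 2.0)
    sample = np.fft.irfft(np.sqrt(eig) * z, n=m)
    return sample[:n]


def make_fbm_trajectories(
    alpha: float,
    D_gen: float,
    n_traj: int = 200,
    n_frames: int = 300,
    dt: float = 1.0,
    loc_noise: float = 0.0,
    origin_spread: float = 5.0,
    seed: int = 0,
) -> tuple[list[Trajectory], GroundTruth]:
    """Generate 2D fractional-Brownian trajectories with a known MSD law.

    The ensemble two-dimensional MSD obeys E[MSD(τ)] = ``D_gen``·τ^``alpha``
    (μm², τ in s), i.e. each coordinate contributes ``D_gen``·τ^α/2.
    Independent Gaussian localization noise of SD ``loc_noise`` μm is added to
    every frame, which inflates the measured MSD by 4·loc_noise² at all lags.

    Setting ``D_gen=0`` yields frozen trajectories whose apparent motion is
    pure localization noise.
    """
    if not 0 < alpha <= 2:
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    rng = np.random.default_rng(seed)
    hurst = alpha / 2.0
    scale = np.sqrt(0.5 * D_gen * dt**alpha)  # per-coordinate fBm amplitude
    trajectories = []
    times = np.arange(n_frames) * dt
    for i in range(n_traj):
        origin = rng.uniform(0, origin_spread, size=2)
        if D_gen > 0:
            steps = np.column_stack(
                [
                    fractional_gaussian_noise(n_frames - 1, hurst, rng),
                    fractional_gaussian_noise(n_frames - 1, hurst, rng),
                ]
            )
            path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) * scale
        else:
            path = np.zeros((n_frames, 2))
        pos = origin + path
        if loc_noise > 0:
            pos = pos + rng.normal(0.0, loc_noise, pos.shape)
        trajectories.append(
            Trajectory(times=times, positions=pos, quality=1.0,
                       span_fraction=1.0, track_id=i)
        )
    truth = pd.DataFrame(
        {"track_id": range(n_traj), "alpha": alpha, "D_um2_s_alpha": D_gen}
    )
    gt = GroundTruth(
        kind="trajectories",
        params=dict(alpha=alpha, D_um2_s_alpha=D_gen, n_traj=n_traj,
                    n_frames=n_frames, dt_s=dt, loc_noise_um=loc_noise,
                    seed=seed),
        truth_table=truth,
    )
    return trajectories, gt


# ---------------------------------------------------------------------------
# fusion movies


def _render_ellipse(
    shape: tuple[int, int], cy: float, cx: float, a_px: float, b_px: float,
    peak: float, oversample: int = 4,
) -> np.ndarray:
    """Anti-aliased filled ellipse (axis-aligned, a along x) via supersampling."""
    os = oversample
    yy, xx = np.mgrid[0 : shape[0] * os, 0 : shape[1] * os]
    yy = (yy + 0.5) / os - 0.5
    xx = (xx + 0.5) / os - 0.5
    inside = ((yy - cy) / b_px) ** 2 + ((xx - cx) / a_px) ** 2 <= 1.0
    binned = inside.astype(float).reshape(
        shape[0], os, shape[1], os
    ).mean(axis=(1, 3))
    return peak * binned


def make_fusion_movie(
    t_fusion: float,
    dt: float = 1.0,
    radius: float = 2.0,
    pixel_size: float = 0.106,
    n_pre: int = 5,
    n_post_pad: int = 10,
    snr: float = np.inf,
    ar_criterion: float = 1.1,
    background: float = 100.0,
    peak: float = 1000.0,
    separated: bool = False,
    relax: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a droplet-pair fusion movie with a known fusion time.

    ``n_pre`` frames show two separated discs; at the contact frame they merge
    into a single ellipse whose aspect ratio relaxes exponentially from 2
    toward 1. The relaxation constant is chosen so the aspect ratio first
    satisfies the spherical criterion (AR ≤ ``ar_criterion``) exactly
    ``t_fusion`` seconds after the last separated frame.

    ``separated=True`` renders two discs that never touch (no-event fixture);
    ``relax=False`` freezes the post-contact aspect ratio at 2 (gel-like,
    never-completing fixture).
    """
    if t_fusion <= dt and not separated:
        raise ValueError("t_fusion must exceed one frame interval")
    rng = np.random.default_rng(seed)
    r_px = radius / pixel_size
    n_relax = int(round(t_fusion / dt)) + n_post_pad
    n_frames = n_pre + (n_relax if not separated else n_post_pad + 5)
    size = int(np.ceil(8 * r_px + 20))
    cy = size / 2.0
    cx = size / 2.0

    # AR(j·dt) = 1 + exp(-j·dt/τ) post-contact; pick τ so the nominal curve
    # crosses the criterion half a frame before j* = t_fusion/dt, i.e. the
    # first frame at or below the criterion is exactly j*, with symmetric
    # margins against rendering error on the neighboring frames.
    tau = (t_fusion - 0.5 * dt) / np.log(1.0 / (ar_criterion - 1.0))

    frames = np.empty((n_frames, size, size), dtype=float)
    for j in range(n_frames):
        img = np.zeros((size, size), dtype=float)
        if separated or j < n_pre:
            gap = 3.0 * _EDGE_SIGMA + 4.0 if separated else 3.0 * _EDGE_SIGMA + 2.0
            off = r_px + gap / 2.0
            img += _render_ellipse((size, size), cy, cx - off, r_px, r_px, peak)
            img += _render_ellipse((size, size), cy, cx + off, r_px, r_px, peak)
        else:
            t_since = (j - n_pre + 1) * dt  # contact frame is n_pre - 1
            ar = 2.0 if not relax else 1.0 + np.exp(-t_since / tau)
            # conserve projected area of the two discs: π a b = 2 π r²
            a_px = np.sqrt(2.0 * ar) * r_px
            b_px = a_px / ar
            img += _render_ellipse((size, size), cy, cx, a_px, b_px, peak)
        img = ndimage.gaussian_filter(img, _EDGE_SIGMA) + background
        frames[j] = _apply_noise(img, snr, background, rng)

    truth = pd.DataFrame(
        [{"t_fusion_s": np.nan if separated else t_fusion,
          "contact_frame": np.nan if separated else n_pre - 1,
          "completes": bool(relax and not separated)}]
    )
    gt = GroundTruth(
        kind="fusion_movie",
        params=dict(t_fusion_s=t_fusion, dt_s=dt, radius_um=radius,
                    pixel_size_um=pixel_size, ar_criterion=ar_criterion,
                    separated=separated, relax=relax, seed=seed),
        truth_table=truth,
    )
    stack = ImageStack(frames, "tyx", pixel_size=pixel_size, frame_interval=dt)
    return stack, gt


# ---------------------------------------------------------------------------
# nucleus stacks


def make_nucleus_stack(
    n_nuclei: int = 3,
    foci_per_nucleus: int | list[int] = 5,
    n_telomeres: int = 10,
    coloc_fraction: float = 0.0,
    shape: tuple[int, int, int] = (16, 192, 192),
    nucleus_radii: tuple[float, float, float] = (6.0, 40.0, 40.0),
    pixel_size: float = 0.106,
    z_step: float = 0.2,
    snr: float = np.inf,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a 3-channel 3D stack of nuclei with telomere and damage puncta.

    Channels: ``dna`` (filled ellipsoidal nuclei), ``telomere`` (Gaussian
    puncta inside nuclei) and ``foci`` (damage puncta, of which a
    ``coloc_fraction`` share their center voxel with a telomere punctum).
    The truth table records per-nucleus counts.

    Raises
    ------
    ValueError
        If the requested puncta cannot be placed inside a nucleus.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    rz, ry, rx = nucleus_radii
    if isinstance(foci_per_nucleus, int):
        foci_counts = [foci_per_nucleus] * n_nuclei
    else:
        foci_counts = list(foci_per_nucleus)
        if len(foci_counts) != n_nuclei:
            raise ValueError("foci_per_nucleus list must have n_nuclei entries")

    # place nuclei on a grid with jitter so they never overlap
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    cell_y = ny / n_rows
    cell_x = nx / n_cols
    if cell_y < 2 * ry + 4 or cell_x < 2 * rx + 4:
        raise ValueError("field too small for requested nuclei")
    centers = []
    for i in range(n_nuclei):
        r, c = divmod(i, n_cols)
        cy = (r + 0.5) * cell_y + rng.uniform(-2, 2)
        cx = (c + 0.5) * cell_x + rng.uniform(-2, 2)
        cz = nz / 2.0 + rng.uniform(-1, 1)
        centers.append((cz, cy, cx))

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    dna = np.zeros(shape, dtype=float)
    telo_delta = np.zeros(shape, dtype=float)
    foci_delta = np.zeros(shape, dtype=float)
    rows = []
    min_sep = 9.0  # px; keeps rendered puncta resolvable as separate objects

    def _dist(p, q):
        return np.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2)

    def _place_inside(cz, cy, cx, avoid, margin=0.8):
        for _ in range(800):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = margin * rng.uniform(0, 1) ** (1 / 3)
            p = (cz + u[0] * rad * rz, cy + u[1] * rad * ry, cx + u[2] * rad * rx)
            if not (1 <= p[0] < nz - 1 and 1 <= p[1] < ny - 1 and 1 <= p[2] < nx - 1):
                continue
            if all(_dist(p, q) > min_sep for q in avoid):
                return p
        raise ValueError(f"cannot place punctum inside nucleus at {(cz, cy, cx)}")

    for nuc_id, ((cz, cy, cx), n_foci) in enumerate(zip(centers, foci_counts), start=1):
        inside = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
        dna[inside] = 500.0
        telo_pts: list[tuple[float, float, float]] = []
        for _ in range(n_telomeres):
            telo_pts.append(_place_inside(cz, cy, cx, telo_pts))
        for p in telo_pts:
            telo_delta[int(round(p[0])), int(round(p[1])), int(round(p[2]))] += 3000.0
        n_coloc_target = int(round(coloc_fraction * n_foci))
        if n_coloc_target > len(telo_pts):
            raise ValueError(
                f"nucleus {nuc_id}: cannot colocalize {n_coloc_target} foci "
                f"with only {len(telo_pts)} telomeres"
            )
        foci_pts: list[tuple[float, float, float]] = []
        for k in range(n_foci):
            if k < n_coloc_target:
                p = telo_pts[k]
            else:
                # away from every telomere and every other focus
                p = _place_inside(cz, cy, cx, telo_pts + foci_pts)
            foci_pts.append(p)
            foci_delta[int(round(p[0])), int(round(p[1])), int(round(p[2]))] += 3000.0
        rows.append(
            {
                "nucleus_id": nuc_id,
                "z_px": cz, "y_px": cy, "x_px": cx,
                "n_foci": n_foci,
                "n_telomeres": n_telomeres,
                "n_colocalized": n_coloc_target,
            }
        )

    background = 20.0
    sig = (_PUNCTA_SIGMA, _PUNCTA_SIGMA, _PUNCTA_SIGMA)
    telo = ndimage.gaussian_filter(telo_delta, sig)
    foci = ndimage.gaussian_filter(foci_delta, sig)
    data = np.stack([dna, telo, foci]) + background
    if not np.isinf(snr):
        for c in range(3):
            data[c] = _apply_noise(data[c], snr, background, rng)
    stack = ImageStack(
        data, "czyx", pixel_size=pixel_size, z_step=z_step,
        channels=("dna", "telomere", "foci"),
    )
    gt = GroundTruth(
        kind="nucleus_stack",
        params=dict(n_nuclei=n_nuclei, n_telomeres=n_telomeres,
                    coloc_fraction=coloc_fraction, shape=shape,
                    pixel_size_um=pixel_size, z_step_um=z_step, snr=snr,
                    seed=seed),
        truth_table=pd.DataFrame(rows),
    )
    return stack, gt


# ---------------------------------------------------------------------------
# FRAP curves


def make_frap_curve(
    mobile_fraction: float = 0.6,
    tau: float = 20.0,
    pre_frames: int = 5,
    post_frames: int = 100,
    dt: float = 2.0,
    residual: float = 0.2,
    photobleach_tau: float = np.inf,
    noise_sd: float = 0.0,
    amplitude: float = 800.0,
    seed: int = 0,
) -> FRAPCurve:
    """Synthesize raw bleach-ROI and whole-cell reference FRAP traces.

    Constructed so that after double normalization (bleach trace divided by
    the acquisition-photobleaching reference) followed by full-scale
    rescaling, the recovery is exactly
    ``mobile_fraction * (1 - exp(-t/tau))`` (plus observation noise).
    ``residual`` is the fluorescence fraction surviving the bleach pulse;
    ``photobleach_tau`` applies an exponential acquisition-bleaching decay to
    both traces, which the normalization must cancel.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = pre_frames + post_frames
    times = np.arange(n) * dt
    t_post = times[pre_frames:] - times[pre_frames]
    ideal = np.ones(n)
    if tau <= 0:
        recovery = np.ones_like(t_post)
    else:
        recovery = 1.0 - np.exp(-t_post / tau)
    ideal[pre_frames:] = residual + (1.0 - residual) * mobile_fraction * recovery
    decay = (
        np.exp(-times / photobleach_tau)
        if np.isfinite(photobleach_tau)
        else np.ones(n)
    )
    bleach = amplitude * ideal * decay
    reference = amplitude * 2.5 * decay
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd * amplitude, n)
        reference = reference + rng.normal(0.0, noise_sd * amplitude, n)
    return FRAPCurve(
        times=times, bleach_roi=bleach, reference_roi=reference,
        bleach_frame=pre_frames,
    )


# ---------------------------------------------------------------------------
# dilute-phase series


def dilute_model_homotypic(
    c_tot: np.ndarray, c_star: float, endogenous: float
) -> np.ndarray:
    """Single-component buffering: c_dil tracks c_tot then pins at a ceiling.

    ``endogenous`` is untagged protein participating in the phase equilibrium:
    the tagged dilute signal saturates at ``c_star - endogenous``.
    """
    ceiling = max(c_star - endogenous, 0.0)
    return np.minimum(np.asarray(c_tot, dtype=float), ceiling)


def dilute_model_heterotypic(
    c_tot: np.ndarray, A: float, K: float
) -> np.ndarray:
    """Heterotypically stabilized scaling: strictly increasing, sublinear.

    c_dil = c_tot − A·c_tot/(K + c_tot); the condensed fraction saturates as
    the finite heterotypic partner is titrated out. For A < K the curve is
    strictly increasing and positive over all c_tot > 0.
    """
    c = np.asarray(c_tot, dtype=float)
    return c - A * c / (K + c)


DILUTE_MODELS = {
    "homotypic": dilute_model_homotypic,
    "heterotypic": dilute_model_heterotypic,
}


def make_dilute_series(
    model: str,
    params: dict[str, float] | None = None,
    n_points: int = 12,
    c_tot_range: tuple[float, float] = (1.0, 30.0),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Generate (c_tot, c_dil) pairs from a registered generative model.

    Noise is additive Gaussian with SD ``noise_sd`` (same units as
    concentration), truncated so c_dil stays within [0, c_tot].
    """
    from .types import DiluteSeries

    if model not in DILUTE_MODELS:
        raise KeyError(f"unknown dilute model {model!r}; have {list(DILUTE_MODELS)}")
    defaults = {
        "homotypic": {"c_star": 12.0, "endogenous": 2.0},
        "heterotypic": {"A": 8.0, "K": 12.0},
    }
    p = {**defaults[model], **(params or {})}
    rng = np.random.default_rng(seed)
    c_tot = np.linspace(*c_tot_range, n_points)
    c_dil = DILUTE_MODELS[model](c_tot, **p)
    if noise_sd > 0:
        c_dil = c_dil + rng.normal(0.0, noise_sd, n_points)
        c_dil = np.clip(c_dil, 0.0, c_tot)
    series = DiluteSeries(c_tot=c_tot, c_dil=c_dil)
    truth = GroundTruth(
        kind="dilute_series",
        params=dict(model=model, **p, n_points=n_points,
                    noise_sd=noise_sd, seed=seed),
        truth_table=pd.DataFrame({"c_tot": c_tot, "c_dil": c_dil}),
    )
    return series, truth


# ---------------------------------------------------------------------------
# coalescence movies


def make_coalescence_movie(
    I1: float,
    I2: float,
    t_merge: int = 10,
    n_frames: int = 20,
    size: int = 96,
    separation_px: float = 20.0,
    noise_sd: float = 0.0,
    background: float = 50.0,
    conserve_fraction: float = 1.0,
    pixel_size: float = 0.106,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render two puncta that merge into one at frame ``t_merge``.

    Pre-merge frames contain two Gaussian puncta with integrated intensities
    ``I1`` and ``I2``; from ``t_merge`` on, a single punctum carries
    ``conserve_fraction * (I1 + I2)`` (1.0 = material conserved; smaller
    values construct deliberate conservation violations). ``t_merge`` at or
    beyond ``n_frames`` renders two objects in every frame.
    """
    rng = np.random.default_rng(seed)
    cy = size / 2.0
    frames = np.empty((n_frames, size, size), dtype=float)

    def punctum(cx, integrated):
        delta = np.zeros((size, size))
        delta[int(cy), int(round(cx))] = integrated
        return ndimage.gaussian_filter(delta, _PUNCTA_SIGMA)

    for t in range(n_frames):
        img = np.zeros((size, size))
        if t < t_merge:
            if I1 > 0:
                img += punctum(size / 2 - separation_px / 2, I1)
            if I2 > 0:
                img += punctum(size / 2 + separation_px / 2, I2)
        else:
            total = conserve_fraction * (I1 + I2)
            if total > 0:
                img += punctum(size / 2, total)
        img += background
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[t] = img

    truth = pd.DataFrame(
        [{"I1": I1, "I2": I2, "t_merge": t_merge,
          "post_intensity": conserve_fraction * (I1 + I2),
          "conserving": conserve_fraction == 1.0}]
    )
    gt = GroundTruth(
        kind="coalescence_movie",
        params=dict(I1=I1, I2=I2, t_merge=t_merge, n_frames=n_frames,
                    noise_sd=noise_sd, conserve_fraction=conserve_fraction,
                    seed=seed),
        truth_table=truth,
    )
    stack = ImageStack(frames, "tyx", pixel_size=pixel_size, frame_interval=1.0)
    return stack, gt
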