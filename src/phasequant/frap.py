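"""FRAP curve normalization and mobile-fraction estimation.

Double normalization: the bleach-ROI trace is divided by its pre-bleach mean
and multiplied by the ratio of the whole-cell (reference) trace's pre-bleach
mean to its current value, cancelling acquisition photobleaching. The curve
is then rescaled to full scale so the pre-bleach mean is exactly 1 and the
first post-bleach point is exactly 0; the plateau of the rescaled curve is
the mobile fraction.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .types import FRAPCurve

__all__ = ["frap_normalize", "fit_recovery"]


def frap_normalize(curve: FRAPCurve) -> FRAPCurve:
    """Apply double normalization followed by full-scale rescaling.

    F₁(t) = (F(t)/⟨F⟩_pre) · (⟨W⟩_pre/W(t)), then
    F₂(t) = (F₁(t) − F₁(t₀)) / (⟨F₁⟩_pre − F₁(t₀)) with t₀ the first
    post-bleach frame. Output invariants: pre-bleach mean of F₂ = 1 and
    F₂(t₀) = 0 exactly. A bleach depth near zero (no-bleach control) makes
    the rescale degenerate; the curve is returned normalized by the double
    normalization only, flagged ``degenerate``.
    """
    if curve.bleach_frame < 2:
        raise ValueError("need >= 2 pre-bleach frames")
    ref = curve.reference_roi
    if np.any(ref <= 0):
        raise ValueError("reference trace has non-positive intensities")
    pre = slice(0, curve.bleach_frame)
    f_pre = curve.bleach_roi[pre].mean()
    w_pre = ref[pre].mean()
    if f_pre <= 0:
        raise ValueError("pre-bleach bleach-ROI mean must be positive")
    f1 = (curve.bleach_roi / f_pre) * (w_pre / ref)
    f0 = f1[curve.bleach_frame]
    depth = f1[pre].mean() - f0
    if abs(depth) < 1e-6 * max(abs(f1[pre].mean()), 1.0):
        return FRAPCurve(
            times=curve.times, bleach_roi=curve.bleach_roi,
            reference_roi=ref, bleach_frame=curve.bleach_frame,
            normalized=f1, degenerate=True,
        )
    f2 = (f1 - f0) / depth
    return FRAPCurve(
        times=curve.times, bleach_roi=curve.bleach_roi,
        reference_roi=ref, bleach_frame=curve.bleach_frame,
        normalized=f2, degenerate=False,
    )


def fit_recovery(curve: FRAPCurve) -> tuple[float, float]:
    """Fit m·(1 − exp(−t/τ)) to the normalized post-bleach recovery.

    Returns (mobile fraction m, recovery time constant τ in s).
    """
    if curve.normalized is None:
        curve = frap_normalize(curve)
    t = curve.times[curve.bleach_frame:] - curve.times[curve.bleach_frame]
    y = curve.normalized[curve.bleach_frame:]

    def model(t, m, tau):
        return m * (1.0 - np.exp(-t / np.clip(tau, 1e-9, None)))

    t_half_guess = max(t[-1] / 5.0, t[1] if len(t) > 1 else 1.0)
    popt, _ = optimize.curve_fit(
        model, t, y, p0=[min(max(y.max(), 0.1), 1.0), t_half_guess],
        bounds=([0.0, 1e-9], [1.5, np.inf]), maxfev=5000,
    )
    return float(popt[0]), float(popt[1])
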