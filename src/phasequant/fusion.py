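"""Droplet fusion scoring from aspect-ratio relaxation.

A fusion event is scored as the time between the last frame where the two
droplets appear separated (no mask overlap or adjacency) and the first frame
where the fused droplet appears spherical. "Spherical" is operationalized as
aspect ratio ≤ ``ar_complete`` (default 1.1) sustained for ``hold_frames``
consecutive frames, so single-frame segmentation noise cannot end an event.
Liquid droplets relax within tens of seconds; gel-like droplets never reach
the criterion and are reported as uncompleted (censored) events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .droplets import (
    DEFAULT_MIN_AREA,
    DEFAULT_RADIUS,
    label_condensates,
    normalize_image,
    phansalkar_threshold,
)
from .types import FusionEvent, ImageStack

__all__ = [
    "aspect_ratio_series",
    "detect_fusion",
    "fusion_cdf",
    "AspectRatioSeries",
    "NoEventError",
]

DEFAULT_AR_COMPLETE = 1.1
DEFAULT_HOLD_FRAMES = 2


class NoEventError(ValueError):
    """The movie contains no two-droplets-become-one transition."""


@dataclass
class AspectRatioSeries:
    """Per-frame object count and largest-object aspect ratio."""

    frames: np.ndarray  # frame indices
    times: np.ndarray  # s
    n_labels: np.ndarray  # objects per frame
    aspect_ratio: np.ndarray  # AR of the largest object; NaN when empty
    frame_interval: float


def aspect_ratio_series(
    movie: ImageStack,
    radius: int = DEFAULT_RADIUS,
    min_area: int = DEFAULT_MIN_AREA,
) -> AspectRatioSeries:
    """Segment every frame and track the largest object's aspect ratio.

    Empty frames are recorded with an undefined (NaN) aspect ratio. The
    series is invariant to uniform intensity rescaling of the movie because
    each frame is min-max normalized before thresholding.
    """
    if movie.axes != "tyx":
        raise ValueError(f"expected a tyx movie, got axes {movie.axes!r}")
    n = movie.n_frames
    counts = np.zeros(n, dtype=int)
    ars = np.full(n, np.nan)
    for t in range(n):
        frame = movie.frame(t).astype(float)
        r = min(radius, min(frame.shape) // 2 - 1)
        mask = phansalkar_threshold(normalize_image(frame), radius=max(r, 1))
        _, records = label_condensates(
            mask, intensity_image=frame, pixel_size=movie.pixel_size,
            min_area=min_area,
        )
        counts[t] = len(records)
        if records:
            largest = max(records, key=lambda rec: rec.area)
            ars[t] = largest.aspect_ratio
    return AspectRatioSeries(
        frames=np.arange(n),
        times=np.arange(n) * movie.frame_interval,
        n_labels=counts,
        aspect_ratio=ars,
        frame_interval=movie.frame_interval,
    )


def detect_fusion(
    series: AspectRatioSeries,
    ar_complete: float = DEFAULT_AR_COMPLETE,
    hold_frames: int = DEFAULT_HOLD_FRAMES,
) -> FusionEvent:
    """Score one fusion event from an aspect-ratio series.

    contact_frame is the last frame showing two (or more) separate objects
    before the count drops to one; completion_frame is the first subsequent
    frame whose aspect ratio stays at or below ``ar_complete`` for
    ``hold_frames`` consecutive frames. Events that never relax are returned
    with ``completed=False`` and no fusion time (right-censored).

    Raises
    ------
    NoEventError
        If the object count never passes from ≥2 to 1.
    """
    counts = series.n_labels
    contact = None
    for t in range(len(counts) - 1):
        if counts[t] >= 2 and counts[t + 1] == 1:
            contact = t
            break
    if contact is None:
        raise NoEventError("no frame where two droplets become one")
    multi_body = bool(np.max(counts[: contact + 1]) > 2)

    ar = series.aspect_ratio
    completion = None
    for t in range(contact + 1, len(counts)):
        window = ar[t : t + hold_frames]
        if len(window) < hold_frames:
            break
        if np.all(window <= ar_complete):
            completion = t
            break
    final_ar = float(ar[~np.isnan(ar)][-1]) if np.any(~np.isnan(ar)) else np.nan
    if completion is None:
        return FusionEvent(
            contact_frame=contact, completion_frame=None, fusion_time=None,
            final_aspect_ratio=final_ar, completed=False, multi_body=multi_body,
        )
    return FusionEvent(
        contact_frame=contact,
        completion_frame=completion,
        fusion_time=(completion - contact) * series.frame_interval,
        final_aspect_ratio=final_ar,
        completed=True,
        multi_body=multi_body,
    )


def fusion_cdf(
    events: list[FusionEvent], horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative fraction of completed fusions vs time.

    Uncompleted events are censored at ``horizon``: they count in the
    denominator but never in the numerator, so gel-like populations plateau
    below 1. Returns (times, cumulative fraction); the step function is
    non-decreasing and bounded by [0, 1].
    """
    if not events:
        raise ValueError("fusion CDF undefined for an empty event list")
    times = sorted(
        e.fusion_time for e in events if e.completed and e.fusion_time <= horizon
    )
    n = len(events)
    grid = np.array([0.0] + times + [horizon])
    frac = np.array([np.sum(np.array(times) <= t) / n for t in grid])
    return grid, frac
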