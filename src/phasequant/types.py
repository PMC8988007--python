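"""Core data containers shared across the pipeline.

All physical quantities carry explicit units in their field names or
docstrings: lengths in micrometres (μm), times in seconds, intensities in
arbitrary camera units (AU). Pixel coordinates are 0-based, origin top-left,
row-major ``(y, x)``; physical coordinates are ``index * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "GroundTruth",
    "DropletRecord",
    "FieldSummary",
    "PhaseDiagram",
    "CsatFit",
    "DiluteSeries",
    "FusionEvent",
    "Trajectory",
    "MSDCurve",
    "PowerLawFit",
    "FRAPCurve",
    "CoalescenceRecord",
]


@dataclass
class ImageStack:
    """An intensity array with named axes and acquisition metadata.

    Parameters
    ----------
    data : ndarray
        Intensity array. Axis order follows ``axes``.
    axes : str
        Axis labels drawn from ``"tczyx"``, one character per array axis,
        e.g. ``"yx"`` for a single 2D frame, ``"tyx"`` for a movie,
        ``"czyx"`` for a multi-channel z-stack.
    pixel_size : float
        Lateral pixel size in μm/px. Must be positive.
    frame_interval : float
        Time between frames in seconds (ignored when there is no t axis).
    channels : tuple of str
        Channel labels; length must match the ``c`` axis when present.
    z_step : float
        Axial spacing in μm (ignored when there is no z axis).
    """

    data: np.ndarray
    axes: str
    pixel_size: float
    frame_interval: float = 1.0
    channels: tuple[str, ...] = ()
    z_step: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} do not match array of ndim {self.data.ndim}"
            )
        if not set(self.axes) <= set("tczyx"):
            raise ValueError(f"unknown axis labels in {self.axes!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if "c" in self.axes and self.channels:
            if len(self.channels) != self.data.shape[self.axes.index("c")]:
                raise ValueError("channel labels do not match c axis length")

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axes.index("t")] if "t" in self.axes else 1

    def frame(self, t: int) -> np.ndarray:
        """Return frame ``t`` (all remaining axes)."""
        if "t" not in self.axes:
            raise ValueError("stack has no time axis")
        return np.take(self.data, t, axis=self.axes.index("t"))

    def channel(self, name: str) -> "ImageStack":
        """Extract one channel as a new stack (c axis dropped)."""
        if "c" not in self.axes:
            raise ValueError("stack has no channel axis")
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None
        c_ax = self.axes.index("c")
        return ImageStack(
            data=np.take(self.data, idx, axis=c_ax),
            axes=self.axes.replace("c", ""),
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            z_step=self.z_step,
        )

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Generator ground truth accompanying a synthetic dataset."""

    kind: str
    params: dict[str, Any]
    truth_table: pd.DataFrame


@dataclass
class DropletRecord:
    """One segmented condensate (all lengths in μm)."""

    label: int
    centroid: tuple[float, float]  # (y, x) μm, intensity-weighted
    area: float  # μm²
    semi_axes: tuple[float, float]  # (a, b) μm, a >= b
    volume: float  # μm³
    mean_intensity: float
    integrated_intensity: float
    area_px: int = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError(f"semi-axes must satisfy a >= b > 0, got {a}, {b}")

    @property
    def aspect_ratio(self) -> float:
        a, b = self.semi_axes
        return a / b


@dataclass
class FieldSummary:
    """Settled condensate load of one imaged field."""

    n_droplets: int
    total_volume_per_area: float  # μm³/μm²
    field_area: float  # μm²
    condition: dict[str, Any] = field(default_factory=dict)


@dataclass
class PhaseDiagram:
    """Grid of (protein, DNA) conditions with settled volume per area.

    ``points`` columns: protein_conc_uM, dna_conc_uM, volume_per_area_um,
    replicate.
    """

    points: pd.DataFrame
    construct: str = ""

    def __post_init__(self) -> None:
        required = {"protein_conc_uM", "dna_conc_uM", "volume_per_area_um", "replicate"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"phase diagram missing columns {sorted(missing)}")
        if (self.points[["protein_conc_uM", "dna_conc_uM"]] < 0).any().any():
            raise ValueError("concentrations must be non-negative")


@dataclass
class CsatFit:
    """Saturation concentration from the x-intercept of a linear fit."""

    c_sat: float  # μM
    c_sat_se: float  # μM
    slope: float  # μm³/μm² per μM
    intercept: float
    fit_range: tuple[float, float]  # μM
    n_points: int


@dataclass
class DiluteSeries:
    """Dilute-phase vs total concentration pairs with model-fit results."""

    c_tot: np.ndarray
    c_dil: np.ndarray
    fitted_model: str = ""  # homotypic | heterotypic | indeterminate
    criterion: dict[str, float] = field(default_factory=dict)
    fit_params: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c_tot = np.asarray(self.c_tot, dtype=float)
        self.c_dil = np.asarray(self.c_dil, dtype=float)
        if self.c_tot.shape != self.c_dil.shape:
            raise ValueError("c_tot and c_dil must have equal length")
        # allow small noise excursions above the diagonal but reject gross ones
        if np.any(self.c_dil > self.c_tot * 1.5 + 1e-9):
            raise ValueError("dilute phase cannot exceed total concentration")


@dataclass
class FusionEvent:
    """A scored droplet-fusion event."""

    contact_frame: int
    completion_frame: int | None
    fusion_time: float | None  # s; None when not completed
    final_aspect_ratio: float
    completed: bool
    multi_body: bool = False

    def __post_init__(self) -> None:
        if self.completed:
            if self.completion_frame is None or self.completion_frame <= self.contact_frame:
                raise ValueError("completed event requires completion_frame > contact_frame")


@dataclass
class Trajectory:
    """One linked particle track (no gaps; consecutive frames only)."""

    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # (n, 2) μm as (y, x)
    quality: float = 0.0
    span_fraction: float = 1.0
    track_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.span_fraction <= 1:
            raise ValueError("span_fraction must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MSDCurve:
    """Ensemble time-averaged mean squared displacement per lag."""

    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # μm² (2D: x and y displacements summed)
    n_pairs: np.ndarray  # displacement pairs contributing per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")
        if len(self.lags) > 1 and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class PowerLawFit:
    """MSD(τ) = D·τ^α fitted on log-log axes."""

    D: float  # μm² s^-α
    alpha: float
    D_se: float
    alpha_se: float
    fit_lag_range: tuple[float, float]  # s
    n_lags: int = 0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not 0 < self.alpha < 2.5:
            raise ValueError(f"alpha {self.alpha} outside plausible range")


@dataclass
class FRAPCurve:
    """Raw and normalized fluorescence-recovery traces."""

    times: np.ndarray  # s
    bleach_roi: np.ndarray  # AU
    reference_roi: np.ndarray  # AU
    bleach_frame: int  # index of first post-bleach frame
    normalized: np.ndarray | None = None
    degenerate: bool = False  # flagged when the bleach depth is ~0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.reference_roi = np.asarray(self.reference_roi, dtype=float)
        n = len(self.times)
        if len(self.bleach_roi) != n or len(self.reference_roi) != n:
            raise ValueError("trace lengths must match times")
        if not 0 < self.bleach_frame < n:
            raise ValueError("bleach_frame must leave pre- and post-bleach frames")


@dataclass
class CoalescenceRecord:
    """Integrated-intensity bookkeeping across a two-into-one merge."""

    pre_intensities: tuple[float, float]
    pre_ses: tuple[float, float]
    predicted_post: float
    predicted_se: float
    measured_post: float
    measured_se: float
    merge_frame: int
    conserved: bool
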