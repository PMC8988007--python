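"""Readers, writers, and run configuration.

Images travel as multi-page TIFF with a JSON sidecar (``<name>.json`` next to
the TIFF) carrying axes, pixel size, frame interval, z step, and channel
labels. Tables are UTF-8 comma-separated CSV with a header row and units
embedded in column names (e.g. ``volume_um3``). When a TIFF has no sidecar
the pixel size falls back to 0.106 μm (a typical effective pixel size for
the spinning-disk/TIRF setups this pipeline targets) with a loud warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import GroundTruth, ImageStack, Trajectory

__all__ = [
    "read_image",
    "write_image",
    "write_truth",
    "write_trajectories",
    "read_trajectories",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("phasequant")

DEFAULT_PIXEL_SIZE = 0.106  # μm


def write_image(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    # explicit photometric keeps 3-length leading axes from being stored RGB
    tifffile.imwrite(path, np.asarray(stack.data), photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "axes": stack.axes,
                "pixel_size_um": stack.pixel_size,
                "frame_interval_s": stack.frame_interval,
                "z_step_um": stack.z_step,
                "channels": list(stack.channels),
            },
            indent=2,
        )
    )
    return path


def read_image(path: str | Path, axes: str | None = None) -> ImageStack:
    """Read a TIFF (with optional JSON sidecar) into an ImageStack.

    ``axes`` overrides or supplies the axis labels when the sidecar is
    absent; otherwise axes are guessed from dimensionality (yx, tyx, tzyx).
    Missing pixel-size metadata falls back to 0.106 μm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    ax = axes or meta.get("axes")
    if ax is None:
        ax = {2: "yx", 3: "tyx", 4: "tzyx"}.get(data.ndim)
        if ax is None:
            raise ValueError(f"cannot infer axes for ndim {data.ndim}; pass axes=")
    if len(ax) != data.ndim:
        raise ValueError(f"axes {ax!r} do not match array of ndim {data.ndim}")
    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        warnings.warn(
            f"{path.name}: no pixel-size metadata; assuming "
            f"{DEFAULT_PIXEL_SIZE} μm/px",
            stacklevel=2,
        )
        pixel_size = DEFAULT_PIXEL_SIZE
    return ImageStack(
        data=data,
        axes=ax,
        pixel_size=pixel_size,
        frame_interval=meta.get("frame_interval_s", 1.0),
        z_step=meta.get("z_step_um", 1.0),
        channels=tuple(meta.get("channels", ())),
    )


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write a ground-truth table as CSV with a JSON parameter sidecar."""
    path = Path(path)
    truth.truth_table.to_csv(path, index=False)
    path.with_suffix(".params.json").write_text(
        json.dumps({"kind": truth.kind, "params": _jsonable(truth.params)}, indent=2)
    )
    return path


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> Path:
    """Write tracks as CSV: track_id, frame, t_s, y_um, x_um, quality."""
    rows = []
    for traj in trajectories:
        dt = np.min(np.diff(traj.times)) if len(traj) > 1 else 1.0
        for t, (y, x) in zip(traj.times, traj.positions):
            rows.append(
                {
                    "track_id": traj.track_id,
                    "frame": int(round(t / dt)),
                    "t_s": t,
                    "y_um": y,
                    "x_um": x,
                    "quality": traj.quality,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read tracks written by :func:`write_trajectories`."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("t_s")
        out.append(
            Trajectory(
                times=grp["t_s"].to_numpy(),
                positions=grp[["y_um", "x_um"]].to_numpy(),
                quality=float(grp["quality"].iloc[0]),
                track_id=int(tid),
            )
        )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    return obj


@dataclass
class RunConfig:
    """Validated parameters for a pipeline run.

    Round-trips losslessly through JSON; every output table carries the
    config hash and seed for provenance.
    """

    inputs: list[str] = field(default_factory=list)
    outdir: str = "results"
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"
    segmentation_radius: int = 30
    min_area: int = 10
    detector_diameter_um: float = 0.5
    threshold_sigmas: float = 2.0
    max_link_um: float = 0.5
    min_span_fraction: float = 0.5
    ar_complete: float = 1.1
    hold_frames: int = 2
    damage_threshold: int = 10
    min_detectable: float = 0.0
    params: dict = field(default_factory=dict)

    _KNOWN_STAGES = (
        "simulate", "droplets", "phase", "fuse", "track", "msd", "frap",
        "foci", "coalesce", "dilute",
    )

    def __post_init__(self) -> None:
        if self.segmentation_radius < 1:
            raise ValueError("segmentation_radius must be >= 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if not 0 < self.min_span_fraction <= 1:
            raise ValueError("min_span_fraction must be in (0, 1]")
        if self.ar_complete < 1:
            raise ValueError("ar_complete must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        unknown = set(self.stages) - set(self._KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
        return Path(path)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns a manifest mapping stage name to the artifact paths it produced.
    Any stage failure raises with the failing stage named; no later stage
    runs. This driver covers the synthetic end-to-end path (simulate →
    droplets → phase); image-driven stages are invoked via their subcommands
    or the library API.
    """
    from . import droplets as dq
    from . import phase as ph
    from . import synthetic as syn

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    provenance = {"config_hash": config.config_hash, "seed": config.seed}

    order = [s for s in config._KNOWN_STAGES if s in config.stages]
    field_paths: list[Path] = []
    summaries = []
    for stage in order:
        try:
            if stage == "simulate":
                artifacts = []
                for i, conc in enumerate(
                    config.params.get("concentrations_uM", [2, 4, 8])
                ):
                    stack, gt = syn.make_droplet_field(
                        n_droplets=config.params.get("n_droplets", 12),
                        radius_range=tuple(
                            config.params.get("radius_range_um", (0.8, 1.6))
                        ),
                        seed=config.seed + i,
                    )
                    p = write_image(stack, outdir / f"field_{conc}uM.tif")
                    write_truth(gt, outdir / f"field_{conc}uM.truth.csv")
                    field_paths.append(p)
                    artifacts.append(str(p))
                manifest[stage] = artifacts
            elif stage == "droplets":
                rows = []
                for p in field_paths or [Path(s) for s in config.inputs]:
                    stack = read_image(p)
                    _, records, summary = dq.segment_field(
                        stack, radius=config.segmentation_radius,
                        min_area=config.min_area,
                    )
                    summaries.append(summary)
                    rows.append(
                        {
                            "field": p.name,
                            "n_droplets": summary.n_droplets,
                            "volume_per_area_um": summary.total_volume_per_area,
                            **provenance,
                        }
                    )
                out = outdir / "field_summaries.csv"
                pd.DataFrame(rows).to_csv(out, index=False)
                manifest[stage] = [str(out)]
            elif stage == "phase":
                concs = config.params.get("concentrations_uM", [2, 4, 8])
                pairs = [
                    (c, s.total_volume_per_area)
                    for c, s in zip(concs, summaries)
                ]
                out = outdir / "csat_fit.json"
                try:
                    fit = ph.fit_csat(pairs, config.min_detectable)
                    payload = {
                        "c_sat_uM": fit.c_sat, "c_sat_se_uM": fit.c_sat_se,
                        "slope": fit.slope, "n_points": fit.n_points,
                        **provenance,
                    }
                except (ph.InsufficientDataError, ph.NoTrendError) as err:
                    payload = {"error": str(err), **provenance}
                out.write_text(json.dumps(payload, indent=2))
                manifest[stage] = [str(out)]
            else:
                logger.info("stage %s has no batch driver; use its subcommand", stage)
                manifest[stage] = []
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
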