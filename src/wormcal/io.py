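"""File formats, configuration, and the end-to-end pipeline runner.

Recordings travel as paired single-channel multi-page grayscale TIFFs
(``*_bf.tif`` + ``*_gcamp.tif``).  All tabular outputs are plain CSV with
``.`` decimals, comma separators, a header row, and empty cells for
missing values, so reruns are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .kymograph import Kymograph, KymographParams, WaveEventGeometry, build_kymograph, detect_wave_geometry
from .segmentation import BulkTrace, MaskStack, Recording, SegmentationParams, extract_trace
from .simulate import GroundTruth, SimConfig
from .trace import (
    DEFAULT_ABSENCE_MIN_DURATION_S,
    DEFAULT_MIN_DISTANCE_S,
    DEFAULT_SMOOTH_WINDOW_S,
    IntervalSummary,
    WavePeaks,
    detect_peaks,
    summarize_intervals,
)

logger = logging.getLogger(__name__)


@dataclass
class PeakParams:
    min_prominence: float | None = None  # None: 4x robust noise scale
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S


@dataclass
class GeometryParams:
    onset_fraction: float = 0.5
    medial_band: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    propagation_threshold: float = 0.7


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, materialized with explicit defaults
    so a saved config reproduces its run exactly."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    kymograph: KymographParams = field(default_factory=KymographParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    absence_min_duration_s: float = DEFAULT_ABSENCE_MIN_DURATION_S
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"]["medial_band"] = list(d["geometry"]["medial_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        geo = dict(d.get("geometry", {}))
        if "medial_band" in geo:
            geo["medial_band"] = tuple(geo["medial_band"])
        return cls(
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            peaks=PeakParams(**d.get("peaks", {})),
            kymograph=KymographParams(**d.get("kymograph", {})),
            geometry=GeometryParams(**geo),
            absence_min_duration_s=float(
                d.get("absence_min_duration_s", DEFAULT_ABSENCE_MIN_DURATION_S)
            ),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def read_recording(
    bf_path: str | Path, gcamp_path: str | Path, fps: float = 15.0
) -> Recording:
    """Load a brightfield/GCaMP TIFF pair as a Recording."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    stacks = []
    for path in (bf_path, gcamp_path):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(
                f"{path}: expected single-channel grayscale pages, got shape {arr.shape}"
            )
        stacks.append(arr)
    bf, fl = stacks
    if bf.shape != fl.shape:
        raise ValueError(
            f"frame mismatch: {bf_path} has {bf.shape[0]} frames of "
            f"{bf.shape[1:]}, {gcamp_path} has {fl.shape[0]} frames of {fl.shape[1:]}"
        )
    return Recording(
        brightfield=bf, fluorescence=fl, fps=fps, source_id=str(Path(bf_path).stem)
    )


def write_recording(
    recording: Recording,
    ground_truth: GroundTruth | None,
    config: SimConfig | None,
    outdir: str | Path,
    stem: str = "recording",
) -> dict[str, Path]:
    """Write a recording as 16-bit TIFF pair plus ground-truth JSON and the
    generator config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "brightfield": outdir / f"{stem}_bf.tif",
        "fluorescence": outdir / f"{stem}_gcamp.tif",
    }
    tifffile.imwrite(paths["brightfield"], recording.brightfield.astype(np.uint16))
    tifffile.imwrite(paths["fluorescence"], recording.fluorescence.astype(np.uint16))
    if ground_truth is not None:
        paths["ground_truth"] = outdir / f"{stem}_truth.json"
        truth = {
            "wave_schedule": [
                {"time_s": t, "initiation_axfrac": x, "is_ectopic": e}
                for t, x, e in ground_truth.wave_schedule
            ],
            "coiled_frames": sorted(ground_truth.coiled_frames),
            "n_frames": recording.n_frames,
            "fps": recording.fps,
        }
        paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    if config is not None:
        paths["config"] = outdir / f"{stem}_simconfig.yaml"
        cfg = asdict(config)
        cfg["ectopic_position_range"] = list(cfg["ectopic_position_range"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".10g")


def write_trace_csv(trace: BulkTrace, path: str | Path) -> None:
    lines = ["frame,time_s,value,valid"]
    for i in range(len(trace.values)):
        lines.append(
            f"{i},{_fmt(trace.time_s[i])},{_fmt(trace.values[i])},{_fmt(trace.valid[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_peaks_csv(peaks: WavePeaks, path: str | Path) -> None:
    lines = ["peak_time_s,amplitude,prominence"]
    for t, a, p in zip(peaks.peak_times_s, peaks.amplitudes, peaks.prominences):
        lines.append(f"{_fmt(t)},{_fmt(a)},{_fmt(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_masks_tiff(masks: MaskStack, path: str | Path) -> None:
    """Binary mask stack as a zlib-compressed 8-bit multi-page TIFF."""
    tifffile.imwrite(
        path, masks.masks.astype(np.uint8) * 255, compression="zlib"
    )


def write_summary_json(summary: IntervalSummary, path: str | Path) -> None:
    d = asdict(summary)
    d["intervals_s"] = [float(v) for v in summary.intervals_s]
    for k, v in d.items():
        if isinstance(v, float) and not np.isfinite(v):
            d[k] = None
    Path(path).write_text(json.dumps(d, indent=1))


def write_kymograph_csv(kymo: Kymograph, path: str | Path) -> None:
    """T rows x 200 columns; invalid cells are empty, never fabricated."""
    lines = [",".join(f"pos{j}" for j in range(kymo.matrix.shape[1]))]
    for row in kymo.matrix:
        lines.append(",".join("" if not np.isfinite(v) else _fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_kymograph_png(kymo: Kymograph, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 8))
    masked = np.ma.masked_invalid(kymo.matrix)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.6")  # invalid (coiled) rows grayed out
    T = kymo.matrix.shape[0]
    ax.imshow(
        masked,
        aspect="auto",
        cmap=cmap,
        extent=(0.0, 1.0, T / kymo.fps, 0.0),
    )
    ax.set_xlabel("axial position (0 = anterior)")
    ax.set_ylabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_geometry_csv(events: list[WaveEventGeometry], path: str | Path) -> None:
    lines = ["peak_time_s,initiation_axfrac,propagation_extent,propagated,ectopic,undetermined"]
    for g in events:
        lines.append(
            ",".join(
                [
                    _fmt(g.peak_time_s),
                    _fmt(g.initiation_axfrac),
                    _fmt(g.propagation_extent_axfrac),
                    _fmt(g.propagated),
                    _fmt(g.ectopic),
                    _fmt(g.undetermined),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineResult:
    trace: BulkTrace
    masks: MaskStack
    peaks: WavePeaks
    summary: IntervalSummary
    kymograph: Kymograph | None
    geometry: list[WaveEventGeometry]
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    recording: Recording,
    outdir: str | Path | None = None,
    with_kymograph: bool = True,
) -> PipelineResult:
    """Segmentation -> bulk trace -> peaks/intervals -> kymograph -> wave
    geometry, optionally writing the full artifact bundle plus a manifest."""
    stage = "segmentation"
    manifest: dict = {
        "config": config.to_dict(),
        "source_id": recording.source_id,
        "n_frames": recording.n_frames,
        "fps": recording.fps,
        "wormcal_version": __version__,
        "versions": _lib_versions(),
    }
    try:
        trace, masks = extract_trace(recording, config.segmentation)
        manifest["n_valid_mask_frames"] = int(masks.valid.sum())
        stage = "trace"
        peaks = detect_peaks(
            trace,
            min_prominence=config.peaks.min_prominence,
            min_distance_s=config.peaks.min_distance_s,
            smooth_window_s=config.peaks.smooth_window_s,
        )
        summary = summarize_intervals(
            peaks, recording.duration_s, config.absence_min_duration_s
        )
        manifest["n_waves"] = peaks.n_waves
        kymo = None
        geometry: list[WaveEventGeometry] = []
        if with_kymograph:
            stage = "kymograph"
            kymo = build_kymograph(recording, masks, config.kymograph)
            manifest["n_valid_kymograph_frames"] = int(kymo.frame_valid.sum())
            stage = "geometry"
            geometry = detect_wave_geometry(
                kymo,
                peaks,
                onset_fraction=config.geometry.onset_fraction,
                medial_band=config.geometry.medial_band,
                propagation_threshold=config.geometry.propagation_threshold,
            )
        stage = "output"
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_trace_csv(trace, outdir / "trace.csv")
            write_peaks_csv(peaks, outdir / "peaks.csv")
            write_summary_json(summary, outdir / "summary.json")
            if kymo is not None:
                write_kymograph_csv(kymo, outdir / "kymograph.csv")
                write_kymograph_png(kymo, outdir / "kymograph.png")
                write_geometry_csv(geometry, outdir / "wave_geometry.csv")
            manifest["status"] = "ok"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return PipelineResult(
            trace=trace,
            masks=masks,
            peaks=peaks,
            summary=summary,
            kymograph=kymo,
            geometry=geometry,
            manifest=manifest,
        )
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise


def _lib_versions() -> dict[str, str]:
    import scipy
    import skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "tifffile": tifffile.__version__,
    }
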