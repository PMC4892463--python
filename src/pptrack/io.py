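"""File formats and configuration.

Canonical interchange formats are plain text: CSV for detections, tracks and
ground truth, JSON for metric reports, YAML/JSON for configuration.  Movies
and density images are multi-page greyscale TIFFs.  An ISBI-challenge-style
XML track format is supported for import/export interoperability.

All writes are atomic: content goes to a temporary file in the destination
directory which is then renamed over the target.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FrameStack, GroundTruth, Track, TrackPoint, TrueTrack
from .detect import DetectionParams
from .link import LinkParams
from .metrics import MatchingSpec

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SchemaError",
    "ConfigError",
    "read_stack",
    "write_stack",
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "read_truth",
    "write_truth",
    "write_tracks_xml",
    "read_tracks_xml",
    "write_json",
    "PipelineConfig",
    "load_config",
]

DETECTIONS_COLUMNS = [
    "frame", "x", "y", "area", "circularity", "major_axis", "minor_axis",
    "mean_intensity", "peak_intensity",
]
TRACKS_COLUMNS = [
    "track_id", "frame", "x", "y", "interpolated", "area", "mean_intensity",
    "model_rw", "model_cv", "model_ca",
]
TRUTH_COLUMNS = ["track_id", "frame", "x", "y", "amplitude", "sigma"]


class FormatError(ValueError):
    """An input file is not in the expected format."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class ConfigError(ValueError):
    """A configuration file is invalid."""


@contextmanager
def _atomic_path(path: str | Path):
    """Yield a temporary path in the target directory; rename over `path` on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_stack(path: str | Path) -> FrameStack:
    """Load a multi-page greyscale TIFF as a FrameStack (bit depth preserved)."""
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        axes = series.axes
        data = series.asarray()
    if "S" in axes or "C" in axes:
        raise FormatError(
            f"{path}: image has a sample/channel axis ({axes!r}); "
            "only greyscale movies are supported"
        )
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a greyscale (T, H, W) TIFF, got shape {data.shape}"
        )
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: expected integer grey levels, got dtype {data.dtype}")
    bit_depth = 8 * data.dtype.itemsize
    return FrameStack(data, bit_depth=bit_depth)


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a FrameStack as a multi-page TIFF (atomically)."""
    data = stack.data
    if not np.issubdtype(data.dtype, np.integer):
        dtype = np.uint8 if stack.bit_depth <= 8 else np.uint16
        data = np.clip(np.rint(data), 0, stack.max_value).astype(dtype)
    with _atomic_path(path) as tmp:
        tifffile.imwrite(str(tmp), data)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")


def write_detections(path: str | Path, detections_per_frame: list[list]) -> None:
    """Write per-frame detection lists to CSV."""
    rows = [
        {
            "frame": d.frame, "x": d.x, "y": d.y, "area": d.area,
            "circularity": d.circularity, "major_axis": d.major_axis,
            "minor_axis": d.minor_axis, "mean_intensity": d.mean_intensity,
            "peak_intensity": d.peak_intensity,
        }
        for frame_dets in detections_per_frame
        for d in frame_dets
    ]
    df = pd.DataFrame(rows, columns=DETECTIONS_COLUMNS)
    with _atomic_path(path) as tmp:
        df.to_csv(tmp, index=False, float_format="%.17g")


def read_detections(path: str | Path) -> list[list]:
    """Read a detections CSV back into per-frame Detection lists."""
    from .core import Detection

    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DETECTIONS_COLUMNS, path)
    if len(df) == 0:
        return []
    n_frames = int(df["frame"].max()) + 1
    out: list[list] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(
            Detection(
                frame=int(row.frame), x=float(row.x), y=float(row.y),
                area=int(row.area), circularity=float(row.circularity),
                major_axis=float(row.major_axis), minor_axis=float(row.minor_axis),
                mean_intensity=float(row.mean_intensity),
                peak_intensity=float(row.peak_intensity),
            )
        )
    return out


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    """Write linked tracks to CSV (full float precision; header always present)."""
    rows = []
    for t in tracks:
        for p in t.points:
            mp = p.model_probs
            rows.append(
                {
                    "track_id": t.id, "frame": p.frame, "x": p.x, "y": p.y,
                    "interpolated": int(p.interpolated), "area": p.area,
                    "mean_intensity": p.mean_intensity,
                    "model_rw": mp[0], "model_cv": mp[1], "model_ca": mp[2],
                }
            )
    df = pd.DataFrame(rows, columns=TRACKS_COLUMNS)
    with _atomic_path(path) as tmp:
        df.to_csv(tmp, index=False, float_format="%.17g")


def read_tracks(path: str | Path) -> list[Track]:
    """Read a tracks CSV; rows are normalised by sorting on (track_id, frame)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["track_id", "frame", "x", "y"], path)
    for optional, default in [
        ("interpolated", 0), ("area", np.nan), ("mean_intensity", np.nan),
        ("model_rw", np.nan), ("model_cv", np.nan), ("model_ca", np.nan),
    ]:
        if optional not in df.columns:
            df[optional] = default
    df = df.sort_values(["track_id", "frame"], kind="stable")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        points = [
            TrackPoint(
                frame=int(r.frame), x=float(r.x), y=float(r.y),
                interpolated=bool(r.interpolated), area=float(r.area),
                mean_intensity=float(r.mean_intensity),
                model_probs=(float(r.model_rw), float(r.model_cv), float(r.model_ca)),
            )
            for r in g.itertuples(index=False)
        ]
        tracks.append(Track(id=int(tid), points=points))
    return tracks


def write_truth(path: str | Path, truth: GroundTruth) -> None:
    """Write ground truth to CSV with schema track_id,frame,x,y,amplitude,sigma."""
    rows = []
    for t in truth.tracks:
        for k in range(len(t)):
            rows.append(
                {
                    "track_id": t.id, "frame": int(t.frames[k]),
                    "x": t.x[k], "y": t.y[k],
                    "amplitude": t.amplitude, "sigma": t.sigma,
                }
            )
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    with _atomic_path(path) as tmp:
        df.to_csv(tmp, index=False, float_format="%.17g")


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRUTH_COLUMNS, path)
    df = df.sort_values(["track_id", "frame"], kind="stable")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        tracks.append(
            TrueTrack(
                id=int(tid),
                frames=g["frame"].to_numpy(dtype=int),
                x=g["x"].to_numpy(dtype=float),
                y=g["y"].to_numpy(dtype=float),
                amplitude=float(g["amplitude"].iloc[0]),
                sigma=float(g["sigma"].iloc[0]),
            )
        )
    return GroundTruth(tracks)


def write_tracks_xml(path: str | Path, tracks: list[Track]) -> None:
    """Export tracks in an ISBI-challenge-style XML layout."""
    root = ET.Element("root")
    contest = ET.SubElement(
        root, "TrackContestISBI2012", {"snr": "", "density": "", "scenario": ""}
    )
    for t in tracks:
        particle = ET.SubElement(contest, "particle")
        for p in t.points:
            ET.SubElement(
                particle, "detection",
                {"t": str(p.frame), "x": repr(float(p.x)), "y": repr(float(p.y)), "z": "0"},
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    with _atomic_path(path) as tmp:
        tree.write(tmp, xml_declaration=True, encoding="utf-8")


def read_tracks_xml(path: str | Path) -> list[Track]:
    """Import ISBI-challenge-style XML tracks."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise FormatError(f"{path}: not well-formed XML ({e})") from e
    tracks = []
    for tid, particle in enumerate(root.iter("particle")):
        points = [
            TrackPoint(
                frame=int(d.get("t")), x=float(d.get("x")), y=float(d.get("y"))
            )
            for d in particle.iter("detection")
        ]
        points.sort(key=lambda p: p.frame)
        tracks.append(Track(id=tid, points=points))
    return tracks


def write_json(path: str | Path, obj: dict) -> None:
    """Write a JSON document atomically."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with _atomic_path(path) as tmp:
        tmp.write_text(json.dumps(obj, indent=2, default=_default) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Resolved configuration of the full pipeline.

    Sections mirror the pipeline stages; unknown keys anywhere are rejected
    on load.  Precedence elsewhere: CLI flag > config file > built-in default.
    """

    # stage parameter sections (dicts so partial overrides are natural)
    simulate: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    link: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)
    # paths
    input: str | None = None
    truth: str | None = None
    output_dir: str = "."
    seed: int = 0

    _SECTION_KEYS = {
        "simulate": {
            "enabled", "n_tracks", "n_frames", "shape", "motion", "step_sd",
            "drift", "cage_radius", "snr", "background", "sigma", "noise",
            "min_separation",
        },
        "detect": {"S", "s", "N", "density", "snr", "F", "adaptive", "tolerance",
                   "max_iterations"},
        "link": {
            "max_dist", "min_track_length", "max_gap", "morph_weight",
            "meas_sd_pos", "meas_sd_feat_frac", "process_sd_pos",
            "process_sd_vel", "process_sd_acc", "process_sd_feat_frac",
        },
        "evaluate": {"radius", "theta"},
        "analyze": {"n_angle_bins", "signed_theta2", "include_interpolated"},
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known_top = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known_top
        if unknown:
            raise ConfigError(
                f"unknown configuration keys: {', '.join(sorted(unknown))} "
                f"(expected among: {', '.join(sorted(known_top))})"
            )
        for section, allowed in cls._SECTION_KEYS.items():
            sub = d.get(section) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {', '.join(sorted(bad))}"
                )
        return cls(**d)

    def detection_params(self) -> DetectionParams:
        d = dict(self.detect)
        d.pop("adaptive", None)
        d.pop("tolerance", None)
        d.pop("max_iterations", None)
        d.setdefault("S", 12)
        d.setdefault("s", 4)
        d.setdefault("N", 100)
        return DetectionParams(**d)

    def link_params(self) -> LinkParams:
        return LinkParams(**self.link)

    def matching_spec(self) -> MatchingSpec:
        if "radius" in self.evaluate:
            return MatchingSpec(radius=self.evaluate["radius"])
        return MatchingSpec.for_particle_size(self.detect.get("S", 12))

    def resolved(self) -> dict:
        """The fully resolved configuration (for logging)."""
        out = asdict(self)
        out["detect_resolved"] = asdict(self.detection_params())
        lp = self.link_params()
        out["link_resolved"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(lp).items()
        }
        out["evaluate_resolved"] = asdict(self.matching_spec())
        return out


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON configuration file, rejecting unknown keys."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: cannot parse config ({e})") from e
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return PipelineConfig.from_dict(data)
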