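"""Shared data containers for the detection/linking pipeline.

Conventions used throughout the package:

* coordinates are 0-based, ``x`` = column, ``y`` = row, and refer to pixel
  centres;
* a movie is a ``(T, H, W)`` array of grey levels within its bit-depth range;
* particle sizes ``S`` (typical) and ``s`` (minimum) are areas in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "Detection",
    "TrackPoint",
    "Track",
    "TrueTrack",
    "GroundTruth",
]


@dataclass
class FrameStack:
    """A 2D+t greyscale movie.

    Parameters
    ----------
    data:
        Array of shape ``(T, H, W)``.  May be float (noise-free renders) or
        an unsigned integer type (camera data).
    bit_depth:
        Nominal bit depth; values are expected in ``[0, 2**bit_depth - 1]``.
    frame_interval:
        Seconds between frames, if known.
    pixel_size_nm:
        Physical pixel size, if known.
    """

    data: np.ndarray
    bit_depth: int = 8
    frame_interval: float | None = None
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, H, W) data, got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class Detection:
    """One segmented particle in one frame."""

    frame: int
    x: float
    y: float
    area: int
    circularity: float
    major_axis: float
    minor_axis: float
    mean_intensity: float
    peak_intensity: float
    label: int = 0
    fit_fallback: bool = False

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class TrackPoint:
    """One time step of a linked track.

    ``interpolated`` marks gap-filled points taken from the filter
    prediction rather than from a detection.
    """

    frame: int
    x: float
    y: float
    interpolated: bool = False
    area: float = np.nan
    mean_intensity: float = np.nan
    model_probs: tuple[float, float, float] = (np.nan, np.nan, np.nan)


@dataclass
class Track:
    """An identity-linked sequence of detections (plus filter history)."""

    id: int
    points: list[TrackPoint] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float).reshape(-1, 2)

    @property
    def n_detections(self) -> int:
        """Number of real (non-interpolated) detections."""
        return sum(not p.interpolated for p in self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TrueTrack:
    """A ground-truth trajectory with its rendering parameters."""

    id: int
    frames: np.ndarray  # strictly increasing, unit step
    x: np.ndarray  # pixels (column)
    y: np.ndarray  # pixels (row)
    amplitude: float  # peak grey levels above background
    sigma: float  # PSF sigma, pixels

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("ground-truth frame indices must increase with unit step")

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class GroundTruth:
    """A set of true tracks, the reference against which metrics are computed."""

    tracks: list[TrueTrack]

    def positions_in_frame(self, frame: int) -> np.ndarray:
        """``(n, 4)`` array of ``x, y, amplitude, sigma`` for particles present in `frame`."""
        rows = []
        for t in self.tracks:
            idx = np.searchsorted(t.frames, frame)
            if idx < len(t.frames) and t.frames[idx] == frame:
                rows.append((t.x[idx], t.y[idx], t.amplitude, t.sigma))
        return np.array(rows, dtype=float).reshape(-1, 4)

    @property
    def n_frames(self) -> int:
        return int(max(t.frames[-1] for t in self.tracks) + 1) if self.tracks else 0

    def __len__(self) -> int:
        return len(self.tracks)
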