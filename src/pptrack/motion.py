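"""Trajectory kinetics: step angles, direction switching, rose diagrams, track density.

For every inter-step of a trajectory two angles are measured: the direction
of motion θ₁ (the heading of the displacement vector, in [0°, 360°)) and the
direction-switching angle θ₂ between consecutive displacement vectors (0° =
same direction, 180° = full reversal).  Confined ("caged") motion leaves a
characteristic signature of θ₂ mass near 180°: a particle bouncing inside a
nanodomain preferentially reverses direction, while free Brownian motion has
uniformly distributed switching angles.

Rose diagrams are 2D angular histograms whose petal sections encode the
number of movements at each (angle, step length) combination.  Track-density
images count, per pixel, the number of distinct tracks whose piecewise-linear
path passes through the pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line

from .core import Track

logger = logging.getLogger(__name__)

__all__ = [
    "RoseHistogram",
    "step_angles",
    "switch_angles",
    "rose_histogram",
    "track_density",
    "plot_rose",
]


def _coords(track, include_interpolated: bool = False) -> np.ndarray:
    """Extract an (n, 2) coordinate array from a Track or array-like."""
    if isinstance(track, Track):
        if include_interpolated:
            return track.xy
        keep = [not p.interpolated for p in track.points]
        return track.xy[np.asarray(keep, dtype=bool)]
    return np.asarray(track, dtype=float).reshape(-1, 2)


def step_angles(
    track, include_interpolated: bool = False
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-step direction of motion θ₁ and step length.

    Gap-filled (interpolated) points are excluded by default so that
    filter-predicted positions do not bias the angle statistics.  Zero-length
    steps carry no direction and are excluded; their count is returned.

    Returns ``(theta1_degrees, lengths_pixels, n_zero_steps)`` with θ₁ in
    [0°, 360°): a displacement of (+1, 0) is 0°, (0, +1) is 90°.
    """
    xy = _coords(track, include_interpolated)
    if len(xy) < 2:
        return np.array([]), np.array([]), 0
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    nonzero = lengths > 0
    theta = np.degrees(np.arctan2(d[nonzero, 1], d[nonzero, 0])) % 360.0
    return theta, lengths[nonzero], int(np.count_nonzero(~nonzero))


def switch_angles(
    track, include_interpolated: bool = False, signed: bool = False
) -> np.ndarray:
    """Direction-switching angles θ₂ between consecutive displacement vectors.

    Zero-length steps are skipped (the switching angle is computed between
    consecutive *non-zero* displacements).  By default θ₂ is unsigned in
    [0°, 180°], where 180° means a full reversal — the caged-motion
    signature; ``signed=True`` returns the signed turn in (−180°, 180°].
    """
    xy = _coords(track, include_interpolated)
    if len(xy) < 3:
        return np.array([])
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    d = d[lengths > 0]
    if len(d) < 2:
        return np.array([])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turn = np.diff(headings)
    turn = (turn + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    turn[turn == -np.pi] = np.pi
    if signed:
        return np.degrees(turn)
    return np.abs(np.degrees(turn))


@dataclass
class RoseHistogram:
    """2D (angle, step-length) histogram backing a rose diagram."""

    angle_edges: np.ndarray  # degrees
    length_edges: np.ndarray  # pixels
    counts: np.ndarray  # (n_angle_bins, n_length_bins)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def angular_counts(self) -> np.ndarray:
        """Counts marginalised over step length."""
        return self.counts.sum(axis=1)

    def modal_angle_bin(self) -> tuple[float, float]:
        """(low, high) edges of the angular bin with the most steps."""
        i = int(np.argmax(self.angular_counts()))
        return float(self.angle_edges[i]), float(self.angle_edges[i + 1])


def rose_histogram(
    angles: np.ndarray,
    lengths: np.ndarray | None = None,
    n_angle_bins: int = 36,
    length_edges: np.ndarray | None = None,
    angle_range: tuple[float, float] = (0.0, 360.0),
) -> RoseHistogram:
    """Bin (angle, length) pairs into a rose histogram.

    Angle bins are right-open and partition `angle_range`; the top of the
    range folds into the last bin (so θ₂ = 180° lands in the [175°, 180°]
    bin of a 36-bin histogram over [0°, 180°]).  Lengths beyond the last
    edge are clipped into the last length bin.  Empty input yields an
    all-zero histogram.
    """
    if n_angle_bins < 4:
        raise ValueError("need at least 4 angle bins")
    angles = np.asarray(angles, dtype=float)
    if lengths is None:
        lengths = np.ones_like(angles)
    lengths = np.asarray(lengths, dtype=float)
    if length_edges is None:
        top = max(float(lengths.max()) if len(lengths) else 1.0, 1e-6)
        length_edges = np.linspace(0.0, top, 6)  # 5 length bins
    length_edges = np.asarray(length_edges, dtype=float)
    angle_edges = np.linspace(angle_range[0], angle_range[1], n_angle_bins + 1)
    if len(angles) == 0:
        counts = np.zeros((n_angle_bins, len(length_edges) - 1), dtype=int)
        return RoseHistogram(angle_edges, length_edges, counts)
    a = np.clip(angles, angle_range[0], np.nextafter(angle_range[1], -np.inf))
    ell = np.clip(lengths, length_edges[0], np.nextafter(length_edges[-1], -np.inf))
    counts, _, _ = np.histogram2d(a, ell, bins=[angle_edges, length_edges])
    return RoseHistogram(angle_edges, length_edges, counts.astype(int))


def track_density(tracks: list, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel count of distinct tracks passing through each pixel.

    Consecutive track points are connected by Bresenham line rasterization;
    a track revisiting a pixel still counts once there.
    """
    h, w = shape
    density = np.zeros((h, w), dtype=np.int32)
    for track in tracks:
        xy = _coords(track, include_interpolated=True)
        if len(xy) == 0:
            continue
        visited = np.zeros((h, w), dtype=bool)
        pts = np.rint(xy).astype(int)
        pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
        if len(pts) == 1:
            visited[pts[0, 1], pts[0, 0]] = True
        for k in range(len(pts) - 1):
            rr, cc = _bresenham_line(pts[k, 1], pts[k, 0], pts[k + 1, 1], pts[k + 1, 0])
            visited[rr, cc] = True
        density += visited
    return density


def plot_rose(hist: RoseHistogram, ax=None, cmap: str = "viridis"):
    """Render a rose diagram: stacked polar bars, colour-coded by step length."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centres = np.radians(0.5 * (hist.angle_edges[:-1] + hist.angle_edges[1:]))
    width = np.radians(np.diff(hist.angle_edges))
    colors = plt.get_cmap(cmap)(np.linspace(0.2, 0.95, hist.counts.shape[1]))
    bottom = np.zeros(len(centres))
    for j in range(hist.counts.shape[1]):
        ax.bar(
            centres, hist.counts[:, j], width=width, bottom=bottom,
            color=colors[j], edgecolor="none",
            label=f"{hist.length_edges[j]:.2g}-{hist.length_edges[j + 1]:.2g} px",
        )
        bottom += hist.counts[:, j]
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize="x-small")
    return ax
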