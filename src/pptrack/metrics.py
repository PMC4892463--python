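"""Evaluation metrics for detection and tracking against ground truth.

Detection level: per-frame optimal one-to-one matching within a radius gives
TP/FP/FN counts, the true-positive rate TPR = TP / (TP + FN), the
false-positive rate FPR = FP / (TP + FP) (the fraction of reported detections
that are false), the localization RMSE over true positives, and the Jaccard
similarity JSC = TP / (TP + FP + FN).

Track level: each ground-truth track is paired one-to-one with the estimated
track that covers most of its time steps; with ``Y_i`` the length of truth
track ``i`` and ``Y_tracked,i`` its covered steps, the track-based error is

    E*_track = 1 - (sum_i Y_tracked,i / Y_i) / T_total ,

and JSC_theta is the track-level Jaccard where an estimated track counts as
a true positive when its matched-step fraction reaches the completeness
threshold theta (default 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .core import GroundTruth, Track

logger = logging.getLogger(__name__)

__all__ = [
    "MatchingSpec",
    "FrameMatch",
    "MatchResult",
    "MetricsReport",
    "as_point_tracks",
    "match_detections",
    "detection_rates",
    "localization_rmse",
    "track_error",
    "jsc_detections",
    "jsc_tracks",
    "evaluate",
]

_BIG = 1e9


@dataclass
class MatchingSpec:
    """How estimated and true positions are matched.

    The default radius ``2 * sqrt(S / pi)`` is twice the equivalent radius of
    the typical particle; matching is an optimal per-frame assignment.
    """

    radius: float = 4.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("match radius must be > 0")

    @classmethod
    def for_particle_size(cls, S: float) -> "MatchingSpec":
        return cls(radius=2.0 * np.sqrt(S / np.pi))


PointTrack = tuple[np.ndarray, np.ndarray]  # (frames, xy)


def as_point_tracks(obj, include_interpolated: bool = True) -> list[PointTrack]:
    """Normalise tracks (GroundTruth, list of Track, or (frames, xy) pairs)."""
    if isinstance(obj, GroundTruth):
        return [(t.frames.copy(), t.xy.copy()) for t in obj.tracks]
    out: list[PointTrack] = []
    for t in obj:
        if isinstance(t, Track):
            if include_interpolated:
                out.append((t.frames, t.xy))
            else:
                keep = np.array([not p.interpolated for p in t.points], dtype=bool)
                out.append((t.frames[keep], t.xy[keep]))
        else:
            frames, xy = t
            out.append(
                (np.asarray(frames, dtype=int), np.asarray(xy, dtype=float).reshape(-1, 2))
            )
    return out


def _frames_dict(tracks: list[PointTrack]) -> dict[int, np.ndarray]:
    by_frame: dict[int, list[np.ndarray]] = {}
    for frames, xy in tracks:
        for f, p in zip(frames, xy):
            by_frame.setdefault(int(f), []).append(p)
    return {f: np.array(ps).reshape(-1, 2) for f, ps in by_frame.items()}


@dataclass
class FrameMatch:
    """Matching outcome for one frame."""

    frame: int
    pairs: list[tuple[int, int, float]]  # (estimated idx, truth idx, distance)
    fp: list[int]  # unmatched estimated indices
    fn: list[int]  # unmatched truth indices


@dataclass
class MatchResult:
    frames: list[FrameMatch]

    @property
    def tp(self) -> int:
        return sum(len(f.pairs) for f in self.frames)

    @property
    def fp(self) -> int:
        return sum(len(f.fp) for f in self.frames)

    @property
    def fn(self) -> int:
        return sum(len(f.fn) for f in self.frames)

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for f in self.frames for (_, _, d) in f.pairs])


def _match_frame(est: np.ndarray, truth: np.ndarray, radius: float) -> tuple[list, list, list]:
    ne, nt = len(est), len(truth)
    if ne == 0 or nt == 0:
        return [], list(range(ne)), list(range(nt))
    D = cdist(est, truth)
    C = np.where(D <= radius, D, _BIG)
    rows, cols = linear_sum_assignment(C)
    pairs, fp, fn = [], set(range(ne)), set(range(nt))
    for r, c in zip(rows, cols):
        if C[r, c] < _BIG / 2:
            pairs.append((int(r), int(c), float(D[r, c])))
            fp.discard(int(r))
            fn.discard(int(c))
    return pairs, sorted(fp), sorted(fn)


def match_detections(estimated, truth, spec: MatchingSpec | None = None) -> MatchResult:
    """Per-frame optimal one-to-one matching of estimated to true positions.

    `estimated` and `truth` may be track collections (see ``as_point_tracks``)
    or dicts mapping frame index to an ``(n, 2)`` position array.  Unmatched
    estimated positions are false positives; unmatched truth positions are
    false negatives.
    """
    spec = spec or MatchingSpec()
    est_frames = estimated if isinstance(estimated, dict) else _frames_dict(as_point_tracks(estimated))
    tru_frames = truth if isinstance(truth, dict) else _frames_dict(as_point_tracks(truth))
    frames = sorted(set(est_frames) | set(tru_frames))
    out = []
    empty = np.empty((0, 2))
    for f in frames:
        pairs, fp, fn = _match_frame(
            est_frames.get(f, empty), tru_frames.get(f, empty), spec.radius
        )
        out.append(FrameMatch(frame=f, pairs=pairs, fp=fp, fn=fn))
    return MatchResult(out)


def detection_rates(matches: MatchResult) -> tuple[float, float]:
    """(TPR, FPR): TP/(TP+FN) and FP/(TP+FP); FPR is 0 with no detections."""
    tp, fp, fn = matches.tp, matches.fp, matches.fn
    if tp + fn == 0:
        raise ValueError("no ground-truth positions to evaluate against")
    tpr = tp / (tp + fn)
    fpr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    return float(tpr), float(fpr)


def localization_rmse(matches: MatchResult) -> float:
    """RMSE (pixels) of true-positive detections; NaN if there are none."""
    d = matches.distances
    if len(d) == 0:
        return float("nan")
    return float(np.sqrt(np.mean(d**2)))


def _matched_steps_matrix(
    truth: list[PointTrack], est: list[PointTrack], radius: float
) -> np.ndarray:
    """M[i, j] = number of time steps of truth track i that estimated track j
    covers within the match radius."""
    M = np.zeros((len(truth), len(est)), dtype=int)
    est_lookup = []
    for frames, xy in est:
        est_lookup.append({int(f): p for f, p in zip(frames, xy)})
    for i, (frames, xy) in enumerate(truth):
        for f, p in zip(frames, xy):
            for j, lut in enumerate(est_lookup):
                q = lut.get(int(f))
                if q is not None and np.hypot(*(q - p)) <= radius:
                    M[i, j] += 1
    return M


def _coverage_matrix(M: np.ndarray, truth: list[PointTrack]) -> np.ndarray:
    """Per-pair coverage ratios: matched steps divided by the truth track length."""
    lengths = np.array([len(frames) for frames, _ in truth], dtype=float)
    return M / lengths[:, None]


def _pair_tracks(R: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one track pairing maximising the total coverage ratio.

    Maximising the summed ratios maximises the correctly-computed-trajectory
    count directly (the quantity the track error is built from), and has a
    unique optimal value, unlike maximising raw step counts.
    """
    if R.size == 0:
        return []
    rows, cols = linear_sum_assignment(-R)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if R[r, c] > 0]


def track_error(estimated, truth, spec: MatchingSpec | None = None) -> float:
    """Track-based error E*_track in [0, 1]; 0 means every truth step tracked."""
    spec = spec or MatchingSpec()
    tru = as_point_tracks(truth)
    est = as_point_tracks(estimated)
    if not tru:
        raise ValueError("truth track set is empty")
    if not est:
        return 1.0
    R = _coverage_matrix(_matched_steps_matrix(tru, est, spec.radius), tru)
    covered = np.zeros(len(tru))
    for i, j in _pair_tracks(R):
        covered[i] = R[i, j]
    return float(1.0 - np.mean(covered))


def jsc_detections(matches: MatchResult) -> float:
    """Detection-level Jaccard similarity TP / (TP + FP + FN) over all frames."""
    denom = matches.tp + matches.fp + matches.fn
    return float(matches.tp / denom) if denom else 1.0


def jsc_tracks(
    estimated, truth, spec: MatchingSpec | None = None, theta: float = 0.8
) -> float:
    """Track-level Jaccard similarity with completeness threshold `theta`.

    An estimated track is a true positive if it is paired to a truth track
    whose steps it covers at a fraction >= theta; other estimated tracks are
    false positives and unrecovered truth tracks are false negatives.
    """
    spec = spec or MatchingSpec()
    tru = as_point_tracks(truth)
    est = as_point_tracks(estimated)
    if not tru:
        raise ValueError("truth track set is empty")
    if not est:
        return 0.0
    R = _coverage_matrix(_matched_steps_matrix(tru, est, spec.radius), tru)
    tp = 0
    recovered = set()
    for i, j in _pair_tracks(R):
        if R[i, j] >= theta:
            tp += 1
            recovered.add(i)
    fp = len(est) - tp
    fn = len(tru) - len(recovered)
    return float(tp / (tp + fp + fn))


@dataclass
class MetricsReport:
    """All evaluation measures for one (estimated, truth) pair."""

    tpr: float
    fpr: float
    rmse: float
    track_error: float
    jsc: float
    jsc_theta: float
    tp: int
    fp: int
    fn: int
    n_estimated_tracks: int
    n_truth_tracks: int

    def as_dict(self) -> dict:
        return {
            "TPR": self.tpr,
            "FPR": self.fpr,
            "RMSE_px": self.rmse,
            "E_track": self.track_error,
            "JSC": self.jsc,
            "JSC_theta": self.jsc_theta,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "n_estimated_tracks": self.n_estimated_tracks,
            "n_truth_tracks": self.n_truth_tracks,
        }


def evaluate(
    estimated, truth, spec: MatchingSpec | None = None, theta: float = 0.8
) -> MetricsReport:
    """Compute the full metrics report for estimated tracks against truth."""
    spec = spec or MatchingSpec()
    matches = match_detections(estimated, truth, spec)
    tpr, fpr = detection_rates(matches)
    return MetricsReport(
        tpr=tpr,
        fpr=fpr,
        rmse=localization_rmse(matches),
        track_error=track_error(estimated, truth, spec),
        jsc=jsc_detections(matches),
        jsc_theta=jsc_tracks(estimated, truth, spec, theta=theta),
        tp=matches.tp,
        fp=matches.fp,
        fn=matches.fn,
        n_estimated_tracks=len(as_point_tracks(estimated)),
        n_truth_tracks=len(as_point_tracks(truth)),
    )
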