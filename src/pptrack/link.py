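"""Trajectory linking with an interacting-multiple-model (IMM) Kalman filter.

Each track runs a bank of three Kalman filters — random walk, constant
velocity and constant acceleration — mixed by evolving model probabilities.
The filter state is augmented with the particle's area and mean intensity
(both modelled as random walks), and the frame-to-frame association cost
combines the Mahalanobis position distance with normalised area/intensity
differences, so morphologically dissimilar particles are not confused even
when spatially close.  Association is a global optimal linear-sum assignment
with gating at the maximum linking distance.

Measurement vector: ``z = (x, y, area, intensity)``.
Full state ordering: ``(x, y, vx, vy, ax, ay, area, intensity)``; each model
uses the leading kinematic subset plus the two feature states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Detection, Track, TrackPoint

logger = logging.getLogger(__name__)

__all__ = [
    "LinkParams",
    "IMMState",
    "IMMPrediction",
    "imm_predict",
    "imm_update",
    "association_cost",
    "assign",
    "link_tracks",
]

# indices of each model's state inside the 8-dim full state
_MODEL_IDX = [
    np.array([0, 1, 6, 7]),  # random walk
    np.array([0, 1, 2, 3, 6, 7]),  # constant velocity
    np.array([0, 1, 2, 3, 4, 5, 6, 7]),  # constant acceleration
]
N_MODELS = 3
_FULL_DIM = 8
_MEAS_IDX = np.array([0, 1, 6, 7])  # x, y, area, intensity


@dataclass
class LinkParams:
    """Linking parameters.

    ``max_dist`` is the maximum linking distance in pixels (hard gate);
    ``min_track_length`` the minimum number of real detections for a track to
    be kept (typically three frames); ``max_gap`` the number of consecutive
    frames a track may coast on predictions.  ``morph_weight`` weights the
    normalised area/intensity terms in the association cost.  Process-noise
    defaults are scaled to ``max_dist``; the measurement noise reflects the
    expected localization accuracy (0.5 px by default).
    """

    max_dist: float = 5.0
    min_track_length: int = 3
    max_gap: int = 1
    morph_weight: float = 1.0
    transition: np.ndarray = field(
        default_factory=lambda: np.full((3, 3), 0.1) + np.eye(3) * 0.7
    )
    meas_sd_pos: float = 0.5
    meas_sd_feat_frac: float = 0.1  # relative noise on area / intensity
    process_sd_pos: float | None = None  # random-walk position step (default max_dist/4)
    process_sd_vel: float | None = None  # CV velocity drift (default max_dist/10)
    process_sd_acc: float | None = None  # CA acceleration drift (default max_dist/10)
    process_sd_feat_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be > 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("transition matrix must be 3x3 with rows summing to 1")
        if self.process_sd_pos is None:
            self.process_sd_pos = self.max_dist / 4.0
        if self.process_sd_vel is None:
            self.process_sd_vel = self.max_dist / 10.0
        if self.process_sd_acc is None:
            self.process_sd_acc = self.max_dist / 10.0


def _model_matrices(params: LinkParams, feat_scale: tuple[float, float]):
    """Per-model (F, H, Q, R) with feature noise scaled to the track."""
    qa = (params.process_sd_feat_frac * feat_scale[0] + 1e-3) ** 2
    qi = (params.process_sd_feat_frac * feat_scale[1] + 1e-3) ** 2
    ra = (params.meas_sd_feat_frac * feat_scale[0] + 1e-3) ** 2
    ri = (params.meas_sd_feat_frac * feat_scale[1] + 1e-3) ** 2
    rp = params.meas_sd_pos**2
    R = np.diag([rp, rp, ra, ri])
    mats = []
    # random walk
    F0 = np.eye(4)
    H0 = np.eye(4)
    Q0 = np.diag([params.process_sd_pos**2] * 2 + [qa, qi])
    mats.append((F0, H0, Q0))
    # constant velocity
    F1 = np.eye(6)
    F1[0, 2] = F1[1, 3] = 1.0
    H1 = np.zeros((4, 6))
    H1[0, 0] = H1[1, 1] = H1[2, 4] = H1[3, 5] = 1.0
    qv = params.process_sd_vel**2
    Q1 = np.diag([0.01, 0.01, qv, qv, qa, qi])
    mats.append((F1, H1, Q1))
    # constant acceleration
    F2 = np.eye(8)
    F2[0, 2] = F2[1, 3] = F2[2, 4] = F2[3, 5] = 1.0
    F2[0, 4] = F2[1, 5] = 0.5
    H2 = np.zeros((4, 8))
    H2[0, 0] = H2[1, 1] = H2[2, 6] = H2[3, 7] = 1.0
    qc = params.process_sd_acc**2
    Q2 = np.diag([0.01, 0.01, 0.04, 0.04, qc, qc, qa, qi])
    mats.append((F2, H2, Q2))
    return mats, R


@dataclass
class IMMState:
    """Per-model Kalman states plus the model-probability simplex."""

    means: list[np.ndarray]
    covs: list[np.ndarray]
    probs: np.ndarray  # (3,), sums to 1
    feat_scale: tuple[float, float]  # (area, intensity) scales for noise terms

    @classmethod
    def from_detection(cls, det: Detection, params: LinkParams) -> "IMMState":
        """Initialise a new track: zero velocity/acceleration with inflated covariance."""
        feat = (max(float(det.area), 1.0), max(float(det.mean_intensity), 1.0))
        _, R = _model_matrices(params, feat)
        var_v = (0.5 * params.max_dist) ** 2
        var_a = (0.25 * params.max_dist) ** 2
        full = np.array(
            [det.x, det.y, 0, 0, 0, 0, det.area, det.mean_intensity], dtype=float
        )
        full_var = np.array(
            [R[0, 0], R[1, 1], var_v, var_v, var_a, var_a, R[2, 2], R[3, 3]]
        )
        means, covs = [], []
        for idx in _MODEL_IDX:
            means.append(full[idx].copy())
            covs.append(np.diag(full_var[idx]))
        return cls(means=means, covs=covs, probs=np.full(N_MODELS, 1 / N_MODELS), feat_scale=feat)


@dataclass
class IMMPrediction:
    """One-step-ahead IMM prediction for a track."""

    means: list[np.ndarray]  # per-model predicted states
    covs: list[np.ndarray]
    c: np.ndarray  # predicted model probabilities
    z_hat: np.ndarray  # combined predicted measurement (x, y, a, i)
    S: np.ndarray  # combined 4x4 innovation covariance
    feat_scale: tuple[float, float]


def _ensure_pd(P: np.ndarray) -> np.ndarray:
    P = 0.5 * (P + P.T)
    try:
        np.linalg.cholesky(P)
        return P
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-9
    for _ in range(12):
        try:
            np.linalg.cholesky(P + jitter * np.eye(P.shape[0]))
            return P + jitter * np.eye(P.shape[0])
        except np.linalg.LinAlgError:
            jitter *= 10
    raise np.linalg.LinAlgError("covariance could not be made positive definite")


def _embed(mean: np.ndarray, cov: np.ndarray, idx: np.ndarray, params: LinkParams):
    """Lift a model state into the 8-dim full space (missing dims: 0 mean, prior var)."""
    m = np.zeros(_FULL_DIM)
    m[idx] = mean
    var = np.array(
        [0.0, 0.0]
        + [(0.5 * params.max_dist) ** 2] * 2
        + [(0.25 * params.max_dist) ** 2] * 2
        + [0.0, 0.0]
    )
    P = np.diag(var)
    P[np.ix_(idx, idx)] = cov
    return m, P


def imm_predict(state: IMMState, params: LinkParams) -> IMMPrediction:
    """Standard IMM mixing followed by one-frame propagation of each model.

    Returns per-model predicted states plus the probability-weighted combined
    measurement prediction and innovation covariance used for gating and cost.
    """
    T = params.transition
    mu = state.probs
    c = T.T @ mu  # predicted model probabilities
    c = np.clip(c, 1e-12, None)
    c /= c.sum()
    mix = (T * mu[:, None]) / c[None, :]  # mix[i, j] = P(model i | model j)
    mats, R = _model_matrices(params, state.feat_scale)

    # mix in the full space, then project to each model's subspace
    full_means, full_covs = [], []
    for j, idx in enumerate(_MODEL_IDX):
        m, P = _embed(state.means[j], state.covs[j], idx, params)
        full_means.append(m)
        full_covs.append(P)
    pred_means, pred_covs = [], []
    for j, idx in enumerate(_MODEL_IDX):
        m_mix = sum(mix[i, j] * full_means[i] for i in range(N_MODELS))
        P_mix = sum(
            mix[i, j]
            * (full_covs[i] + np.outer(full_means[i] - m_mix, full_means[i] - m_mix))
            for i in range(N_MODELS)
        )
        F, H, Q = mats[j]
        x = F @ m_mix[idx]
        P = _ensure_pd(F @ P_mix[np.ix_(idx, idx)] @ F.T + Q)
        pred_means.append(x)
        pred_covs.append(P)

    # combined measurement prediction and innovation covariance
    z_models = []
    S_models = []
    for j, idx in enumerate(_MODEL_IDX):
        F, H, Q = mats[j]
        z_models.append(H @ pred_means[j])
        S_models.append(H @ pred_covs[j] @ H.T + R)
    z_hat = sum(c[j] * z_models[j] for j in range(N_MODELS))
    S = sum(
        c[j] * (S_models[j] + np.outer(z_models[j] - z_hat, z_models[j] - z_hat))
        for j in range(N_MODELS)
    )
    return IMMPrediction(
        means=pred_means,
        covs=pred_covs,
        c=c,
        z_hat=z_hat,
        S=_ensure_pd(S),
        feat_scale=state.feat_scale,
    )


def imm_update(
    pred: IMMPrediction, det: Detection, params: LinkParams
) -> tuple[IMMState, np.ndarray]:
    """Per-model Kalman update plus likelihood-weighted model-probability update.

    Returns the updated state and the fused (x, y) position estimate.
    """
    z = np.array([det.x, det.y, det.area, det.mean_intensity], dtype=float)
    mats, R = _model_matrices(params, pred.feat_scale)
    means, covs, loglik = [], [], np.empty(N_MODELS)
    for j, idx in enumerate(_MODEL_IDX):
        F, H, Q = mats[j]
        x, P = pred.means[j], pred.covs[j]
        S = _ensure_pd(H @ P @ H.T + R)
        nu = z - H @ x
        Sinv_nu = np.linalg.solve(S, nu)
        K = P @ H.T @ np.linalg.inv(S)
        means.append(x + K @ nu)
        covs.append(_ensure_pd((np.eye(len(x)) - K @ H) @ P))
        sign, logdet = np.linalg.slogdet(S)
        loglik[j] = -0.5 * (nu @ Sinv_nu + logdet + len(z) * np.log(2 * np.pi))
    w = pred.c * np.exp(loglik - loglik.max())
    if w.sum() <= 0:
        w = pred.c.copy()
    probs = w / w.sum()
    # smooth the feature noise scales toward the current measurement
    feat = (
        0.9 * pred.feat_scale[0] + 0.1 * max(float(det.area), 1.0),
        0.9 * pred.feat_scale[1] + 0.1 * max(float(det.mean_intensity), 1.0),
    )
    state = IMMState(means=means, covs=covs, probs=probs, feat_scale=feat)
    xy = sum(probs[j] * means[j][:2] for j in range(N_MODELS))
    return state, xy


def coast(pred: IMMPrediction) -> IMMState:
    """Advance a track without a measurement (gap frame): keep predictions."""
    return IMMState(
        means=[m.copy() for m in pred.means],
        covs=[P.copy() for P in pred.covs],
        probs=pred.c.copy(),
        feat_scale=pred.feat_scale,
    )


def association_cost(
    pred: IMMPrediction, det: Detection, params: LinkParams
) -> float:
    """Gated association cost between a prediction and a detection.

    Mahalanobis distance of the position innovation plus
    ``morph_weight * (|d area| / mean area + |d intensity| / mean intensity)``;
    infinite beyond the Euclidean gate ``max_dist``.
    """
    dx = det.x - pred.z_hat[0]
    dy = det.y - pred.z_hat[1]
    if np.hypot(dx, dy) > params.max_dist:
        return np.inf
    S_pos = pred.S[:2, :2]
    d = np.array([dx, dy])
    maha = float(np.sqrt(d @ np.linalg.solve(S_pos, d)))
    cost = maha
    if params.morph_weight > 0:
        mean_a = 0.5 * (pred.z_hat[2] + det.area)
        mean_i = 0.5 * (pred.z_hat[3] + det.mean_intensity)
        da = abs(det.area - pred.z_hat[2]) / mean_a if mean_a > 0 else 0.0
        di = (
            abs(det.mean_intensity - pred.z_hat[3]) / mean_i if mean_i > 0 else 0.0
        )
        cost += params.morph_weight * (da + di)
    return cost


_BIG = 1e9


def _skip_penalty(pred: IMMPrediction, params: LinkParams) -> float:
    """Non-assignment penalty: the cost of a match at the gate radius."""
    s_max = float(np.max(np.linalg.eigvalsh(pred.S[:2, :2])))
    return params.max_dist / np.sqrt(max(s_max, 1e-12))


def assign(
    predictions: list[IMMPrediction],
    detections: list[Detection],
    params: LinkParams,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally optimal gated assignment of detections to track predictions.

    Solves a linear-sum assignment on the gated cost matrix augmented with
    per-track and per-detection skip options priced at the gate-radius cost.
    Returns (matches, unmatched_track_indices, unmatched_detection_indices).
    """
    n, m = len(predictions), len(detections)
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    C = np.full((n + m, m + n), _BIG)
    for i, pred in enumerate(predictions):
        for j, det in enumerate(detections):
            c = association_cost(pred, det, params)
            if np.isfinite(c):
                C[i, j] = c
    penalties = np.array([_skip_penalty(p, params) for p in predictions])
    det_penalty = float(np.median(penalties))
    for i in range(n):
        C[i, m + i] = penalties[i]
    for j in range(m):
        C[n + j, j] = det_penalty
    C[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(C)
    matches = []
    unmatched_tracks = []
    unmatched_dets = []
    for r, c in zip(rows, cols):
        if r < n and c < m:
            if C[r, c] < _BIG / 2:
                matches.append((r, c))
            else:  # forced infeasible pairing: both sides unmatched
                unmatched_tracks.append(r)
                unmatched_dets.append(c)
        elif r < n:
            unmatched_tracks.append(r)
        elif c < m:
            unmatched_dets.append(c)
    return matches, unmatched_tracks, unmatched_dets


@dataclass
class _ActiveTrack:
    id: int
    state: IMMState
    points: list[TrackPoint]
    misses: int = 0
    n_real: int = 0


def _finalize(at: _ActiveTrack, params: LinkParams) -> Track | None:
    points = list(at.points)
    while points and points[-1].interpolated:
        points.pop()
    if sum(not p.interpolated for p in points) < params.min_track_length:
        return None
    return Track(id=at.id, points=points)


def link_tracks(
    detections_per_frame: list[list[Detection]],
    params: LinkParams | None = None,
) -> list[Track]:
    """Link per-frame detections into trajectories with the IMM filter.

    Frame by frame: predict every active track, associate globally, update
    matched tracks, coast unmatched tracks on their predictions for up to
    ``max_gap`` frames (gap-filled points flagged ``interpolated``), start new
    tracks from unmatched detections, and finally drop tracks with fewer than
    ``min_track_length`` real detections.
    """
    params = params or LinkParams()
    if len(detections_per_frame) < 2:
        raise ValueError("need at least two frames to link")
    active: list[_ActiveTrack] = []
    finished: list[Track] = []
    next_id = 0

    def new_track(det: Detection, frame: int) -> _ActiveTrack:
        nonlocal next_id
        st = IMMState.from_detection(det, params)
        tp = TrackPoint(
            frame=frame, x=det.x, y=det.y, interpolated=False,
            area=float(det.area), mean_intensity=det.mean_intensity,
            model_probs=tuple(st.probs),
        )
        at = _ActiveTrack(id=next_id, state=st, points=[tp], n_real=1)
        next_id += 1
        return at

    for det in detections_per_frame[0]:
        active.append(new_track(det, 0))

    for t in range(1, len(detections_per_frame)):
        dets = detections_per_frame[t]
        preds = [imm_predict(at.state, params) for at in active]
        matches, un_tracks, un_dets = assign(preds, dets, params)
        survivors: list[_ActiveTrack] = []
        for i, j in matches:
            at = active[i]
            at.state, xy = imm_update(preds[i], dets[j], params)
            at.points.append(
                TrackPoint(
                    frame=t, x=dets[j].x, y=dets[j].y, interpolated=False,
                    area=float(dets[j].area),
                    mean_intensity=dets[j].mean_intensity,
                    model_probs=tuple(at.state.probs),
                )
            )
            at.misses = 0
            at.n_real += 1
            survivors.append(at)
        for i in un_tracks:
            at = active[i]
            at.misses += 1
            if at.misses <= params.max_gap:
                at.state = coast(preds[i])
                z = preds[i].z_hat
                at.points.append(
                    TrackPoint(
                        frame=t, x=float(z[0]), y=float(z[1]), interpolated=True,
                        area=float(z[2]), mean_intensity=float(z[3]),
                        model_probs=tuple(preds[i].c),
                    )
                )
                survivors.append(at)
            else:
                tr = _finalize(at, params)
                if tr is not None:
                    finished.append(tr)
        for j in un_dets:
            survivors.append(new_track(dets[j], t))
        active = survivors

    for at in active:
        tr = _finalize(at, params)
        if tr is not None:
            finished.append(tr)
    finished.sort(key=lambda tr: tr.id)
    logger.info("linked %d tracks", len(finished))
    return finished
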