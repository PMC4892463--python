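"""Synthetic ground-truthed movie generation.

Generates fluorescence-spot movies with the statistical structure typical of
single-particle-tracking benchmarks: isotropic Gaussian spots on a flat
background, Brownian / directed / caged motion, and a Poisson + additive
Gaussian camera noise model (defaults: mean 5, s.d. 30 grey levels on 8-bit
data).  Every movie comes with exact ground truth, so the detection, linking,
metric and motion-analysis modules are testable without external datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import FrameStack, GroundTruth, TrueTrack

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseSpec",
    "MotionSpec",
    "DENSITY_TRACK_COUNTS",
    "simulate_tracks",
    "render_frames",
    "add_noise",
    "measure_snr",
    "amplitude_for_snr",
]

#: Track counts that realise the low/medium/high density presets on a
#: 512x512 field; scale by area for other field sizes.
DENSITY_TRACK_COUNTS = {"low": 500, "medium": 2500, "high": 5000}


@dataclass
class NoiseSpec:
    """Camera noise model: Poisson shot noise then additive Gaussian read noise.

    The default Gaussian component (mean 5, s.d. 30 grey levels, 8-bit output)
    reproduces a standard severe-noise benchmark regime.
    """

    poisson: bool = True
    gaussian_mean: float = 5.0
    gaussian_sd: float = 30.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass
class MotionSpec:
    """Per-track motion model.

    ``brownian``: i.i.d. Gaussian steps of s.d. ``step_sd`` per axis.
    ``directed``: Brownian steps plus a constant drift velocity.
    ``caged``: Brownian steps confined to a disc of radius ``cage_radius``
    around the starting point by specular (billiard) reflection at the cage
    wall; the particle never leaves its cage.
    """

    model: str = "brownian"
    step_sd: float = 1.0
    drift: tuple[float, float] = (0.0, 0.0)
    cage_radius: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "directed", "caged"):
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.model == "caged" and (self.cage_radius is None or self.cage_radius <= 0):
            raise ValueError("caged motion requires cage_radius > 0")


def _reflect_into_disc(p: np.ndarray, step: np.ndarray, radius: float) -> np.ndarray:
    """One displacement inside a disc centred at the origin, with specular
    reflection off the wall (iterated for multiple wall contacts)."""
    d = step.astype(float)
    p = p.astype(float)
    for _ in range(16):
        q = p + d
        if q @ q <= radius * radius:
            return q
        # first intersection of the segment p -> p+d with the circle
        a = d @ d
        b = 2.0 * (p @ d)
        c = p @ p - radius * radius
        disc = max(b * b - 4 * a * c, 0.0)
        t = np.clip((-b + np.sqrt(disc)) / (2 * a), 0.0, 1.0)
        hit = p + t * d
        n = hit / max(np.hypot(*hit), 1e-12)
        remainder = (1.0 - t) * d
        d = remainder - 2.0 * (remainder @ n) * n
        p = hit
    # numerical corner case: give up and clamp just inside the wall
    r = max(np.hypot(*p), 1e-12)
    return p * min(1.0, 0.999 * radius / r)


def _reflect_scalar(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by repeated reflection at the boundaries."""
    if hi <= lo:
        return np.clip(v, lo, hi)
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def simulate_tracks(
    n_tracks: int,
    n_frames: int,
    shape: tuple[int, int] = (512, 512),
    motion: MotionSpec | None = None,
    seed: int = 0,
    amplitude: float = 100.0,
    sigma: float = 1.5,
    margin: float | None = None,
    min_separation: float | None = None,
) -> GroundTruth:
    """Draw `n_tracks` ground-truth trajectories of `n_frames` steps each.

    Starting points are uniform inside the image minus a `margin` (default
    ``3 * sigma``, plus the cage radius for caged motion).  Positions are kept
    in bounds by reflection, so coordinates are always renderable.  With
    ``min_separation`` set, starting points are rejection-sampled to be at
    least that far apart; an impossible request raises ``ValueError``.

    Identical seeds reproduce the output exactly.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    motion = motion or MotionSpec()
    rng = np.random.default_rng(seed)
    h, w = shape
    if margin is None:
        margin = 3.0 * sigma
        if motion.model == "caged":
            margin += motion.cage_radius
    lo_x, hi_x = margin, w - 1 - margin
    lo_y, hi_y = margin, h - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("image shape too small for the requested margin")

    # starting points (optionally with a minimum pairwise separation)
    starts = np.empty((n_tracks, 2))
    if min_separation is None:
        starts[:, 0] = rng.uniform(lo_x, hi_x, n_tracks)
        starts[:, 1] = rng.uniform(lo_y, hi_y, n_tracks)
    else:
        placed = 0
        attempts = 0
        max_attempts = 1000 * n_tracks
        while placed < n_tracks:
            if attempts >= max_attempts:
                raise ValueError(
                    "image shape too small to place "
                    f"{n_tracks} tracks with min_separation={min_separation}"
                )
            cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
            attempts += 1
            if placed == 0 or np.min(
                np.hypot(*(starts[:placed] - cand).T)
            ) >= min_separation:
                starts[placed] = cand
                placed += 1

    tracks = []
    frames = np.arange(n_frames)
    for i in range(n_tracks):
        steps = rng.normal(0.0, motion.step_sd, size=(n_frames - 1, 2))
        if motion.model == "directed":
            steps = steps + np.asarray(motion.drift, dtype=float)
        pos = np.empty((n_frames, 2))
        pos[0] = starts[i]
        if motion.model == "caged":
            centre = starts[i]
            r = motion.cage_radius
            for t in range(1, n_frames):
                rel = _reflect_into_disc(pos[t - 1] - centre, steps[t - 1], r)
                pos[t] = centre + rel
        else:
            pos[1:] = starts[i] + np.cumsum(steps, axis=0)
        pos[:, 0] = _reflect_scalar(pos[:, 0], lo_x, hi_x)
        pos[:, 1] = _reflect_scalar(pos[:, 1], lo_y, hi_y)
        tracks.append(
            TrueTrack(
                id=i,
                frames=frames.copy(),
                x=pos[:, 0],
                y=pos[:, 1],
                amplitude=float(amplitude),
                sigma=float(sigma),
            )
        )
    return GroundTruth(tracks)


def render_frames(
    truth: GroundTruth,
    background: float = 10.0,
    shape: tuple[int, int] = (512, 512),
    n_frames: int | None = None,
) -> FrameStack:
    """Render the ground truth into a noise-free float movie.

    Each particle is an isotropic 2D Gaussian of its stated sigma and peak
    amplitude, added to a flat background.  Off-image parts are clipped
    silently.
    """
    if not truth.tracks:
        raise ValueError("ground truth is empty")
    if n_frames is None:
        n_frames = truth.n_frames
    h, w = shape
    stack = np.full((n_frames, h, w), float(background))
    for t in truth.tracks:
        half = int(np.ceil(4.0 * t.sigma))
        for k, f in enumerate(t.frames):
            if f >= n_frames:
                continue
            cx, cy = t.x[k], t.y[k]
            x0 = max(int(np.floor(cx)) - half, 0)
            x1 = min(int(np.floor(cx)) + half + 2, w)
            y0 = max(int(np.floor(cy)) - half, 0)
            y1 = min(int(np.floor(cy)) + half + 2, h)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-((xs - cx) ** 2) / (2 * t.sigma**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * t.sigma**2))
            stack[f, y0:y1, x0:x1] += t.amplitude * np.outer(gy, gx)
    return FrameStack(stack, bit_depth=16)


def add_noise(stack: FrameStack, noise: NoiseSpec | None = None, seed: int = 0) -> FrameStack:
    """Corrupt a noise-free stack with Poisson shot noise and Gaussian read noise.

    Per pixel: draw Poisson with mean equal to the clean value (if enabled),
    add a Gaussian draw of mean ``gaussian_mean`` and s.d. ``gaussian_sd``,
    then clip to the bit-depth range and quantise.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    clean = np.clip(stack.data.astype(float), 0.0, None)
    out = rng.poisson(clean).astype(float) if noise.poisson else clean.copy()
    if noise.gaussian_sd > 0:
        out += rng.normal(noise.gaussian_mean, noise.gaussian_sd, size=out.shape)
    else:
        out += noise.gaussian_mean
    max_value = 2**noise.bit_depth - 1
    out = np.clip(np.rint(out), 0, max_value)
    dtype = np.uint8 if noise.bit_depth <= 8 else np.uint16
    return FrameStack(
        out.astype(dtype),
        bit_depth=noise.bit_depth,
        frame_interval=stack.frame_interval,
        pixel_size_nm=stack.pixel_size_nm,
    )


def amplitude_for_snr(
    snr: float, background: float, noise: NoiseSpec | None = None
) -> float:
    """Peak amplitude that realises a requested SNR on a flat background.

    Inverts the noise model: the background standard deviation is
    ``sqrt(background + gaussian_sd**2)`` (Poisson variance equals its mean),
    and SNR = amplitude / background s.d.
    """
    noise = noise or NoiseSpec()
    var = noise.gaussian_sd**2 + (background if noise.poisson else 0.0)
    if var <= 0:
        raise ValueError("noise model has zero variance; SNR is undefined")
    return float(snr * np.sqrt(var))


def measure_snr(
    stack: FrameStack,
    truth: GroundTruth,
    inner_factor: float = 2.0,
    outer_factor: float = 4.0,
) -> float:
    """Measure the mean per-particle SNR of a rendered (noisy) stack.

    For each ground-truth particle, SNR = (peak - local background mean) /
    (local background s.d.), where the local background is an annulus of inner
    radius ``inner_factor * sigma`` and outer radius ``outer_factor * sigma``
    around the true position.  Particles whose annulus leaves the image are
    skipped with a warning.  A noise-free image returns ``inf``.
    """
    h, w = stack.frame_shape
    data = stack.data.astype(float)
    values: list[float] = []
    n_skipped = 0
    for t in truth.tracks:
        r_out = int(np.ceil(outer_factor * t.sigma))
        r_in = inner_factor * t.sigma
        for k, f in enumerate(t.frames):
            if f >= stack.n_frames:
                continue
            cx, cy = int(round(t.x[k])), int(round(t.y[k]))
            if (
                cx - r_out < 0
                or cx + r_out >= w
                or cy - r_out < 0
                or cy + r_out >= h
            ):
                n_skipped += 1
                continue
            patch = data[f, cy - r_out : cy + r_out + 1, cx - r_out : cx + r_out + 1]
            yy, xx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
            rr = np.hypot(xx, yy)
            ann = (rr >= r_in) & (rr <= r_out)
            # peak: brightest pixel within 1 px of the true position
            core = patch[r_out - 1 : r_out + 2, r_out - 1 : r_out + 2]
            peak = core.max()
            bg = patch[ann]
            sd = bg.std()
            # below any camera quantisation step the image is noise-free
            if sd < 1e-3:
                values.append(np.inf)
            else:
                values.append(float((peak - bg.mean()) / sd))
    if n_skipped:
        logger.warning("measure_snr: skipped %d particles too close to the border", n_skipped)
    if not values:
        raise ValueError("no particle had a valid background annulus")
    return float(np.mean(values))
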