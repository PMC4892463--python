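"""Spot detection via the particle-probability image (PPI).

The detector runs six steps per frame:

1. **PPI construction** — multi-scale Haar-like local-contrast features are
   computed (square centre-surround plus horizontal/vertical bar kernels),
   the per-pixel maximum over kernels and scales forms the contrast image,
   the top ``K = round(F * N * S)`` pixels are classified as particle pixels
   (``F`` is the enhancement factor derived from the SNR estimate and density
   class), and the PPI assigns each pixel the fraction of particle pixels in
   a particle-sized window around it.
2. **Particle-existing regions (PERs)** — connected regions of
   ``PPI >= 1/e``, soft-rethresholded region-by-region at half the region's
   maximum PPI.
3. **Markers** — local maxima of a lightly smoothed frame, restricted to
   PERs and to ``PPI > 0.5 * max PPI`` of their PER.
4. **Marker-controlled watershed** of the Sobel gradient image, with the
   non-PER complement as background marker and segments clipped to their PER.
5. **Localization** — background-subtracted intensity-weighted centre of
   mass per segment (2D Gaussian fit for very small particles, ``S < 9``),
   plus morphology and intensity descriptors.
6. **Adaptive parameter setting** — the working SNR estimate (and, if
   needed, the density class) is refined by bisection until the detection
   count agrees with the expected count ``N`` within tolerance.

Everything is deterministic; ties are broken in raster (row-major) order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.filters import sobel
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import Detection, FrameStack

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "HaarFeatureImage",
    "PERLabelMap",
    "MarkerSet",
    "enhancement_factor",
    "compute_haar_features",
    "classify_pixels",
    "compute_ppi",
    "extract_pers",
    "find_markers",
    "segment_watershed",
    "localize",
    "detect_frame",
    "adapt_params",
    "detect_stack",
]

PER_THRESHOLD = 1.0 / np.e  # base PPI threshold for particle-existing regions
PER_REFINE_FACTOR = 0.5  # region-local soft threshold: half the region max
MARKER_PPI_FACTOR = 0.5  # markers need PPI > this fraction of their PER max
MARKER_SMOOTH_FACTOR = 0.4  # marker smoothing s.d. as a fraction of sqrt(s/pi)
CLASSIFY_CAP_FRACTION = 0.25  # at most this fraction of pixels classified particle

DENSITY_MULTIPLIERS = {"low": 1.0, "medium": 1.25, "high": 1.5}
_DENSITY_ORDER = ["low", "medium", "high"]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def enhancement_factor(snr: float, density: str) -> float:
    """Particle enhancement factor ``F`` from the SNR estimate and density class.

    ``F = clamp(1 + 0.25 * max(0, 4 - snr), 1, 3) * density multiplier``
    (low 1.0, medium 1.25, high 1.5): monotone non-increasing in SNR,
    non-decreasing in density.  Noisy or dense images get more pixels
    classified as particle, enhancing weak spots.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if density not in DENSITY_MULTIPLIERS:
        raise ValueError(f"unknown density class {density!r}")
    base = np.clip(1.0 + 0.25 * max(0.0, 4.0 - snr), 1.0, 3.0)
    return float(base * DENSITY_MULTIPLIERS[density])


@dataclass
class DetectionParams:
    """The five user parameters of the detector.

    ``S`` and ``s`` are the typical and minimum particle sizes (areas in
    pixels); ``N`` is the expected number of particles per frame; ``density``
    is the qualitative particle-density class; ``snr`` the estimated
    signal-to-noise ratio.  ``F`` is derived unless given explicitly.
    """

    S: int
    s: int
    N: int
    density: str = "medium"
    snr: float = 4.0
    F: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.s <= self.S):
            raise ValueError("need 1 <= s <= S")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.F is None:
            self.F = enhancement_factor(self.snr, self.density)
        if self.F < 1:
            raise ValueError("F must be >= 1")


@dataclass
class HaarFeatureImage:
    """Per-pixel maximal multi-scale local contrast (grey-level units)."""

    values: np.ndarray
    scales: list[int]  # inner-window widths used, pixels


@dataclass
class PERLabelMap:
    """8-connected particle-existing regions; label 0 is background."""

    labels: np.ndarray
    n_regions: int


@dataclass
class MarkerSet:
    """Watershed seed pixels: ``(row, col)`` positions with their PER id."""

    rows: np.ndarray
    cols: np.ndarray
    per_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)


def _nearest_odd(x: float) -> int:
    """Nearest odd integer >= 1 (ties resolved upward)."""
    k = int(np.floor(x))
    lo = k if k % 2 == 1 else k - 1
    hi = lo + 2
    lo = max(lo, 1)
    return lo if (x - lo) < (hi - x) else hi


def _mean_filter(frame: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return ndimage.uniform_filter(frame, size=size, mode="reflect")


def compute_haar_features(frame: np.ndarray, S: int, s: int) -> HaarFeatureImage:
    """Multi-scale Haar-like local-contrast image.

    Three kernel geometries per scale — square centre-surround, horizontal
    bar and vertical bar — each responding with ``mean(inner window) -
    mean(surround)``; the surround ring/strips are as wide as the inner
    half-width.  Scales span inner widths from the minimum-particle to twice
    the typical-particle equivalent width.  The output is the per-pixel
    maximum over kernels and scales; borders are handled by reflection.
    Mean-difference kernels are DC-free, so a constant offset leaves the
    result unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    w_min = _nearest_odd(np.sqrt(s))
    w_max = max(_nearest_odd(2.0 * np.sqrt(S)), w_min)
    out = np.full_like(frame, -np.inf)
    scales: list[int] = []
    for win in range(w_min, w_max + 1, 2):
        half = max((win - 1) // 2, 1)
        w_out = win + 2 * half
        if w_out > min(h, w):
            logger.warning("haar scale %d (outer %d) larger than image; skipped", win, w_out)
            continue
        scales.append(win)
        inner_sq = _mean_filter(frame, (win, win))
        outer_sq = _mean_filter(frame, (w_out, w_out))
        ring = (outer_sq * w_out**2 - inner_sq * win**2) / (w_out**2 - win**2)
        np.maximum(out, inner_sq - ring, out=out)
        # horizontal bar: inner strip win rows tall, w_out wide; surround above/below
        inner_h = _mean_filter(frame, (win, w_out))
        outer_h = _mean_filter(frame, (w_out, w_out))
        strips_h = (outer_h * w_out**2 - inner_h * win * w_out) / (w_out**2 - win * w_out)
        np.maximum(out, inner_h - strips_h, out=out)
        # vertical bar
        inner_v = _mean_filter(frame, (w_out, win))
        strips_v = (outer_h * w_out**2 - inner_v * win * w_out) / (w_out**2 - win * w_out)
        np.maximum(out, inner_v - strips_v, out=out)
    if not scales:
        raise ValueError("no Haar scale fits inside the image")
    return HaarFeatureImage(values=out, scales=scales)


def classify_pixels(haar: HaarFeatureImage, params: DetectionParams) -> np.ndarray:
    """Classify the ``K = round(F * N * S)`` strongest feature pixels as particle.

    ``K`` is capped at 25% of the image; ties are broken in raster order.
    Raises if the requested ``K`` reaches the whole image.
    """
    values = haar.values
    n = values.size
    K = int(round(params.F * params.N * params.S))
    if K >= n:
        raise ValueError(
            f"K={K} covers the whole {values.shape} image; parameters inconsistent"
        )
    K = min(K, int(CLASSIFY_CAP_FRACTION * n))
    mask = np.zeros(n, dtype=bool)
    if K > 0:
        # stable sort on the negated values keeps raster order among ties
        order = np.argsort(-values.ravel(), kind="stable")
        mask[order[:K]] = True
    return mask.reshape(values.shape)


def compute_ppi(binary: np.ndarray, S: int) -> np.ndarray:
    """Particle-probability image from the particle/background classification.

    ``PPI(p)`` is the fraction of particle pixels in the ``w x w`` window
    centred at ``p``, with ``w`` the nearest odd integer to ``sqrt(S)``;
    windows at the border use their intersection with the image.
    """
    w = _nearest_odd(np.sqrt(S))
    b = binary.astype(float)
    counts = ndimage.uniform_filter(b, size=w, mode="constant", cval=0.0) * w**2
    denom = (
        ndimage.uniform_filter(np.ones_like(b), size=w, mode="constant", cval=0.0)
        * w**2
    )
    return np.clip(counts / denom, 0.0, 1.0)


def extract_pers(ppi: np.ndarray, s: int = 1) -> PERLabelMap:
    """Particle-existing regions by soft thresholding of the PPI.

    The initial mask is ``PPI >= 1/e``; each 8-connected region is then
    re-thresholded at ``max(1/e, 0.5 * region max PPI)`` so that strong and
    weak regions each keep only their relatively strong pixels.  Regions
    smaller than the minimum particle size ``s`` are discarded.
    """
    mask = ppi >= PER_THRESHOLD - 1e-12
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return PERLabelMap(labels=labels, n_regions=0)
    region_max = ndimage.maximum(ppi, labels, index=np.arange(1, n + 1))
    thr = np.maximum(PER_THRESHOLD, PER_REFINE_FACTOR * np.asarray(region_max))
    thr_map = np.zeros(n + 1)
    thr_map[1:] = thr
    refined = mask & (ppi >= thr_map[labels] - 1e-12)
    labels, n = ndimage.label(refined, structure=_EIGHT)
    if n and s > 1:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        keep = areas >= s
        keep[0] = False
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[labels]
        n = int(keep.sum())
    return PERLabelMap(labels=labels, n_regions=n)


def find_markers(
    frame: np.ndarray, pers: PERLabelMap, ppi: np.ndarray, s: int
) -> MarkerSet:
    """Watershed seeds: smoothed-image local maxima inside PERs.

    The frame is smoothed with a Gaussian of s.d.
    ``MARKER_SMOOTH_FACTOR * sqrt(s / pi)`` — a fraction of the
    equivalent-disc radius of the minimum particle area.  The smoothing is
    deliberately light: its role is numerical stabilisation of local-maxima
    extraction, and heavier smoothing measurably merges the maxima of
    particle pairs a few pixels apart, while the noise maxima admitted by
    light smoothing are largely absorbed by the PPI gate below and the
    minimum-area merge in the watershed step.  Markers are strict
    8-neighbourhood local maxima of the smoothed image (plateaus collapse to
    their centroid pixel) that lie inside a PER and whose PPI exceeds half
    the maximum PPI of that PER.  A PER without a qualifying maximum falls
    back to its PPI-maximum pixel.
    """
    rows: list[int] = []
    cols: list[int] = []
    ids: list[int] = []
    if pers.n_regions == 0:
        return MarkerSet(np.array([], int), np.array([], int), np.array([], int))
    sigma_g = MARKER_SMOOTH_FACTOR * np.sqrt(s / np.pi)
    smooth = ndimage.gaussian_filter(np.asarray(frame, dtype=float), sigma_g, mode="reflect")
    cand = smooth >= ndimage.maximum_filter(smooth, size=3, mode="reflect")
    per_max = ndimage.maximum(ppi, pers.labels, index=np.arange(1, pers.n_regions + 1))
    per_max = np.concatenate([[0.0], np.asarray(per_max, dtype=float).ravel()])
    # restrict candidates to PERs before labelling plateaus (cheap and safe:
    # a plateau straddling a PER edge collapses within the PER part)
    cand &= pers.labels > 0
    comp, n_comp = ndimage.label(cand, structure=_EIGHT)
    if n_comp:
        centroids = ndimage.center_of_mass(cand, comp, index=np.arange(1, n_comp + 1))
        for ci, (cy, cx) in enumerate(centroids, start=1):
            ry, rx = int(round(cy)), int(round(cx))
            if comp[ry, rx] != ci:
                # centroid fell outside a non-convex plateau: nearest member pixel
                ys, xs = np.nonzero(comp == ci)
                k = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
                ry, rx = int(ys[k]), int(xs[k])
            per_id = int(pers.labels[ry, rx])
            if per_id == 0:
                continue
            if ppi[ry, rx] > MARKER_PPI_FACTOR * per_max[per_id]:
                rows.append(ry)
                cols.append(rx)
                ids.append(per_id)
    # fallback: a PER with no qualifying maximum uses its PPI-maximum pixel
    have = set(ids)
    missing = [p for p in range(1, pers.n_regions + 1) if p not in have]
    if missing:
        logger.warning("%d PER(s) had no qualifying local maximum; using PPI peak", len(missing))
        pos = ndimage.maximum_position(ppi, pers.labels, index=missing)
        if isinstance(pos, tuple):  # single region: a bare (row, col) tuple
            pos = [pos]
        for per_id, (ry, rx) in zip(missing, pos):
            rows.append(int(ry))
            cols.append(int(rx))
            ids.append(per_id)
    return MarkerSet(np.asarray(rows, int), np.asarray(cols, int), np.asarray(ids, int))


def segment_watershed(
    frame: np.ndarray, markers: MarkerSet, pers: PERLabelMap, s: int = 1
) -> np.ndarray:
    """Marker-controlled watershed of the gradient image, restricted to PERs.

    The Sobel gradient magnitude of the raw frame is flooded from the particle
    markers, with the non-PER complement excluded from flooding (the
    background restriction).  A PER containing one marker therefore becomes
    one segment equal to the PER; a PER with several markers is partitioned
    between them along the gradient ridges.  Each catchment is finally
    intersected with its marker's PER, so no pixel outside a PER is ever
    labelled.  Segments smaller than ``s`` are merged into the largest
    adjacent segment of the same PER, or discarded if isolated.

    Returns an integer label map (0 = background), one segment per marker.
    """
    h, w = frame.shape
    if len(markers) == 0:
        return np.zeros((h, w), dtype=np.int32)
    grad = sobel(np.asarray(frame, dtype=float))
    seeds = np.zeros((h, w), dtype=np.int32)
    for i in range(len(markers)):
        seeds[markers.rows[i], markers.cols[i]] = i + 2
    ws = watershed(grad, markers=seeds, mask=pers.labels > 0)
    segments = np.zeros((h, w), dtype=np.int32)
    for i in range(len(markers)):
        seg = (ws == i + 2) & (pers.labels == markers.per_ids[i])
        segments[seg] = i + 1
    # merge undersized segments into their largest neighbour within the PER
    if s > 1:
        areas = np.bincount(segments.ravel(), minlength=len(markers) + 1)
        small = [l for l in range(1, len(markers) + 1) if 0 < areas[l] < s]
        for l in sorted(small, key=lambda l: areas[l]):
            seg = segments == l
            dil = ndimage.binary_dilation(seg, structure=_EIGHT) & ~seg
            neigh = np.unique(segments[dil])
            neigh = [
                int(m)
                for m in neigh
                if m > 0 and markers.per_ids[m - 1] == markers.per_ids[l - 1]
            ]
            if neigh:
                target = max(neigh, key=lambda m: np.count_nonzero(segments == m))
                segments[seg] = target
            else:
                segments[seg] = 0
    return segments


def _gaussian_fit(patch: np.ndarray, x0: float, y0: float) -> tuple[float, float] | None:
    """Least-squares isotropic 2D Gaussian fit on a small window.

    Returns the fitted (x, y) in patch coordinates, or None on divergence.
    """
    ph, pw = patch.shape
    yy, xx = np.mgrid[0:ph, 0:pw]
    offset = float(patch.min())
    amp = float(patch.max() - offset)
    if amp <= 0:
        return None

    def resid(p):
        a, cx, cy, sig, c = p
        model = a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2)) + c
        return (model - patch).ravel()

    try:
        res = least_squares(
            resid,
            x0=[amp, x0, y0, 1.0, offset],
            bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, pw, ph, max(ph, pw), np.inf]),
            max_nfev=200,
        )
    except Exception:  # pragma: no cover - optimizer pathologies
        return None
    if not res.success:
        return None
    _, cx, cy, _, _ = res.x
    if not (0 <= cx <= pw - 1 and 0 <= cy <= ph - 1):
        return None
    return float(cx), float(cy)


def localize(
    frame: np.ndarray,
    segments: np.ndarray,
    S: int,
    frame_index: int = 0,
    markers: MarkerSet | None = None,
) -> list[Detection]:
    """Sub-pixel localization and shape/intensity description per segment.

    For typical particles (``S >= 9``) the position is the intensity-weighted
    centre of mass over the segment after background subtraction (negative
    residuals clipped to zero).  The background has two parts: the median of
    the segment-boundary ring (just outside the segment, excluding other
    segments) estimates the local background, and, for segments with interior
    pixels, the median residual on the segment's own rim is removed as well —
    the segment is bounded by an isophote, and centroiding the intensity
    *above* that isophote eliminates the truncation discontinuity that
    otherwise biases the centroid toward the pixel grid.  For very small particles
    (``S < 9``) a 2D Gaussian is fitted in a 7x7 window seeded at the
    marker, falling back to the weighted centroid on divergence.

    Circularity is ``4 * pi * area / perimeter**2`` (clipped to (0, 1]);
    major/minor axes come from the second moments of the segment.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    detections: list[Detection] = []
    marker_by_label: dict[int, tuple[int, int]] = {}
    if markers is not None:
        for i in range(len(markers)):
            marker_by_label[i + 1] = (int(markers.rows[i]), int(markers.cols[i]))
    for prop in regionprops(segments, intensity_image=frame):
        lbl = prop.label
        # pad the bounding box by one pixel so the outer boundary ring fits
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(prop.slice, (h, w))
        )
        seg = segments[sl] == lbl
        patch = frame[sl]
        ring = ndimage.binary_dilation(seg, structure=_EIGHT) & (segments[sl] == 0)
        interior = ndimage.binary_erosion(seg)
        rim = seg & ~interior
        if ring.any():
            bg = float(np.median(patch[ring]))
        else:  # fully enclosed by other segments: use the segment rim instead
            bg = float(np.median(patch[rim])) if rim.any() else 0.0
        resid = np.clip(patch - bg, 0.0, None) * seg
        if interior.any() and rim.any():
            # remove the boundary-isophote pedestal (see docstring)
            resid = np.clip(resid - np.median(resid[rim]), 0.0, None) * seg
        total = resid.sum()
        y_off, x_off = sl[0].start, sl[1].start
        if total > 0:
            ys, xs = np.nonzero(seg)
            cx = float((resid[ys, xs] * xs).sum() / total) + x_off
            cy = float((resid[ys, xs] * ys).sum() / total) + y_off
        else:
            cy, cx = prop.centroid
        fallback = False
        if S < 9:
            my, mx = marker_by_label.get(lbl, (int(round(cy)), int(round(cx))))
            half = 3
            y0, y1 = max(my - half, 0), min(my + half + 1, h)
            x0, x1 = max(mx - half, 0), min(mx + half + 1, w)
            fit = _gaussian_fit(frame[y0:y1, x0:x1], mx - x0, my - y0)
            if fit is not None:
                cx, cy = fit[0] + x0, fit[1] + y0
            else:
                fallback = True
        perim = prop.perimeter
        circularity = 4 * np.pi * prop.area / perim**2 if perim > 0 else 1.0
        circularity = float(np.clip(circularity, 1e-6, 1.0))
        detections.append(
            Detection(
                frame=frame_index,
                x=cx,
                y=cy,
                area=int(prop.area),
                circularity=circularity,
                major_axis=float(prop.axis_major_length),
                minor_axis=float(prop.axis_minor_length),
                mean_intensity=float(prop.intensity_mean),
                peak_intensity=float(prop.intensity_max),
                label=int(lbl),
                fit_fallback=fallback,
            )
        )
    return detections


def detect_frame(
    frame: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[Detection]:
    """Run the full per-frame detection pipeline (steps 1-5)."""
    haar = compute_haar_features(frame, params.S, params.s)
    binary = classify_pixels(haar, params)
    ppi = compute_ppi(binary, params.S)
    pers = extract_pers(ppi, params.s)
    markers = find_markers(frame, pers, ppi, params.s)
    segments = segment_watershed(frame, markers, pers, params.s)
    return localize(frame, segments, params.S, frame_index=frame_index, markers=markers)


def adapt_params(
    params: DetectionParams,
    frame: np.ndarray,
    tolerance: float = 0.2,
    max_iterations: int = 10,
    frame_index: int = 0,
) -> tuple[DetectionParams, list[Detection]]:
    """Adaptive parameter setting (step 6).

    Detects, compares the detection count with the expected count ``N`` and,
    while the relative difference exceeds `tolerance`, bisects the working
    SNR estimate over [0.5, 10] (fewer detections than expected => lower SNR
    estimate => larger enhancement factor => more pixels classified), stepping
    the density class only when the SNR bounds are exhausted.  Returns the
    best iterate if the loop does not converge.
    """
    if not (0 < tolerance < 1):
        raise ValueError("tolerance must be in (0, 1)")
    lo, hi = 0.5, 10.0
    snr_w = float(np.clip(params.snr, lo, hi))
    density = params.density
    best: tuple[int, DetectionParams, list[Detection]] | None = None
    for it in range(max_iterations):
        p = replace(params, snr=snr_w, density=density, F=None)
        dets = detect_frame(frame, p, frame_index=frame_index)
        diff = abs(len(dets) - params.N)
        logger.debug(
            "adapt iteration %d: snr=%.3f density=%s detected=%d expected=%d",
            it, snr_w, density, len(dets), params.N,
        )
        if best is None or diff < best[0]:
            best = (diff, p, dets)
        if diff <= tolerance * params.N:
            return p, dets
        if len(dets) < params.N:
            hi = snr_w  # need a larger F
        else:
            lo = snr_w
        if hi - lo < 0.05:
            di = _DENSITY_ORDER.index(density)
            step = 1 if len(dets) < params.N else -1
            if 0 <= di + step < len(_DENSITY_ORDER):
                density = _DENSITY_ORDER[di + step]
                lo, hi = 0.5, 10.0
                snr_w = float(np.clip(params.snr, lo, hi))
                continue
            break  # parameter space exhausted
        snr_w = 0.5 * (lo + hi)
    logger.warning(
        "adapt_params did not converge in %d iterations (best |diff|=%d)",
        max_iterations, best[0],
    )
    return best[1], best[2]


def detect_stack(
    stack: FrameStack,
    params: DetectionParams,
    adaptive: bool = True,
    tolerance: float = 0.2,
    max_iterations: int = 10,
) -> list[list[Detection]]:
    """Detect every frame of a stack.

    With ``adaptive=True`` the expected count ``N`` for frame ``t + 1`` is
    updated to the number of particles detected in frame ``t``, and the
    working parameters are refined per frame.
    """
    out: list[list[Detection]] = []
    current = params
    for t in range(stack.n_frames):
        if adaptive:
            p, dets = adapt_params(
                current, stack.data[t], tolerance=tolerance,
                max_iterations=max_iterations, frame_index=t,
            )
            current = replace(p, N=max(len(dets), 1))
        else:
            dets = detect_frame(stack.data[t], current, frame_index=t)
        logger.info("frame %d: %d detections", t, len(dets))
        out.append(dets)
    return out
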