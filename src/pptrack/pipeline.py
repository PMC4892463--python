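"""End-to-end pipeline: simulate -> detect -> link -> evaluate -> analyze."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as pio
from .core import FrameStack, GroundTruth
from .detect import detect_stack
from .link import link_tracks
from .metrics import evaluate
from .motion import rose_histogram, step_angles, switch_angles, track_density
from .simulate import (
    MotionSpec,
    NoiseSpec,
    add_noise,
    amplitude_for_snr,
    render_frames,
    simulate_tracks,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _simulate_stage(cfg: pio.PipelineConfig, out: Path) -> tuple[FrameStack, GroundTruth]:
    sc = dict(cfg.simulate)
    sc.pop("enabled", None)
    shape = tuple(sc.pop("shape", (256, 256)))
    noise_cfg = sc.pop("noise", {})
    noise = NoiseSpec(**noise_cfg) if isinstance(noise_cfg, dict) else NoiseSpec()
    snr = sc.pop("snr", 4.0)
    background = sc.pop("background", 20.0)
    motion = MotionSpec(
        model=sc.pop("motion", "brownian"),
        step_sd=sc.pop("step_sd", 1.0),
        drift=tuple(sc.pop("drift", (0.0, 0.0))),
        cage_radius=sc.pop("cage_radius", None),
    )
    amplitude = amplitude_for_snr(snr, background, noise)
    truth = simulate_tracks(
        n_tracks=sc.pop("n_tracks", 100),
        n_frames=sc.pop("n_frames", 50),
        shape=shape,
        motion=motion,
        seed=cfg.seed,
        amplitude=amplitude,
        sigma=sc.pop("sigma", 1.5),
        min_separation=sc.pop("min_separation", None),
    )
    clean = render_frames(truth, background=background, shape=shape)
    stack = add_noise(clean, noise, seed=cfg.seed + 1)
    pio.write_stack(out / "movie.tif", stack)
    pio.write_truth(out / "truth.csv", truth)
    logger.info(
        "simulate: %d tracks, %d frames, %s, SNR %.2f (amplitude %.1f)",
        len(truth), truth.n_frames, shape, snr, amplitude,
    )
    return stack, truth


def run_pipeline(cfg: pio.PipelineConfig, stages: set[str] | None = None) -> dict:
    """Run the configured pipeline stages and write their artifacts.

    Stages: ``simulate`` (optional; otherwise ``cfg.input`` is read),
    ``detect``, ``link``, ``evaluate`` (if ground truth is available) and
    ``analyze``.  Every stage logs its parameters and result counts; a fixed
    seed makes all outputs reproducible.  Returns a summary dict with the
    artifact paths and, if evaluated, the metrics report.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("resolved config: %s", cfg.resolved())
    summary: dict = {"output_dir": str(out)}
    stages = stages or {"simulate", "detect", "link", "evaluate", "analyze"}

    truth = None
    if cfg.simulate.get("enabled", False) and "simulate" in stages:
        stack, truth = _simulate_stage(cfg, out)
        summary["movie"] = str(out / "movie.tif")
        summary["truth"] = str(out / "truth.csv")
    elif cfg.input:
        stack = pio.read_stack(cfg.input)
        logger.info("loaded %s: %d frames of %s", cfg.input, stack.n_frames, stack.frame_shape)
    else:
        raise ValueError("no input movie: enable simulation or set an input path")
    if cfg.truth:
        truth = pio.read_truth(cfg.truth)

    if "detect" not in stages:
        return summary
    params = cfg.detection_params()
    detections = detect_stack(
        stack, params,
        adaptive=cfg.detect.get("adaptive", True),
        tolerance=cfg.detect.get("tolerance", 0.2),
        max_iterations=cfg.detect.get("max_iterations", 10),
    )
    pio.write_detections(out / "detections.csv", detections)
    summary["detections"] = str(out / "detections.csv")
    summary["n_detections"] = int(sum(len(d) for d in detections))

    if "link" not in stages:
        return summary
    tracks = link_tracks(detections, cfg.link_params())
    pio.write_tracks(out / "tracks.csv", tracks)
    summary["tracks"] = str(out / "tracks.csv")
    summary["n_tracks"] = len(tracks)

    if truth is not None and "evaluate" in stages:
        report = evaluate(
            tracks, truth, cfg.matching_spec(), theta=cfg.evaluate.get("theta", 0.8)
        )
        pio.write_json(out / "report.json", report.as_dict())
        summary["report"] = str(out / "report.json")
        summary["metrics"] = report.as_dict()
        logger.info("metrics: %s", report.as_dict())

    if "analyze" in stages:
        n_bins = cfg.analyze.get("n_angle_bins", 36)
        incl = cfg.analyze.get("include_interpolated", False)
        t1, lengths, t2 = [], [], []
        for tr in tracks:
            a, ell, _ = step_angles(tr, include_interpolated=incl)
            t1.append(a)
            lengths.append(ell)
            t2.append(
                switch_angles(
                    tr, include_interpolated=incl,
                    signed=cfg.analyze.get("signed_theta2", False),
                )
            )
        t1 = np.concatenate(t1) if t1 else np.array([])
        lengths = np.concatenate(lengths) if lengths else np.array([])
        t2 = np.concatenate(t2) if t2 else np.array([])
        rose1 = rose_histogram(t1, lengths, n_angle_bins=n_bins)
        rose2 = rose_histogram(
            np.abs(t2), None, n_angle_bins=n_bins, angle_range=(0.0, 180.0)
        )
        import pandas as pd

        for name, rose in [("theta1", rose1), ("theta2", rose2)]:
            df = pd.DataFrame(
                rose.counts,
                index=[f"{a:.1f}" for a in rose.angle_edges[:-1]],
                columns=[f"{l:.3g}" for l in rose.length_edges[:-1]],
            )
            df.index.name = "angle_bin_start_deg"
            with pio._atomic_path(out / f"rose_{name}.csv") as tmp:
                df.to_csv(tmp)
        density = track_density(tracks, stack.frame_shape)
        pio.write_stack(
            out / "density.tif",
            FrameStack(density.astype(np.uint16)[None], bit_depth=16),
        )
        summary["rose_theta1"] = str(out / "rose_theta1.csv")
        summary["rose_theta2"] = str(out / "rose_theta2.csv")
        summary["density"] = str(out / "density.tif")
    return summary
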