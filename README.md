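# pptrack

Automated single-particle detection and trajectory linking for 2D+t
fluorescence microscopy movies in low signal-to-noise conditions — vesicles
under TIRF illumination, sptPALM single-molecule data, and similar
spot-tracking problems where particles are a few pixels wide and barely rise
above camera noise.

## What it does

**Detection** avoids explicit denoising. Multi-scale Haar-like features
(inner-window mean minus surround mean, three kernel shapes) turn each frame
into a contrast image; the `K = round(F·N·S)` strongest pixels are classified
as particle pixels, where `S` is the typical particle area, `N` the expected
particle count and `F` an enhancement factor determined by the SNR estimate
and density class. The *particle probability image* (PPI) then assigns each
pixel the fraction of particle pixels in a particle-sized window around it.
Particle-existing regions (PERs) are extracted by soft thresholding
(`PPI ≥ 1/e`, then region-locally at half the regional maximum), markers are
found as local maxima restricted to PERs, and a marker-controlled watershed
of the gradient image — confined to the PERs — yields one segment per
particle. Positions are background-subtracted intensity-weighted centroids
(2D Gaussian fits for particles smaller than 9 px), accurate to well under
0.1 px on clean spots. Five user parameters (`S`, `s`, `N`, density class,
SNR estimate) drive everything, and an adaptive search refines the SNR
estimate and density class per frame until the detection count matches the
expected count.

**Linking** runs an interacting-multiple-model (IMM) Kalman filter per
track — random walk, constant velocity, constant acceleration — whose state
is augmented with particle area and mean intensity, and whose
frame-to-frame association solves a gated global assignment with costs
combining the Mahalanobis position distance and normalised
morphology/intensity differences. Tracks coast over single-frame gaps and
must collect at least three detections (configurable) to be reported.

**Evaluation and analysis**: TPR/FPR, localization RMSE of true positives,
the track-based error

    E*_track = 1 − (Σᵢ Y_tracked,i / Yᵢ) / T_total,

and detection-/track-level Jaccard similarities (JSC, JSCθ); per-step
direction θ₁ and direction-switching θ₂ angle statistics with rose-diagram
histograms and track-density images — confined ("caged") motion shows up as
θ₂ mass concentrated at 180°.

**Synthetic movies**: a generator produces ground-truthed movies (Gaussian
spots, Brownian/directed/caged motion, Poisson + additive Gaussian noise,
amplitude calibrated to a requested SNR), so the whole pipeline is testable
without any external dataset.

See `docs/methods.md` for the model details, parameter defaults and
numerical choices.

## Worked example

Simulate a movie of 50 diffusing particles at SNR 4 (Poisson + Gaussian
read noise, 8-bit), detect, link, evaluate against the ground truth, and
analyse the motion:

```sh
pptrack simulate --n-tracks 50 --n-frames 30 --width 256 --height 256 \
        --snr 4 --seed 7 --out movie.tif --truth-out truth.csv
pptrack detect --input movie.tif --S 12 --s 4 --N 50 --density low --snr 4 \
        --out detections.csv
pptrack track --detections detections.csv --max-dist 5 --min-frames 3 \
        --out tracks.csv
pptrack evaluate --tracks tracks.csv --truth truth.csv --radius 4 \
        --out report.json
pptrack analyze --tracks tracks.csv --out-prefix analysis_ \
        --width 256 --height 256
```

which prints

```
wrote movie.tif (50 tracks, 30 frames, SNR 4.0)
wrote detections.csv (1470 detections)
wrote tracks.csv (60 tracks)
wrote report.json
  TPR: 0.9806666666666667
  FPR: 0.005409060175794456
  RMSE_px: 0.5921498244888626
  E_track: 0.09200000000000008
  JSC: 0.9754641909814323
  JSC_theta: 0.5942028985507246
  TP: 1471
  FP: 8
  FN: 29
  n_estimated_tracks: 60
  n_truth_tracks: 50
wrote analysis_rose_theta1.csv, analysis_rose_theta2.csv, analysis_density.tif
```

Reading the numbers: 98.1% of the 1500 true particle appearances were
detected (TPR), 0.5% of reported detections were false (FPR), and matched
detections were localized to 0.59 px RMS under this noise level. Linking
recovered 90.8% of all true track time steps (`E_track` = 0.092); the
track-level Jaccard (JSCθ = 0.59) is stricter, counting only tracks that
cover ≥ 80% of their ground-truth trajectory as correct — broken tracks
count against it even when every fragment is accurate. The `analyze` step
writes the θ₁/θ₂ rose-diagram histograms as CSV and the track-density image
as a 16-bit TIFF.

The same pipeline runs from a single config file
(`pptrack run --config cfg.yaml`), and each stage is a plain library call
(`pptrack.detect_stack`, `pptrack.link_tracks`, `pptrack.evaluate`, ...) for
scripted use.

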