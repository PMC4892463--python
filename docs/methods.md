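# Methods

`pptrack` detects sub-resolution fluorescent particles in noisy 2D+t movies
and links them into trajectories. This note records the model, the tunable
parameters, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Detection: the particle-probability image

Raw frames are never denoised. Instead, per-pixel evidence for "a particle is
here" is accumulated non-locally:

1. **Haar-like contrast features.** For each pixel, the difference between
   the mean intensity of a small inner window and the mean of its immediate
   surround is computed for three kernel geometries (square centre-surround,
   horizontal bar, vertical bar) at several scales. Inner-window widths are
   odd integers from roughly the minimum-particle width `√s` to twice the
   typical-particle width `2√S`; the surround ring/strips are as wide as the
   inner half-width. The per-pixel maximum over kernels and scales is the
   contrast image. Because every kernel is a difference of means it is
   DC-free: adding a constant to a frame changes nothing. Width ties at the
   scale floor resolve upward, so the degenerate 1-pixel inner window — a
   pure pixel-noise amplifier under heavy read noise — is never used.

2. **Classification.** The `K = round(F·N·S)` strongest contrast pixels are
   classified as particle pixels (ties in raster order, `K` capped at 25% of
   the image). `N` is the expected particle count, `S` the typical particle
   area, and `F ∈ [1, 4.5]` the enhancement factor
   `clamp(1 + 0.25·max(0, 4 − SNR), 1, 3) × {low: 1.0, medium: 1.25, high: 1.5}`:
   noisy or dense images get a larger pixel budget, so weak particles are not
   starved. Any monotone substitute can be configured.

3. **PPI.** Each pixel's particle probability is the fraction of particle
   pixels in the `w×w` window centred on it, `w = odd(√S)`; border windows
   use their image intersection. The PPI is by construction in [0, 1].

4. **Particle-existing regions (PERs).** The PPI is thresholded at `1/e`,
   8-connected regions are formed, and each region is re-thresholded at
   `max(1/e, 0.5 × its own PPI maximum)` — a soft, region-local rule that
   keeps weak-but-coherent regions while splitting bridges between a strong
   and a weak particle. Regions smaller than the minimum particle area `s`
   are discarded.

5. **Markers.** Watershed seeds are strict 8-neighbourhood local maxima of a
   lightly smoothed frame (Gaussian s.d. `0.4·√(s/π)`, a fraction of the
   minimum-particle equivalent-disc radius) that lie inside a PER and have
   PPI above half their PER's maximum; plateaus collapse to their centroid
   pixel, and a PER without a qualifying maximum falls back to its PPI peak.
   The smoothing is deliberately light: it exists only to stabilise maxima
   numerically. Measured on two-spot fixtures at SNR 4, heavier smoothing
   (s.d. ≈ 1.1) merges the maxima of pairs out to ~4.6 px and caps the
   sensitivity of the whole detector, while with s.d. ≈ 0.45 pairs are
   resolved down to ~3.5 px and the extra noise maxima are absorbed by the
   PPI gate and the minimum-area merge.

6. **Marker-controlled watershed.** The Sobel gradient magnitude of the raw
   frame is flooded from the markers with flooding confined to the PER mask,
   and each catchment is intersected with its marker's own PER. A PER with
   one marker therefore becomes one segment equal to the PER; a PER with
   several markers is partitioned along its gradient ridges. Segments
   smaller than `s` merge into their largest same-PER neighbour. No pixel
   outside a PER is ever labelled.

7. **Localization.** For typical particles (`S ≥ 9`) the position is the
   intensity-weighted centre of mass over the segment after two-part
   background removal: the median of the ring just outside the segment
   (local background), then — for segments with interior pixels — the median
   residual on the segment's own rim. The segment is bounded by an isophote;
   centroiding the intensity *above* that isophote removes the truncation
   discontinuity that otherwise biases centroids toward the pixel grid
   (measured: 0.07 px vs 0.09 px RMSE on clean spots, and exact on the
   degenerate two-pixel case, which skips the pedestal). For very small
   particles (`S < 9`) an isotropic 2D Gaussian is least-squares fitted in a
   7×7 window seeded at the marker, falling back to the weighted centroid if
   the fit diverges. Circularity is `4π·area/perimeter²`; axes come from the
   segment's second moments.

8. **Adaptive parameter setting.** After each detection pass the count is
   compared with `N`; while the relative difference exceeds the tolerance
   (default 0.2, at most 10 iterations) the working SNR estimate is bisected
   over [0.5, 10] — too few detections lower it (raising `F`), too many
   raise it — and the density class steps up/down only when the SNR interval
   is exhausted. For image sequences, `N` for frame *t*+1 is the count
   detected in frame *t*. Non-convergence returns the best iterate with a
   warning.

### Detection parameters (defaults)

| parameter | meaning | default / typical |
|---|---|---|
| `S` | typical particle area, px | 12 for a σ ≈ 1.5 px PSF |
| `s` | minimum particle area, px | 4 |
| `N` | expected particles per frame | user estimate; refined adaptively |
| `density` | qualitative crowding class | `medium` |
| `snr` | SNR estimate | 4; refined adaptively |

## Linking: IMM filter with morphology-augmented association

Each track carries a bank of three Kalman filters — random walk, constant
velocity, constant acceleration — over the state
`(x, y, vx, vy, ax, ay, area, intensity)` (each model uses its kinematic
subset; area and mean intensity evolve as random walks in every model). The
standard interacting-multiple-model cycle is used: transition-weighted mixing
(done in the 8-dimensional union space, then projected to each model),
per-model prediction, likelihood-weighted model-probability update. The
transition matrix defaults to 0.8 self / 0.1 cross; initial model
probabilities are uniform; new tracks start with zero velocity/acceleration
under inflated covariance.

Association is a global linear-sum assignment per frame on gated costs:
Mahalanobis distance of the position innovation plus
`λ·(|Δarea|/mean area + |Δintensity|/mean intensity)` (λ = 1 by default; a
cost using circularity/axes can be enabled but those features are not in the
filter state). Pairs farther than the maximum linking distance (hard
Euclidean gate, default 5 px) are forbidden; per-track and per-detection
"skip" options are priced at the Mahalanobis cost of a displacement of gate
length along the widest innovation axis. Unmatched tracks coast on their
predictions for up to one frame (gap-filled points are flagged
`interpolated` and trailing ones are stripped); unmatched detections start
new tracks; tracks with fewer than three real detections are dropped.

Noise scales: measurement s.d. 0.5 px in position (the expected localization
accuracy) and 10% relative in area/intensity; process noise is scaled to the
maximum linking distance (random-walk position step `max_dist/4`, velocity
and acceleration drift `max_dist/10`). With these defaults the
constant-velocity model's probability overtakes 0.5 within 3–4 steps on
clean directed motion, while the wider prediction covariances of the
acceleration model keep it from shadowing the simpler one.

## Evaluation metrics

Detections are matched to ground truth per frame by optimal one-to-one
assignment within a match radius (default `2√(S/π)`, twice the equivalent
particle radius). TPR = TP/(TP+FN); FPR = FP/(TP+FP), i.e. the fraction of
reported detections that are false (defined as 0 when nothing is reported);
RMSE is over true positives; JSC = TP/(TP+FP+FN).

At the track level, truth track *i* of length `Y_i` is paired one-to-one
with estimated tracks to maximise the summed coverage ratios
`Y_tracked,i / Y_i` (a step is covered when the paired track has a position
within the match radius at that frame); the track-based error is
`E*_track = 1 − (Σ_i Y_tracked,i / Y_i) / T_total`. Maximising the ratio sum
(rather than raw step counts) optimises exactly the quantity the error is
built from and makes the optimum unique; on all small instances the
implementation agrees with exhaustive pairing. JSCθ applies the same pairing
with a completeness threshold (default θ = 0.8): a paired estimate covering
at least θ of its truth track is a track-level TP.

## Trajectory motion analysis

For each inter-step, θ₁ is the heading of the displacement
(`atan2(Δy, Δx)` in [0°, 360°), x = column, y = row) and θ₂ the unsigned
angle between consecutive displacements in [0°, 180°] (180° = full
reversal); a signed variant in (−180°, 180°] is available. Gap-filled points
are excluded by default so filter predictions cannot smooth the statistics;
zero-length steps carry no direction and are skipped (their count is
reported). Rose histograms are right-open 2D (angle × step length) counts,
default 36 angle bins for θ₁ and 10°-wide bins generally, with overflow
lengths clipped into the last bin. Track-density images count distinct
tracks per pixel after Bresenham rasterization of each track's polyline —
a revisiting track counts once.

Confined ("caged") motion concentrates θ₂ near 180°: a particle bouncing in
a nanodomain preferentially reverses. Free diffusion has uniform θ₂ (36-bin
chi-square test not rejected), and drift shows up as the modal θ₁ bin.
Because the θ₂ density near its mode is nearly flat at realistic confinement
(cage radius ≈ 2 px, step s.d. ≈ 1 px), the modal-bin signature is assessed
on an ensemble of caged trajectories, as rose diagrams aggregate trajectories
in practice.

## Synthetic data generator

Movies are isotropic 2D Gaussian spots (per-track amplitude and PSF sigma)
on a flat background, corrupted by Poisson shot noise followed by additive
Gaussian read noise (defaults: mean 5, s.d. 30 grey levels, clipped and
quantised to 8 bits — a standard severe-noise benchmark regime). Spot
amplitudes can be calibrated from a requested SNR by inverting the noise
model (`A = SNR·√(background + σ_read²)`), and the generator measures SNR
the same way the detector's user would: (peak − local background mean) /
(local background s.d.) in a 2σ–4σ annulus, averaged over particles.

Motion models: Brownian (i.i.d. Gaussian steps), directed (drift +
diffusion), and caged (specular billiard reflection at a circular cage wall,
so trajectories never leave the cage). Density presets follow the benchmark
regimes of 500/2500/5000 tracks on a 512×512 field; sizes are scaled by
area for smaller test fields. Positions reflect at image margins so every
particle stays renderable.

Not emulated: photobleaching/blinking kinetics, uneven illumination and gain
maps, camera-specific EMCCD/sCMOS noise physics beyond Poisson+Gaussian,
motion-model switching within a track, and particle fusion/splitting.
Passing tests on this generator therefore demonstrate the algorithmic
properties of the pipeline (signal enhancement, segmentation, association,
metric correctness), not robustness to instrument-specific artefacts of any
particular microscope.

## Problem sizes used in tests and the acceptance script

Noise-free exactness uses 20 spots × 50 frames on 256×256; the noisy-regime
benchmark uses 250 tracks × 100 frames on 256×256 (the same areal density as
2500 tracks on 512×512) averaged over 5 movies; the SNR sweep uses 31 tracks
× 20 frames on 128×128 (the low-density regime, chosen because crowding
masks pure noise-driven degradation) × 5 seeds per SNR; angle
statistics use 2×10⁵ caged steps (20 cages × 10⁴ steps) and 10⁴ Brownian
steps. These sizes give stable statistics for every reported quantity while
keeping a full run in the minutes range on one CPU.

## Known limitations

* The detector resolves particle pairs down to ~3.5 px at SNR 4; closer
  pairs merge into one detection (the match radius and density determine how
  often this matters).
* The linking framework targets low/medium densities; at high density the
  single-hypothesis frame-to-frame assignment fragments tracks.
* At SNR ≈ 1 the false-positive rate rises steeply (the enhancement factor
  trades specificity for sensitivity by design); downstream track filtering
  removes most transient false detections but detection-level FPR is high.
* Gap handling coasts on filter predictions for one frame by default; longer
  occlusions split tracks.
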