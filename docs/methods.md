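# Methods

This note documents the models, the synthetic data they are trained and
verified on, the numerical choices that required a decision, and what the
passing tests do and do not establish about real clinical data.

## The analysis problem

A single-frame Doppler screen capture contains a B-mode sub-image (where
the sample volume sits) and a spectral sub-image whose columns index time
and whose rows index blood velocity about a zero line (rows increase
downward; `velocity = (zero_line_row − row) · vel_per_px`). The pipeline
identifies which of four views the capture shows — umbilical artery (UA),
middle cerebral artery (MCA), aortic isthmus (AoI), left ventricular
inflow–outflow (LVIO) — rejects captures of other anatomies, traces the
velocity envelope with its physiological events, and computes the indices
used clinically: peak velocities, cycle length, the pulsatility index
(PI), and for LVIO the systolic/diastolic durations.

Physiology drives the staging. UA and MCA flow is one-sided (entirely
above or below the zero line); AoI may show diastolic reversal on the
opposite side; LVIO combines aortic outflow and mitral inflow with
opposite signs. The amplitude gate exploits exactly this: one-sided
patterns have `V_min ≈ 0` so `(V_min, V_range)` separates the UA/MCA
group from AoI/LVIO before any neural network runs.

## Synthetic studies

`fetaldoppler.synthetic` generates annotated studies with exact ground
truth. Design and defaults:

* **Cycle templates.** Monotone cubic (PCHIP) splines through anchors
  placed at the annotated events. Defaults (cm/s, ms): UA — 500 ms cycle,
  systolic peak 60, end-diastolic 25; MCA — 450, 50, 12; AoI — 450 ms,
  peak 55, end-diastolic 8, diastolic reversal reaching 25% of the peak
  (so AoI is two-sided by default); LVIO — 560 ms, outflow peak +60,
  E peak −35, A peak −45, lobes joined by zero-velocity gaps. A fifth
  OTHER class (narrow valve-like spike, peak 80, near-zero diastole)
  stands in for out-of-domain anatomies such as tricuspid or pulmonary
  traces. Values are plausible mid-gestation magnitudes chosen once; no
  cohort informs them.
* **Event set.** UA/MCA/AoI annotate onset S and S peak; LVIO annotates
  onset S, S peak, end S, onset E, E peak, A peak, end A. All events in a
  template must be ≥ 80 ms apart (LVIO's seven events are spaced at 16%
  of the cycle so the whole jitter range stays valid); templates
  violating this are rejected, keeping ground truth compatible with the
  post-processing minimum-distance rule.
* **Tracks.** 1–18 cycles concatenated, each cycle's duration and
  magnitude scaled by an independent uniform factor within ±10%
  (datasets default to 2–6 cycles). Per-study shape jitter (±8% on peaks
  and duration) adds between-subject variety.
* **Rendering.** The sweep speed is chosen so the track fills the 512
  columns minus a 6-column right margin (so the last cycle's event bands
  stay inside the raster); the velocity scale puts the extreme velocity
  at 85% of the available half-range, with the zero line at 80% height
  for one-sided views and mid-height for two-sided ones — emulating a
  sonographer's scale adjustments. Columns are filled between the zero
  line and the envelope row with an intensity ramp (0.95 at the line to
  0.55 at the edge), multiplicative uniform speckle (±15%) and a clipped
  Gaussian background (σ = 0.02, floor 0.08). Optional aliasing wraps
  out-of-range rows modulo the raster height. An event's pixel column is
  the nearest column on the event's own lobe (same velocity sign as the
  event), so the stored event magnitude always equals the envelope value
  at its column.
* **B-mode.** Per-view Gaussian-blob textures — view-consistent
  statistics, not anatomy — with a coloured cursor overlay (dashed line
  or bounding box) and optional coloured burn-in blocks, all recorded as
  ground truth.
* **Determinism.** Every study derives from a `SeedSequence` child of the
  dataset seed; identical (config, seed) reproduce byte-identical rasters
  and truth.

What the simulator does **not** model: realistic speckle statistics or
point-spread functions, fetal anatomy, probe-angle effects, intra-view
pathology (absent/reversed end-diastolic flow), vendor UI chrome, or
compression artifacts. Tests passing on these studies demonstrate the
*mechanics* of the pipeline — calibration arithmetic, mask encoding and
decoding, event timing, index formulas, optimization — not clinical-grade
accuracy on scanner output.

## Classification stages

**Amplitude gate.** KNN with K = 13 on `(V_min, V_range)`, z-scored per
feature, Euclidean distance, distance ties broken by training index
(stable sort); K is odd so binary votes cannot tie. Features come from
binarizing the normalized spectrogram at 0.1 — this threshold cleanly
separates fill (≥ 0.55 before speckle) from background (≤ 0.08) in the
simulator and is configurable for real data.

**Pair classifiers.** Two dual-encoder residual CNNs (UA vs MCA, AoI vs
LVIO). Each branch encodes one region (B-mode 256×256, Doppler 512×256,
weights not shared), global-average-pools, and projects to a fixed
embedding; the concatenated embedding feeds a fully connected head ending
in 2 logits. The full-scale profile projects each branch to 1024 so the
concatenation is 2048, with head layers 2048→256→2; the reduced profile
(stem 8, two residual stages, projection 32, ~1e5 parameters) is the
desk-scale default used by all tests. Training: cross-entropy, Adam at
1e-3, batch 16 (8 at desk scale), learning rate ×0.1 after 20 epochs
without validation improvement. With no pretrained weights available
offline, encoders initialize from seeded He-normal draws.

**Confidence models.** One keep/skip model per (view, dataset-context).
Regions are embedded by a fixed-seed, untrained reduced convolutional
encoder — seeded random convolutional features are a serviceable generic
descriptor at this problem size and keep the stage deterministic. PCA
retains the *minimal* component count whose cumulative explained variance
reaches 0.85 (asserted in both directions by tests); an XGBoost
classifier (300 trees, depth 3, learning rate 0.1) scores keep
probability, thresholded at 0.5 (keep when equal). Reported metrics: FNR,
FPR (percent) and AUC.

## Waveform delineation

**Architecture.** Per-view W-Net: two stacked U-Nets where the first
U-Net's full-resolution decoder output feeds the second U-Net, and the
first decoder's intermediate features are concatenated into the matching
second-encoder levels (cross-U skips, preventing a bottleneck between the
two U's). Output head: 1×1 convolution to M+1 sigmoid channels — channel
0 the envelope region, channels 1..M one per event type, encoded in
training targets as 5-column × 9-row bands centred on the event pixel.
The reduced profile (base width 8, depth 3, one 3×3 convolution per
block, ~32k parameters) is the test default; a full profile (base 32,
depth 5, double convolutions) is configuration only.

**Optimization.** The objective is the combined soft Dice + soft F1 loss.
For binary targets the two terms are algebraically identical
(`2TP/(2TP+FP+FN) = 2|P∩T|/(|P|+|T|)`), so the equal-weight default
equals plain soft Dice; both weights remain configurable. Dice sums are
aggregated per channel over the whole batch: with per-sample sums, a
sample without positives for a rare channel has denominator ≈ smooth and
its gradient swamps the channel, driving it into sigmoid saturation from
which the overlap loss (gradient ∝ p(1−p)) cannot recover. Two further
stabilizers address the same rare-channel pathology: event-channel head
biases start at −4 (sparse initial predictions), and a small auxiliary
binary cross-entropy term (weight 0.3, configurable, 0 disables) is added
during training — its positive-pixel gradient does not vanish under
saturation. Adam at 1e-3, batch 16, reduce-on-plateau ×0.1 / patience 20,
and per-image duplication with a vertically flipped copy.

**Crop sampling.** Desk-scale training draws one random 96×96 crop per
image per epoch; half the crops are placed around a randomly chosen event
band (uniformly positioned within the crop). Crop origins align to the
8-pixel pooling grid so the pooling phase matches full-raster inference,
and convolutions use reflect padding — with zero padding, networks
trained on small crops learn border-keyed features that do not exist in
the interior of a full 512×256 raster and transfer catastrophically
badly. Inference always runs on the full raster; predictions binarize at
0.5.

## Post-processing and indices

* **Smoothing:** 7×7 Gaussian blur (σ = 1, the kernel's ±3σ), re-binarize
  at 0.5, 3×3 binary dilation, 3×3 closing. Closings operate on
  zero-padded arrays so raster borders are treated as plain background.
* **Envelope:** after selecting the dominant side of the zero line (the
  side holding the maximum |velocity|; ties go to the upper side; twice
  for LVIO, whose two one-sided curves are merged by larger magnitude),
  each column's velocity is the filled pixel farthest from the zero line.
  Because dilation pushes solid boundaries out ~1 px and the blur erodes
  curved peaks, the extreme row is refined against the raw pre-smoothing
  channel within ±2 rows of the cleaned column's span — robust to specks
  (which the cleaned support excludes) and unbiased on solid fills.
* **Events:** per event channel, gaps are closed along time (1×9
  element), connected components reduce to area-weighted time centroids,
  and candidates closer than 80 ms are resolved by keeping the
  larger-area component, earlier on ties, until all pairwise gaps are
  ≥ 80 ms (a gap of exactly 80 ms is allowed). Event magnitudes are the
  envelope value at the event's column, snapping up to 3 columns to the
  nearest supported column; farther events are dropped with a warning.
* **Cycles and indices:** cycles span consecutive onset-S times (≥ 2
  required); other events belong to the cycle containing their time.
  `PI = (V_max − V_min)/V_mean` on envelope magnitudes with `V_mean` the
  time-average over the cycle's supported columns — PI is undefined
  (error) when the mean vanishes, scale-invariant, and vertical-flip
  invariant. LVIO durations: `S = |t(end S) − t(onset S)|`,
  `D = |t(end A) − t(onset E)|`; a missing constituent event omits the
  metric with a warning. Evaluation reduces each index to its per-image
  median across cycles (prediction and truth separately), then reports
  MAPE as mean ± SD of per-image percentage errors (zero-truth images
  excluded and counted) and RMSE as mean ± SD of per-image absolute
  errors.

## Problem sizes and verification

The test suite and the acceptance script use desk-scale configurations
chosen once: the gate is fitted and evaluated on 200 + 200 studies (50
per view); the mask round trip runs 100 noiseless studies per view; the
delineation study trains the reduced W-Net on 200 UA spectrograms for 20
epochs (batch 16, crops 96) and evaluates 50 held-out studies. At these
sizes the measured results are: gate accuracy 100%, round-trip event
recovery 100% of cycles within one time- and one velocity-pixel, held-out
envelope Dice ≈ 0.995, V_max MAPE ≈ 0.3%, and every onset-S pair needed
for cycle segmentation recovered. The PI computation agrees with numeric
integration of the closed-form test envelope to < 1e-3.

## Known limitations

* Synthetic-to-real transfer is untested; vendor-specific palettes,
  fonts and layouts will need configuration (binarization threshold,
  annotation palette, grey tolerance).
* The reduced networks are sized for CPU training on synthetic data;
  real cohorts would use the full profiles and substantially more
  epochs.
* The simulator's OTHER class is a single template family; real
  out-of-domain diversity (valve traces, venous signals, non-cardiac
  structures) is far broader, so confidence-model performance here only
  demonstrates the mechanism.
* Multi-frame (cine) captures are rejected by design; PI is reported per
  image, not pooled across a study.
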