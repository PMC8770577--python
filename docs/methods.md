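# Methods

This note documents the models and procedures implemented in `sortcyte`,
the assumptions behind them, the defaults and why, and what the synthetic
benchmark does and does not establish about real instrument data.

## Coordinate and unit conventions

Images are 8-bit grayscale, row 0 at the top; the flow axis x runs along
image columns, y along rows; pixel indices are 0-based. The pixel size is
fixed at 24.5/36 ≈ 0.6806 µm/px (a 36 px crop spans 24.5 µm) and every
µm↔px conversion uses it. Flows are in µl/s, concentrations in cells/ml,
pulse volumes in nl, times in seconds, areas in µm².

## Poisson coincidence model

During a sorting pulse of duration τ (default 2 ms) everything inside the
sorting region is deflected. With cells travelling independently, the
number in the pulse volume V = Q_total·τ is Poisson with mean
μ = c_channel·V, where c_channel = c_sample·Q_sample/Q_total is the
sheath-diluted channel concentration. The coincidence probability is
P(n > 1) = 1 − e^(−μ)(1 + μ). The planner (`gates.make_plan`) exposes the
whole chain plus the derived event rate c_channel·Q_total and the average
free spacing 1/(c_channel·A_cross) − d_cell along the channel. The channel
cross-section default, 20 µm × 20 µm = 400 µm², is a derived constant
(uniquely consistent with the published free-spacing figures) and is
configurable.

The independence assumption fails for clumped cells: avalanches traverse
the channel occupying consecutive camera frames, so their inter-event gaps
equal the frame period 1/3000 s ≈ 0.33 ms. Two gates address this:

* **contour-count gate** — allow sorting only when exactly one contour is
  in the frame (zero means nothing to sort);
* **timing gate** — suppress any event whose gap to the previous event is
  below ΔT_min (default 0.38 ms, just above the frame period). The
  boundary is inclusive, and the event clock advances on suppressed events
  too, so an entire burst keeps itself suppressed. Offline,
  `detect_avalanches` flags maximal runs of ≥ 3 consecutive frame-period
  gaps (tolerance 50 µs); under exponential gaps at 200 events/s the
  false-positive rate is ~p³ ≈ 7·10⁻⁶ per position.

## Real-time image pipeline

The background model is the arithmetic mean of the last 100 frames (ring
buffer; exact mean, not an exponential filter). Segmentation thresholds
the *absolute* background difference — the sign convention is a package
choice; cells render both darker (rim) and brighter (interior) than
background — at 6 grayscale by default, ≈ 2σ of the static sensor noise
(sd 2.9), then applies one erosion and one dilation with a full 3×3
element. Contours are the external boundaries of connected components
(holes filled first), ordered by enclosed area.

Morphometrics are computed on the sub-pixel contour polygon via Green's
theorem: area by the shoelace formula (winding-independent), second
moments of area about the *centroid* so that the orientation

    φ = ½·arctan2(2 μ₁₁, μ₂₀ − μ₀₂)

is translation-invariant; the reported tilt is |φ| ∈ [0°, 90°] relative to
the flow axis. Near-isotropic contours (anisotropy below 10⁻³ of the
moment trace) are flagged degenerate and report 0°. Crops (18 or 36 px)
are centred on the bounding-box middle with half-away-from-zero rounding
(bit-reproducible) and padded with the local background median when they
extend past the frame.

## Synthetic data generator

The generator emulates the operating point of the instrument, not its
optics. A session has a flat background level (default 39; sessions span
24–49), a *static* Gaussian noise pattern (sd 2.9) identical in every
frame — fresh per-image noise exists only as augmentation — and dark
channel walls at configurable rows (default 14/66), kept clear of the
10-row background-estimation strip.

Cells are anisotropic annuli: the whole body sits below background with
the membrane rim darkest and the interior relatively bright, blurred with
σ = 0.8 px; 30% carry a trailing tail lobe (neural-process-like, the
morphology most confusable with an attached doublet). Areas are uniform
in 20–35 µm²; tilts are Normal(0, 16.31°), giving the half-normal median
of 11°. The photometric body is drawn at 0.83 of the nominal boundary —
calibrated once so that the reference segmentation (threshold 6, one
erosion + one dilation) recovers the nominal area without bias; the
ground-truth mask keeps the full extent.

Event times combine a homogeneous Poisson process at the planner's rate
with superimposed avalanche bursts (Poisson burst starts; geometric
lengths with mean 10, truncated at 4 so every burst is detectable; events
spaced exactly one frame period). A configurable fraction of events are
doublets: a second cell at 4–14 µm. Ground truth carries object count,
centroids, nearest-neighbour distance, area, tilt, fluorescence, class and
avalanche membership; an event is labelled *doublet* iff it has more than
one object or a neighbour closer than 15 µm.

Two labelled crop datasets feed classifier training:

* **two-class dataset** — single cells whose class-1 members differ by an
  `effect`-scaled morphology shift (brighter interior, shallower rim,
  higher eccentricity); at `effect=0` the classes are generatively
  identical, so chance accuracy is the exact null. Fluorescence is
  lognormal around 4,000 (class 1) vs 300 (class 0) a.u. Samples are
  split round-robin into measurement groups whose background differs by
  3 grayscale — within-study session drift; the full 24–49
  between-experiment range is handled by augmentation, not inside one
  dataset.
* **doublet dataset** — single vs doublet crops. Default neighbour
  separations run 1–12 µm: a 36 px crop spans ±12.25 µm from the cell
  centre, so a farther neighbour leaves the field of view and the image
  no longer determines the label. The 15 µm *labelling rule* for streams
  is unaffected; the cap only keeps the supervised task well-posed.

What passing synthetic tests does **not** show: robustness to real optics
(defocus gradients, birefringent-substrate distortion), deformation
mechanics, fluorescence trace artefacts, or the accuracy levels reported
on recorded datasets — those require the original data and are out of
scope here.

## MLP architecture screening

Architectures are input 324 (18×18) → k ∈ {1..4} ReLU hidden layers →
softmax output. Two counts coexist deliberately:

* `count_params` — full trainable parameters, Σ(d_in+1)·d_out over all
  layers **including the output layer**. With a 4-unit output this
  reproduces the reference designs exactly (8,708 / 78,964 / 39,284 /
  23,396), which a 2-unit output does not; the default output width is
  therefore 4, with the width configurable.
* `hidden_weight_count` — the screening budget metric: inter-layer weights
  up to the last hidden layer only (324·n₁ + Σ nᵢnᵢ₊₁; no biases, no
  output layer). An exhaustive scan shows the published survivor split
  (30 / 671 / 16,527 / 379,293 under an 80,000-parameter budget) is
  reproduced exactly only by a strict `< 80,000` cut on this metric — no
  cap on the full count reproduces it — so enumeration filters on it.

Enumeration is vectorised (no models are instantiated) and completes in
seconds. Inference timing follows the pre-heat + 10 repetitions × 500
individual forwards protocol; absolute times are hardware- and
power-setting-specific, are reported with machine metadata, and are never
compared against fixed expectations.

## Training

The native MLP scales 8-bit inputs by 1/255, uses He-normal
initialisation, ReLU hidden activations and a softmax output, and is
trained by gradient descent on categorical cross-entropy,
W ← W − l·∂L/∂W, with gradients averaged over the batch. The default
optimiser is plain gradient descent; classical momentum is available
behind a `TrainConfig.momentum` flag (default 0). The shipped doublet
classifier turns momentum on (0.9, l = 1.5·10⁻³, 5,000 iterations): with
/255-scaled raw pixels the plain update does not converge inside a
practical iteration budget on that task. No deep-learning framework is
used anywhere; the explicit numpy backward pass is validated against
central finite differences (relative error < 10⁻⁵).

Batches draw an equal quota from every measurement group (remainder to
the first groups, deterministically; small groups sampled with
replacement), so no session dominates. The validation split is assembled
once, stratified by group, before the first iteration and never changes.
Validation accuracy is recorded every 50 iterations (the evaluation
interval is a package choice) and can be smoothed with a rolling median
(window 50).

Augmentation applies, in a fixed canonical order, rotation → shifts →
vertical flip → multiplicative then additive brightness → Gaussian noise,
clipping to [0, 255]. Geometric steps at identity settings are skipped
entirely, making the all-identity configuration a bit-exact no-op.
Rotation and shift pad with the image's border median as a background
proxy; horizontal flipping is excluded because flow direction breaks that
symmetry. Default ranges are the calibrated ones (±10°, ±1 px, ±12 gray,
×0.6–1.3, noise sd 3.0).

Learning-rate screening trains briefly at each grid point from a fresh
copy of the initial weights and records the tail-mean loss; the knee is
the learning rate minimising the rolling-median-smoothed d(loss)/d(log l).
A flat or monotone-increasing curve yields a degeneracy flag instead of a
knee.

The doublet filter removes events with p_doublet > 0.3. The classifier
interface is pluggable (anything with `predict_proba`); the shipped
default is the package's own MLP on 36×36 crops.

## Sorting plan

Precision is reported as the sorted-sample *concentration* and
sensitivity as the *yield*; ratios with zero denominators are NaN and
named in an `undefined` field, never silently zero. Score comparisons are
`>= threshold` (ties sort). The composite trigger requires: area within
[20, 35] µm² (debris below, aggregates/other types above), exactly one
contour, timing-gate pass, and score ≥ threshold. `yield_min` converts a
required cell count, realistic sort rate and duration budget into the
minimum acceptable yield (capped at 1 with a warning when the budget is
unreachable). Gated fractions always report raw counts alongside the
percentage; printed percentages use one decimal.

## SSAW physics

λ = v/f with the substrate's surface sound speed (3978.2 m/s on lithium
niobate) and the IDT excitation frequency (55.23 MHz) gives 72.03 µm; the
maximum translocation per pulse is λ/4 = 18.01 µm. The radiation force on
a small compressible sphere is F = −(π p₀² V_c β_w / 2λ)·φ·sin(2kx) with
contrast factor φ = (5ρ_c − 2ρ_w)/(2ρ_c + ρ_w) − β_c/β_w; φ > 0 means
node-seeking. x is measured from a pressure node (the origin is a
documented package convention). The acoustic pressure p₀ has no canonical
value, so force magnitudes are demonstrative; the cell-density default is
1.05·10³ kg/m³ (between water and protein), configurable.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to characterise behaviour statistically: arrival-rate and
chi-square checks use 1–2 minute simulated streams (render-free),
Monte-Carlo coincidence checks use 10⁵ pulse windows, classifier checks
use 500–1,000 crops per class with held-out validation, enumeration runs
the full 837,930-candidate grid. Randomness always flows through
explicitly seeded `numpy` generators; rendering, augmentation, batching
and training are bit-reproducible under a fixed seed in single-threaded
execution. Degenerate inputs (empty masks, < 3-vertex polygons, zero-area
contours, empty score sets, zero denominators) raise or flag explicitly
rather than returning silent zeros.

## Known limitations

* The generator's phenotypes are parametric stand-ins; classifier
  accuracies on synthetic crops say nothing quantitative about recorded
  datasets.
* The HDF5 container mirrors the RT-DC-style per-event layout but does not
  claim full `.rtdc` dialect compatibility.
* Inference-time measurements depend on hardware, thread count and CPU
  power state; only the protocol is contract-tested.
* Fluorescence is a per-event scalar; 1-D trace waveforms and their peak
  assignment are not modelled.
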