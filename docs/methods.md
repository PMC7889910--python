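# Methods

This note documents the models and procedures implemented in `breathcad`, the
defaults and why they were chosen, the numerical decisions, and the limits of
what the synthetic benchmark establishes.

## Problem setting

The package targets three-class screening of breath samples — early gastric
cancer (EGC, code 0), advanced gastric cancer (AGC, code 1), healthy controls
(code 2) — from Raman-style spectra: ~1200 intensities on an ordered axis
spanning 400–1500. The axis is treated as a unitless ordered scale named
cm⁻¹ by convention; the source material is internally inconsistent about
physical units (a 400–1500 "nm" range alongside a 2 "cm⁻¹" augmentation
shift), so no physical unit claim is made. The real cohort behind the method
is not publicly deposited, so the package ships a synthetic generator that
emulates its stated structure and serves as the test bed.

## Synthetic cohort generator

Each spectrum is `bands + baseline + noise + spikes`:

* **Bands.** Nine Gaussian profiles (Lorentzian selectable) at shared centers
  520–1440 cm⁻¹, sigma 12 cm⁻¹ (≈13 points at default sampling). The three
  classes differ only in mean band amplitudes (range 0.3–1.2); per-spectrum
  amplitudes are drawn `Normal(mean, 0.05)` clipped at zero. Class
  separation is therefore carried entirely by relative band intensities, the
  mechanism by which VOC concentration changes would appear in real spectra.
* **Baseline.** A random polynomial of order 2 on the normalized axis with
  coefficients uniform in ±0.15 (constant term nonnegative) — smooth drift of
  the same order of magnitude as the weaker bands.
* **Noise.** I.i.d. Gaussian, sd 0.02 (≈2 % of a unit band).
* **Spikes.** Cosmic-ray-like artifacts: Poisson count with mean 0.3 per
  spectrum, uniform position, triangular shape with full width ≤ 3 points and
  amplitude 1.5–4× the largest band mean, i.e. rare, narrow and positive —
  the three properties the despiker exploits. Config validation enforces
  that spikes stay narrower than the narrowest band in points.

Defaults follow the published cohort: 55 EGC / 89 AGC / 56 healthy (200
samples), 1200 points over 400–1500. Where the source states no value
(band shapes, amplitude levels, noise scale, spike statistics) the defaults
above were chosen once as a realistic, clearly separable spectroscopy
scenario and are not tuned against test outcomes. Randomness is
counter-keyed: spectrum *i* uses the stream `(seed, i)`, so cohorts are
reproducible independent of generation order.

## Preprocessing

Fixed stage order `remove_spikes → median_filter → baseline_correct →
smooth`; despiking must precede the median filter and baseline fit because a
large spike biases both. Every stage preserves the axis and length; any
stage can be disabled.

* **Spike removal.** Modified z-score (0.6745·(d−median)/MAD, std fallback
  when the MAD is zero) of the first differences; points adjacent to
  differences with |z| > 6 are grouped into runs. A run is replaced by
  linear interpolation from its flanks only if it is no longer than
  `spike_width_max` (default 5 flagged points — a w-point spike flags w+2
  points, so this removes spikes up to 3 points wide) *and* rises above the
  flank line (positive excursion). Genuine bands produce long flagged runs
  and are never altered; the operation is idempotent.
* **Median filter.** Window 5 (odd required), reflected edges, via
  `scipy.ndimage.median_filter`.
* **Baseline.** Default asymmetric least squares (Eilers–Boelens): minimize
  `Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²z)²` with asymmetric weights (p = 0.01 below, 1−p
  above), 10 reweighting iterations. λ = 1e7: stiff enough that band heights
  above baseline are preserved to better than 1 % for band widths up to ~20
  points (a λ of 1e5 attenuates a 20-point-sigma band by ~10 %, violating
  the requirement that baseline correction not cut down band strength),
  while still capturing linear and gentle polynomial drift to ~1e−7.
  Fallback: iteratively clipped polynomial fit (degree 3, Lieber-style
  min-clipping, 30 iterations).
* **Smoothing.** Savitzky–Golay, window 7, order 2, polynomial-interpolation
  edges, so polynomials up to the filter order pass through unchanged.

## Augmentation and features

Originals are cropped to the centered 1200-point window; one augmented copy
per spectrum shifts the signal right by 2 axis units (linear re-interpolation
onto the original axis, leading gap edge-filled). 200 originals therefore
become 400 samples (the source reports 368 samples and 453,600 values after
augmentation, which does not follow from its stated procedure — 200×2×1200 =
480,000; the stated rule is implemented and the discrepancy simply noted).
Copies carry `source_id` metadata so splits can keep them with their source.

Peaks are local maxima with prominence above `0.5 × sd(intensity)`
(`scipy.signal.find_peaks`); each carries position, height, FWHM by
half-height crossing interpolation, trapezoid area, prominence. The 50 most
prominent peaks (ties to the smaller position) are kept and re-ordered by
position; if fewer than 50 exist, zero-height placeholders pad the front.
The feature vector is the 50 peak **heights** — height is the dominant
discriminative attribute and yields a fixed-length input; widths/areas stay
available on the `Peak` objects for diagnostics. Features are min–max
scaled to [0, 1] with statistics from the training partition only (the
decoder is a logistic sigmoid, so inputs must be representable in (0, 1));
validation/test values may fall slightly outside [0, 1] and are not clipped.

## Network and training

All activations are logistic sigmoids; decoders are untied from encoders.
One autoencoder's objective over a batch of n samples is

    J = (1/n) Σᵢ ½‖xᵢ − x̂ᵢ‖² + α Σⱼ KL(p‖ρ̂ⱼ) + β(‖W‖²_F + ‖W′‖²_F)

with ρ̂ⱼ the batch-mean activation of hidden unit j and Bernoulli KL
divergence as the sparsity penalty. Defaults: sparsity target p = 0.05,
sparsity weight α = 4, learning rate 0.001, 1000 epochs (the published
configuration), weight decay β = 1e−4 (unstated in the source; a small
conventional value). The KL arguments are clamped to [1e−8, 1−1e−8] (logged)
rather than raising at the open-interval boundary.

Training is plain full-batch gradient descent from a Glorot-uniform
initialization (±√(6/(d+h)), zero biases). The gradient routes the sparsity
term through every sample's hidden pre-activation via
`α(−p/ρ̂ⱼ + (1−p)/(1−ρ̂ⱼ))/n`. Layers (default sizes 100 then 40, the
best-performing published architecture; its prose alternative of 50 second-
layer units is selectable) are pretrained greedily on unlabeled features,
each on the previous layer's codes, with per-layer seeds derived from the
base seed by `SeedSequence([seed, layer])`. The softmax head (3 classes) is
trained on the top codes from zero initialization by gradient descent on
L2-penalized cross-entropy (lr 0.5, 500 epochs, l2 1e−4 — convex, so only
convergence matters). Fine-tuning backpropagates plain cross-entropy
through head and all encoder layers jointly (decoders discarded, standard
practice; lr 0.5, 500 epochs). Prediction is the argmax of the softmax
probabilities, ties to the lowest class code. Non-finite costs abort with a
diagnostic rather than training on.

The full train → predict path is a pure function of (data, config, seed);
the test suite checks every analytic gradient (autoencoder, softmax,
fine-tune) against central finite differences to < 1e−6 relative error.

## Evaluation

Splits default to 70/15/15 (the alternative 75/25 preset mentioned elsewhere
in the source is available by configuring fractions). Global partition
sizes are `floor(n·fraction)` with remainders assigned train-first;
stratification apportions classes under those global capacities so per-class
proportions hold within one sample per partition; a `groups` argument keeps
augmented copies with their source (leakage guard). Metrics: confusion
matrix ordered EGC/AGC/HEALTHY; one-vs-rest TP/TN/FP/FN per class; precision
TP/(TP+FP); recall TP/(TP+FN); F = 2PR/(P+R); multiclass accuracy =
trace/total (per-class one-vs-rest accuracy available from the binary
counts); macro averages over classes with defined values. Undefined 0/0
ratios are NaN in memory and `null` plus a `*_defined: false` flag in
exports — never a silent zero. ROC is a descending-score threshold sweep
with tie blocks collapsed, AUC by the trapezoid rule, which equals
concordant-pair counting with ties worth ½ (asserted against a brute-force
oracle and scikit-learn in the tests; sklearn is never the implementation).

## What a green benchmark does and does not establish

The synthetic world is *designed* to be separable: class amplitude
differences (up to 0.8) dwarf the amplitude spread (0.05) and noise (0.02),
so the end-to-end benchmark — held-out accuracy ≥ 0.90 on the default cohort
— verifies that the pipeline's plumbing (preprocessing, feature alignment,
pretraining, fine-tuning, leakage-guarded evaluation) preserves and recovers
class structure that is genuinely present. It does **not** reproduce or
validate the published real-data accuracies (the real cohort is unavailable),
and it says nothing about instrument drift, patient covariates, or overlap
between metabolic profiles of real disease states.

Other known limitations: feature columns are aligned by peak *rank and
position*, not by band identity, so a missed weak peak shifts a sample's
remaining features by one column (the padded-placeholder convention keeps
this rare with the default prominence floor); the optimizer is plain
gradient descent, adequate at this scale but slow for much larger cohorts;
and the generator draws spike amplitudes relative to the largest band mean,
so extremely weak-signal regimes are not represented.
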