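# Methods

This note documents the models and procedures histofusion implements, the
choices made where the design was genuinely open, and what the synthetic
testbed does and does not demonstrate.

## Patch preparation

Slides are tiled on a regular grid with `patch_size = stride`
(non-overlapping); border remainders smaller than a full patch are
discarded rather than padded, matching non-overlapping stride semantics.
Patches are resized with Pillow's Lanczos kernel (a = 3). Magnification
is treated as metadata: the synthetic rasters are single-plane, so no
pyramid decoding is needed or implemented.

**Tissue mask.** The tissue detector is intentionally simple: a pixel is
tissue if its HSV saturation exceeds 0.07 *or* its grayscale intensity is
below 0.8 of the dtype maximum. This is the standard
stain-versus-white-glass heuristic; both thresholds are arguments. The
20% tissue threshold is inclusive (≥), and a slide whose patches all fail
the rule is flagged insufficient (empty sequence) rather than raising.

**Sequence order.** Patches are ordered by grid row ascending, then grid
column descending: the sequence starts at the top-right patch, runs to
the top-left, then restarts at the right of the next row, ending at the
bottom-left. Coordinates are 0-based with row 0 at the top; centers are
recorded in slide pixel space. The order is a total order on grid cells,
so it is invariant to input shuffling.

## Pathway scoring

Expression preprocessing is log2(x + 1) followed by per-gene median
centering (each gene's median across samples becomes exactly 0). Base 2
with a unit pseudocount is the RNA-seq convention; centering is per gene
across samples, which is what "median centering" means in the signature
literature. A signature's score is the plain mean of its member genes'
values per sample; the number of genes matched is recorded, and a
signature with no matching genes is skipped with a warning (an error in
strict mode).

The differential screen is a two-sided two-sample t-test per signature.
Welch's unequal-variance form is the default — the pooled form is a flag —
because equal group variances cannot be assumed and Welch is never much
worse. Significance is the raw p < α (strict), with no multiple-testing
correction by default; a Benjamini–Hochberg option exists but is off, so
the screen matches the raw-threshold convention of signature panels.
Significant scores can be exported with average-linkage hierarchical
clustering on correlation distance (1 − Pearson r), with scipy's
deterministic leaf order, as a TSV any heatmap viewer can consume.

## Fusion network

All network code is NumPy with hand-derived backpropagation; every
gradient path (dense, convolution, max-pool, peephole LSTM, masked BPTT)
is verified against central finite differences in the test suite.

* **CNN.** Two architectures share one implementation: `small-cnn`
  (four 3×3 conv blocks with 2×2 max-pooling, then an FC layer of 128
  units) for 64-px desk-scale patches, and `alexnet-style` (11/5/3/3/3
  conv stack, FC 4096) for 256-px patches. Per-patch image features are
  the penultimate (FC) layer activations.
* **MLP.** Three FC+ReLU layers (defaults 1024/512/256) on the pathway
  score vector; the genomic features are the last layer's output.
  Pathway scores are z-scored per signature over the training set before
  the MLP — SGD behaves badly on raw score scales — with the means/SDs
  stored in the model for inference.
* **Fusion.** Image and genomic features are concatenated and passed
  through one FC+ReLU to the LSTM input dimension. In image-only mode
  the FC sees the image features alone. The patient's genomic vector is
  repeated at every sequence step (one expression profile per patient).
* **LSTM.** Peephole form: the gates see the cell state through
  elementwise (diagonal) weights. "Seven cells" is read as unroll length
  T = 7: a slide's ordered patch list is chunked into consecutive windows
  of 7; a final short chunk is kept and padded, with a step mask that
  freezes the state and zeroes the output at padded steps. The
  alternative reading (seven stacked layers) was rejected as inconsistent
  with per-step pooling; T is configurable.
* **Biomarker.** Average pooling of the hidden outputs over all valid
  steps of all chunks — one vector of length `lstm_hidden` per patient.
* **Loss.** Multitask cross-entropy (natural log) on the primary pattern
  (classes 3/4) and the Gleason sum (classes 6/7/8), reduced by batch sum
  as written; a mean-reduction flag exists for learning-rate
  comparability. Predicted probabilities are clamped at 1e-12 with a
  warning. During stage 2 the batch unit is the chunk, each chunk
  inheriting its slide's labels.
* **Training.** Two stages of momentum SGD (batch 32, momentum 0.9,
  weight decay 5e-5, lr 1e-3 annealed ×0.1 per interval). Stage 1 trains
  the CNN on individual patches; stage 2 freezes the CNN (a flag
  unfreezes it — freezing matches the staged description and makes the
  stage-2 problem small), precomputes patch features once, and trains
  MLP + fusion FC + LSTM + heads on chunks. Full-scale defaults are
  50,000/5,000 iterations with anneal intervals 10,000/2,000; the desk
  configuration used by tests and the acceptance script runs 300/300
  iterations with interval 120. Training errors out before starting if a
  configured class is absent from the training labels.

## Survival analysis

The Cox partial log-likelihood is maximized by Newton–Raphson with
step-halving. Ties use the Efron approximation by default (the default of
the R `survival` package); Breslow is a flag. Convergence is declared
when the gradient max-norm falls below 1e-8 *or* the relative
log-likelihood change falls below 1e-9 — near the optimum the gradient is
a difference of large sums and can sit at the float noise floor, so a
pure gradient criterion stalls. Standard errors come from the inverse
observed information; the baseline cumulative hazard is the Breslow step
estimate. Monotone likelihood (perfect separation) is detected by
coefficient divergence (|β| > 50) and raised as an error; rank-deficient
designs are rejected up front. The solver agrees with lifelines to 1e-4
on shared problems (test suite).

Harrell's C counts pairs where the member with the strictly earlier
observed time had an event; concordant pairs score 1, tied risks 0.5.
Feature selection is a univariate Wald screen (p < 0.05, strict), run one
feature at a time before the multivariate fit, guarded by a minimum
event count (default 10, configurable). The evaluation protocol fits
each selected biomarker feature jointly with the clinical factors on the
train+validation patients and reports per-covariate hazard ratios plus
the C-index on the held-out test patients (a flag switches to full-cohort
evaluation). Continuous clinical covariates enter untransformed;
biomarker activations, whose units are arbitrary, are z-scored by the
pipeline so their hazard ratios read per standard deviation. On a
Gleason-7-only cohort the secondary pattern is an affine function of the
primary and is unidentifiable in a Cox model; collinear clinical columns
are detected on the centered design and dropped with NaN reported in
their HR column. If no biomarker passes the screen, the smallest-p
convergent feature is carried forward with a warning so the report is
never empty. The permuted-outcome control re-runs the whole screen+fit+
evaluate chain with (time, event) jointly permuted, averaged over 20
permutations — a single permutation on a small test split is far too
noisy to read.

## Texture baselines and the correlation screen

LBP uses the rotation-invariant uniform coding (radius 1, 8 points,
P + 2 histogram bins, normalized to sum 1), computed on 8-bit quantized
grayscale with border pixels (incomplete neighborhoods) excluded. HOG
uses 9 orientation bins, 16-px cells, 2×2-cell blocks, L2 block norm.
Both follow the original method papers' defaults and are configurable.
Slide-level features are the elementwise mean over kept patches.

The image-feature vs pathway-score correlation screen pairs k =
min(p_img, p_scores) features one-to-one per repeat (consecutive blocks
of the larger set first, paired positionally, so that every feature is
paired; extra repeats use sorted random subsets), computes the k Pearson
correlations across samples, and t-tests them against zero. One-to-one
pairing keeps the coefficients within a repeat approximately independent,
so the per-repeat p-values are calibrated under the no-correlation null
(all-pairs k×k correlation sets are not: their dependence overdisperses
the t statistic). Spearman is available via a flag.

## Synthetic cohort

The generator's defaults define the study conditions: 60 patients, 7
tissue patches per slide at 64 px, 500 genes, 20 signatures of 10 genes
(5 informative), log-scale gene noise SD 1.0, signature shift +2.0 in the
4+3 group, baseline hazard 0.02 events/month, log-hazard coefficient 1.5
per unit latent risk, 30% censoring. Gleason groups are allocated in the
proportions 43 : 146 : 101 : 49 (3+3 : 3+4 : 4+3 : 4+4, largest-remainder
rounding), the shape of a real public prostate cohort. Slides with a
mixed score carry ~70% primary-pattern patches. Latent risk =
1.0 × (fraction of pattern-4 patches) + 1.0 × (mean informative-signature
score), tying both modalities to outcome so that fusion can beat either
alone. Survival is exponential with uniform administrative censoring on
[0, τ], with τ solved numerically so the expected censoring fraction
equals the configured rate. Texture: pattern 3 is 2–4 large ellipses,
pattern 4 is 16–24 small ones, on a pink background with Gaussian pixel
noise; a blank background row composed into each slide raster gives the
tissue filter true negatives. Identical config + seed reproduces the
cohort bit for bit.

What the testbed does **not** emulate: stain variability and color
heterogeneity, gigapixel scale and pyramidal formats, realistic gland
morphology, correlated gene–gene structure, non-proportional hazards,
and informative censoring. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that it recovers planted multimodal
signal at realistic sizes — not that the learned biomarkers would
transfer to real slides.

## Problem sizes and numerics

Tests and the acceptance script use the desk configuration (small CNN,
128-unit LSTM, 300 iterations per stage, 60 patients), chosen so the full
study runs in minutes on one CPU while keeping every stage non-trivially
exercised; the full-scale settings remain the config defaults. Reported
end-to-end quantities are medians over three seeds because a 20%-of-44
held-out split is small. Degenerate inputs are handled explicitly:
constant score rows give t = 0 / p = 1; constant features are skipped by
the Wald screen; empty patch sequences raise; probability clamps and
sigmoid input clipping keep the network finite for any input.

## Known limitations

The Cox solver targets small-to-moderate covariate counts (Newton with a
dense information matrix). Stage-1 CNN training at the 300-iteration desk
scale only partially converges (its job is to shape features, which the
stage-2 sequence model then separates). The LBP/HOG baselines are
deliberately minimal; no learned baseline is provided. The CLI is a thin
wrapper — programmatic use through `histofusion.pipeline.run` is the
primary interface.
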