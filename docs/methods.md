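# Methods

`pirinv` reimplements, end to end and on synthetic data with known ground
truth, the analysis chain used to ask whether a sensory cortex contains a
subpopulation of neurons that encode odor identity independently of odor
concentration: two-photon calcium movies → ROI segmentation → ΔF/F and
deconvolved firing-rate proxies → response detection → population-vector
statistics and decoding → per-cell invariance classification with bootstrap
nulls → spatial-organization tests. This note documents the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Synthetic data generator (`pirinv.synth`)

The generator is the study-design stand-in: every downstream stage is
validated against the structure it plants.

**Trial structure.** An odor trial lasts 30 s — 8 s pre-stimulus baseline,
2 s odor, 20 s post-stimulus — sampled at 15 Hz (450 frames). Each stimulus
is presented on 4 trials. Two stimulus sets are built in: a 13-odorant
panel at a single 1:10,000 vol/vol dilution, and a concentration series of
3 odorants × 3 ten-fold dilutions (1:10,000, 1:1,000, 1:100).

**Functional categories.** Cells are assigned, with configurable
proportions, to:

| category | default | response model |
|---|---|---|
| `identity_only` | 10% | odor-selective amplitudes identical across dilutions (the concentration-invariant cells) |
| `concentration_modulated` | 5% | odor-selective, recruited only at dilutions at/above a per-cell threshold |
| `mixed` | 5% | amplitude redrawn independently per odorant×dilution (identity×concentration interaction) |
| `suppressed` | 11% | odor-unspecific negative responses whose magnitude ramps with concentration |
| `null` | remainder | no stimulus-locked response |

The first three categories together make up the 20% "activated" fraction.
Tuning is sparse: each responsive cell has one preferred odorant at full
amplitude (drawn once per cell from N(1.0, 0.3) ΔF/F, floored at 0.2) and
responds to each other odorant with probability 0.3 at 20–80% of that
amplitude. Suppression is modeled as broadly tuned because making it
odor-selective would smear its concentration dependence across the
odorant factor of the per-cell ANOVA, where the design has little power;
broad suppression with a concentration ramp (0.3→1.0 of −0.6× the cell's
amplitude) loads the concentration main effect, so suppressed cells are
correctly excluded from the invariant class.

**Noise.** Scalar per-trial responses get i.i.d. Gaussian noise
(`trial_noise_sd`, default 0.2 ΔF/F) — this is the noise the per-cell ANOVA
sees, putting single-cell identity-test power near 1 for full-amplitude
responses. Traces get white per-frame noise (`trace_noise_sd`, default
0.05 ΔF/F), a realistic shot-noise level for somatic GCaMP6s; per-frame and
per-trial noise are distinct parameters because a per-frame SD of 0.2 would
represent far noisier recordings than the study conditions.

**Calcium dynamics.** Responses are onset-locked events convolved with an
instant-rise exponential kernel exp(−t/τ), τ = 2 s (GCaMP6s-like). Each
responsive cell–stimulus pair fires per trial with probability
`p_respond` = 0.75 (trial-to-trial reliability), with the amplitude drawn
once per cell–stimulus and jittered ±15% per trial.

**Movies.** Cells are placed by rejection sampling with non-overlapping
circular masks (radius 5 μm at 1.36 μm/pixel). The radial intensity
profile is annular — dim nucleus-like center, peak at 0.55 R, decaying
toward the rim (point-spread blur) — so per-pixel signal amplitudes within
a mask are non-uniform and border pixels carry the least signal; this is
what makes the pixel-weight estimation and the border-ratio selection
criterion meaningful. The movie adds a smooth multiplicative neuropil field
driven by a common slow signal (amplitude 0.1 ΔF/F), a global sinusoidal
drift (period 300 s, amplitude 0.05), white pixel noise (SD 0.03), and
spontaneous (stimulus-unlocked) events at 0.05 Hz per cell so that even
unresponsive cells are segmentable, as real neurons are. All draws descend
from one seed through fixed-purpose child generators, so the same config
yields the same category/mean structure in the table, trace and movie
generators.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: breathing-locked dynamics and sniff
modulation, temporally autocorrelated noise, overlapping cell masks,
z-drift and slow photobleaching, non-instant calcium rise times, and any
relation between cell position and tuning (maps are spatially unclustered
by construction, which is what the nearest-neighbor-index null tests need).

## Segmentation (`pirinv.segmentation`)

Pixels are clustered by greedy merging: at each step the pair of
4-connected neighboring regions with the highest Pearson correlation is
merged, the merged region's signal is the *average of the two region
signals* (not pixel-count-weighted), and neighbor correlations are
recomputed exactly. Clustering stops after `I` merges; the reference value
I = 25,000 for a 256 × 256 field is scaled proportionally with pixel count
(1,562 for 64 × 64). Correlations are computed on preprocessed signals:
30 s temporal bins, first-order zero-phase Butterworth high-pass with a
100 s cutoff period, and subtraction of each pixel's projection onto the
global mean signal. Ties in correlation are broken by the lowest (row,
col) lexicographic order of the two regions' minimum pixels; zero-variance
signals get correlation −∞ and merge last. Both choices make the procedure
deterministic.

**Pixel weights.** Each candidate region's per-pixel weights start uniform
at 1/N and are updated by computing the region signal x_reg = Xw and
regressing every pixel time course onto it, w ← Xᵀx_reg/‖x_reg‖²,
renormalized to sum 1 and repeated 3 times. This is a power iteration
toward the dominant rank-1 component of the region's (centered) signal
matrix, so weights converge to the pixels' relative signal amplitudes —
low-signal pixels (nuclei, mask edges) contribute little to the extracted
trace. Weights are estimated on *full-rate* signals that have received the
same large-scale-correlation removal as the clustering input (high-pass +
global projection, no binning): on raw signals the shared neuropil/drift
component dominates the rank-1 fit and flattens the weight maps, which
would defeat the border criterion below.

**Region selection.** A region is kept as a neuron iff (i) minsize ≤ size
≤ maxsize pixels; (ii) dispersion — mean squared pixel distance to the
centroid divided by size, ≈1/2π for a disk, growing with elongation — is
below `maxdisp` = 0.5; and (iii) the ratio of the mean weight of border
pixels (4-adjacent to an out-of-region pixel) to the mean weight of all
pixels is below `maxborder` = 0.9. The interactive curation step of a live
setup is replaced by optional include/exclude id lists. On the 64 × 64
demo movie (25 cells, fixed seed) the chain recovers 92% of planted cells
at IoU ≥ 0.5; the misses are low-activity cells whose weight maps are too
flat to pass the border criterion — the same cells a human curator would
be unsure about.

## Signal extraction (`pirinv.extraction`)

Motion is corrected by sub-pixel Fourier cross-correlation against the
mean of the first 100 frames (10× spectral upsampling). Traces are
weighted in-ROI pixel averages; neuropil contamination is removed as
F_true = F_measured − 0.5 · F_neuropil with the neuropil signal averaged
over a 20 μm disk around the cell center excluding all ROI pixels. ΔF/F
uses F0 = median fluorescence of seconds 4–8 of each trial's baseline;
trials with F0 ≤ 0 are marked invalid.

**Deconvolution.** The firing-rate proxy is r(t) = f′(t) + f(t)/τ, the
exact left inverse of exp(−t/τ) convolution in continuous time. The
derivative is the causal first difference r[n] = (f[n] − f[n−1])·rate +
f[n]/τ with r[0] = f[0]/τ, chosen so that an event raising f at frame n
peaks in r at frame n; discretization error is O(1/rate) (verified by the
15 vs 60 Hz inversion test). The result is low-pass filtered with a
four-pole Butterworth at 2.5 Hz applied forward–backward (zero phase) so
that response-window integrals are not delayed.

**Response detection.** Per trial, the baseline SD of ΔF/F is computed on
the full 8 s pre-stimulus period; a trial is *activated* if ΔF/F stays
above +2·SD for ≥ 21 consecutive frames in a run starting within the 4 s
post-onset window (contained in [onset, onset + window + run]), and
*suppressed* with the mirrored threshold and 19 frames. Run lengths were
calibrated at 15 Hz and are rescaled proportionally at other frame rates.
`calibrate_threshold_roc` reproduces the calibration procedure: a grid over
(threshold multiplier, run length) scored by Youden's J on labeled
positive trials versus blank (no-stimulus) trials.

## Population statistics (`pirinv.population`)

Population vectors are per-trial means of the deconvolved signal over the
4 s after onset. Correlation analysis uses signed responses; lifetime
sparseness Sl = (1 − (Σr/N)²/(Σr²/N))/(1 − 1/N) clips negative responses
to 0 first, since the statistic is defined for non-negative rates and can
exceed 1 with signed inputs (an all-zero profile returns Sl = 0). For the
concentration series, sparseness can be evaluated per dilution or over all
9 odorant–dilution stimuli. Responsive fractions are means over trials of
the flagged-cell fraction; tuning maps keep only cell–odor pairs flagged on
≥ 2 of 4 trials, with the preferred odorant the strongest kept mean.
Hierarchical display ordering uses average linkage on (1 − Pearson)
distance (the linkage was an open choice; average linkage is the common
default for correlation distances).

## Decoding (`pirinv.decoding`)

The default classifier is LDA on the principal components capturing 95% of
variance, with the PCA basis refit inside every training fold so no test
information leaks into it; a one-vs-all linear SVM (C = 1) on raw
responses is the alternative. All accuracies are leave-one-out.

Two calibration details matter and are deliberate deviations from the
naive procedure. With equal class counts, each LOO fold trains on a
*balanced* subset: the same-position trial of every other class is dropped
along with the test trial. Naive LOO leaves the tested class with one
fewer trial, so its centroid is estimated with higher variance and, on
pure noise, sits systematically farther from the test point — permuted-
label accuracy lands ~2.4 points below chance at 4 trials/class. Balanced
folds restore mean-at-chance calibration (8.1% vs 7.7% for 13 classes),
at the cost of one training trial per class. LDA priors are uniform, since
per-fold class counts are a cross-validation artifact rather than real
class frequencies.

Time-resolved decoding accumulates ΔF/F (not deconvolved rate) over a
5-frame (~333 ms) sliding window: the deconvolved trace is impulsive at
onset and carries no sustained in-odor signal, whereas ΔF/F persists
through the kernel decay. Train-at-timepoint fits the classifier on the
window at a fixed post-onset time and evaluates the held-out trials at
every other time.

The concentration-generalization task tests each trial of odorant *o* at
dilution *d* against seven training groups: *o* at its most distant
dilution only (for the middle dilution, the lower one) plus the other two
odorants at all three dilutions; chance is 1/7 ≈ 14%. The "100-fold"
subset restricts scoring to tests at the lowest and highest dilutions,
where training is two log-units away. On synthetic data the planted
invariant subpopulation scores ~100% on the 100-fold subset while the
generic remainder is near chance — the qualitative signature the per-cell
statistics below quantify.

## Invariance statistics (`pirinv.invariance`)

Each cell's 36 responses (3 odorants × 3 concentrations × 4 trials; the
scalar response is the 4 s post-onset mean, the same window as the
population vectors) are fit with a fixed-effects linear model: odorant
identity, concentration, identity×concentration, and trial number as a
main effect only. Sums of squares are type II, computed by model
comparison — each factor's SS is the residual-SS drop when it is added to
the model containing all other terms, respecting marginality for the
interaction — with F-tests against the full-model residual (24 df).
Because the design matrix is identical for every cell, the residual
projection matrices are built once and applied to all cells at once; the
implementation matches `statsmodels` `anova_lm(typ=2)` to full precision
and classifies 10,000 cells in ~40 ms, which is what makes the bootstrap
below routine.

A cell is **concentration-invariant** iff p_identity < α and
p_concentration > α and p_interaction > α (α = 0.01). The false-positive
rate of this conjunction on null data is bounded by α, because the
identity test alone fires at rate α and the two complement tests can only
remove cells; the 10,000-null-cell simulation shows ~0.9% invariant calls.
Other outcomes map to `mixed_interaction` (interaction significant),
`identity_and_concentration`, `concentration_only`, or `unmodulated`;
cells with zero residual variance are `degenerate` and excluded from
fraction denominators. A two-stage variant (first discard
interaction-significant cells, then test the rest) is available and yields
the identical invariant set by construction.

**Identity-shuffle bootstrap.** The null for "are invariant cells
overrepresented?" randomizes cell identity independently within each of
the 9 odorant–concentration blocks, keeping the 4 trials of a triplet
together — this preserves every block's marginal response distribution
exactly while destroying within-cell cross-stimulus structure. The
invariant fraction is recomputed per replicate (default 1,000; the
replicate count is configurable) and p = (#{null ≥ observed} + 1)/(n + 1).
Per-site significance uses the 99th percentile of the site's own null
distribution. Subsampling to a smaller population reuses the per-cell
calls, since the ANOVA is independent across cells.

## Spatial analysis (`pirinv.spatial`)

The nearest neighbor index of a class is the mean Euclidean distance (μm)
from each member to its nearest same-class neighbor ("nearest" excludes
the cell itself; classes need ≥ 2 members). Significance comes from
permuting labels over fixed positions (1,000 shuffles), one-sided toward
clustering, with the add-one estimator (#{shuffle ≤ observed} + 1)/(n + 1)
so p is never 0. A site-level statistic pools per-class NNIs weighted by
class size (the pooling rule was an open choice; both per-class and pooled
p-values are reported). Positive controls confine each constrained class
to 3–4 of 16 equal sub-areas (unconstrained background classes fill the
remaining cells); sub-area sets are redrawn up to 50 times if capacity is
insufficient. Starter-cell ensembles grow k-nearest-neighbor cell sets
around every cell and report LOO decoding accuracy per (starter, k).

## Problem sizes and defaults

The shipped analyses and tests use desk-scale sizes chosen to keep each
stage's statistical behavior measurable: 300-cell sites for population
statistics (a typical imaging site yields 100–400 cells), 3,000 cells for
invariant-fraction recovery, 10,000 null cells for the FPR bound, a
64 × 64 / 25-cell movie for segmentation, 200-shuffle × 400-map NNI
calibration, and 200 label permutations for decoder calibration. All
stochastic stages take explicit seeds; the pipeline derives stage seeds
from one master seed and reproduces bit-identically.

## Known limitations

* The greedy clustering recomputes neighbor correlations exactly but is a
  serial Python loop; fields much beyond 256 × 256 would want a compiled
  neighbor-update kernel.
* Deconvolution is the stated linear inverse; no constrained or
  sparsity-regularized spike inference is attempted.
* The run-length detector assumes approximately white baseline noise
  within a trial; strongly autocorrelated noise would need the run
  thresholds recalibrated (the ROC harness exists for exactly that).
* Balanced LOO folds discard one trial per non-tested class; with 4 trials
  per stimulus this costs a little sensitivity in exchange for calibrated
  chance levels.
* The ANOVA treats trials as a fixed effect and assumes homoscedastic
  Gaussian residuals; the generator satisfies this by construction, real
  deconvolved responses only approximately.
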