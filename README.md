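# pirinv

Analysis pipeline for odor coding in densely imaged cortical populations,
exercised entirely on synthetic two-photon data with planted ground truth.
It asks a concrete systems-neuroscience question: when the same odorants
are presented across a 100-fold concentration range, does a subpopulation
of neurons keep encoding odor *identity* regardless of *intensity* — and
can that subpopulation be found with per-cell statistics and validated
against shuffle nulls?

The pipeline covers the full path from raw movies to that answer:

1. **Simulation** (`pirinv.synth`) — calcium movies and response tables
   with known cell categories: 30 s trials (8 s baseline, 2 s odor, 20 s
   post) at 15 Hz, 4 trials per stimulus, 13 odorants at one dilution or
   3 odorants × 3 ten-fold dilutions, GCaMP6s-like kernel (τ = 2 s),
   correlated neuropil background, drift, annular cell profiles.
2. **Segmentation** (`pirinv.segmentation`) — greedy correlation
   clustering of 4-connected pixels (merge the most correlated neighboring
   pair, average their signals, repeat for I merges; I = 25,000 at
   256 × 256, scaled by pixel count), iterative pixel-weight estimation,
   and size/dispersion/border-ratio region selection.
3. **Extraction** (`pirinv.extraction`) — sub-pixel registration, weighted
   trace extraction, neuropil correction (r = 0.5, 20 μm disk), ΔF/F
   against the 4–8 s baseline median, linear deconvolution
   r(t) = f′(t) + f(t)/τ with zero-phase 2.5 Hz Butterworth smoothing, and
   run-length response detection (±2 SD for 21/19 consecutive frames,
   ROC-calibrated).
4. **Population statistics & decoding** (`pirinv.population`,
   `pirinv.decoding`) — trial-by-trial Pearson correlation structure,
   lifetime sparseness Sl = (1 − (Σr/N)²/(Σr²/N))/(1 − 1/N), PCA,
   leave-one-out LDA/SVM decoding, time-resolved decoding, and a 7-group
   concentration-generalization task (train on the most distant
   concentration only, chance 1/7).
5. **Invariance statistics** (`pirinv.invariance`) — per-cell three-way
   type II ANOVA (identity, concentration, interaction, trial); a cell is
   concentration-invariant iff identity is significant (p < 0.01) while
   concentration and interaction are not, which bounds the false-positive
   rate at 1%; overrepresentation is tested with a cell-identity-shuffle
   bootstrap and a per-site 99th-percentile criterion.
6. **Spatial analysis** (`pirinv.spatial`) — nearest-neighbor-index
   shuffle tests for spatial clustering of functional classes, simulated
   clustered maps (classes confined to 3–4 of 16 sub-areas), and
   starter-cell ensemble decoding.

Every stage is importable as a library module; the numbered scripts under
`analysis/` run the study in order and write their tables under
`results/`. A thin CLI (`pirinv simulate|segment|corr|sparseness|decode|
nni|invariance|run|fixtures`) wraps the same functions.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_segment.py
python analysis/05_invariance.py
```

prints, among other lines:

```
concentration series: 300 cells of which 30 planted concentration-invariant
recovered 92% of 25 planted cells at IoU >= 0.5 (mean IoU 0.92)
concentration-invariant: 11.0% of cells (planted 10.0%), i.e. 62% of identity-significant cells
identity-shuffle bootstrap: null 3.2 +/- 1.0% vs observed 11.0%, p = 0.0010
100-fold generalization: invariant subset 100% vs generic subset 12% (chance 14.3%)
```

Reading these numbers: segmentation finds 23 of the 25 planted cells (the
two misses are low-activity cells whose weight maps fail the border
criterion). The three-test ANOVA recovers the planted 10% invariant
fraction to within a point (11.0%, the excess being the ≤1% false-positive
allowance plus sampling). The identity-shuffle bootstrap shows that 11% is
far outside what random cell/stimulus pairings produce (~3%), and a linear
classifier restricted to the invariant cells generalizes odor identity
across a 100-fold concentration change at 100% while the remaining
"generic" cells are at chance — the planted concentration-invariant code
is real, detectable, and functionally sufficient.

The other drivers produce the remaining analyses: `03_responses.py`
(detection + ROC calibration), `04_population_decoding.py` (13-odor LOO
decoding at 84.6% vs 7.7% chance, correlation summaries, time-resolved
decoding), `06_spatial.py` (NNI shuffle tests and clustered-map controls).

## Repository layout

```
src/pirinv/        library: synth, segmentation, extraction, population,
                   decoding, invariance, spatial, pipeline, cli
analysis/          numbered drivers, 01_simulate ... 06_spatial
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, parameters, design choices, limitations
results/           tables written by the analysis drivers
```
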