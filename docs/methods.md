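# Methods

## Problem and pipeline

The package classifies two visually similar lesion classes — melanoma
(positive) vs. dysplastic/common nevus (negative) — from grayscale texture,
and ranks wavelet bases by how well their features survive resolution
downgrading. The pipeline is: indexed grayscale mapping → A/A2/A4 pyramid →
depth-3 wavelet-packet energy descriptor (252 components) → standardized
C-SVM scored by stratified 10-fold cross-validated AUC, hyperparameters
tuned by Bayesian optimization → selection conditions over the AUC grid.

## Preprocessing

* **Grayscale mapping.** Any fixed linear, strictly monotone channel
  combination is admissible for the indexed representation; the default is
  ITU-R 601 luma (0.299, 0.587, 0.114), chosen purely for convention, with
  the unweighted channel mean as a config alternative (`grayscale_map`).
  Gray pixels map to themselves, so the output range stays [0, 255].
* **Pyramid.** A2 and A4 are produced by one and two rounds of disjoint 2x2
  block averaging (2272x1704 → 1136x852 → 568x426 for native dermoscopy
  frames). Averaging preserves the global mean exactly and each step halves
  both axes; an odd axis is zero-padded by one row/column first.
* **Dimension fitting.** Before a depth-3 transform both axes are made
  multiples of 8, by default by appending zero rows/columns at the
  bottom/right (original pixels untouched); central cropping is the
  alternative, removing symmetrically with the odd remainder taken from the
  bottom/right. Padding to the *next even number only* at each level (the
  behavior a 568x426 frame historically received, yielding 428 columns) is
  reproduced implicitly: periodized transforms ceil-halve every axis, so
  odd intermediate sizes stay well-defined regardless.

## Wavelet-packet features

* **Catalogue.** 53 filter banks: Haar (id 1), db1–db10 (2–11), sym2–sym8
  (12–18), coif1–coif5 (19–23), bior{1.1…6.8} (24–38), rbio{1.1…6.8}
  (39–53), with the standard published coefficients (via PyWavelets). Ids 1
  and 2 are mathematically the same filter; both entries are kept so the
  catalogue numbering is stable. Reverse biorthogonal banks are the
  biorthogonal ones with analysis and synthesis pairs exchanged.
* **Transform.** Separable analysis (filter + decimate rows, then columns)
  with **periodization** boundary handling. Rationale: output sizes are
  exactly ⌈n/2⌉ per axis, Parseval's identity holds for the orthogonal
  families (checked to 1e-6 relative in tests), perfect reconstruction
  holds for all 53 banks (1e-8 absolute), and three iterations are always
  well-defined. The packet tree decomposes *every* node to depth 3 — no
  entropy-based basis pruning — giving 85 nodes of which 21 are internal.
* **Features.** Per branch: child energies e_i = Σ|coefficients| (raw sums,
  deliberately not normalized by sub-image area), e_i/e_max, and
  e_i/Σ_{k≠i}e_k; 21 x 12 = 252 components in fixed breadth-first branch
  order (children always LL, LH, HL, HH). Degenerate branches: an all-zero
  branch yields 12 zeros; a branch where one child holds all the energy
  uses ε = 1e-12 in the fractional-ratio denominator, keeping the feature
  finite, deterministic and monotone in e_i. Feature order must be stable
  because standardization is per-component.

## SVM evaluation

* Soft-margin binary C-SVM (L1 penalty), solved by libsvm's SMO with
  gradient tolerance 1e-3 and dual coefficients initialized at zero.
  Kernels: linear, polynomial (x'x + r)^p with offset r fixed at 1 and
  integer degree 1–10, gaussian exp(−γ|x_i − x_j|²).
* Stratified 10-fold CV with a seeded shuffle; AUC is computed per held-out
  fold from decision values (class predictions would give degenerate
  two-point ROCs) with the positive class as target, then averaged over
  folds — not pooled. The fold-mean support-vector count is reported as a
  stability diagnostic: well-conditioned features separate with few SVs.
* Standardization to N(0, 1) uses the population-sd convention and maps
  zero-variance columns to zeros. Default is fit-on-training-fold
  (`leakage_mode="fold_safe"`), the defensible statistical choice;
  `"whole_dataset"` standardizes once before splitting for comparison with
  setups that did so.
* Class imbalance is optionally handled by seeded sub-sampling of the
  majority class to a target ratio (`imbalance_subsample_ratio`); no
  class-weighted losses.

## Bayesian optimization

* Objective: 1 − mean CV AUC, minimized over log10-scaled boxes
  [1e-3, 1e6] for C and γ; polynomial degree is a continuous relaxation of
  [1, 10] rounded at evaluation, with a cache so duplicate rounded specs are
  not refit. The box is searched continuously (a discretized log grid is a
  config choice away via the candidate set).
* Surrogate: Gaussian-process regression with a constant x squared-
  exponential kernel plus a white-noise term, y-normalized, refit each
  iteration. The GP is the standard companion of the expected-improvement
  acquisition; EI is evaluated in closed form (Φ/φ) against the lowest
  posterior mean among evaluated points, maximized over 2000 fresh seeded
  uniform candidates per iteration.
* Initial design: 5 scrambled-Sobol points. Budget: 60 evaluations by
  default (the pipeline default is 15 at desk scale). Early stop when the
  loss drops below 0.02 (CV AUC ≥ 0.98), configurable.
* Overexploitation escape: if the posterior sd is below 1e-4 over the whole
  candidate set, the predicted spread is inflated 10x for that proposal,
  pushing the acquisition toward unexplored regions; escapes are recorded
  in the trace. The 1e-4 / 10x constants are package choices — the
  mechanism needs a trigger and a strength, and the results are insensitive
  to either within an order of magnitude because a single inflated proposal
  only reorders one acquisition.
* Incumbent traces are monotone by construction, and the whole loop is
  deterministic given the seed.

## Selection conditions

Condition 1 = top-n (n = 6 by default) ids by AUC at one resolution;
Condition 2 = n
 = 1. Conditions 3–5 first select the n ids with the largest
SUM(i) = Σ over the three resolutions of AUC_i — so the selected *set* is
identical whatever the priority — then order by AUC at the priority
resolution (3: A, 4: A2, 5: A4), breaking ties by SUM then by smaller id.
"Equal AUC" for tie-grouping means equal after rounding to 3 decimals,
matching the precision at which such grids are reported and avoiding
float-exactness fragility; tie groups render parenthesized. All three
operations are tested against brute-force oracles (exhaustive sort, argmax
scan, subset enumeration) on hundreds of random grids.

## Synthetic data: what it emulates and what it does not

The generator emulates the *statistical* premise of the analysis — a class
difference concentrated at a controllable spatial scale: both classes share
a Gaussian background (sd 10 intensity units around mid-gray 128) and,
optionally, a fixed dark Gaussian-profile blob (amplitude 60) for lesion-
like appearance; positives add band-limited unit-variance noise (white
noise spectrally masked to the annulus band_center ± band_width/2, default
0.25 ± 0.05 cycles/pixel) scaled by effect_size x background sd. Pixel
values are clipped to [0, 255].

The background level and sd were chosen so that clipping is negligible at
the default effect sizes: saturation at 0/255 is a nonlinearity that smears
power across the spectrum and would otherwise leak class signal outside the
intended band, breaking the generator's own ground-truth contract (the
original draft placement at level 170/sd 20 did exactly that).

Not emulated: dermoscopic color patterns, hair and other artifacts,
segmentation masks, inter-patient variability, or any non-stationary
texture. Passing tests on this data therefore demonstrate that the
machinery recovers a planted spectral class difference — they do not
certify clinical performance on real dermoscopy images, which must be
re-established with the real-data loader (`real_labels_csv`).

Effect-size calibration: with 252 aggregated energy features, even weak
per-pixel band signal accumulates; effect size ≈ 0.2 already yields AUC
0.8–0.9 at 64x64, and the test suite's "strong signal" condition
(effect 8) is far beyond separability. The class-exchangeability case
(effect 0) keeps both classes on a single RNG stream with literally
identical sampling distributions.

## Problem sizes and numerical choices

Desk-scale defaults — 40 images/class at 256x256 (pyramid 256/128/64), 5
wavelet ids, optimizer budget 15 — run the full experiment in minutes; unit
and acceptance tests use 64x64 / 32x32 images, 20–50 per class, chosen as
the smallest sizes at which the statistical contracts (chance-level null
AUC, band-power confinement, separability) are stable. Transform tests use
16x16 random matrices against a dense circular-convolution reference.
Tolerances: Parseval 1e-6 relative, perfect reconstruction 1e-8 absolute,
convolution oracle 1e-10, filter-norm checks 1e-9 (the precision of
published coefficient tables).

## Known limitations

* The AUC grids on synthetic textures saturate near 1.0 for strong
  effects, compressing differences between bases; ranking behavior is most
  informative at weak effect sizes.
* The GP surrogate treats the rounded polynomial degree as continuous; for
  very small boxes the duplicate-rejection fallback (most-uncertain
  candidate) can spend evaluations on the boundary.
* `cv_auc` flags but does not retry non-converged SMO fits.
* Figures are diagnostic, not publication-grade.
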