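# wavederm

Wavelet-packet texture features and resolution-invariant SVM ranking for
dermoscopy lesion classification.

Distinguishing malignant melanoma from a dysplastic (atypical) nevus in a
dermoscopy image is a texture problem: skin manifests repetitive patterns —
pigment network, globules, streaks — at several spatial scales at once.
`wavederm` implements a classification pipeline built on that observation,
and asks a practical follow-up question: **which wavelet bases keep their
classification performance when the image resolution is downgraded?** A base
that does lets a classifier run on 4x- or 16x-smaller images with no loss of
accuracy, which matters for low-resource (e.g. mobile) screening.

## The method

1. **Resolution pyramid.** Each RGB image is mapped to an indexed grayscale
   intensity matrix (a fixed linear, strictly monotone channel combination;
   ITU-R 601 luma by default) and downgraded twice by 2x2 block averaging,
   giving the levels A (native), A2 (1/2) and A4 (1/4). Dimensions are
   fitted to multiples of 2³ = 8 by zero-padding at the bottom/right (or
   central cropping).

2. **Wavelet-packet energy features.** A full 2-D wavelet packet transform
   (separable Mallat filtering, periodized boundaries) is applied to depth
   3, decomposing every node — detail channels included — so the tree has
   1 + 4 + 16 = 21 internal branches. Each branch contributes 12 features
   from its four children's energies *e*ᵢ = Σ|coefficients| (order LL, LH,
   HL, HH): the energies themselves, the maximum-energy ratios *e*ᵢ/*e*max,
   and the fractional ratios *e*ᵢ/Σₖ≠ᵢ*e*ₖ — a 21 x 12 = 252-component
   descriptor per image. The catalogue holds 53 bases: Haar (1),
   Daubechies db1–db10 (2–11), symlets sym2–sym8 (12–18), coiflets
   coif1–coif5 (19–23), biorthogonal (24–38) and reverse biorthogonal
   (39–53) filter banks.

3. **C-SVM with Bayesian-optimized kernels.** A soft-margin binary SVM
   (linear, polynomial or gaussian kernel) is scored by stratified 10-fold
   cross-validated ROC AUC on N(0, 1)-standardized features. C and the
   kernel parameter (γ or the polynomial degree) are tuned over 1e-3..1e6
   (log scale, 60 evaluations by default) by a Gaussian-process surrogate
   with the expected-improvement acquisition
   EI(x) = E[max(0, μ_Q(x_best) − f(x))], plus an overexploitation escape
   that inflates the posterior spread when it collapses.

4. **Resolution-invariance ranking.** From the AUC grid over
   (wavelet x resolution x kernel), Condition 1 selects the top-n bases at
   one resolution, Condition 2 the single best, and Conditions 3–5 rank by
   SUM(i) = Σ_resolutions AUCᵢ and order the selected set by the AUC at a
   priority resolution (A, A2 or A4). Equal AUC after rounding to 3
   decimals forms parenthesized tie groups.

Real dermoscopy datasets are access-restricted, so a synthetic texture
generator stands in by construction: two classes share a noise background
and a smooth dark lesion blob, and the positive class carries extra noise
power confined to a chosen annulus of the 2-D spectrum — a known "preferred
scale" that the downstream ranking should recover.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/05_resolution_ranking.py` (40 synthetic 64x64 images, class
signal at 0.25 cycles/pixel with effect size 0.25, bases 1 = haar,
26 = bior1.5, 46 = rbio3.1, gaussian kernel) prints:

```
AUC grid (wavelet x resolution, gaussian kernel):
resolution      A     A2   A4
wavelet_id
1           1.000  1.000  0.8
26          0.975  1.000  0.5
46          0.900  0.775  0.5

selection conditions:
  kernel resolution condition_1 condition_2 condition_3 condition_4 condition_5
gaussian          A     1 26 46           1     1 26 46         NaN         NaN
gaussian         A2   (1 26) 46      (1 26)         NaN   (1 26) 46         NaN
gaussian         A4   1 (26 46)           1         NaN         NaN   1 (26 46)

average AUC per resolution (mean over wavelet ids):
  kernel resolution  mean_auc
gaussian          A  0.958333
gaussian         A2  0.925000
gaussian         A4  0.600000
```

Reading: each grid cell is the Bayesian-optimized 10-fold CV AUC of that
wavelet base at that resolution (0.5 = chance, 1.0 = perfect). Here the Haar
base keeps AUC ≥ 0.8 across the whole pyramid, so Conditions 3–5 rank it
first at every priority resolution — it is the resolution-invariant choice
for this texture — while base 46 degrades once the band is pushed past the
reduced Nyquist limit. The average-AUC table summarizes how much
classification power each resolution retains overall.

The same experiment runs from a shell via the thin CLI:

```bash
wavederm synth --out data/            # synthetic PNGs + labels.csv
wavederm run  --config config.yaml    # full pipeline, writes CSV + figures
wavederm rank --grid out/auc_grid.csv # selection conditions from a grid
wavederm report --results out/        # re-render summaries
```

Real data plugs in through the same loader: a directory of PNG/BMP/JPEG
images plus a `labels.csv` (`filename,label` with labels `melanoma` /
`nevus`), configured via `real_labels_csv`.

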