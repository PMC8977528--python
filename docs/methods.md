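# Methods

## Scope and model of the data

`salpinx` quantifies two compartments of H&E-stained fallopian-tube
sections.

1. **Stroma.** Square RGB tiles of sub-epithelial stroma, labeled by
   cohort group (`Benign`, `NoSTIC`, `AwaySTIC`, `NearSTIC`), are reduced
   to a 1114-dimensional texture descriptor and screened for features
   whose case-level medians differ between groups. The `AwaySTIC` /
   `NearSTIC` distinction (more vs. less than 2 mm from a STIC lesion) is
   a manifest label supplied by the annotation step; the package never
   sees whole slides and never computes distances.
2. **Epithelium.** Ordered secretory/ciliated label sequences along
   monolayer ROIs, exported from an upstream cell classifier, are scanned
   for maximal homogeneous runs. A secretory (ciliated) cell expansion —
   SCE (CCE) — is a run of strictly more than 10 cells of one type.
   Alternative length conventions are exposed for reuse: >12 (the p53
   signature length criterion) and >30 (SCOUT).

## Stain model

Pixels follow Beer–Lambert absorbance: optical density
`OD = -log10((I + 1)/255)` per RGB channel, with the +1 intensity offset
avoiding `log 0`. Concentrations are the least-squares projection of the
OD vector onto unit stain vectors (Ruifrok–Johnston H&E defaults,
overridable), clamped at zero. Rendering inverts the same transform and
rounds to 8-bit. Because of that rounding, recovery degrades where the
*combined* OD of both stains approaches the 8-bit floor (combined OD ≈ 2.5
leaves less than one intensity unit); at the renderer's operating range
the round-trip error is < 1% relative RMS, and each stain alone inverts
cleanly over its full [0, 1.5] OD range.

Color normalization is Reinhard mean/std matching in CIELAB against a
designated reference tile, switchable off. Channels with (numerically)
zero spread in source or reference pass through unchanged; a fully
degenerate reference is flagged `zero_spread`.

## Texture panel

Per stain channel: 45 SFTA + 256 LPQ + 256 BSIF = 557 features; both
channels give 1114. Feature names (`channel.family.index`) are frozen per
package version.

* **SFTA.** Multi-level Otsu with 8 thresholds; the two-threshold
  decomposition produces 7 band images (between consecutive thresholds)
  plus 8 upper-threshold images — 15 binary images, the only decomposition
  size consistent with 45 = 15 × 3 features. Thresholds are found by an
  exact dynamic program maximizing between-class variance in
  O(classes · bins²); the common combinatorial search becomes intractable
  at 9 classes. Per binary image, in fixed order: box-counting fractal
  dimension of region borders (4-connectivity borders; image-edge pixels
  of a region count as border), mean gray level inside regions, region
  pixel count. Empty regions give (0, 0, 0); a constant channel emits the
  defined fallback (dimension 0, the constant as mean, count 0) with a
  warning.
* **LPQ.** Short-term Fourier phase over a 7×7 uniform window at the four
  lowest non-zero frequencies (1/w, 0), (0, 1/w), (1/w, 1/w), (1/w, −1/w);
  signs of the 8 real/imaginary responses form an 8-bit code; the
  256-bin histogram over valid pixels (window fully inside the image, no
  padding) is normalized to sum 1. Decorrelation is on by default with
  correlation coefficient 0.9: responses are whitened by the SVD of the
  model response covariance before quantization, with a tiny graded
  diagonal perturbation for deterministic eigenvector order.
* **BSIF.** Eight zero-mean 7×7 filters, learned once by FastICA on
  patches of a seeded synthetic texture corpus and shipped as a text data
  file (regenerate with `scripts/make_bsif_bank.py`); response signs give
  the 8-bit code, histogram as for LPQ.
* **Ties.** Responses that are zero in exact arithmetic (constant inputs,
  symmetric cancellations) code as bit 0. Floating point turns such zeros
  into ~1e-16 noise, so anything within 1e-9 of the response scale is
  snapped to zero before quantization.

## Cohort screen

Tiles aggregate to one element-wise median vector per case per group
(tubes contributed separately count as separate cases); columns are
z-scored (mean 0, sample SD 1; constant columns zeroed and flagged).
Each feature gets a one-way ANOVA across the four groups at the
Bonferroni threshold `0.05 / n_features` (0.05/1114 ≈ 4.49e-5). Features
passing the screen enter Tukey–Kramer pairwise comparisons via the
studentized-range distribution with the Kramer unequal-n adjustment; the
post-hoc threshold defaults to `0.05 / |significant set|`, a documented
interpretation since the derivation of the conventional printed cut is
not fixed by the screen itself. Z-scoring is applied before both the
screen (where it leaves F unchanged) and the UMAP embedding
(umap-learn, seeded, 2-D).

## Epithelial statistics

Runs never span ROI boundaries, and runs touching an ROI end count in
full — the true run may extend past the selection, a truncation bias
that shortens observed runs slightly. Per-slide summaries pool all ROIs:
relative SCE/CCE = count / total cells; mean expansion size averages
qualifying run lengths per slide and is *missing* (never zero) when no
run qualifies. Note that splitting an ROI inside a run of length
≥ 2(threshold+1) can *increase* the expansion count (two qualifying
halves); only boundary splits are guaranteed invariant.

Group comparisons dispatch to Kruskal–Wallis (≥3 groups, tie-corrected),
Mann–Whitney (2 groups), Wilcoxon signed-rank (paired) and Fisher's exact
(2×2 tables). All-tied data returns (0, 1).

## Biomarker evaluation

ROC curves treat high values as positive (STIC vs Benign+NoSTIC pooled);
candidate cutoffs are the unique observed values plus a sentinel, the AUC
is the rank-based pairwise probability with ties counted ½, the 95% CI is
DeLong's (a seeded stratified bootstrap is available), and the operating
cutoff maximizes Youden's J with ties broken toward higher specificity.
Spearman correlations use mid-ranks with an exact permutation p for
n ≤ 9. Confounder adjustment is OLS on the natural-log outcome with
group, age, menopausal status, BRCA and chemotherapy indicators; zero
outcomes are offset by half the smallest positive value and flagged;
rank-deficient designs fail loudly naming the collinear columns.

## Synthetic cohorts

The epithelium is a two-state Markov chain (initial state from the
stationary distribution), so run lengths are geometric:
`P(L ≥ m) = p^(m−1)` and `E[L | L > 10] = 10 + 1/(1−p)`. Age (+0.25
logit/decade on secretory persistence, −0.25 on ciliated) and STIC status
(+1.35 logit) shift the persistence parameters; the defaults put the mean
SCE size of Benign slides near 14 cells and STIC slides near 22, so the
ROC stage rediscovers a cutoff in the neighborhood of 15 on synthetic
cohorts — a calibration choice for the generator, not an estimate of any
real cohort. Group sizes default to a 39/13/25 fimbria design
(epithelium) and 43/38/34 cases (stroma; each STIC case contributes both
AwaySTIC and NearSTIC tiles), ages uniform 40–80, menopause thresholded
at 51 with 10% noise, BRCA/chemotherapy Bernoulli per group.

Stromal tiles are rendered from Gaussian random fields (spectral
filtering of seeded white noise; elliptical envelope for anisotropy)
driving eosin and hematoxylin concentration maps, plus Poisson-scattered
elliptical nuclear blobs and white noise, through the Beer–Lambert
transform. Groups differ in correlation length (4/5/6.5/9 px) and
anisotropy (1/1.1/1.25/1.5) — texture statistics, not gross color — with
an `effect_scale` knob making between-group parameter distance monotone.

What the generator does *not* emulate: real nuclear morphology, collagen
fiber structure, staining batch effects beyond global casts, spatial
correlation between tiles of one case, classifier label noise in the
cell sequences, and lesion geometry. Passing tests therefore demonstrate
the pipeline's statistical machinery and its sensitivity to controlled
texture/topology effects, not clinical performance on real slides.

## Problem sizes and numerics

Tests run the full panel on 64-px tiles (the pipeline is size-agnostic;
the descriptor dimensionality never changes), Monte-Carlo checks use
10⁶ cells for run-length tails and 10⁵ for persistence recovery, null
calibration uses 200 simulated 4-group cohorts of 1114 features, and the
end-to-end graded-effect check uses 8 cases × 3 tiles per group.
Studentized-range p-values come from scipy's `studentized_range`;
tie tolerances are relative (1e-9 of scale); all simulations are seeded
and bit-reproducible.
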