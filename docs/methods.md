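# Methods

This note records the models, parameter choices and numerical decisions
behind `msigrade`, and what the synthetic phantoms do and do not
establish about real data.

## Data model

An MSI acquisition is a raster of pixels (default pitch 100 µm), one mass
spectrum per pixel per ionization mode over m/z 460–1200.  Positive- and
negative-mode rasters acquired with a half-pitch offset are co-registered
by nearest-neighbour pairing of the offset-corrected pixel centres (ties
broken by lowest (y, x)); each mode is TIC-scaled independently before
the joint matrix is assembled because ionization efficiencies differ
between polarities.  All statistics operate on the `PeakMatrix`:
pixels × mode-tagged centroid features (`POS_703.57`, `NEG_536.50`, …).

## Preprocessing

* **Smoothing** — Savitzky–Golay, window 9 points, polynomial order 3
  (typical reflectron-TOF profile widths); undershoot clipped at zero.
* **TIC normalization** — each spectrum scaled to a common total ion
  current; the dataset default target is the median raw TIC so
  intensities stay on a familiar scale.  The chain order is
  smooth → TIC → pick; the steps nearly commute and the alternative
  order is available.
* **Peak picking** — local maxima with S/N ≥ 3.  Noise is 1.4826 × the
  median absolute deviation of the residual after subtracting a
  running-median trend (~100 points, reflect padding — nearest padding
  repeats a single endpoint across half the edge window and manufactures
  false peaks at the mass-range edges).  S/N uses the height above the
  trend: a literal intensity-over-noise rule would pass every point of
  any spectrum whose baseline offset exceeds 3× the noise.
* **Alignment** — peaks pooled over pixels, clustered by single linkage
  along m/z with gaps > 0.15 Da splitting groups (TOF-scale accuracy over
  this mass window); each group becomes one feature at its
  intensity-weighted mean m/z.  Groups present in fewer than 25% of
  pixels are dropped at the dataset level: at S/N 3 a long profile axis
  yields roughly one noise maximum per thousand points just above
  threshold, and these are uncorrelated across pixels, whereas genuine
  lipid features appear in essentially every on-tissue pixel.
  Centroided input skips smoothing and picking.

## Spatially-aware segmentation

Each pixel's feature vector is augmented with the Gaussian-weighted
feature vectors of its grid neighbours within Chebyshev radius r
(weight `exp(−(di²+dj²)/(2σ²))`, σ = r/2, missing neighbours
zero-padded); standard k-means (k-means++, 10 restarts, one seed for the
ensemble) runs on the augmented vectors.  With r = 0 the operation *is*
plain k-means, which the tests exploit as an oracle.  Defaults k = 7,
r = 1: seven molecular signatures resolving six tissue histologies plus
one off-tissue matrix cluster.

Clustering operates by default on log-transformed TIC-scaled
intensities.  MSI intensity noise is multiplicative, so on the raw scale
the within-class variance grows with the square of the class mean and
k-means spends clusters splitting bright classes instead of separating
dim ones; the log transform equalizes the variance across classes.  An
`eps` of 1e−6 guards exact zeros produced by alignment.

Segments are mapped to histology by plurality over annotated pixels
(ties break by label order; clusters with no annotated pixels default to
mucin/matrix and are flagged).

## PLS-DA classification

Class labels are one-hot encoded and regressed on column-centered
intensities with an A-component PLS2 (NIPALS) fit; a pixel takes the
class with the largest predicted score, ties breaking by class order.
With A equal to the rank of X the fit coincides with ordinary least
squares — the number of components is the regularizer.  Unit-variance
scaling is off by default since TIC-normalized intensities share a
scale.

The pipeline classifier (`PixelClassifier`) trains and predicts on the
same spatially augmented log-TIC representation the segmentation uses.
This choice is load-bearing: at the generator's calibrated noise level
the Bayes-optimal single-pixel six-class accuracy (nearest true class
centroid in log space) is about 0.81, while the augmented representation
reaches ≥ 0.90 held out.  Tissue classification is a spatial problem;
a per-pixel classifier that ignores the neighbourhood discards most of
the available signal.  The low-level `train_plsda` / `predict_histology`
functions still operate on any plain matrix.

A is chosen by stratified 5-fold cross-validation with the
one-standard-error rule over candidates {4, 8, 12, 16}: the augmented
representation multiplies the feature space ninefold, so useful
components extend past the usual single-spectrum range (accuracy still
improves from A = 10 to A = 15 on the default phantom).  The pipeline
default fixes A = 12 for speed; CV is enabled by setting
`n_components: null`.

Necrosis subtyping (UN vs ILN) is available both inside the single
seven-class model and as a two-stage variant — a six-class model with
merged necrosis followed by a dedicated two-class subtyper — mirroring
a workflow where the necrosis segment is mined after the fact.

## Marker statistics

The a.u.c. is the rank-based Mann–Whitney concordance probability
`P(target > rest) + ½P(tie)`; it is invariant under monotone intensity
transforms.  The rest sample is a seeded random subset of non-target
pixels of size min(n_target, n_rest), stratified as evenly as possible
across the other histologies so that no single rival class dominates —
which suppresses markers that separate several histologies at once.
Fold change is the ratio of arithmetic mean intensities (raw scale),
summarized as mean ± sd across samples (ddof 1); a single-sample fold
change is reported with sd 0 and flagged.  A zero rest mean raises an
error rather than producing infinity.

## mTRG

With T = % viable tumor + usual necrosis and F = % fibrosis +
inflammation over the lesion denominator (adjacent liver, mucin/matrix
and unclassified pixels excluded; unsubtyped necrosis counts as UN, the
conservative reading):
T = 0 → 1; T < 7 → 2; T < 50 → 3; otherwise F ≥ 5 → 4, else 5.
The rules are evaluated top-down, so the grade is a total function of
the composition and monotone non-decreasing in T at fixed F.  Decisions
at the published table's edges: T in [7, 50) maps to grade 3 regardless
of F (the tumor range drives the grade); F = 5 with bulky tumor maps to
grade 4 (the row requiring a fibrotic response claims the boundary);
T = 7 exactly is grade 3.  A `tumor_tolerance` flag (default 0%) lets
noisy automated classifications still reach grade 1.  Grades 1–2 form
the major, 3 the partial, and 4–5 the minor response group.

## Survival

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated
to lifelines (events processed before censorings at tied times; df =
groups − 1).  Grader agreement is the Pearson product-moment correlation
of grade vectors (Spearman behind a flag); constant vectors are an
error.  A filter restricts analysis to chemotherapy-treated lesions when
the clinical table carries a `chemo` column.

## Synthetic phantoms

The generator emulates the anatomy of a treated liver metastasis: a
matrix frame, a liver rim, and a lesion whose interior is partitioned by
thresholded smooth Gaussian random fields into a tumor core with
embedded UN foci, ILN foci ringed by one pixel of fibrosis, and
contiguous inflammation/fibrosis bands — the band order places
inflammation at the tumor–fibrosis interface, as inflammatory stroma
sits in real lesions.  Quantile thresholds hit the requested class
fractions up to blob discretization.  Defaults (fractions of the lesion
interior): ILN 0.14; tumor/inflammation/fibrosis bands 0.42/0.18/0.40;
UN 0.22 of the tumor core.  In-lesion mucin pockets are opt-in: they
share the mucin/matrix signature but sit in a tumor neighbourhood, so
under spatial augmentation they constitute an eighth spatial-spectral
context, and k = 7 has no slack for it.

Intensities are `signature(class, feature) × exp(N(0, σ_log²)) ×
tic_factor`.  The signature table elevates each published marker in its
histology by its printed fold change, adds 30 nuisance features at
baseline (so ranking has something to reject), and gives mucin/matrix
pixels a dim lipid profile (0.4) dominated by two synthetic
matrix-cluster ion features (1.2 off tissue, 0.05 on tissue) — off-tissue
MALDI pixels show matrix ions, which is what gives the matrix segment
its own molecular signature.  σ_log defaults to 0.944, the value for
which the binormal a.u.c. `Φ(ln FC / (σ√2))` of the fold-5.62 ILN marker
equals 0.902 (verified numerically in the tests); the per-pixel TIC
factor is log-normal with unit mean and CV 0.25, a typical pixel-to-pixel
TIC spread.  Noise is multiplicative log-normal because intensities are
positive and CV-stable.

Profile rendering draws each peak as a Gaussian (amplitude = matrix
intensity, default FWHM 0.25 Da on a FWHM/5 axis) plus constant baseline
and white noise, for exercising the preprocessing chain.  Survival
records draw exponential event times with per-response-group monthly
hazards (defaults 0.012 / 0.034 / 0.078, giving 3-year survival of
roughly 65% / 30% / 6% — the clear three-arm separation of stratified
CRCLM cohorts), independent uniform censoring on a fraction
`censor_rate` of subjects, and administrative censoring at the horizon
(36 months).

Study scenarios cycle through five lesion compositions whose true
compositions land safely inside each grade's T/F region, so a cohort
spans the full grade scale.

**What the phantoms do not show.** Class differences ride only on the
published marker lipids plus two matrix ions; real spectra differ across
hundreds of correlated lipids, show mass drift, isotopes and matrix
artifacts, and real annotation is imperfect.  Passing tests demonstrate
that the pipeline recovers structure it is designed for at a calibrated,
realistic noise level — not that it will reach the same accuracies on
clinical cohorts.

## Problem sizes

The default phantom is 128 × 128 pixels (16 384 spectra, 53 features);
the packaged end-to-end study uses 20 lesions at 48 × 48 with a fixed
A = 12 classifier, which keeps a full run (segmentation of 8 training
lesions, library of ~12 000 augmented spectra, classification of 12 test
lesions, grading, survival) around 20 s on one CPU.  Larger cohorts
scale linearly in pixels.

## Known limitations

* The spatially-aware k-means implements the fixed (non-adaptive)
  Gaussian neighbourhood; the edge-preserving adaptive variant is out of
  scope, so segment boundaries blur at one-pixel structures.
* k = 7 leaves zero cluster slack: if one histology's within-class
  spread exceeds another's between-class separation, a class can lose
  its cluster to a split.  The phantom geometry keeps regions contiguous
  and comparable in size for this reason.
* PLS-DA scores are not calibrated probabilities; argmax labels only.
* Vendor raw formats, 3-D MSI, ion mobility, baseline subtraction, mass
  recalibration and isotope deconvolution are not implemented.
* Fold-change dispersion is across samples; the across-pixel variant
  sits behind a flag, and with one sample the sd is 0 by construction.
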