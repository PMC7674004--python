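# Methods

This note documents the models, numerical choices and open design
decisions behind `octamls`, in the package's own words. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pipeline model

The unit of analysis is one eye: six co-registered grayscale en-face OCTA
projections (superficial, deep, avascular, whole retina, choriocapillaris,
choroid) on a common grid, plus an annotated fundus overview with circular
delineations of the optic disc and the fovea, plus laterality (OD/OS) and
optional clinical scalars (circumpapillary RNFL thickness in µm,
visual-field mean deviation in dB).

### Fovea–disc axis

Head tilt during acquisition rotates the retinal anatomy in the image
frame, so sector analysis must be referenced to the fovea–disc axis. The
angle α is the arctangent of the (row, col) difference between the fovea
and disc circle centroids; image rows increase downward and α > 0 means
the fovea lies below the disc row. For left eyes the column difference is
negated so mirrored eyes yield the same α. The device's exact sign
convention is not public; this one is chosen, documented and used
consistently — any consistent convention gives identical sector features
because generation and analysis share it. The sector map (not the image)
is rotated: binary masks rotate losslessly with nearest-neighbour
resampling, and the annular sectors are in fact constructed analytically
in polar coordinates, so the rotation costs no resampling at all and the
six wedges partition the annulus *exactly* (half-open arcs,
pixel-center inclusion).

### Segmentation

*Macrovessels* (superficial layer anchor, the highest-contrast layer):
threshold at the upper 88th intensity percentile, morphological opening
then closing, drop 8-connected components with area < 250 px. Choices the
source method leaves open:

- Structuring element: 3×3 square, one iteration each — the smallest
  kernel that removes single-pixel speckle without merging capillaries.
- Percentiles: linear interpolation between order statistics.
- Tie rule: when the percentile value saturates at the image minimum or
  maximum the comparison is strict (`>`), otherwise inclusive (`≥`). This
  makes a constant image yield an empty mask, lets a bright minority on a
  dark-majority background survive, and keeps a bright-majority image from
  becoming an all-true mask.
- The 250-px cutoff is resolution-bound; it is scaled by
  `image_area / 245²` on other grid sizes.
- Connectivity is 8-way for the area filter as well (stated only for the
  ONH step in the source; unified for consistency).

*ONH optically hollow area* (choroid anchor, best hollow/vascular
contrast): global histogram equalization, keep pixels at or below the
40th percentile of the equalized image (strictly below when the value
saturates), keep the largest 8-connected component, and summarize it as a
circle with the component's centroid and equal-area radius √(area/π).

### Sectors and the VIM feature

The annulus runs from the ONH-OH circle radius to the minimum distance
from the disc center to an image border ("largest possible, radius
constant for all sectors"). The Garway-Heath arc layout — temporal 90°
centered on the disc→fovea direction, the four oblique sectors 40° each,
nasal 110° — is the standard map; the source prints no angles, so the
layout is configurable (`SectorSpec`). The feature is the median intensity
over ROI ∖ (macrovessels ∪ ONH circle) — the median being robust to
residual bright-vessel outliers and free of normality assumptions. An ROI
that is empty after exclusions raises an error; a silent zero would mimic
disease. 6 layers × 7 sectors = 42 features.

### Classification protocol

Outer leave-one-out over subjects; all training-side decisions (feature
ranking, top-k selection, grid search with stratified 5-fold CV scored by
accuracy) use only the outer training split. The published protocol picks
k as the argmax of the *outer* accuracy-vs-k curve; this is reproduced
exactly, ties broken toward the smallest k, and flagged in every report as
optimistically biased. Binary ROC scores are signed SVM decision values or
tree-ensemble class probabilities; the severity task is one-vs-all with
per-class scores. Leaf/split-size percentages convert to counts by
ceiling (scikit-learn's fractional semantics). No class reweighting.
All stochastic components derive child seeds from one master seed via
`numpy.random.SeedSequence`.

The gradient-boosting model is scikit-learn's
`GradientBoostingClassifier` (xgboost is not a dependency); the boosted-
tree grid maps gamma → `min_impurity_decrease`, column subsampling →
`max_features`, leaf percentage → fractional `min_samples_leaf`.
`min_child_weight` has no analogue there and is omitted from the default
grid.

### Statistics

- Mann-Whitney: exact enumeration of all C(n₁+n₂, n₁) assignments (ties
  via midranks) when n₁+n₂ ≤ 12; tie-corrected normal approximation (no
  continuity correction) otherwise. Two-sided p = fraction of assignments
  with |U − n₁n₂/2| at least the observed deviation.
- Permutation one-way ANOVA: F statistic, add-one estimator
  p = (1 + #{F\* ≥ F}) / (1 + n_perm), default n_perm = 10⁴ (stable
  3-decimal p at desk scale); post hoc pairwise permutation tests on
  |Δmean| with Benjamini–Hochberg adjustment (the unnamed "FDR" is read
  as BH).
- DeLong: placement values via midranks; covariance of paired AUROCs from
  the empirical placement covariance; identical score vectors give z = 0,
  p = 1 by convention.
- McNemar–Bowker: Σ(n_ij − n_ji)²/(n_ij + n_ji) over off-diagonal pairs
  with positive sums; df = number of included pairs; reduces to McNemar
  without continuity correction at K = 2.
- Stratified bootstrap: resampling within each class stratum preserves
  class counts, so AUROC/sensitivity/specificity are defined on every
  resample; percentile 2.5/97.5 interval.
- KS normality uses estimated parameters without the Lilliefors
  correction, hence conservative; it gates nothing in the pipeline (rank
  tests are used throughout) and is provided for data description.

## The phantom: what it does and does not emulate

Defaults state the world once: 245×245 px grid (a typical 3×3 mm en-face
raster; the source prints no pixel dimensions), 8-bit intensity range,
disc radius 30 px at the image center, disc intensity 25, layer
backgrounds superficial/deep/avascular/retina/choriocapillaris/choroid =
120/110/30/115/130/140 a.u. (free parameters — no healthy-eye intensity
statistics are published), Gaussian noise σ = 6, a 7-branch macrovessel
tree of width 4–8 px and length 90–140 px per branch (each branch > 250 px
in area, so the survival filter is exercised in both directions; a
separate 100-px blob fixture exercises removal). Severity effects are
linear per step (healthy=0, mild=1, moderate=2, severe=3) with clamping to
[0, 255] — the simplest monotone model consistent with the cohort
ordering; the default effect map concentrates loss at superficial-IT
(−9.6 a.u./step) and spares the avascular and choroidal layers. RNFL is
drawn at 95 − 12·step ± 8 µm, clamped at a 50 µm floor (the floor
effect). Diagnosis/type groups draw their severity stratum with the
37/26/19 mild/moderate/severe mix of the reference cohort.

The feature-level generator (`generate_cohort_feature_table`) draws the
42-column table directly — Gaussian around group means — for
classification and statistics tests where image synthesis would only add
runtime; the image generator feeds the geometry/segmentation tests and the
end-to-end pipeline.

Not emulated: OCTA speckle/decorrelation statistics, projection and
motion artifacts, anatomically realistic vasculature, inter-eye
correlation. A green test therefore establishes *pipeline correctness*
(geometry, exclusion logic, protocol fidelity, statistical calibration),
never clinical performance.

## Numerical and degenerate-input choices

- A percentile threshold needs a spread background: on a noise-free
  two-level image the 88th percentile collapses onto the background level
  and the tie rule above returns the empty mask rather than an
  all-background "vessel" mask.
- The hollow-circle step assumes the choroid's dark-disc contrast
  dominates; strong artificial sector steps on the *choroid* background
  can divert the largest dark component (the retinal layers carry the
  sector effects in the phantom defaults).
- `estimate_fovea_disc_angle` raises on coincident centroids; annulus
  construction raises when the disc touches the image border
  (outer ≤ inner radius).
- Bootstrap CIs on pooled LOOCV scores are anti-conservative under the
  null: decision scores differ systematically between training folds, so
  the pooled-score AUROC has more replicate-to-replicate spread than a
  subject-level bootstrap (which treats the scores as fixed) can express,
  and class imbalance adds a mild pessimistic bias (leaving out a subject
  tilts the training balance against its own class). The null-calibration
  acceptance test documents and asserts the nominal coverage anyway and
  is expected to sit a few points below it.

## Known limitations

- The k-selection-on-test-curve protocol is reproduced for fidelity, not
  endorsed; reports carry an explicit optimism note.
- Exact Mann-Whitney is enumeration-based and deliberately capped at
  small n (no network algorithm).
- The phantom's intensity levels are conventions, not measurements;
  absolute VIM values have no clinical meaning.
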