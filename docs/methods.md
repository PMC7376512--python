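# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `ki67hotspot`, and what the synthetic data do and do
not establish.

## Hot-spot detection

**Inputs.** A slide is a table of nucleus centroids (µm, origin at the
slide's top-left, x rightward, y downward) with cell class
(tumor/immune/stroma/other), Ki67 status, and ROI membership, plus ROI
polygons classified invasive / in-situ / artifact. The scanner pixel
pitch (0.4537 µm) is carried as provenance metadata only; no pixel data
are touched. Hot-spot analysis first restricts to tumor-class cells in
invasive ROIs — in-situ components and Ki67-positive lymphocytes are a
classic source of false hot spots and are excluded by construction.

**Heatmap.** The accumulator grid covers the bounding box of the
invasive ROIs. The bin size defaults to one eighth of the drawing
radius (65 µm at 20×, 32.5 µm at 40×): the grid must be much coarser
than the slide for the heatmap to act as a density smoother, and tying
it to the radius keeps disc rasterisation scale-free. It is
configurable. A bin belongs to a cell's disc iff the bin *center* lies
within Euclidean distance ≤ r of the centroid (closed boundary);
boundary discs are clipped, not wrapped. Accumulation is implemented
exactly by per-row difference arrays (each (cell, grid-row) pair
contributes one contiguous run of bins), which is O(cells × rows/disc)
and bit-identical to a brute-force distance check.

**Eligibility masks.** Ratio heatmaps mask bins whose total in-radius
count is below the app's cell target; this is what prevents the
documented tendency of ratio heatmaps to place hot spots on sparse
tissue peripheries where a handful of positive cells gives ratio ≈ 1.
Circle apps additionally mask seed bins below the target on the
positive basis (`enforce_min_cells=True` by default) so that circle
apps have a defined minimum-cell semantics; since overshoot in the
published registry suggests enforcement may be weak in the original
platform, the mask can be disabled.

**Extraction.** Circle: the field-of-view disc centered on the maximal
eligible bin. Ties are broken to the smallest (row, col) in row-major
scan order — stable and documented. Contour: among super-level sets
{H ≥ t} for t in the (finite) set of distinct heatmap values, take the
8-connected component containing the eligible maximum at the highest t
whose component holds ≥ m tumor cells; the region is the union of that
component's bin squares. Because the components are nested as t
decreases, the contained-cell count is monotone, and the implementation
binary-searches the level list; a full linear sweep is kept as a test
oracle and agrees bit-exactly. Cells map to bins half-open
([x, x+b) × [y, y+b)), so every cell belongs to exactly one bin, and a
contour region's cell count is exactly the sum over its bins. If even
the lowest level holds fewer than m cells the result is
`no_valid_hotspot`, never a sub-minimum region.

**Scoring.** Ki67 index = 100·n⁺/n over cells inside the region, with
the circle boundary closed. n = 0 is flagged, not divided.

## Global scoring

The global index is 100·positive/total over predicted-tumor cells in
the tumor-area ROIs (invasive-only by default; in-situ inclusion is a
flag). Classification is pluggable: the `oracle` classifier copies
ground truth (making pipeline tests exact), and `noisy:<fp>,<fn>`
corrupts the tumor call at given false-positive/false-negative rates.
The upstream watershed segmentation settings of the original
nucleus-detection pipeline are recorded as constants for provenance but
never executed — the package's inputs are already nucleus tables. The
global index is exactly conserved under disjoint spatial partition
(cell-count-weighted mean of sub-indices), which the tests assert to
machine precision.

## Synthetic slides and cohorts

The generator produces the statistical structure the analysis assumes:

* **Tumor nuclei**: Thomas cluster process (parents 8/mm², mean 450
  offspring, cluster σ 140 µm) plus a 1100/mm² homogeneous background,
  restricted to an irregular invasive ROI on a 2.6 × 2.6 mm slide
  (~13 000 tumor cells). These densities give peak local counts above
  1200 cells per 0.26 mm-radius disc, matching the requirement that
  even the largest cell-target apps find valid hot spots on nearly
  every slide, as in clinical material (dense carcinoma reaches several
  thousand nuclei/mm²).
* **Positivity field**: p(x) = baseline + Σₖ aₖ·exp(−dₖ²/2σₖ²) clamped
  to [0, 1]. Defaults: one bump per slide, amplitude U(0.05, 0.25),
  σ U(800, 1200) µm, centered on a cluster parent (proliferative foci
  are themselves cellular), baseline ~ Beta(1.5, 9). Two properties
  drove this choice. First, the bump scale is broad relative to every
  hot-spot region (0.13–0.52 mm radius): with sharp bumps, apps of
  different region size see systematically different dilutions of the
  peak, which acts as a slide-varying rater effect and destroys the
  empirically observed pattern that reproducibility is governed by the
  *number of scored cells*; broad fields put all apps on the same local
  plateau so binomial counting noise (∝ 1/√cells) dominates
  between-app disagreement. Second, the marginal distribution of the
  realized global index (median ≈ 20–24%, roughly balanced around the
  20% cut-off) matches the reported clinical distributions closely
  enough that dichotomy-based analyses are non-degenerate.
* **Confounders**: homogeneous immune cells (150/mm², 30% Ki67⁺) and
  stroma (100/mm²) across the slide; with probability 0.3 an in-situ
  ROI whose tumor component has baseline + 0.3 positivity, to exercise
  the invasive-only restriction.
* **Ground truth**: `true_global_ki67` is the mean of p over the
  generated invasive tumor cells and `true_hotspot_ki67` its maximum,
  so hot-spot truth ≥ global truth holds identically.
* **Outcomes**: RFS and OS times are exponential with log-hazard
  β·1[true global Ki67 ≥ 20%] (β = log 3 by default; baseline hazards
  0.05/yr and 0.03/yr), with *independent* exponential censoring whose
  rate is solved numerically so the expected censored fraction equals
  the configured rate. Covariates (ER/PR/HER2, grade, mitotic score,
  pT, pN) are drawn to resemble an ER+/HER2− luminal cohort, with
  grade/mitotic score shifted upward for proliferation-high patients;
  the intrinsic subtype label is luminal B iff truly high, flipped with
  25% label noise and missing in 20%.
* **Seeding**: one master seed; each slide's stream derives from
  SeedSequence(master, SHA-256(slide_id)), so cohorts are
  bit-reproducible and slides independent of cohort size. A
  covariate-only cohort mode (no point patterns) integrates the bump by
  a fixed 256-point Monte-Carlo average over an ROI-sized disc; its
  true-Ki67 distribution agrees with the slide-based mode.

**What the synthetic data do not emulate**: real stain variation,
segmentation and classification errors (beyond the parametric noisy
classifier), nucleus-scale exclusion effects, spatially correlated
immune infiltrates, informative censoring, and any coupling between
covariates and outcome other than through proliferation. Passing tests
therefore demonstrate correctness and internal consistency of the
methods and the qualitative orderings they imply — not clinical
performance on real slides.

## Statistics

* **ICC**: two-way random-effects, absolute-agreement, single
  measurement (ICC(2,1); computed via `pingouin`), on ln(Ki67% + 1) —
  the +1 admits zero scores. Complete-case across the compared
  methods. App groups for the reproducibility analysis: target ≈200
  cells {APP06, 08, 10, 12, 14, 16}; 400–800 {APP20, 21, 22, 24, 25,
  26}; ≈1000 {APP05, 09, 13, 23, 27}.
* **Bland–Altman**: bias with one-sample t-test, 1.96·SD limits of
  agreement, proportional bias by OLS of differences on pair means;
  constant pairs are flagged degenerate rather than regressed.
* **Dichotomy** at ≥ 20%; missing propagates. **Surrogate subtype**
  (St Gallen 2013): luminal A-like iff ER ≥ 1%, HER2−, PR ≥ 20% and
  Ki67 low; luminal B-like otherwise among ER+/HER2−; others not
  applicable. **Concordance** vs intrinsic labels: complete-case match
  rate and Cohen's κ, with the 2×2 table emitted so κ is recomputable.
* **McNemar**: exact binomial on discordant pairs (continuity-corrected
  χ² optional). **Survival**: Kaplan–Meier with two-sided log-rank;
  Cox partial likelihood with Efron ties (via `lifelines`); adjusted
  models mirror the clinical analysis (RFS: pN1 + Ki67 class; OS:
  grade + mitotic score + pN1 + Ki67 class). Monotone-likelihood or
  non-convergent strata (e.g. a grade stratum with no events) are
  reported per covariate in a note column, not raised. α = 0.05
  two-sided throughout.
* **QC**: an app is flagged when its median realized hot-spot cell
  count exceeds 2× its target (configurable) — dense tissue makes
  fixed-size circle apps overshoot their nominal counts.
* **Exclusion rule**: a slide enters the score matrix only if every
  configured app and the global scorer succeeded on it; failures are
  logged per slide with mechanical reason codes (`no_invasive_tumor`,
  `no_valid_hotspot`).

## Problem sizes

The default experiment sizes are chosen as the smallest that make each
property statistically unambiguous: oracle equivalence on 120 fuzzed
slides (≤500 cells, grids ≤60×60, bit-exact), the minimum-cell
guarantee on 1000 fuzzed slides (zero tolerance), reproducibility
ordering on 20 cohorts × 150 slides (the ordering must hold in ≥18),
hazard-ratio recovery on 200 replicates of n = 500 (mean within
[3.4, 4.7] of true HR 4, ≥90% CI coverage, null rejection 2–8%), and a
single 150-slide end-to-end replication.

## Known limitations

* The original commercial platform's heatmap resolution, connectivity
  and tie rules are proprietary and unpublished; the conventions here
  (bin = r/8, 8-connectivity, row-major tie-break, closed boundaries)
  are documented alternatives, so numeric identity with that platform
  is not claimed.
* Whether circular apps enforce their cell target by masking or not is
  unknown in the original; both behaviours are supported.
* ICC confidence intervals inherit two-decimal rounding from the
  backend; estimates are full precision.
* The generator's survival model links hazard only to the Ki67
  dichotomy, so adjusted Cox models estimate covariate effects that
  are truly null apart from their correlation with proliferation.
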