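# Methods

## The lesion-load model

A canonical probabilistic map over a common 2 mm isotropic MNI-like
grid stores, per voxel, the count I ∈ {0..N} of healthy control
subjects (N = 12 in the reference study design) whose binarised tract
or activation map contains that voxel; I/N is the voxel's probability
of belonging to the structure. The lesion load of a binary lesion mask
L is the probability-weighted overlap volume

    LL = Σ_{v: L(v)=1} (I(v)/N) · v_cc        [cc]

so 0 ≤ LL ≤ min(lesion volume, Σ_v (I/N)·v_cc). The weighting (rather
than a probability cutoff followed by volume counting) is the only
reading that reconciles "summing the intersecting voxel intensities"
with load tables expressed in cc; the raw weighted voxel count is also
exposed on the result object.

All cross-volume operations require an exact grid match (shape equal,
affines within 1e-4 mm). No resampling is performed anywhere: spatial
normalisation is an upstream registration concern, and silently
resampling would hide registration errors.

### Canonical map construction

Per-subject tract volumes are trimmed at the 50th percentile **of their
nonzero value distribution** (linear-interpolation percentile, kept at
`>=` the cut). A percentile over all voxels of a mostly-zero tract
volume would be meaningless; the within-tract trimming is applied per
subject, before binarisation. Thresholding uses a ~1e-9 relative slack
below the cut so limiting percentiles behave continuously.

Activation maps are masked to gray matter before aggregation.
Aggregation is a voxelwise sum of binary maps; the combined
structural+functional map sums the two components on the probability
scale capped at 1, stored back as counts round(p·N). The cap keeps the
combined map a probability; the published combined-load column is not
consistently reproducible by any simple function of its two component
columns, so no attempt is made to match it exactly.

## The cohort analyses

### Regressions

Single-load models: OLS of an outcome on the (transformed) load plus
age and months post-stroke. Fluency outcomes (CIUs/min, Words/min) use
a cube-root transform of volumetric predictors; naming (BNT) is linear
in load. After the initial fit, cases with |internally studentized
residual| > 2.5 are removed and the model is refit **once** (no
iteration). On the reference table this removes at most one case
(patient 2 for CIUs/min), consistent with the reference analysis
removing two of fifty.

The dorsal–ventral comparison regresses an outcome on the AF, EMC and
UF loads controlling total lesion volume. Its published partial
correlations are reproduced to two decimals only under the convention:
cube root applied to all four volumetric terms for fluency outcomes, no
demographic covariates, and no outlier pass — so that is the convention
implemented (`fit_dorsal_ventral_comparison`). Partial R is the signed
partial correlation between outcome and one term given all other model
terms (residualise both, correlate), with a t-test p-value on n−k−2
degrees of freedom. p-values are two-sided and uncorrected, matching
the reference analysis.

### Severity stratification

Two-step clustering of a single behavioral score with k = 2 is replaced
by the **exact** least-squares two-group partition: scan the n−1 sorted
split points, minimise total within-group sum of squares. For one
variable this is the global k-means optimum without seed dependence;
tests verify it against brute force and a k-means oracle. The lower
group is severe.

Discriminant accuracy is the resubstitution accuracy of a one-variable
linear discriminant with pooled within-group variance and priors
proportional to group sizes (the classical default), cross-checked
against scikit-learn's LDA.

ROC conventions: severe is predicted when the predictor is **at or
above** a cutpoint (larger load = worse outcome); candidate cutpoints
are midpoints between consecutive observed values plus sentinels beyond
the extremes — the printed reference thresholds (3.74, 4.01, 4.25 cc)
are exactly such midpoints of consecutive AF-load values in the
table, which anchors this convention independently of any accuracy
figure. The operating point maximises Youden's J = sens + spec − 1 with
ties broken toward higher specificity; reported accuracy is the raw
proportion correct; AUC is the trapezoidal area, identical to the
normalised Mann–Whitney U statistic (ties count ½), which the tests
assert exactly. Cutoff "bands" are the open interval between the
largest severe and smallest non-severe score; when reproducing the
published band analyses, severe = score ≤ the band's printed low
endpoint (8 CIUs/min, 31 Words/min, BNT 5).

### Known discrepancies with the printed sources

The printed patient table does not exactly regenerate every printed
headline percentage, and three gaps are arithmetic rather than
conventional:

* The printed fluency ROC "accuracy 96% (sensitivity 91%, specificity
  85%)" is impossible as stated: raw accuracy is a prevalence-weighted
  average of sensitivity and specificity and must lie in [85, 91]. The
  recomputed accuracy is 88% (and the published 96.0 matches a printed
  band AUC instead). The companion numbers do reproduce: threshold
  3.74 cc exactly, band AUC 93.6 vs 93.5.
* The printed naming ROC accuracy (90%) likewise exceeds what its own
  sensitivity/specificity (91%/75%) permit with any group sizes from
  the table; recomputed: 84%, with sensitivity 91% and threshold
  3.74 cc (published ~4.01 cc, a neighbouring midpoint).
* The lesion-volume classifier reproduces its printed 88% accuracy
  exactly and is ordered below the AF load by AUC, but its
  Youden-optimal threshold on the table is ~73 cc, not the printed
  ~105 cc (which appears only under a different severity labeling whose
  accuracy is then 82%).

The acceptance tests for these blocks assert the printed values at
their stated tolerances and therefore fail honestly; every other
headline number reproduces within tolerance.

## The synthetic-data generator

What it emulates, and with which defaults:

* grid 48×56×48 at 2 mm (0.008 cc voxels), N = 12 map subjects;
* tract tubes of radius 7 mm around a curved left-hemisphere
  centerline, per-subject centerline jitter SD 2 mm — giving a canonical
  AF-like map with ~12 cc probability-weighted volume and a graded rim,
  matching the reference load scale (loads 0–12 cc, decision region
  ~4 cc);
* activation blobs (radius 6–7 mm) at three nodes, masked by a crude
  cortical-ribbon stand-in;
* lesions grown by 6-connected flood fill with distance-biased random
  priorities (pure random priorities degenerate into invasion
  percolation, i.e. fractal ~30%-fill shapes; the distance bias with
  roughness 0.6 yields compact but irregular, non-convex masks),
  targeting 15–250 cc, within the reference cohort's observed range;
* a severity mixture (default 70% severe) placing large lesions on the
  tract and smaller ones off it, and outcomes

      outcome = max(0, β0 + β1·LL^(1/3) + ε),  ε ~ N(0, σ)

  with defaults (35, −16, 6) for CIUs/min, (60, −22, 10) for Words/min,
  (14, −5.5, 2) for BNT — intercepts near the unlesioned reference
  means, slopes steep enough that loads beyond ~4 cc push fluency
  toward the floor. CIUs/min is capped at Words/min; BNT is rounded and
  clipped to 0..15. The censored-at-zero fraction is recorded in the
  truth dict so recovery tests can use low-censoring regimes.

One integer seed drives a spawned stream hierarchy (maps / lesions /
outcomes / demographics), so each stage is independently reproducible
and identical seeds give bit-identical cohorts.

What it does **not** emulate: vascular-territory lesion geometry,
registration error, partial-volume effects, right-hemisphere homologs,
or realistic tractography variability. Passing tests on synthetic data
therefore validate the *arithmetic and statistical machinery*, not
anatomical claims.

A table-level simulator (`simulate_cohort_table`) draws loads directly
from the severity mixture (defaults: severe 4–12 cc, mild 0–3.5 cc)
and outcomes from the same generative model, skipping volumetric
generation; parameter-recovery tests use it at n = 200 over 100
replicate seeds (volumetric generation is exercised end-to-end at
smaller n with exact load self-consistency checks). Problem sizes in
the test suite (10–20 volumetric patients, 16³–32³ oracle grids) were
chosen as the smallest sizes that exercise every code path
meaningfully.

## Numerical and design choices

* Percentile definition: nonzero-distribution, linear interpolation,
  `>=` cut (see above).
* Grid comparison tolerance 1e-4 mm on affines; volume round-trips are
  bit-exact on values.
* Lesion-load vectorisation is tested against a naive triple loop to
  1e-9 on random ≤32³ instances; loads are asserted bounded, monotone
  under lesion growth, and additive over disjoint lesions.
* Boundary ties: a load exactly at the decision threshold classifies as
  severe (conservative for screening); the cluster split assigns
  boundary scores to the severe (lower) group.
* Degenerate inputs raise typed errors (all-zero volumes, all-equal
  scores, one-group partitions, rank-deficient designs, tubes or
  lesions that cannot fit the grid); an empty lesion mask yields load 0
  with a logged warning so batch runs survive.
* The combined-map rounding (counts = round(p·N)) loses at most 1/(2N)
  probability per voxel; tests assert the capped-sum semantics exactly
  at N = 12.

## Limitations

The reference cohort is a transcription of a printed table (two OCR
repairs documented in the CSV history); its median months post-stroke
is 15.5 against a published rounded 16, and its exact naming cluster
boundary sits one BNT point above the published one — both consistent
with small differences between the printed table and the authors'
working data. Resubstitution (not cross-validated) accuracies are
reported by design, matching the reference analysis; they overstate
out-of-sample performance. The package deliberately performs no
registration, lesion drawing, tractography or fMRI modelling.
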