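# Methods

## Scope and data model

`strokekit` operates on 3D binary lesion masks with explicit voxel
geometry. A mask pairs a `{0,1}` voxel array with its grid shape and
per-axis spacing in mm; the voxel volume (∏ spacing / 1000 ml) is the only
bridge between voxel counts and the milliliter quantities every clinical
threshold uses. Geometry is read from the NIfTI affine — spacing is the
per-axis Euclidean norm of the affine's first three columns, which remains
correct for rotation-only affines — and the affine itself is carried
through write/read round-trips.

Prediction/ground-truth pairs must share their grid: shapes must match
exactly and spacings to within 1e-3 mm per axis. Resampling is deliberately
not performed; silently interpolating a binary mask changes lesion
topology and volume, so a grid mismatch is an error the caller must
resolve upstream. Probability maps are binarized at a fixed threshold of
0.5 with a `≥` comparison before anything else happens; all downstream
logic is strictly binary.

## Lesion instancing

Disconnected ischemias are isolated by connected-component analysis
(`scipy.ndimage.label`) under a configurable 3D neighborhood: 6 (faces),
18 (faces+edges) or 26 (full). The default is 26, the common choice for
lesion instancing; since different choices change lesion counts at corner
contacts, the connectivity used is recorded in every metric report and
shared by all rules that count lesions. No minimum-size filter is applied
by default — single-voxel components count as lesions — but `min_voxels`
is exposed for sensitivity analyses.

Instance ids are assigned deterministically: decreasing voxel count,
ties broken by the lexicographically smallest minimum voxel coordinate.
This makes per-instance tables reproducible across runs and platforms.
The labeling is validated in tests against an independent brute-force BFS
flood fill.

## The four case metrics

* **DSC** `2|P∩G|/(|P|+|G|)`: voxel overlap, biased toward large lesions.
* **AVD** `|vol(P) − vol(G)|` in ml, always computed from spacing.
* **ALD** `|K_P − K_G|`: difference in connected-component counts.
* **Lesion-wise F1** `2TP/(2TP+FP+FN)` over instances. Matching is by
  any-voxel overlap: a ground-truth instance touched by ≥ 1 predicted
  voxel is a TP, an untouched one an FN, and a predicted instance touching
  no ground-truth voxel an FP. No IoU threshold and no one-to-one
  assignment is imposed, so one predicted blob covering two ground-truth
  lesions scores TP = 2, FP = 0. This is the simplest deterministic rule;
  it is isolated in a single function so stricter matchers (IoU ≥ t,
  Hungarian assignment) can be swapped in without touching callers.

Empty-vs-empty convention: DSC and F1 are 1.0 when both masks are empty —
a correct "no ischemia" call is perfect agreement — and 0.0 when exactly
one is empty. Cohorts genuinely contain such scans, so the convention is
explicit rather than an implementation accident.

Size-stratified summaries bin cases by ground-truth volume into
[0, 5), [5, 20) and [20, ∞) ml — the boundaries belong to the upper bin —
and report median and interquartile range per bin, matching the field's
median ± IQR reporting convention.

## Majority-vote fusion

The consensus of *n* candidate segmentations marks a voxel lesion iff at
least `min_votes` inputs agree. The default `min_votes` is the strict
majority ⌈(n+1)/2⌉, which reproduces the 2-of-3 rule for three inputs.
Voting happens on binary labels only. The rule is monotone — the fusion
always lies between the voxelwise AND and OR of its inputs — and
permutation-invariant; both properties are tested, along with an
exhaustive check of all 2ⁿ vote patterns for n ≤ 5. The practical value
of the vote is that uncorrelated failure modes cancel; the test suite
demonstrates this by fusing three independently flip-corrupted copies of
a phantom and verifying the fusion beats each input's Dice in ≥ 95 % of
trials.

## Stroke pattern rules

The four-class decision list, applied in order, with inequalities exactly
as the clinical definition states them:

1. total volume 0 ml → **no ischemia**;
2. largest lesion fraction > 0.95 → **single vessel infarct** (a fraction
   of exactly 0.95 is *not* SVI);
3. lesion count ≥ 3 AND (largest fraction < 0.60 OR total volume < 5 ml)
   → **scattered infarcts** (exactly 5.0 ml fails; exactly 3 lesions
   passes);
4. otherwise → **SVI with accompanying scattered infarcts**.

Rule 2 pre-empts rule 3: a mask whose dominant lesion exceeds 95 % with
three tiny satellites is SVI. The thresholds are a config object
(`PatternRuleConfig`) so the rule set can be re-tuned, and lesion counting
uses the same connectivity setting as the metrics. The classifier is a
total function — every mask gets exactly one label — and is invariant to
translation and instance relabeling, both property-tested.

## Vascular territory

The lesion load per territory is the volume of lesion voxels carrying each
label of an integer atlas volume already living in the mask's grid
(registration to an anatomical template is out of scope). Loads, including
the out-of-atlas remainder (label 0), partition the lesion volume exactly;
this identity is asserted to 1e-9 ml in tests. The scan-level territory is
the argmax of the loads; exact ties break by the fixed ordering MCA, PCA,
ACA, pons/medulla, cerebellum, and an empty mask yields no territory.

## Classification metrics

Pattern/territory prediction is scored from a confusion matrix (rows =
true class) with per-class F1 `2TP_c/(2TP_c+FP_c+FN_c)` and balanced
accuracy, the macro-average of per-class recall `TP_c/(TP_c+FN_c)`. A
class never true and never predicted has no defined F1 and is reported as
an explicit `None`, never a silent 0 — small classes must stay visible. A
class with zero true instances makes balanced accuracy undefined and
raises, naming the class. Both metrics are cross-checked against
scikit-learn on random matrices in the test suite.

## Challenge ranking

Input is a long-form (team, case, metric, value) table with a declared
better-direction per metric; missing or undefined cells are rejected, not
imputed. Two schemes:

* **rank-then-aggregate**: teams are ranked within every (case, metric)
  pair (ties share averaged fractional ranks), and a team's score is the
  mean of its ranks pooled over all (case, metric) pairs with equal
  weights. Pooling over pairs, rather than averaging within metrics first,
  is the documented default; with complete tables and equal case sets the
  two pooling orders coincide.
* **aggregate-then-rank**: per metric, team values are averaged over cases
  and the aggregates ranked; the final score is the mean of per-metric
  ranks.

Stability is assessed by a case bootstrap (default 1000 replicates): case
ids are resampled with replacement, the same resample applied to every
team and metric so re-ranking is coherent, and the scheme recomputed per
replicate. The result carries the point estimate, each team's
rank-frequency distribution and the seed. For rank-then-aggregate the
per-(case, metric) ranks are resample-invariant, so replicates reduce to
averaging precomputed per-case mean ranks over the drawn ids — the
bootstrap is exact and fast. Tie ranks are fractional; in the frequency
table they are counted at their floor so each team's row sums to the
replicate count.

## Synthetic fixtures

The generators emulate the structure of a stroke cohort at the mask level:

* **Phantoms**: per-scan lesion counts fixed or Poisson (study default
  mean 3); lesion volumes log-normal with median 4 ml and log-sd 1.2,
  which populates all three size bins (<5, 5–20, ≥20 ml); lesions
  rasterized as ellipsoids with axis ratios uniform in [0.6, 1.4] —
  simple shapes whose voxel-count quantization is analyzable. Placement
  enforces a minimum background separation (default 2 voxels) so the
  realized component count equals the requested count. Volume draws are
  capped at the largest ellipsoid that fits the grid, and lesions are
  placed largest-first; if a lesion still cannot be placed it is halved
  and retried, so only genuinely infeasible specs (e.g. an over-packed
  confinement region) raise.
* **Corruption**: a simulated segmenter applies, in fixed order,
  per-lesion drops → boundary erosion/dilation → Poisson false-positive
  blob insertion → independent voxel flips. The fixed order makes
  composed effects reproducible and attributable.
* **Toy atlases**: slab or nested-box partitions of the grid carrying the
  five territory names. These are synthetic stand-ins that keep the
  load/argmax logic testable; they have no anatomical shape.

Everything is a pure function of its seed. What the fixtures do *not*
model: image intensities, acquisition artifacts, anatomically shaped
lesions or territories, and spatially correlated segmentation errors.
Passing tests therefore demonstrate the correctness of the metrics, rules
and ranking machinery — not the clinical performance of any segmenter on
real MRI.

## Problem sizes and numerical choices

Tests and the acceptance script run on grids of 20³–64³ voxels, cohorts of
40 cases, 100–200 replicate checks and 1000 bootstrap replicates — sizes
chosen so the whole suite executes in well under a minute while keeping
Monte-Carlo assertions (3-standard-error bands, ≥95 %-of-trials claims)
statistically meaningful. Volume comparisons use exact voxel counts;
the only tolerances are 1e-3 mm for spacing compatibility, 1e-9 ml for
partition identities, and printed-precision rounding in reports.

## Known limitations

* Lesion matching has no overlap-fraction threshold; a one-voxel graze
  counts as a detection. The matcher is pluggable for stricter studies.
* The bootstrap resamples cases only; team-level uncertainty (e.g.
  retraining variance) is out of scope.
* Masks are evaluated in their native grid; cross-grid comparison
  requires the caller to resample beforehand.
* The pattern rules are the final published heuristics; the iterative
  human-in-the-loop process that produced them is historical and not
  reimplemented.
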