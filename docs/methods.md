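# Methods

This note documents the statistical procedure the package implements,
the choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## The model

A patient record is seven clinical indicators plus a binary pregnancy
outcome after fresh-embryo transfer. The fitted artifact is a
scorecard: per-indicator interval schemes mapping any value to a
category A–D and points 4–1 (4 = normal, 1 = extremely abnormal), a
normalized weight per indicator, and grade thresholds on the weighted
total

  total = Σᵢ wᵢ · pointsᵢ ,  Σᵢ wᵢ = 1,  total ∈ [1, 4].

Because the weights are a convex combination, the total is bounded by
the minimum and maximum per-indicator points — the [1, 4] range is
structural, not clipped (a guard clears only float round-off at the
bounds).

## Cleaning

Range rules (defaults: age 18–55 y, BMI 10–60 kg/m², FSH 0–100 mIU/mL,
AFC 0–100, AMH 0–30 ng/mL, oocytes 0–60, endometrial thickness
0–30 mm; all overridable) either drop the record or clip to the bound,
per rule. Imputation (mean for continuous indicators, mode for integer
counts, mode ties to the smaller value) runs after the range step so
outliers cannot contaminate the imputation statistics. Cleaning is
idempotent.

## Screening

Classical equal-variance one-way ANOVA per candidate indicator between
outcome groups, df (1, n−2), selection at p < α (default .01), no
multiple-testing correction (the screen is a per-indicator gate, not an
inference). A forced list bypasses the test; BMI is forced by default.
Degenerate inputs (both groups constant at the same mean) return
F = 0, p = 1 rather than erroring.

## Entropy/MDL discretization

Class entropies are in bits. Candidate cuts are midpoints between
adjacent distinct values whose class composition differs (boundary
points); at each recursion level the best-gain cut is tested against
the Fayyad–Irani criterion

  Gain > log₂(N−1)/N + Δ/N,
  Δ = log₂(3^k − 2) − [k·Ent(S) − k₁·Ent(S₁) − k₂·Ent(S₂)],

with k, k₁, k₂ the distinct class counts of parent and children.
Recursion continues on both sides of every accepted cut. Ties in gain
break toward the smaller cut value. When more cuts are accepted than
the interval budget allows (4 intervals for monotone indicators, 7 for
medium ones), the highest-gain cuts are kept. The implementation is
vectorized over distinct-value blocks (prefix sums), so cohorts of
60 000+ records discretize in milliseconds; an independent pure-Python
brute-force oracle in the test suite checks exact agreement on small
instances.

Points are assigned from observed per-interval pregnancy rates rather
than taken on faith from a declared direction: monotone families get a
monotone 4..1 profile whose direction follows the end-interval rates
(rate ties resolved toward the larger sample), and the medium family
puts 4 points on the maximum-rate interval with points decreasing by
one per step outward (1,2,3,4,3,2,1 over seven intervals). The stored
orientation tag reflects the realized direction. Two rows of the
bundled reference table pair letters and points inconsistently with
their own footnote (the AMH rows, whose highest-rate interval is
printed as D/1, and the endometrial-thickness rows, printed A→D against
points 1→4); the fixture resolves both by rate rank, which reproduces
every self-consistent row, and records the deviation in its metadata.
BMI is not entropy-split (its rate profile is too flat); it uses the
fixed WHO bands with a unimodal profile centered on normal weight
(18.5–25).

Intervals are half-open [lo, hi). Printed labels such as "11-15" for
count indicators are the display form of cuts at .5 midpoints (10.5,
15.5). The printed endometrial-thickness rows "9-11" and "≥11" overlap;
the fixture reads them as [8.5, 11) and [11, ∞).

## Random-forest weighting

The forest is a bagged ensemble of CART trees (default 500 trees, √p
features per split, unlimited depth) on a stratified 80/20 split.
Importance is out-of-bag permutation importance: per tree, the drop in
OOB accuracy when one feature's OOB values are permuted, averaged over
trees (the unscaled mean-decrease-in-accuracy of classical random
forests). scikit-learn exposes no OOB permutation importance, so the
bagging loop and the permutation are implemented here over
`DecisionTreeClassifier`. Negative raw importances are floored at 0;
the vector is normalized to sum to 1. Constant features get weight 0
with a warning; an all-zero vector is an error. By default the forest
sees the discretized 1–4 points, since discretization precedes
weighting in the pipeline (raw-value mode is available). Training rows
are put in a canonical sort order before splitting and bootstrapping,
so weights depend on the multiset of records, not file order, and a
fixed seed gives bit-identical output. The forest is never shipped as
a predictor; only its importances are used (OOB and held-out accuracy
are reported as diagnostics).

## Grading

Grade thresholds come from the same MDLP discretizer applied to
(total score, outcome) with the interval budget equal to the grade
count (default 5). Bands are upper-inclusive on the worst side: grade
E is total ≤ τ₁, the best grade is total > τ_max, and a total exactly
at an intermediate threshold takes the lower grade. If the discretizer
cannot support the requested number of grades (outcome rate too flat,
too few distinct totals) stratification fails with an explicit error
rather than inventing thresholds. The bundled reference grade scheme
stores only the two published endpoints (2.38, 3.84); the intermediate
thresholds are `None` placeholders flagged unpublished, so mid-band
totals score but return no grade until thresholds are refitted on data.

## k-fold consistency

Classification consistency is grade agreement between the full-cohort
system and systems refitted on each k−1 fold union, evaluated on the
held-out fold. Folds are a seeded random permutation with maximally
equal sizes; the overall figure is the record-weighted mean with a
normal-approximation 95% CI on the per-record agreement indicator.
Rates in report tables round half-up to two decimals; an empty
interval's rate is an undefined marker, never 0.

## Synthetic cohorts

The generator draws each indicator independently: an interval with the
reference table's marginal frequencies, then a uniform value within the
interval (integer draws for counts; open-ended intervals truncated at
the plausible-range bounds). The outcome is Bernoulli with probability
logistic in the record's weighted points score under the reference
schemes/weights; intercept and slope are calibrated once,
deterministically, by weighted least squares against the table's
category rates, using the exact rest-score distribution obtained by
discrete convolution (no sampling). The calibrated model reproduces
the overall pregnancy rate (~24.8%) and the direction and ordering of
every category-rate profile, but compresses their extremes (e.g. the
age > 40 rate simulates near 7% against the printed 2.8%): a
single-score logistic with independent indicators cannot match every
marginal simultaneously. `plant_structure` replaces the outcome model
with piecewise-constant rates across user-planted change-points, with
values uniform over the plausible range — the configuration used for
recovery tests.

What passing tests show, and do not show: recovery and consistency
results on these cohorts validate the *procedure* (the discretizer
finds planted boundaries; the forest ranks a determinative feature
first; rebuilds are stable when the structure is well separated). They
say nothing about clinical performance on real cohorts, where
indicators are correlated (AMH with age, AFC with AMH) and rate
profiles are sharper.

## Problem sizes and numerical choices

- Planted-boundary recovery runs at n = 60 000 with one planted
  indicator per cohort and stratum rates 0.05/0.15/0.25/0.35; the
  recovered cuts land within ~2% of a stratum width of truth. The
  recovery tolerance is one stratum width: the maximum-likelihood
  localization error of an entropy change-point between adjacent
  Bernoulli rates is of order 1/KL data points (tens of points at
  these rates), so single-data-gap accuracy is not statistically
  attainable and stratum width is the meaningful scale.
- Consistency demonstrations run at n = 20 000, k = 10, 60 trees with
  a binary stratification (measured 92.2% at the documented seed).
  With five grades on these synthetic cohorts consistency drops to
  ~85%: per-fold systems agree on cuts and weights, but near-tied
  candidate thresholds on the smooth synthetic score→rate gradient
  swap in and out of the top-gain set, shifting whole bands. This is a
  property of the generator's smoothness, not of the pipeline: sharper
  plateau structure (as the two-cluster and grid-valued test cohorts
  have) yields 100%.
- Entropy uses log base 2 throughout; 0·log 0 ≡ 0.
- The equal-rate tie rule (larger sample wins) and the smaller-cut
  gain tie rule make every fit deterministic; all stage seeds fan out
  from a single config seed, so identical inputs give byte-identical
  system JSON.
- The reference table's per-indicator totals sum to 60 647, one less
  than the stated 60 648-record cohort; the fixture keeps the printed
  numbers verbatim and the discrepancy is surfaced here rather than
  repaired.

## Limitations

- Indicator independence in the generator (no AMH–age coupling).
- No multi-way splits, no χ²/quantile discretization alternatives, no
  multiple-testing correction — the pipeline reproduces one specific
  construction.
- The published intermediate grade thresholds and the exact published
  consistency figure depend on the original hospital cohort and are
  not reproducible from printed information; the package targets the
  procedure, not those numbers.
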