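# Methods

## Problem and model

Two untargeted LC-MS metabolomics feature tables — a *reference* and a
*target* — describe overlapping sets of metabolites, but the features of the
same metabolite differ between the tables by a systematic, generally
nonlinear inter-dataset shift in retention time (column ageing, gradient
differences), a small systematic shift in m/z (calibration), and a possible
offset in intensity (ionization efficiency, detector gain), on top of
per-feature noise.  Only three summary values per feature are assumed
available: median RT (minutes), median m/z (Daltons) and median feature
intensity (used as log10FI).  The goal is a one-to-one correspondence
between the two tables.

The workflow has three steps.

**Step 1 — candidate matching.**  All pairs whose inter-dataset distances
`dist_d = v_target − v_ref` (d ∈ {RT, MZ, log10FI}) fall inside
user-chosen linear bands
`lower_intercept_d + lower_slope_d · v_ref ≤ dist_d ≤ upper_intercept_d + upper_slope_d · v_ref`
become candidate matches.  Absolute and relative (e.g. ppm) tolerances, and
noncentered/asymmetric bands, are all linear in the reference value.
Inequalities are non-strict.  Candidates form a bipartite graph; connected
components with one edge are unique matches, larger components are
multi-match clusters that necessarily contain wrong matches.  There is no
universal band width; the choice is an analyst decision guided by the
diagnostic plots, which is why the library requires thresholds explicitly
and only ships a wide "overview" preset (RT ±1 min, MZ ±0.025 Da) for a
first look.

**Step 2 — unique correspondence.**  The expected shift of each candidate
match is the median distance of its k nearest neighbor matches; only
Step-1 unique matches are eligible as neighbors, which keeps the consensus
robust against the conflicting edges inside clusters.  Two neighbor
definitions exist: `cross` ranks neighbors per dimension by the reference
abscissa of that dimension alone (giving one smoothed curve per dimension —
equal abscissas get equal expected shifts), while `circle` uses one shared
neighbor set per match in the (RT_ref, MZ_ref) plane after scaling each
axis to unit MAD (allowing co-eluting features at different masses to carry
different shifts).  FI never enters the neighbor metric.  Residuals
(distance − expected shift) are normalized per dimension by the robust
scale F·MAD (F = 3 default, raw MAD without the 1.4826 factor), so
magnitude 1 sits exactly at the median ± F·MAD limits.  The penalization
score of a match is `sqrt(Σ_d W_d · normalized_d²)` with nonnegative
weights, default [1, 1, 1]; the preset [1, 1, 0.2] lets FI matter only when
its difference is large, and W_FI = 0 removes FI entirely.  Each cluster is
then resolved greedily: select the remaining edge with the lowest score,
discard edges sharing a feature with it, repeat.  This is deliberately the
recursive per-cluster rule, not an optimal bipartite assignment — a
Hungarian solution could select a different, globally cheaper edge set, but
would no longer pick the locally most plausible match first.

**Step 3 — poor-match filtering (optional).**  Unique matches far from the
modeled shift are flagged: method `scores` flags selected matches whose
score exceeds median + F·MAD of the selected scores; method `residuals`
flags a match when any enabled dimension has |residual − median| > F·MAD.
Flagging never changes which matches were selected, only their status, so
it can be applied or skipped per application (off by default in the
library API, on by default in the CLI `match` command, matching how the
headline numbers are usually reported).

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| threshold bands | none (required) | min / Da / log10 | analyst choice, plot-guided |
| neighbor method | `cross` | — | `circle` for mass-dependent drift |
| k | ceil(1% of reference set), min 5 | features | neighbor consensus size |
| F | 3 | MADs | residual normalization scale |
| weights W | [1, 1, 1] | — | [1, 1, 0.2] preset down-weights FI |
| poor method / F_tighten | `scores` / 3 | — / MADs | Step 3 |

## Numerical choices

- Threshold inequalities are non-strict (≤); band validity is checked at the
  endpoints of the observed reference range (bounds are linear, so endpoint
  checks suffice).
- Neighbor ties at rank k are all included, making the kNN median
  deterministic and order-independent.  A unique match may be its own
  neighbor; the median makes self-inclusion innocuous.
- Equal scores within a cluster are broken by smaller |normalized RT
  residual|, then |normalized MZ residual|, then lexicographically smallest
  (ref_id, target_id) — resolution is invariant to input row order.
- Residual normalization is centered by default: (x − median)/(F·MAD), so
  ±1 falls symmetrically at median ± F·MAD; an `uncentered` variant
  dividing raw residuals by (median + F·MAD) is exposed for comparison.
- Degenerate scales: if all residuals in a dimension are identical the
  normalized residuals are 0 (the dimension carries no information); if the
  MAD is 0 while residuals differ (more than half the residuals sit exactly
  at the median, e.g. a noise-free pair with a few chance candidates), the
  mean absolute deviation about the median is used as the spread so that
  outlying candidates still rank above perfect ones.  In the poor-match
  filter a zero MAD degenerates to "strictly above the median".
- With fewer than 3 selected matches the poor filter is skipped (robust
  statistics are meaningless); with fewer than k eligible neighbors k is
  reduced with a warning; with zero eligible neighbors matching aborts with
  advice to widen the thresholds.
- The candidate search sorts the target set on m/z and scans a window per
  reference feature; it is exactly equivalent to the all-pairs double loop
  (property-tested) while keeping memory proportional to the result.  A cap
  (default 50× the smaller set size) aborts pathologically wide bands.

## Synthetic benchmark generator

`generate_pair` emulates a paired-dataset simulation with a known answer
key: reference RT uniform over a ~10-min gradient (0.5–11.5 min), m/z
log-uniform over 70–1000 Da (log-uniform approximates the decreasing
density of metabolite masses), log10FI normal (mean 5, sd 0.8).  A chosen
subset reappears in the target after a sigmoid-plus-linear RT shift
(amplitude 0.3 min at mid-gradient plus 0.01·RT drift), a 5 ppm systematic
m/z shift, a 0.1 log10FI offset, and per-feature noise (RT sd 0.01 min,
m/z sd 2 ppm, log10FI sd 0.05 by default); decoy features are drawn
independently in the target frame so chance matches can occur.  Default
sizes are 4755 features per set with 2717 planted correspondences.
Optional extras generate what the validation strategies consume: shared
annotations, npeaks counts, per-sample covariates (age, BMI, sex) with
feature effects shared across the datasets, and sample-by-feature matrices
with correlated adduct blocks.  Block members co-elute (sub-second RT
spread) and share their RT noise draw — the features of one metabolite
shift together in both datasets.

What the generator does *not* emulate: correlated (non-Gaussian) drift
beyond the smooth family, mass-dependent intensity response, missing
values, isotopologue mass spacing, or peak-shape information.  Passing
tests on this generator therefore demonstrate the mechanics of the method
(shift modeling, resolution, filtering, validation accounting) under
controlled drift and noise — not performance on any particular instrument
pairing.

Benchmark runs at the default size take about a second; the test suite
uses 120–2000-feature versions of the same design for the property suites
and keeps the full 4755-feature design for the end-to-end acceptance
checks (single seed in the tests, five seeds in `scripts/acceptance.py`).

## Known limitations

- **Scale-blind robust thresholds under mass-proportional noise.**  Each
  dimension is normalized by a single global MAD, and the `scores` filter
  applies a single median + F·MAD cut.  When m/z noise is proportional
  (ppm-scale, as mass analyzers behave), residual scale varies ~14× across
  a 70–1000 Da range, so correctly matched high-mass features carry
  systematically larger normalized residuals and are preferentially
  flagged poor — on the default benchmark the filter removes ≈11% of true
  matches, nearly all at high mass, while precision stays at 100%.  Even
  with homoscedastic residuals a median + 3·MAD cut on the skewed score
  distribution flags ≈4%.  Step 3 is optional for exactly this kind of
  trade-off; analysts working over wide mass ranges should inspect the
  flagged set (or the row-6 diagnostic panel) before discarding it.
- Greedy per-cluster resolution can differ from the optimal assignment on
  clusters with near-tied scores.
- The shift model extrapolates flatly beyond the outermost neighbors, so
  expected shifts at the extreme ends of the RT/MZ range lean on one-sided
  neighborhoods.
- Sequential matching of more than two datasets against one reference is
  possible but compounds matching errors; no multi-dataset mode is
  provided.
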