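# Methods

## The model

A night of sleep is represented as an epoch-coded hypnogram (30-s
epochs) over five canonical stages — WASO, Stage 1, Stage 2, SWS, REM —
harmonised from R&K (Stages 3/4 merged into SWS) and AASM codings.  The
unit of analysis is the *bout*: a maximal uninterrupted run of one
stage.  Each bout becomes one data point carrying its stage identity and
duration, the identities/durations of up to three preceding bouts, its
start clock time (Time of Day), time since sleep onset (Time Slept), and
the subject's age, sex and BMI.  Wake before sleep onset is removed from
every record and a terminal wake bout is never an outcome: the models
describe the dynamics of sleep once begun, not sleep/wake homeostasis.

All variables are discrete.  A Bayesian network over them is learned in
two steps: K2 ordered greedy hill climbing proposes, for each variable
in a fixed causal ordering (demographics → time variables → past bouts
from the deepest lag forward → present bout), the single preceding
parent whose addition most improves the family BIC, stopping when no
addition helps; maximum-likelihood counts score the search, and a
uniform Dirichlet prior (pseudo-count 1) smooths the CPTs used for
prediction and inference.  The BIC is

    score = log L̂ − (ln N)/2 · (number of free parameters),

with higher (closer to zero) better.  Inference is exact enumeration
over the unobserved joint — at most thirteen variables of cardinality
≤ 5, so the full joint never exceeds ~10⁶ states and in routine use
(all-but-one variable observed) collapses to a handful of factor
products.  The network is generative: ancestral sampling produces
discrete data points, and Bayes inversion yields posteriors over parent
variables (e.g. the age category) given observed sleep.

### Structural zeros

Because bouts are maximal runs, stage variables at adjacent lags can
never be equal.  These cells are masked to probability exactly zero
before normalisation, and the BIC's parameter count excludes both the
masked cells (one fewer free parameter per row) and parent
configurations that are themselves impossible (two constrained parents
equal) — rows that can never receive data should not be charged for.

### Model families

Nine variable sets are prespecified.  Family 1 varies history depth
alone: 1A = {t, t−1}, 1B = {t..t−2}, 1C = {t..t−3} (each "slot" is the
stage identity plus its 4-bin duration).  Family 2 adds Time of Day and
Time Slept with 0/1/2 bouts of history (2A/2B/2C); family 3 further adds
Age, Sex, BMI (3A/3B/3C).

## Preprocessing

* **Exclusion screening** (all thresholds configurable): respiratory
  indices AHI > 15, OAHI > 15, OAI > 5, CAI > 5, RDI > 15; age outside
  18–90; BMI outside 18.5–50; reported disorders or sleep/psychiatric
  medication; sleep onset outside 18:14–01:20; total sleep time outside
  285–650 min; first night only.  Missing BMI flags a subject for
  exclusion from BMI-conditioned models only.  Clock times are stored as
  minutes since noon so the bedtime window, which spans midnight, is a
  plain interval.
* **Smoothing**: for REM, then SWS, then Stage 2 — in that order, each
  pass seeing the previous pass's output — interior gaps of ≤ 1 minute
  (2 epochs) of any other stage lying strictly between two runs of the
  target stage are relabelled to that stage.  On interior gaps this
  run-length rule equals a morphological closing (dilation + erosion)
  with a 3-epoch structuring element, but record ends are never
  extended.  The operation is idempotent.  Smoothing is theory-driven:
  it keeps brief arousals from splitting ultradian-cycle bouts, at the
  documented cost of a bias towards longer S2/SWS/REM durations and
  less transition mass into WASO/S1 (both directions are asserted by the
  acceptance suite).
* **Discretization**: per-stage bout durations get 4 logarithmically
  spaced bins from the stage's minimum duration to its 95th percentile
  (durations are close to log-normal; the maximum would be
  outlier-driven), the top bin open above; the scheme stores geometric
  bin midpoints for expected-duration readout.  Time of Day and Time
  Slept use empirical tertiles; age is cut at 43 and 67 years
  (younger 18–42 / mid 43–66 / older 67–90); BMI splits at 25 kg/m².
  Quantiles are nearest-rank (type 1) for cross-implementation
  determinism, pooled over all sources so one scheme serves every
  model comparison.  Bin codes are 0-based throughout ("bin 1" in
  prose = code 0); missing values are −1 and each model keeps only
  complete cases over its own variables, so no artificial "none"
  category is fabricated for shallow-history points.

## Evaluation

Predictive error for one point is the mean over categories of
|one-hot(actual) − predicted|; predictive accuracy is the 0/1 indicator
of the argmax (ties to the lowest category, deterministically).  Note
that the mean of this L1 error over a test set is *linear* in the
predicted vector, so among constant predictors it is minimised by the
one-hot of the modal category, not by the empirical distribution (which
minimises the Brier error) — the property suite asserts the correct
statement.  Cross-validation is k = 5 with 3 random shuffles, the
structure search re-run on every training split and only test-split
metrics reported; folds split at the data-point level (subjects can
leak across folds, deliberately mirroring the pooled design), with a
grouped subject-level split available behind a flag.  Out-of-dataset
generalisability holds out each source in turn.  Chance is 20% for the
5-way stage and 25% for the 4-bin duration target.

Age-category inference trains model 3A on all but a hold-out set of
subjects, computes for each held-out data point the posterior over the
age category given the point's other variables, votes with the argmax,
and predicts each subject's most common vote (ties to the lower
category); repeats use disjoint hold-out draws.

Uncertainty: leave-one-dataset-out refits give per-parameter means and
SDs across sources; confidence intervals use a percentile bootstrap
resampling *subjects* (data points within a subject share demographics
and a night, so a point-level bootstrap would understate variance).

## The synthetic cohort generator

Each subject's night is a semi-Markov process: bout stages follow a
first- (or second-) order chain with zero diagonal, bout durations are
per-stage log-normal, quantised to 30-s epochs (minimum one).  Defaults
define the study conditions:

| parameter | default | rationale |
|---|---|---|
| transition matrix | the published whole-night first-order matrix | self-contained printed chain |
| duration medians (WASO,S1,S2,SWS,REM) | 1.5, 1.0, 6.0, 8.0, 10.0 min | short wake/S1 interruptions, REM bouts longer than SWS |
| duration log-SD | 0.8, 0.7, 0.8, 0.8, 0.9 | heavy right tails of observed bout histograms |
| night length | uniform 360–480 min | inside the 285–650 min screening window |
| lights-off | N(23:30, 40 min), clipped to the bedtime window | typical adult bedtimes |
| pre-onset wake | log-normal, median 10 min | short sleep latency |
| onset stage | S1 0.60, S2 0.35, SWS 0.02, REM 0.03 | sleep begins in light NREM |
| demographics | age ~ U(18, 90), sex Bernoulli(0.5), BMI log-normal(24, 0.15) | balanced age tripartition, BMI mass on both sides of 25 |

Transition matrices may vary over (time-of-night third × age group ×
sex) and duration medians by multiplicative modulators; `planted_effect_config`
installs named effects (time or age/sex on transitions or durations) at
a stated magnitude and the returned `GroundTruth` records the realised
parameters for recovery tests.  The second-order default mixes the
previous bout's row into the current one (weight 0.3), giving a genuine
2-back dependence.  The printed matrix's WASO row sums to 0.99 from
rounding; it is kept as printed and rows are renormalised only inside
the sampler.

What the generator does *not* emulate: EEG microstructure, scorer
disagreement, apnea events, real inter-dataset heterogeneity (beyond
configurable per-dataset parameter shifts), or within-subject
night-to-night correlation.  Passing recovery tests therefore shows the
*estimators* are correct and the pipeline is closed under its own
assumptions — not that real sleep satisfies those assumptions.

### Numerical and design notes

* **End-of-record censoring.** The simulator truncates the final sleep
  bout at the configured night length.  Within any fixed window,
  complete bouts are a length-biased sample (long bouts are likelier to
  straddle the boundary), so duration-recovery checks run on long
  simulated nights and drop each record's final (censored) sleep bout;
  with realistic night lengths the same bias shifts the long-duration
  bin by ~0.02 for REM — worth remembering when interpreting real
  fixed-window recordings.
* **Nesting inflates demographic edges.** ~75 data points share one
  subject's age/sex/BMI, and this cluster correlation can hand K2
  spurious edges *among* demographic variables even when the generator
  has none (the BIC penalty assumes independent points).  The
  substantive recovery claims are therefore about demographics as
  parents of the stage/duration variables, where within-subject
  variation keeps the inflation negligible.
* **Ties and degenerate inputs.** Greedy-search ties go to the earliest
  candidate in the node order; argmax ties to the lowest category;
  unseen parent configurations are uniform under the prediction prior
  and contribute nothing to the MLE score; transition rows with zero
  conditioning counts are reported as NaN, never silently uniform;
  MOV/unscored epochs inherit the neighbouring epoch's stage to
  preserve bout continuity.
* **Problem sizes.** The test and acceptance suites use cohorts of
  80–600 subjects (≈6k–45k data points, ≥10⁵ bout transitions where a
  ±0.01 recovery band is asserted) and 10-seed batteries for the
  stochastic recovery claims; the bare-chain recovery of the printed
  transition matrix uses 10⁶ transitions (Monte-Carlo SE ≲ 0.002 per
  cell).

## Known limitations

Discretization discards within-bin duration resolution; the pooled
(non-hierarchical) treatment of data points understates subject-level
uncertainty; point-level CV folds leak subjects unless the grouped
split is requested; and the printed headline accuracies of the original
multi-cohort study depend on its 14 source datasets, which this package
does not ship — its claims are the self-contained printed quantities
plus ground-truth recovery on the bundled simulator.
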