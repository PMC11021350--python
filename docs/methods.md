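# Methods

## Model and test

State-trace analysis asks whether two dependent variables measured over the
same conditions are consistent with a single latent dimension. The null
hypothesis is purely ordinal: there exists one total order of conditions
along which both condition-mean vectors are weakly nondecreasing. Conjoint
monotonic regression (CMR) measures departure from that null as

    T = min over total orders π of  SSE_x(π) + SSE_y(π),

where `SSE_v(π)` is the weighted sum of squared deviations of the best
weakly-nondecreasing fit to variable `v` along `π` (weighted isotonic
regression, computed by the pool-adjacent-variables algorithm in O(n)).
Searching *total* orders with ties permitted in the fitted values is
deliberate: allowing arbitrary partial orders would let every dataset fit
perfectly and make the null vacuous. Jointly decreasing relations need no
special handling — reversing a common order preserves it.

The search over orders is combinatorial. The optimiser is tiered:
exhaustive enumeration (Heap's algorithm) up to 8 conditions; depth-first
branch and bound to 14, using the conjoint SSE of the partial prefix as the
lower bound (restriction of any completion to the prefix is feasible for
the prefix, and SSE only accumulates, so the bound is valid) with a
multistart incumbent and a 2×10⁶-node budget; above 14, multistart
adjacent-transposition descent from four deterministic starts (sorted by
x, by y, by standardised x+y, and identity, plus any warm start). Results
carry an `exact` flag: true only for exhaustive and completed
branch-and-bound searches. The heuristic's adequacy is monitored by
equivalence tests against exhaustive enumeration on small instances and by
a 1e-9 agreement requirement between tiers.

### Bootstrap

The p-value uses the add-one convention `p = (1 + #{T* ≥ T})/(B + 1)`,
which cannot return zero. Two resampling schemes:

* **participant_resample** (default for item-level data): participants are
  resampled with replacement *within their emotion-perception group*
  (the factor is between-subjects, so resampling must respect the strata),
  condition means are recomputed from the resampled per-participant
  proportions, and each resampled mean vector is recentred on the fitted
  monotonic values (`m* − m̄ + m̂`), so the resampling population satisfies
  the null exactly. Precision weights are held at their observed-data
  values across replicates; re-estimating them per replicate would add
  noise without changing the null geometry.
* **parametric_normal** (required for summary-statistics input): condition
  means are drawn from Normal(fitted value, sd/√n), the procedure implied
  by reanalysing published (M, SD, N) tables under a normality assumption.

Within one test, the observed statistic and every bootstrap statistic use
the same solver (exhaustive up to 7 conditions, the multistart heuristic
above), keeping the comparison like-for-like: a solver bias that shrank
only the bootstrap statistics would make the test anticonservative.

Default weights are precision weights `n_c / s_c²` per condition (variance
floored at 1e-4 for degenerate all-equal cells); an unweighted option
exists because the weighting scheme for participant-level CMR is a genuine
design choice and results can be weight-sensitive. Monotonicity checks use
an absolute tolerance of 1e-9 on fitted differences. Bonferroni
multiplicity is m = 3 for the three pairwise analyses. One master seed
expands deterministically (via `SeedSequence`) into per-analysis streams;
identical inputs and seed give byte-identical reports.

The recentred bootstrap is approximate: when the true means sit strictly
inside the monotone cone, the observed statistic is often exactly zero and
the test is mildly conservative. The calibration study below measures this
directly (observed type-I error ≈ 0.015–0.025 at α = .05).

## Data reduction

Item responses are coded yes = 1, no = 0; "don't know" responses are
treated as missing and removed before any proportion is formed, so a
cell's endorsement rate is yes/(yes+no) over its remaining items. "Say"
probe questions are parsed but excluded from analysis (a comprehension
control, not a ToM measure). The emotion-perception median split sends
scores strictly above the median to `high` and ties at the median to `low`
— the tie rule is arbitrary but deterministic and recorded in every
report. Participants missing more than 20% of their relevant cells are
excluded from an analysis entirely; others are simply absent from the
cells they cannot contribute to, and any condition left with fewer than
two contributors is an error.

## Synthetic generator

The generator emulates the structure of the study data, not the
instrument's content. Each of the 20 conditions (5 social exchange types ×
target/lure × high/low emotion perception) has a latent value θ_c on the
logit scale, decomposed by default into additive exchange, item-type and
group effects chosen to give realistic endorsement rates (targets ≈
0.6–0.9, lures ≈ 0.1–0.5, sincere easiest, lying hardest, a modest group
separation). Each probe question maps the latent value through its own
logistic link `p = logistic(a·θ + b)` with distinct slopes/intercepts —
under this **one_latent** model the population means of any two questions
are automatically jointly monotone, so the population CMR misfit is zero
(asserted by exhaustive enumeration on subsamples in the tests).

The **two_latent** model adds a second dimension: a crossing pattern η_c
alternating ±1 along the θ-sorted conditions, entering the latent value as
`θ_c + δ·λ_q·η_c` with loadings λ = (think 0, do +1, feel −1). "Do" and
"feel" are pushed in opposite directions, so the do–feel pair departs from
monotonicity at any δ that disturbs a near-tie, and every pair involving
"think" departs once δ exceeds the adjacent θ spacing. The presets δ ∈
{small 0.4, medium 0.8, large 1.4} were frozen after a one-off tuning run
against the population misfit of the default θ grid; all three produce a
strictly positive population misfit for all three question pairs, and δ = 0
reduces the model to one_latent exactly (same seed, byte-identical
output). Setting the loadings this way rather than perturbing a single
question is what lets *all three* pairwise analyses carry signal, which is
the qualitative pattern the battery is designed to detect.

Participant heterogeneity is a random intercept on the latent scale
(SD 0.3 by default; 0 for idealised tests). Emotion-perception scores are
drawn per generating group from Normal(24.92, 0.96) (high) and
Normal(20.90, 2.50) (low), rounded and clipped to the 0–28 scale, so the
pipeline's median split approximately — not perfectly — recovers the
generating groups, as a real median split would. Two layouts exist: an
idealised `grid` (a configurable number of items per cell, all questions of
a scene sharing its item type) and `tasit` (the instrument's scene
taxonomy: 15 part-two scenes, 5 per exchange type; 16 part-three scenes, 8
sarcastic and 8 lying; 4 questions per scene with item type alternating
over scene × question, hence 124 responses per participant, 93 scored).
Don't-know contamination is either a per-response rate (default 0.004) or
an exact count for structural studies.

What the generator does **not** emulate: the instrument's actual
target/lure allocation per scene, item-level difficulty variation within a
cell, response dependencies within a scene, and any systematic missingness
mechanism. Passing tests therefore show that the pipeline and test behave
correctly for data *of this structure*, not that any particular empirical
dataset is one- or multi-dimensional.

## Study sizes and numerical choices

The calibration study uses 200 one-latent datasets of 50 participants with
B = 199 bootstrap replicates — sizes at which the binomial 95% acceptance
region around α = .05 ([0.020, 0.080] for 200 trials) is informative while
the full study runs in well under a minute. The power study uses 10
two-latent datasets at the study-scale n = 114 with the large preset.
Production analyses default to B = 10,000; the simulation studies use
B = 199 per the usual simulation/analysis split. Reports are JSON with
sorted keys and full float precision, so determinism is verifiable by byte
comparison.

## Known limitations

* The bootstrap is a single (not double) bootstrap; its mild conservatism
  under strictly-interior nulls is measured but not corrected.
* Above 14 conditions optimality of the order search is heuristic
  (`exact=false`); the misfit statistic is then an upper bound, applied
  equally to observed and bootstrap statistics.
* Partial orders supplied a priori, signed-difference extensions, and
  individual-participant state traces are out of scope.
* The weighting scheme (precision vs none) is a modelling choice the data
  cannot adjudicate; both are exposed.
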