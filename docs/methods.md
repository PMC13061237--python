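# Methods

## Model of a participant flow

A flow is a single linear chain of cohort states S₀ → S₁ → … → S_m
(no branching or merging), where each transition is one exclusion step
with a free-text reason. The package maintains, and re-validates on
every mutation, three structural invariants: there is exactly one more
snapshot than exclusion record; cohort sizes are non-increasing; and
participants are conserved (n₀ = n_final + Σ removed). Each snapshot
carries a full descriptive summary of every tracked variable, so all
outputs are pure functions of the snapshot sequence.

Exclusions may be supplied as boolean keep-masks (True = retain) or as
pre-filtered tables. Subset verification for filtered tables uses a
stable internal row identity assigned at initialization; tables that
lack it are matched on full-row equality, which is slower and requires
unique rows. Filtered tables may arrive in any row order — rows are
re-sorted by the internal identity so the two workflows (stepwise
masks vs. a list of pre-filtered tables) produce identical snapshots,
summaries, and drift values; this equivalence is asserted in the test
suite.

By default each step must remove at least one participant (strict
validation); `FlowOptions(strict=False)` downgrades violations to
warnings for automated pipelines. A step may remove the entire cohort:
this warns, and every drift value against the empty cohort is emitted
as NaN rather than an exception so the tables still render.

## Descriptive summaries

* Normally distributed continuous: mean and sample SD (n−1
  denominator; the convention is not universal, so it is stated here).
* Non-normally distributed continuous: median and quartiles by linear
  interpolation (the "type 7" rule — again a documented choice, since
  several quartile conventions exist). Mean and SD are retained
  internally because the standardized difference has a single
  continuous form.
* Categorical: counts and proportions per level, with missingness as
  an explicit level. Proportions are computed against the **total**
  snapshot size, so the missingness category competes for mass and all
  listed proportions sum to 1. (Published tables are not always
  consistent on this point — in one reference case study the printed
  category counts at a step exceed the printed step n, so no single
  denominator convention can reproduce every printed percentage; the
  total-n convention was chosen because it keeps missingness visible
  in every output.)

## Missing-value handling

All cells whose trimmed string form is in the token set (default:
`""`, `"NA"`, `"N/A"`, `"None"`, `"NULL"`, `"NaN"`, `"nan"`, `"."`;
alphabetic tokens match case-insensitively), plus native nulls, are
rewritten to one internal marker at initialization. The operation is
idempotent and shape-preserving. Numeric sentinel codes (−999 and
kin) are deliberately not treated as missing unless the user adds
them: silent coercion of numbers is more dangerous than a visible
spike in a histogram. The package performs no imputation of any kind;
missingness is preserved, displayed, and participates in the
categorical drift statistics as an ordinary category. Whether
missingness-as-category is *interpretable* depends on the missingness
mechanism (defensible under MCAR, descriptive under MAR, potentially
misleading under MNAR); that judgement is the analyst's.

## Drift statistics

Continuous: SMD = (x̄₁ − x̄₂)/√((s₁² + s₂²)/2), computed from
non-missing summaries. The low-level function follows that formula
order; the drift table reports the signed value as (later − earlier),
so a positive entry means the variable increased over the step. This
matches the signed values printed in the reference case-study tables.
Display may optionally show magnitudes; computation is always at full
precision with rounding applied only at display time (configurable,
default 2 decimals).

Binary: SMD = |p₁ − p₂|/√([p₁(1−p₁) + p₂(1−p₂)]/2), a magnitude.

Multi-level categorical (K ≥ 3): the Mahalanobis generalization
SMD = √(Tᵀ S⁻¹ T), with T the proportion differences for K−1
categories (one dropped; for non-singular S the result is invariant to
which, asserted to 1e-8 in tests) and S the average of the two
cohorts' multinomial covariances: S_kk = [p⁽¹⁾ₖ(1−p⁽¹⁾ₖ) +
p⁽²⁾ₖ(1−p⁽²⁾ₖ)]/2, S_kl = −[p⁽¹⁾ₖp⁽¹⁾ₗ + p⁽²⁾ₖp⁽²⁾ₗ]/2. Category sets
are aligned on the union of labels across the two cohorts with absent
levels at proportion 0. When S is singular the Moore–Penrose
pseudo-inverse is used; if the contrast T has a component outside the
range of S the statistic is undefined and a degenerate-input error is
raised (rather than silently projecting it away). With K = 2 the
quadratic form collapses exactly to the binary formula (asserted to
1e-10 over random pairs). Zero pooled variance with a non-zero
difference is undefined in all three forms and raises.

Small-sample correction: the Hedges factor is computed in its exact
gamma-ratio form J(df) = Γ(df/2)/(√(df/2)·Γ((df−1)/2)), df = n₁+n₂−2,
via log-gamma for stability. The textbook approximation
1 − 3/(4·df − 1) agrees to better than 1e-3 only from df ≈ 6 upward
(it is off by 7×10⁻³ at df = 2), which is why the exact form is the
implementation. The correction applies to the continuous and binary
forms; no standard small-sample factor exists for the multi-level
Mahalanobis statistic, so it is left uncorrected — at cohort sizes in
the thousands J > 0.9999, making the distinction numerically
irrelevant there.

Non-normal continuous variables are displayed as median [IQR] but
their drift uses the mean/SD form — there is only one continuous SMD.
This conflation is a known limitation for heavily skewed variables.

Threshold: |SMD| > 0.1 is flagged as a potentially meaningful
compositional change, following the covariate-balance literature.
Conventional effect-size buckets (0.2 / 0.5 / 0.8) come from
experimental behavioural research and should be applied to selection
drift with caution.

## Display rules

Variables appear in `display_order`; categorical levels follow
`class_order` when given, otherwise initial-cohort frequency rank
(ties broken lexicographically — a documented arbitrary choice). With
a `category_limit` of N, the N most prevalent levels in the initial
cohort are shown and the remainder pooled into "Other"; pooling
conserves counts and is **display-only** — drift is always computed on
the full category set, so no statistic depends on a visualization
parameter. The drift table has no column for the initial cohort, which
has no incoming transition.

## Flow diagram

The diagram spec is a deterministic function of the flow state: cohort
node i chains to cohort node i+1, exclusion node i hangs off cohort
node i with exactly one incoming and no outgoing edges. DOT text is
generated directly (it is a trivial line format) and panels are
written as separate PNG files referenced from the nodes, keeping the
graph file text-diffable; rendering to SVG shells out to Graphviz's
`dot` when available and otherwise degrades to DOT-only with a
warning. Panel colors are a fixed palette assigned by initial-cohort
frequency rank so a category keeps its color across snapshots.
Continuous panels use a 20-bin histogram (a density curve would be an
equally defensible encoding; the histogram was chosen as the more
literal one). Panel regeneration on unchanged input is byte-identical.

## Automatic type detection

The simplified interface infers types: non-numeric → categorical;
numeric with ≤ 10 distinct non-missing values → categorical (so 0/1
indicators get the binary formula); otherwise continuous, classified
normal when |sample skewness| ≤ 1.0. Both thresholds are exposed
(`TypeDetectionRule`) and are heuristics, not tests — no formal
normality testing is performed, and an all-missing column is a
detection error directing the user to declare the type explicitly.
The wrapper adds no computation: feeding its detected specs to the
full interface reproduces its outputs exactly.

## Synthetic cohort generator

The generator emulates the marginal structure of a large multi-center
ICU cohort: independent categorical blocks (label probabilities),
continuous blocks (normal, or log-normal rescaled to the requested
mean/SD when flagged skewed), per-variable missingness planted
completely at random, and selection steps that are either uniform
retention or logistic models on standardized continuous covariates and
category indicators. The `eicu_like` preset uses a 6-level ethnicity
(majority share ≈ 0.78), a 55/45 sex split, age 62.8 ± 16.2 years, a
right-skewed severity score 57.3 ± 25.8 with 5% missingness, a 93%
uniform first retention step, and a biomarker-availability step with
logit −2 + 0.8·(standardized severity) + 0.4·(majority ethnicity) —
values chosen once to mirror the reference cohort's step-1 marginals
and a realistic testing-availability mechanism.

What the generator does **not** emulate: correlations between
variables, informative (MAR/MNAR) missingness, time structure, or any
real database's joint distribution. Passing tests therefore
demonstrate that planted *marginal* shifts are detected and null
mechanisms are not flagged; they say nothing about performance under
correlated covariates, which only affects the interpretation, not the
computation, of per-variable SMDs.

Randomness discipline: one root seed is split into per-variable child
streams keyed by a stable hash of the variable name, so adding a
variable to a configuration leaves existing columns' draws unchanged,
and a fixed configuration reproduces byte-identical outputs
end-to-end.

## Problem sizes in the test suite

Unit and property tests run on cohorts of 10–20,000 rows; the
calibration checks use 100 replicates at n = 5,000 (null flagging rate
under uniform retention < 5% at the 0.1 threshold) and 100 replicates
at n = 1,000 per arm (a planted 0.5-SD shift flagged in every
replicate). Case-study drift values are recomputed from printed
summary statistics, which is exact and instantaneous; the full
credentialed patient-level databases those summaries came from are
deliberately out of scope.
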