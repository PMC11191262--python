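# Methods

## Scope and data model

The package analyses one trial at a time: a subject table (randomization
arm, HLA DR3/DR4/A2 flags, age at T1D onset, numeric baseline covariates)
and a long-format measurement table (subject × endpoint × visit week).
Visits follow a fixed schedule — weeks −4 (screening), 0 (randomization), 6,
12, 18, 24 — and week 0 is always the baseline for derived quantities;
week −4 is retained in files but never used as a delta baseline.  Missing
visits are absent rows, never sentinel values, so missingness is
unambiguous when rules are counted.

A single weeks→months conversion, 1 month = 4.345 weeks, is used wherever
the per-month decline slope meets the week-indexed schedule.

## Endpoint derivations

**Delta ratios.**  Δ(V₀→Vₙ) = (v(Vₙ) − v(V₀)) / v(V₀), dimensionless and
scale-invariant.  Undefined when either visit is missing or the baseline is
zero; both cases are signals that simply leave the descriptor absent for
that subject.  Discretization is trichotomous — increasing (Δ > 0), stable
(Δ = 0), decreasing (Δ < 0) — with the stable band taken literally at zero
by default.  A configurable `zero_tolerance` exists because continuous
assays essentially never produce exact zeros, but it is opt-in: fidelity
first.

**Tertile bins.**  Baseline characteristics are rank-binned into
low/medium/high with sizes as equal as possible; when n mod 3 ≠ 0 the extra
members go bottom-up (low first, then medium), so 10 values split 4/3/3.
Tied values never straddle a boundary: the boundary moves to the nearest
rank position where adjacent sorted values differ, and on an equidistant
tie to the higher position, putting the tied run in the lower bin.  A
variable whose values are all identical carries no information and is
dropped with a warning; fewer than three values is an error.

**Expected-AUC response.**  observed − (baseline + s·t) with
s = −0.0245 pmol/mL/month (95% CI −0.0271, −0.0215) and t the elapsed
months.  Positive = better than the average disease course.  The response
is computed at every post-baseline visit with an observed value and
discretized improved / as-expected / worse (the middle category is again an
exact zero by default).

**Quantitative response (QR).**  log(observed+1) minus a linear expectation
in log(baseline+1) and age at onset.  The model's published coefficients
are not hard-coded — the package refuses to invent them — so QR requires
user-supplied coefficients; the expected-AUC residual is the default
responder statistic.

## The formal context and mining

Descriptors are (variable, category) pairs: arm levels, explicit positive
*and* negative HLA categories (DR4− is a materialized category, not the
absence of DR4+ — absence would conflate negativity with missingness), the
pooled treated (doses B+C) / untreated (placebo + dose A) grouping, tertile
categories, delta categories per endpoint × (week 0 → later visit), and
response categories for the AUC endpoint.  A per-variable missingness mask
records which subjects were measured; a subject unmeasured for a variable
supports neither that variable's categories nor their negation, and every
rule is evaluated on its complete cases (subjects measured for all
variables the rule touches), with the effective n reported.

Concepts are enumerated by Close-by-One in lectic order, pruned by minimum
extent size; the enumeration is deterministic and reports exactly the
closed descriptor sets (distinct closures).  Rules are generated over the
closed-set basis.  For closed intents B ⊂ B′ with strictly smaller extent,
the emitted antecedents are the minimal generators of B (smallest subsets
with B's extent) within the antecedent vocabulary and size cap, and the
emitted consequents are the *minimal consequent generators* of B′ relative
to B — smallest Z ⊆ B′∖B with ext(B∪Z) = ext(B′) — plus the full
difference when it fits the cap.  Minimal consequent generators are what
keep the basis complete under a consequent-size cap: any rule X → Y
passing the filters has a representative with the same extent pair.
Confidence-1 rules inside a concept are emitted with singleton consequents
(larger subsets of the same intent add no extent information).  Default
caps: antecedent ≤ 3 descriptors, consequent ≤ 2.

A brute-force enumerator over all small (X, Y) subset pairs, computing
metrics by plain row counting, serves as the independent oracle in the test
suite; it shares no code with the miner and is scope-guarded to tiny
contexts.

## Rule statistics

support = |ext(X∪Y)| (a config switch counts |ext(X)| instead — both
readings of "patients for whom the association was identified" are
implemented, the joint count being the one consistent with the confidence
formula); confidence = |ext(X∪Y)|/|ext(X)|; lift = confidence/P(Y),
computed as one integer-ratio division so the identity
lift·|ext(X)|·|ext(Y)| = n·support holds exactly in floating point.

The Fisher p is two-sided by the minimum-likelihood convention: over all
2×2 tables with the observed margins, sum the hypergeometric probabilities
no larger than the observed table's.  All tables with fixed margins share
one denominator, so the summation runs on exact integer weights.  A zero
margin is degenerate and yields p = 1.

The MWW p compares the numeric parent of the consequent (the underlying
delta ratio, response residual or baseline value) between subjects
satisfying X and subjects not satisfying X.  This antecedent-split reading
is the one that uses both rule parts non-circularly; it is a design choice,
as is the absence of the statistic when the consequent spans more than one
source variable or a group has fewer than two values.  The exact branch
(tie-free, min(n₁,n₂) ≤ 8) computes the symmetric-tail p
P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|) from the exact U distribution (dynamic
programme, cached); ties or larger groups use the tie-corrected normal
approximation (scipy).  Two identical samples give p = 1 in either branch.

Filtering keeps rules with support ≥ 4 ∧ confidence ≥ 0.75 ∧ lift ≥ 1.25 ∧
p ≤ 0.05, where p is min(Fisher, MWW) when both exist ("either test flags
it"); a switch requires both.  No multiple-testing correction is applied —
by design the approach is exhaustive and descriptive — and the number of
rules tested is reported in provenance so users can post-correct.  Note
that the min-p rule together with the MWW antecedent split makes the
selection intentionally sensitive: under the null generator a few dozen
chance dose×HLA rules per 41-subject trial pass the filters, which the
acceptance script quantifies as an empirical specificity curve.

Dose focus operationalizes "dose necessary and sufficient": sufficiency is
the rule passing as stated with a dose descriptor in the antecedent;
necessity is the reduced rule (antecedent minus dose descriptors) failing
confidence or lift, or not being scorable.  Both rule versions' metrics are
reported.  This is one defensible reading of an operation the source
platform does not specify.

## Synthetic cohort generator

The generator reproduces the statistical skeleton the analysis assumes;
it makes no mechanistic immunology claims.

* **Allocation**: deterministic largest-remainder, active:placebo 3:1 with
  actives split evenly across doses A/B/C; leftover seats go to the
  highest dose first (the escalation design favoured a larger dose-C
  group), so n = 41 gives 10/10/10/11.
* **HLA**: strata {DR3 only, DR4 only, DR3/DR4} with default frequencies
  (0.244, 0.463, 0.293).  The DR4-only 46.3% is the reported most-common
  stratum; the split of the remainder between DR3-only and DR3/DR4 is a
  generator choice (the source reports only the mode).  HLA-A2 positivity
  is independent at 0.634.  Every subject is DR3+ and/or DR4+ (inclusion
  criterion).
* **C-peptide AUC**: baseline ~ U(0.4, 1.2) pmol/mL; per-subject slope
  −0.0245/month + N(0, 0.005)/month jitter (no between-patient variance is
  published; 0.005 is a generator choice of the same order as the
  population CI half-width); value(w) = baseline + slope·w/4.345 + N(0,
  0.01), truncated at 0 because a normalized AUC is nonnegative.
* **Companions**: fasting C-peptide/glucose ratio tracks the subject's AUC
  excursion from baseline with coupling +0.5; daily insulin dose per kg
  with coupling −0.8; both with the same additive noise.
* **Immune markers**: three phenomenological series (treatment-specific
  granzyme-B+ CD4, disease-specific perforin+ CD8, IL-17+ CD4) linearly
  interpolating per-arm mean fold-changes over weeks 0–24 (e.g. perforin+
  CD8 rises 1.4× under dose B and falls to 0.7× under dose C), with
  proportional noise.
* **Planted rules**: a conjunction of arm/HLA conditions; each matching
  subject's AUC decline slope is multiplied by the effect (0 = halted) with
  the given penetrance.  v1 restricts effects to the AUC endpoint —
  companions inherit it through the couplings — and predicates to
  dose/HLA/treated-group conditions, matching the association pattern the
  analysis is designed to find.

What the generator does **not** emulate: assay-specific error structure,
informative dropout, visit-time jitter, correlated HLA–baseline
confounding, non-linear C-peptide trajectories (honeymoon rebound), or any
mechanistic link from immune markers to clinical outcome beyond the
planted couplings.  Passing tests therefore demonstrate that the pipeline
recovers structure it is pointed at under clean conditions, not that it
would behave identically on real trial data.

## Pipeline defaults and problem sizes

The default pipeline projects the mined context onto subject-level
antecedent descriptors (arm or treated-group depending on mode, HLA,
baseline tertiles) × outcome consequents at week 24 (delta and response
categories), mirroring the main-time-point focus of this kind of analysis;
all visits and the full roster are reachable through configuration.
Determinism is end-to-end: one seeded generator per stage, canonical
column/row orders, a total order on reported rules (lift desc, support
desc, lexicographic), and 12-significant-digit canonical float formatting,
so a config + seed reproduces every output file byte-for-byte.

Validation sizes used by the test-suite and acceptance script: 500 random
contexts (≤ 15 subjects × ≤ 12 descriptors) for miner-vs-brute-force
equivalence and closure laws; every 2×2 table with n ≤ 30 for Fisher;
every tie-free rank split with n₁+n₂ ≤ 12 for exact MWW; 20 × 200-subject
cohorts for slope recovery; 100 seeds of 41-subject trials for
planted-rule recovery (with 0.9 penetrance and halted decline the planted
association is recovered in ≳ 95% of seeds) and 50 null seeds for the
specificity characterization.

## Known limitations

* Rule counts from the original platform are not reconstructible (they
  depend on a private descriptor roster), so no attempt is made to match
  them; validation is property-based instead.
* The QR model is unusable without externally supplied coefficients.
* The MWW attachment point (antecedent split on the consequent's numeric
  parent) and the dose-necessity reduction are documented interpretations
  of under-specified operations; both are isolated behind switches or
  single functions.
* Mining cost grows with context width; the closed-set enumeration is
  exact, not heuristic, so very wide unprojected contexts (hundreds of
  columns) can be slow — project the context or raise min support.
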