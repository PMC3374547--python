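# Methods

This note records the model, the defaults, and the judgement calls behind
`claimsdeid`, in enough detail that a reviewer can decide whether the
numbers it produces mean what they appear to mean.

## Threat model

Only identity disclosure is modelled: an adversary tries to attach a name
to a released record.  Attribute disclosure (learning a fact about a person
without locating their record) is out of scope throughout.

The adversary is assumed to know, about a target patient:

* the level-1 quasi-identifiers exactly as released — age, sex, and the
  two DaysInHospital outcomes; and
* for each level-2 (claim) quasi-identifier — specialty, place of service,
  CPT code, LOS, DSFC, diagnosis — the values of at most *p*ᵢₕ claims,
  without knowing which values co-occurred in one claim (*inexact
  knowledge*) or the order of the claims beyond what DSFC reveals
  (*inexact order*).

Membership is uncertain: the adversary does not know whether the target is
in the released sample, only that the chance equals the sampling fraction
α.  Both relaxations of the knowledge assumptions (a fully known claim; a
known value-pair order) are implemented as attack variants, not as part of
the design criterion.

## Risk calculus

For a record in a population equivalence class of size *F*ⱼ, the
re-identification probability is 1/*F*ⱼ; the file-level (prosecutor/max)
metric is 1/minⱼ *F*ⱼ.  Population class sizes behind a sample are
estimated either by the large-sample inversion *f*ⱼ/α or by zero-truncated
Poisson moment matching (solve *f*ⱼ = λ/(1−e^(−λ)), estimate λ/α; the
sample class is observed only because it is non-empty, so the matched λ
lies *below* *f*ⱼ — at α = 1 the estimate falls in [*f*ⱼ−1, *f*ⱼ]).

The release criterion ties a per-record threshold θ to a risk-exposure
budget anchored at the HIPAA Safe Harbor population-uniqueness rate
*u* = 0.0004: assuming every over-threshold record is re-identified with
certainty, exposure parity requires θ·MaxSup = *u*, i.e. MaxSup = *u*/θ.
At the production operating point θ = .05 this gives *F*min = 1/θ = 20,
MaxSup = 0.8 %, an in-sample minimum class size *k* = ⌈α·*F*min⌉ (the
ceiling is conservative: the implied population floor *k*/α never falls
below *F*min), and a worst-case expected re-identified fraction
MaxSup·1 + (1−MaxSup)·θ = 5.76 %.  One source inconsistency is resolved
here: a restatement of the *k* rule as "30α" contradicts the floor of 20
and the worked value *k* = 4 at α = 0.2, so *k* = ⌈α·*F*min⌉ is
implemented.

Marketer risk — the expected number of correct matches when every sample
record is matched to a uniformly chosen population record of its class —
is Σⱼ *f*ⱼ/*F*ⱼ; under uniform sampling of *n* from *N* its expectation is
*n·J*/*N* for *J* population classes.  It is the right metric for
register-matching attacks (voter lists, discharge databases) and is
dominated by the prosecutor criterion above, which is why the search
optimizes only the latter.

## Adversary power

Power must rise with the number of claims *n* and fall with the diversity
*u*/*n* of the values.  The implemented default is the reciprocal of
diversity, *p*ᵢₕ = ⌈*n*/*u*⌉, clamped to [1, min(*p*ₘ, *n*)], with
*p*ₘ = 5 by default and 0 for patients with no claims.  It is the simplest
formula satisfying every required property; any alternative with the same
monotonicities can be substituted.  Power is computed on the *generalized*
values of the node under evaluation, because the adversary's knowledge is
expressed in the released vocabulary and coarsening merges values (so power
can only rise up the lattice).

## Generalization hierarchies

* Age: years → 5-year → 10-year → 20-year intervals, each anchored at 0,
  left-closed right-open, with an "80+" catch-all.  The anchor choice is
  ours; only widths are prescribed by the design.
* DaysInHospital (Y2 and Y3 move as one lattice dimension): days →
  {days ≤ 14, ">2 weeks"} → {days ≤ 7, "1–2 weeks", ">2 weeks"}.
* LOS: days → {days ≤ 6, week-range buckets (1–2], (2–4], (4–8], (8–12],
  (12–26], 26+} → "<1 week" replaces the day labels → "<4 weeks" merges
  everything below four weeks.  A stay of exactly 7 days sits on the
  boundary and is binned with week 1, i.e. "(1–2] weeks".
* DSFC: stored 0-based (first claim of each patient-year at 0); levels are
  fixed blocks over 1-based days — weeks [1–7], [8–14], …; 2-week blocks;
  "months" as 28-day blocks.  Fixed 28-day months were chosen over
  calendar months so that the month level coincides exactly with a
  "4 weeks" coarsening; calendar months would make the chain depend on an
  arbitrary calendar origin the data do not carry.
* Sex: never generalized.
* Specialty, PlaceOfService, CPT, Diagnosis: exactly one predetermined
  grouping level each, driven by two-column CSV tables.  Diagnosis maps
  ICD-9-CM codes to primary condition groups by longest-prefix match; a
  Charlson comorbidity score (prefix-weight table, summed once per
  condition per patient-year, categorized 0 / 1–2 / 3–4 / 5+) is available
  for release post-processing.  **The bundled tables are synthetic
  demonstration tables** sized to the synthetic vocabulary; they are not
  clinically authoritative and real deployments must supply their own.

The refinement property (each level is a strict coarsening of the previous
one) is what makes acceptability monotone up the lattice and is enforced
by property tests over the full value domains.

## Node evaluation and search

Exact evaluation of a node would enumerate every combination of *p*ᵢₕ
values per quasi-identifier for every patient, which is combinatorially
hopeless.  Instead a hierarchical bootstrap samples patients with
replacement; each sampled patient contributes one random draw of background
knowledge (a per-QI simple random sample of min(*p*ᵢₕ, *n*ᵢ) values without
replacement), which is matched against the full generalized dataset.  A
patient is high-risk when the match count falls below *k* — the sample-side
test, identical to the population test under the large-sample assumption
and much cheaper than re-estimating *F* per draw.  The node statistic is
the mean high-risk fraction over iterations; its Monte-Carlo standard error
is the between-iteration standard deviation over √B.

Defaults follow the full-scale design (10,000 patients × 1,000
iterations); the CLI and the test suite run desk-scale configurations
(hundreds of patients, tens of iterations), which the bootstrap's
convergence makes a fidelity, not correctness, trade-off.  Passing
`patients_per_iteration=None` sweeps every patient exactly once per
iteration, which is exact when background knowledge is deterministic (all
of a patient's values for a QI identical and within the cap) — the mode
the oracle tests use.

The search processes nodes bottom-up.  A node whose estimate clears the
MaxSup boundary by at least two standard errors tags all of its
generalizations acceptable (or, failing by the same margin, all of its
specializations unacceptable) without evaluating them; borderline nodes
never tag, so stochastic noise near the boundary cannot poison the pruning.
All evaluations reuse one seed (common random numbers), which keeps
estimates comparable across nodes and the result invariant to enumeration
order.  Among acceptable nodes the winner minimizes non-uniform-entropy
information loss — Σ over records and QI columns of −log₂(count of the
record's original value within its generalized group / group size) — with
ties broken by lower total level sum, then lexicographic levels.  When not
even the top node is acceptable the result says so (`releasable=False`)
rather than raising: "cannot release" is a legitimate outcome, and at
desk-scale sample sizes with the production budget (MaxSup = 0.8 %) it is
the expected one, since a single high-risk patient among a few hundred
already exceeds the budget.

## Attack simulation

The simulator is a from-scratch implementation (naive list scans, no code
shared with the search's matcher; a cross-validation test holds the two
matchers to identical match sets over a thousand random draws).  Failed
membership draws count in the denominator.  The `same_claim` variant picks
the fully known claim uniformly among the target's claims; the `ordered`
variant orders one drawn pair per QI by true DSFC, with ties consistent
with either order (a simultaneous pair cannot falsify an order claim).
Background knowledge is drawn from the untruncated D1, matching runs
against the truncated release D2 — so a known-but-truncated claim can
void a match, which is also why attack rates need *not* be monotone in the
power cap under truncation (more knowledge means more chances to know a
deleted claim); the monotonicity tests therefore run without truncation.

## Synthetic data

The generator emulates the structures the risk machinery is sensitive to:
negative-binomial claim counts (mean 12, dispersion 2 — median near 10
with a long right tail, echoing the shape of real claims distributions
without claiming to reproduce any particular release), a chronic fraction
(default 0.3) whose patients repeat one diagnosis across all claims (low
diversity, maximal diagnosis power), Zipf-skewed code vocabularies
(exponent 1.1) so rare combinations exist, DaysInHospital with a mass at
zero and a geometric tail (so top-coding has work to do), and 0-based DSFC
with each patient-year's first claim at day 0.  Ages are uniform on 0–99
and sexes balanced.  An optional blueprint pins exact level-1 values so
oracle tests can dictate the equivalence-class structure.  What it does
*not* emulate: clinical code co-occurrence, seasonality, provider-patient
network structure, or the marginals of any real dataset — so passing tests
demonstrate correctness of the machinery, not expected risk levels on real
data.

Sampling is fixed-size (round(α·N) patients without replacement) rather
than Bernoulli, so fixture sizes are reproducible; the large-sample
relation E[*f*ⱼ] = α·*F*ⱼ holds either way and is verified by simulation.

## Numerical and degenerate-input choices

* Percentiles are nearest-rank (the ⌈p·n⌉-th order statistic) everywhere —
  well-defined on tiny vectors, no interpolation rule to argue about.
* Truncation ties (equal scores) are broken by larger DSFC then larger row
  position: deterministic, and it preserves the earliest clinical history.
* ⌈α·*F*min⌉ is computed after rounding α·*F*min to 9 decimals so that
  binary-float artifacts (0.2·20 → 4.000000000000001) cannot inflate *k*.
* The zero-truncated Poisson root is bracketed on (0, *f*ⱼ], where the
  monotone mean function guarantees brentq convergence; *f*ⱼ = 1
  degenerates to the identity estimate.
* Missing values pass through generalization unchanged, are excluded from
  power counts and from background-knowledge pools, and blank ID cells on
  input mean "already suppressed", not a category.
* Pseudonyms are HMAC-SHA256 tokens truncated to 16 hex digits (64 bits:
  collision-free in practice at release scale); an empty key is rejected
  because an unkeyed hash of a low-entropy identifier is
  dictionary-attackable.

## Known limitations

* The truncation score, the power formula, the marketer closed form and
  the code-grouping tables are documented reconstructions of components
  whose authoritative definitions are not public; all are configurable.
* Acceptability monotonicity up the lattice is provable only when the
  adversary's power is fixed; with value-dependent power, coarsening both
  enlarges classes (risk down) and raises power (risk up).  Empirically the
  first effect dominates on every fixture tested, and the two-standard-
  error tagging margin limits the damage of any local non-monotonicity,
  but the search is heuristic in exactly the way the underlying design is.
* Per-record risk at desk-scale sample sizes is dominated by small-sample
  uniqueness; conclusions about realistically sized releases require
  realistically sized inputs.
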