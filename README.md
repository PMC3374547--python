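# claimsdeid

De-identification of longitudinal health-claims data for public release,
with quantitative re-identification risk assessment.

Publishing claims data (one demographics row per patient, many claim rows
with diagnosis, procedure, provider and timing fields) exposes patients to
*identity disclosure*: an adversary who knows a few facts about a person —
their age and sex, a handful of their diagnoses or visit dates — can try to
single out their records.  `claimsdeid` is for data custodians and
disclosure-control researchers who need to prepare such a release and
defend, with numbers, the claim that the residual risk is acceptable.

## What it does

The pipeline has four stages, each usable on its own:

1. **Preprocessing** (`claimsdeid.preprocess`, `claimsdeid.claims_model`):
   irreversible keyed pseudonyms (HMAC-SHA256) for member/provider IDs;
   top-coding of PayDelay and DaysInHospital at the 99th percentile;
   truncation of per-patient claim counts at the 95th percentile, deleting
   the *rarest* claims first (score = Σ per-QI −log₂ relative frequency);
   removal of patients with stigmatized diagnosis/procedure codes; and
   suppression of provider/vendor/PCP IDs whose practice pattern
   (specialty, place, CPT, diagnosis group) is estimated to be shared by
   fewer than 20 providers in the member population.

2. **Risk calculus** (`claimsdeid.risk_metrics`): for a record in a
   population equivalence class of size *F*ⱼ the re-identification
   probability is 1/*F*ⱼ; the file metric is max ⱼ 1/*F*ⱼ.  A release from a
   sample with fraction α estimates *F*ⱼ from sample sizes *f*ⱼ (large
   sample *f*ⱼ/α, or a zero-truncated Poisson moment estimator).  A
   threshold θ = .05 (floor *F*min = 20) and the HIPAA Safe Harbor
   uniqueness rate *u* = 0.04 % fix the budget MaxSup = *u*/θ = 0.8 % of
   records allowed above threshold, enforced in-sample as a minimum class
   size *k* = ⌈α·*F*min⌉.  Marketer risk Σⱼ *f*ⱼ/*F*ⱼ covers
   population-register matching attacks.

3. **LOLA search** (`claimsdeid.hierarchy`, `claimsdeid.adversary`,
   `claimsdeid.lola`): generalization ladders per quasi-identifier (age
   bins, day→week→month coarsenings, grouped clinical codes) span a lattice
   of release candidates.  The adversary's per-patient, per-QI *power*
   *p*ᵢₕ = min(⌈*n*/*u*⌉, *p*ₘ, *n*) — more claims, more knowable; more
   diverse values, less knowable; capped at *p*ₘ = 5 — drives a
   hierarchical bootstrap that estimates, per lattice node, the proportion
   of patients whose sampled background knowledge matches fewer than *k*
   records.  The search prunes with predictive tagging (acceptability is
   monotone up the lattice) and returns the acceptable node with minimal
   non-uniform-entropy information loss.

4. **Attack simulation** (`claimsdeid.attack_sim`): an independently coded
   Monte-Carlo adversary (membership draw, target draw, background
   knowledge draw, matching, uniform pick) measures the realized match rate
   on a released dataset, including the sensitivity variants *same claim*
   (one full claim tuple known) and *ordered* (temporal order of one value
   pair per QI known) across power caps 5/10/15.

Because real claims data of this shape are proprietary,
`claimsdeid.synthetic_data` generates populations with the structural
features that matter (long-tailed claim counts, chronic low-diversity
patients, skewed code vocabularies, exact class-size blueprints) so the
whole pipeline runs self-contained.

## Worked example

```python
import pandas as pd
from claimsdeid import (RiskParams, SynthConfig, build_default_hierarchies,
    build_lattice, generate_population, search, worst_case_reident_fraction)
from claimsdeid.attack_sim import AttackConfig, simulate_attack1
from claimsdeid.claims_model import Dataset
from claimsdeid.hierarchy import apply_node
from claimsdeid.preprocess import truncate_claims

# 1. the release calculus at the production operating point
params = RiskParams.from_threshold(theta=0.05, u=0.0004, alpha=0.2)
print(f"k = {params.k} records, MaxSup = {params.maxsup:.1%}, "
      f"worst-case bound = {worst_case_reident_fraction(params.maxsup, params.theta):.1%}")

# 2. lattice search on a concentrated cohort (two 60-patient blocks)
rows, crows = [], []
for i in range(120):
    m, base = f"B{i:03d}", 20 if i < 60 else 30
    rows.append((m, base + i % 5, "M", 0, 0))
    crows.append(dict(member_id=m, provider_id="P1", vendor="V1", pcp="C1",
                      year="Y1", specialty="Internal", place_of_service="Office",
                      cpt_code="99213", los=0, dsfc=0, pay_delay=10,
                      diagnosis="250.00"))
cohort = Dataset(pd.DataFrame(rows, columns=["member_id", "age", "sex",
                                             "dih_y2", "dih_y3"]),
                 pd.DataFrame(crows), sampling_fraction=1.0)
hierarchies = build_default_hierarchies()
lattice = build_lattice(hierarchies, ["age", "days_in_hospital"])
res = search(cohort, lattice, hierarchies, RiskParams(alpha=1.0),
             iterations=30, patients_per_iteration=120, seed=9)
print(f"releasable: {res.releasable}; optimal node "
      f"{dict(zip(lattice.qi_names, res.optimal.levels))}; "
      f"info loss {res.info_loss[res.optimal]:.1f} bits; "
      f"{len(res.candidates)} candidate nodes")

# 3. simulated attack on a small fully generalized synthetic release
pop = generate_population(SynthConfig(n_patients=600, seed=7))
full = build_lattice(hierarchies, ["age", "days_in_hospital", "los", "dsfc",
                                   "specialty", "place_of_service",
                                   "cpt_code", "diagnosis"])
d2_raw, plan = truncate_claims(pop, 0.95)
d1 = apply_node(pop, full.top, hierarchies)
d2 = apply_node(d2_raw, full.top, hierarchies)
atk = simulate_attack1(d1, d2, AttackConfig(alpha=0.2, iterations=10000, seed=11))
print(f"attack on 600-patient release: {atk.rate:.2%} re-identified "
      f"(se {atk.se:.2%}, truncation cutoff {plan.cutoff})")
```

Output:

```
k = 4 records, MaxSup = 0.8%, worst-case bound = 5.8%
releasable: True; optimal node {'age': 1, 'days_in_hospital': 0}; info loss 278.6 bits; 9 candidate nodes
attack on 600-patient release: 13.54% re-identified (se 0.34%, truncation cutoff 28)
```

Reading it: with a 20 % sample and a class-size floor of 20, the search
must enforce sample classes of at least *k* = ⌈0.2·20⌉ = 4; at most 0.8 %
of records may exceed the .05 threshold, which bounds the expected
re-identified fraction at 0.8 %·1 + 99.2 %·.05 = 5.76 % ≈ 5.8 % even if
every over-threshold record were re-identified with certainty.  On the
concentrated cohort the search finds that 5-year age bins (level 1) already
make every demographic class large enough, at an information cost of
279 bits.  The attack measurement makes the small-sample effect concrete: a
600-patient release is far more exposed (13.5 % of attack iterations
succeed even at full generalization) than a realistically sized one, which
is why per-record risk must be assessed against the member *population*,
not the file at hand.

A `deidentify` console script wraps the same pipeline
(`gen-synthetic`, `preprocess`, `assess-risk`, `lola`, `simulate-attack`);
run `deidentify COMMAND --help` for options.

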