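"""Monte-Carlo simulated re-identification attack on a released dataset.

The simulation mimics a "nosey neighbor" adversary end to end.  D1 is the
generalized dataset with all claims; D2 is the released version of D1 with
truncated claims (same generalization, same patients).  One attack
iteration: (1) a Bernoulli(α) draw decides whether the target is in the
release at all — a miss is a failed iteration; (2) a target patient is
drawn uniformly from D1; (3) the adversary's background knowledge is drawn
from the target's D1 claims, p_ih values per quasi-identifier; (4) the
knowledge is matched against D2, yielding a matching equivalence class;
(5) one record of the class is picked uniformly; (6) the attack succeeds
iff that record is the target.  The success rate over iterations estimates
the probability that a member-population patient is correctly re-identified.

Two sensitivity variants relax the knowledge assumptions: ``same_claim``
gives the adversary one full claim tuple (all QIs known to co-occur in one
claim), ``ordered`` gives the temporal order of one pair of values per QI.

The matcher here is deliberately written from scratch (plain loops over
per-patient lists) and shares no code with :mod:`claimsdeid.lola`, so the
two implementations can cross-validate each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import adversary
from .claims_model import Dataset, LEVEL1_QIS, LEVEL2_QIS
from .exceptions import IntegrityError
from .lola import BackgroundKnowledge, _dsfc_order  # shared data type, not matching code

__all__ = ["AttackConfig", "AttackResult", "simulate_attack1", "simulate_variant", "attack_grid"]

VARIANTS = ("baseline", "same_claim", "ordered")


@dataclass
class AttackConfig:
    """Parameters of one simulated-attack run."""

    alpha: float
    iterations: int = 10000
    p_m: int = 5
    variant: str = "baseline"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class AttackResult:
    """Match-rate estimate with its binomial standard error."""

    successes: int
    iterations: int

    @property
    def rate(self) -> float:
        return self.successes / self.iterations

    @property
    def se(self) -> float:
        r = self.rate
        return math.sqrt(r * (1 - r) / self.iterations)


def _nv(v):
    return None if (v is None or v is pd.NA or (isinstance(v, float) and math.isnan(v))) else v


def _patient_views(ds: Dataset, qis) -> list[dict]:
    """Flat per-patient view: level-1 tuple plus claim value lists."""
    claims_by_member: dict = {}
    for row in ds.claims.itertuples(index=False):
        rec = {qi: _nv(getattr(row, qi)) for qi in qis}
        rec["_t"] = _dsfc_order(getattr(row, "dsfc"))
        claims_by_member.setdefault(row.member_id, []).append(rec)
    views = []
    for row in ds.patients.itertuples(index=False):
        views.append(
            {
                "member": row.member_id,
                "level1": tuple(_nv(getattr(row, c)) for c in LEVEL1_QIS),
                "claims": claims_by_member.get(row.member_id, []),
            }
        )
    return views


def _consumes(claims: list[dict], qi: str, known: tuple) -> bool:
    """Each known value must be backed by a distinct claim."""
    pool = [rec[qi] for rec in claims if rec[qi] is not None]
    for v in known:
        try:
            pool.remove(_nv(v))
        except ValueError:
            return False
    return True


def _matches(view: dict, bk: BackgroundKnowledge) -> bool:
    if view["level1"] != bk.level1:
        return False
    for qi, known in bk.level2.items():
        if known and not _consumes(view["claims"], qi, known):
            return False
    if bk.same_claim_tuple is not None:
        want = {qi: _nv(v) for qi, v in bk.same_claim_tuple.items()}
        found = False
        for rec in view["claims"]:
            if all(rec[qi] == v for qi, v in want.items()):
                found = True
                break
        if not found:
            return False
    if bk.ordered_pairs is not None:
        for qi, (a, b) in bk.ordered_pairs.items():
            a, b = _nv(a), _nv(b)
            ok = False
            recs = view["claims"]
            for i, r1 in enumerate(recs):
                if r1[qi] != a:
                    continue
                for j, r2 in enumerate(recs):
                    if i != j and r2[qi] == b and not (r1["_t"] > r2["_t"]):
                        ok = True
                        break
                if ok:
                    break
            if not ok:
                return False
    return True


def _draw_bk(
    target: dict, prof: adversary.AdversaryProfile, rng: np.random.Generator,
    qis, variant: str,
) -> BackgroundKnowledge:
    claims = target["claims"]
    level2 = {}
    ordered = {} if variant == "ordered" else None
    for qi in qis:
        backed = [rec for rec in claims if rec[qi] is not None]
        p = min(prof.power_of(target["member"], qi), len(backed))
        if p == 0:
            level2[qi] = ()
            continue
        drawn_idx = rng.choice(len(backed), size=p, replace=False)
        drawn = [backed[i] for i in drawn_idx]
        level2[qi] = tuple(rec[qi] for rec in drawn)
        if ordered is not None and p > 1:
            c1, c2 = drawn[0], drawn[1]
            if c1["_t"] > c2["_t"]:
                c1, c2 = c2, c1
            ordered[qi] = (c1[qi], c2[qi])
    same_claim = None
    if variant == "same_claim" and claims:
        rec = claims[int(rng.integers(len(claims)))]
        same_claim = {qi: rec[qi] for qi in qis}
    return BackgroundKnowledge(
        level1=target["level1"],
        level2=level2,
        same_claim_tuple=same_claim,
        ordered_pairs=ordered or None,
    )


def simulate_attack1(
    d1: Dataset, d2: Dataset, cfg: AttackConfig, qis=LEVEL2_QIS
) -> AttackResult:
    """Run the six-step simulated attack against the released dataset.

    ``d1`` and ``d2`` must hold the same patients at the same generalization
    level; ``d2`` is the claim-truncated release.
    """
    m1, m2 = set(d1.patients["member_id"]), set(d2.patients["member_id"])
    if m1 != m2:
        raise IntegrityError(
            "D1 and D2 must hold the same patients (they differ beyond truncation)"
        )
    rng = np.random.default_rng(cfg.seed)
    prof = adversary.profile(d1, qis=qis, p_m=cfg.p_m)
    d1_views = _patient_views(d1, qis)
    d2_views = _patient_views(d2, qis)
    successes = 0
    for _ in range(cfg.iterations):
        if rng.random() >= cfg.alpha:
            continue  # target not in the release: failed iteration
        target = d1_views[int(rng.integers(len(d1_views)))]
        bk = _draw_bk(target, prof, rng, qis, cfg.variant)
        matching = [v["member"] for v in d2_views if _matches(v, bk)]
        if not matching:
            continue  # truncation removed the known claims
        pick = matching[int(rng.integers(len(matching)))]
        if pick == target["member"]:
            successes += 1
    return AttackResult(successes=successes, iterations=cfg.iterations)


def simulate_variant(
    d1: Dataset, d2: Dataset, cfg: AttackConfig, variant: str, qis=LEVEL2_QIS
) -> AttackResult:
    """Run one sensitivity-analysis variant of the simulated attack."""
    return simulate_attack1(d1, d2, dc_replace(cfg, variant=variant), qis=qis)


def attack_grid(
    d1: Dataset,
    d2: Dataset,
    cfg: AttackConfig,
    p_m_values=(5, 10, 15),
    variants=VARIANTS,
    qis=LEVEL2_QIS,
) -> pd.DataFrame:
    """Assumption × power grid of attack rates.

    All cells of one variant row share the same seed so rates are paired
    across powers; rows share the base seed so variants are paired too.
    """
    rows = []
    for variant in variants:
        for p_m in p_m_values:
            res = simulate_attack1(
                d1, d2, dc_replace(cfg, variant=variant, p_m=p_m), qis=qis
            )
            rows.append(
                {
                    "variant": variant,
                    "p_m": p_m,
                    "successes": res.successes,
                    "iterations": res.iterations,
                    "rate": res.rate,
                    "se": res.se,
                }
            )
    return pd.DataFrame(rows)
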