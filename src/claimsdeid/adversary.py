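"""Per-patient, per-quasi-identifier adversary power.

An adversary's *power* p_ih is the number of claim values for quasi-
identifier h they are assumed to know about patient i.  Power grows with the
patient's claim count (more claims, more exposure) and shrinks with the
diversity of the values (a chronic patient whose diagnosis repeats is easy
to know; knowing one claim predicts the rest).  The default formula is the
reciprocal of diversity, ceil(n/u), clamped to [1, min(p_m, n)] with a
global cap p_m (default 5); a patient with no claims has power 0.

Power is computed on the dataset's *current* values, so after generalization
values merge, diversity falls, and power can only rise — the adversary's
knowledge is expressed in the released vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .claims_model import Dataset, LEVEL2_QIS

__all__ = ["AdversaryProfile", "diversity", "power", "profile", "LEVEL2_QIS"]


@dataclass
class AdversaryProfile:
    """p_ih and diversity for every (patient, level-2 QI) pair."""

    p_m: int = 5
    qis: tuple[str, ...] = LEVEL2_QIS
    p: dict = field(default_factory=dict)  # (member_id, qi) -> int
    diversity: dict = field(default_factory=dict)  # (member_id, qi) -> float

    def power_of(self, member_id, qi: str) -> int:
        return self.p.get((member_id, qi), 0)


def diversity(values) -> float:
    """Distinct fraction u/n of a patient's values for one QI, in (0, 1]."""
    values = list(values)
    if not values:
        raise ValueError("diversity undefined for an empty multiset")
    return len(set(values)) / len(values)


def power(n: int, u: int, p_m: int = 5) -> int:
    """Adversary power for a patient with n claims and u distinct values.

    ceil(n/u) clamped to [1, min(p_m, n)]; 0 when the patient has no claims
    (no level-2 background knowledge is possible).
    """
    if n == 0:
        return 0
    if not 1 <= u <= n:
        raise ValueError(f"need 1 <= u <= n, got u={u}, n={n}")
    return max(1, min(math.ceil(n / u), p_m, n))


def profile(ds: Dataset, qis=LEVEL2_QIS, p_m: int = 5) -> AdversaryProfile:
    """Compute p_ih for every patient and level-2 QI of ``ds``.

    Values are taken as-is (possibly generalized labels); missing values are
    excluded from both the count and the distinct count.
    """
    prof = AdversaryProfile(p_m=p_m, qis=tuple(qis))
    grouped = ds.claims.groupby("member_id", sort=False)
    stats: dict = {}
    for member, g in grouped:
        for qi in qis:
            vals = g[qi].dropna().tolist()
            stats[(member, qi)] = vals
    for member in ds.patients["member_id"]:
        for qi in qis:
            vals = stats.get((member, qi), [])
            n = len(vals)
            if n == 0:
                prof.p[(member, qi)] = 0
                continue
            u = len(set(vals))
            prof.p[(member, qi)] = power(n, u, p_m)
            prof.diversity[(member, qi)] = u / n
    return prof
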