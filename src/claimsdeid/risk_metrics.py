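"""Identity-disclosure risk metrics for a sampled release.

The unit of risk is the equivalence class: all records sharing the same
quasi-identifier values.  For a record in population class ``j`` of size
``F_j`` the probability of correct re-identification under a targeted
(prosecutor) attack is ``1/F_j``; the file-level metric is the maximum over
records.  Because the release is a sample with fraction α of the member
population, population class sizes are estimated from sample sizes ``f_j``
(large-sample ``f_j/α``, or a zero-truncated Poisson moment estimator for
small fractions).

The release criterion ties a per-record probability threshold θ (default
.05, i.e. a population class-size floor of 20) to the HIPAA Safe Harbor
risk-exposure budget: with a population-uniqueness rate ``u`` (0.04%) under
Safe Harbor, at most ``MaxSup = u/θ`` of the records may exceed θ, assuming
those records are re-identified with certainty.  The equivalent sample-side
constraint is a minimum class size ``k = ceil(α·F_min)``.

Marketer risk — the expected number of records correctly matched when every
sample record is linked to a uniformly chosen population record in its class
— is ``Σ_j f_j / F_j``; it covers population-register matching attacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DomainError, SchemaError

__all__ = [
    "EquivalenceClassTable",
    "RiskParams",
    "RiskReport",
    "equivalence_classes",
    "record_risk",
    "max_risk",
    "estimate_population_class_size",
    "compute_k",
    "maxsup_from_exposure",
    "worst_case_reident_fraction",
    "acceptability",
    "marketer_risk",
]


@dataclass
class EquivalenceClassTable:
    """Partition of records by quasi-identifier tuple.

    ``classes`` maps the QI tuple to the row labels of its members; ``f``
    holds sample class sizes and ``F``, when set, known or estimated
    population sizes.
    """

    classes: dict[tuple, list]
    f: dict[tuple, int]
    F: dict[tuple, float] | None = None

    @property
    def n_records(self) -> int:
        return sum(self.f.values())

    def sizes(self) -> list[int]:
        return sorted(self.f.values())

    def estimate_F(self, alpha: float, method: str = "large_sample") -> None:
        self.F = {
            t: estimate_population_class_size(fj, alpha, method)
            for t, fj in self.f.items()
        }

    def record_F(self) -> np.ndarray:
        """Per-record population class size, in class iteration order."""
        if self.F is None:
            raise DomainError("population class sizes not set; call estimate_F")
        return np.concatenate(
            [np.full(self.f[t], self.F[t]) for t in self.classes]
        )


@dataclass
class RiskParams:
    """Thresholds tying the release to its risk-exposure budget.

    theta
        per-record re-identification probability threshold (default .05)
    f_min
        population class-size floor, 1/theta (default 20)
    alpha
        sampling fraction of the release
    maxsup
        allowed proportion of above-threshold records, u/theta (default 0.008)
    safe_harbor_u
        Safe Harbor population-uniqueness rate anchoring the budget (0.0004)
    """

    theta: float = 0.05
    f_min: int = 20
    alpha: float = 1.0
    maxsup: float = 0.008
    safe_harbor_u: float = 0.0004

    def __post_init__(self) -> None:
        for name in ("theta", "alpha", "maxsup"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DomainError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_threshold(
        cls, theta: float = 0.05, u: float = 0.0004, alpha: float = 1.0
    ) -> "RiskParams":
        """Derive the floor and MaxSup from θ and the uniqueness rate."""
        return cls(
            theta=theta,
            f_min=math.ceil(round(1.0 / theta, 9)),
            alpha=alpha,
            maxsup=maxsup_from_exposure(theta, u),
            safe_harbor_u=u,
        )

    @property
    def k(self) -> int:
        return compute_k(self.f_min, self.alpha)


@dataclass
class RiskReport:
    """Outcome of the acceptability assessment for one release candidate."""

    per_record_risk: np.ndarray
    max_risk: float
    prop_high_risk: float
    acceptable: bool
    marketer_expected_matches: float | None = None
    params: RiskParams = field(default_factory=RiskParams)

    def to_dict(self) -> dict:
        out = {
            "n_records": int(len(self.per_record_risk)),
            "max_risk": float(self.max_risk),
            "prop_high_risk": float(self.prop_high_risk),
            "acceptable": bool(self.acceptable),
            "theta": self.params.theta,
            "maxsup": self.params.maxsup,
            "alpha": self.params.alpha,
            "k": self.params.k,
        }
        if self.marketer_expected_matches is not None:
            out["marketer_expected_matches"] = float(self.marketer_expected_matches)
        return out


def equivalence_classes(records: pd.DataFrame, qi_columns) -> EquivalenceClassTable:
    """Partition ``records`` by tuple equality on ``qi_columns``."""
    if len(records) == 0:
        raise DomainError("cannot partition an empty table")
    missing = [c for c in qi_columns if c not in records.columns]
    if missing:
        raise SchemaError(f"unknown quasi-identifier column(s): {missing}")
    classes: dict[tuple, list] = {}
    cols = [records[c] for c in qi_columns]
    for idx, key in zip(records.index, zip(*cols)):
        classes.setdefault(tuple(key), []).append(idx)
    return EquivalenceClassTable(
        classes=classes, f={t: len(m) for t, m in classes.items()}
    )


def record_risk(F_j: float) -> float:
    """Probability of re-identifying a record in a population class of size
    ``F_j`` (the reciprocal)."""
    if F_j < 1:
        raise DomainError(f"class size must be >= 1, got {F_j}")
    return 1.0 / F_j


def max_risk(table: EquivalenceClassTable) -> float:
    """File-level risk: the highest per-record risk, 1/min_j F_j."""
    F = table.F if table.F is not None else {t: float(f) for t, f in table.f.items()}
    return record_risk(min(F.values()))


def _zt_poisson_mean(lam: float) -> float:
    return lam / -math.expm1(-lam)


def estimate_population_class_size(
    f_j: int, alpha: float, method: str = "large_sample"
) -> float:
    """Estimate the population class size behind a sample class of size f_j.

    ``large_sample`` inverts the expectation f_j = α·F_j.  ``truncated_poisson``
    moment-matches a zero-truncated Poisson: solve f_j = λ/(1−e^{−λ}) for λ
    and return λ/α; as f_j → 1, λ → 0 and the estimate degenerates to f_j.
    """
    if f_j < 1:
        raise DomainError(f"sample class size must be >= 1, got {f_j}")
    if not 0 < alpha <= 1:
        raise DomainError(f"sampling fraction must be in (0, 1], got {alpha}")
    if method == "large_sample":
        return f_j / alpha
    if method == "truncated_poisson":
        if f_j <= 1:
            return float(f_j)
        # λ/(1-e^-λ) is increasing from 1 (λ→0) with slope < 1, so the root
        # of mean(λ) = f_j lies in (f_j - 1, f_j]
        lam = brentq(lambda l: _zt_poisson_mean(l) - f_j, 1e-12, float(f_j))
        return lam / alpha
    raise DomainError(f"unknown estimator {method!r}")


def compute_k(F_min: int, alpha: float) -> int:
    """Minimum sample equivalence-class size enforcing a population floor of
    ``F_min`` under sampling fraction α: k = ceil(α·F_min)."""
    if F_min < 1:
        raise DomainError(f"F_min must be >= 1, got {F_min}")
    if not 0 < alpha <= 1:
        raise DomainError(f"sampling fraction must be in (0, 1], got {alpha}")
    return math.ceil(round(alpha * F_min, 9))


def maxsup_from_exposure(theta: float, u: float) -> float:
    """Largest proportion of above-threshold records keeping risk exposure at
    or below the Safe Harbor budget: u/θ, assuming those records are
    re-identified with probability 1 (θ·maxsup = u·1)."""
    if not 0 < theta <= 1:
        raise DomainError(f"theta must be in (0, 1], got {theta}")
    if not 0 <= u <= 1:
        raise DomainError(f"uniqueness rate must be in [0, 1], got {u}")
    return u / theta

def worst_case_reident_fraction(maxsup: float, theta: float) -> float:
    """Conservative bound on the expected re-identified fraction: the MaxSup
    records at probability 1, everyone else exactly at θ."""
    if not 0 <= maxsup <= 1 or not 0 <= theta <= 1:
        raise DomainError("maxsup and theta must be in [0, 1]")
    return maxsup * 1.0 + (1.0 - maxsup) * theta


def acceptability(F_hat, params: RiskParams) -> RiskReport:
    """Assess per-record population class sizes against the release criterion.

    A record is high-risk when 1/F̂ exceeds θ; the release is acceptable when
    the high-risk proportion is at most MaxSup.
    """
    F_hat = np.asarray(F_hat, dtype=float)
    if F_hat.size == 0:
        raise DomainError("no records to assess")
    if (F_hat < 1).any():
        raise DomainError("population class sizes must be >= 1")
    risk = 1.0 / F_hat
    prop = float(np.mean(risk > params.theta))
    return RiskReport(
        per_record_risk=risk,
        max_risk=float(risk.max()),
        prop_high_risk=prop,
        acceptable=prop <= params.maxsup,
        params=params,
    )


def marketer_risk(
    sample_classes: Mapping[tuple, int], population_classes: Mapping[tuple, float]
) -> float:
    """Expected number of correct matches when each sample record is matched
    to a uniformly chosen population record of its class: Σ_j f_j/F_j.

    Divide by the sample size for the marketer *proportion*.
    """
    total = 0.0
    for t, fj in sample_classes.items():
        if t not in population_classes:
            raise DomainError(f"sample class {t!r} absent from population")
        Fj = population_classes[t]
        if Fj < fj:
            raise DomainError(
                f"population class {t!r} smaller than sample class ({Fj} < {fj})"
            )
        total += fj / Fj
    return total
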