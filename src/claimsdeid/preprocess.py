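"""Pre-risk-assessment de-identification steps.

Four transforms run before any lattice search: top-coding of extreme
numeric values (PayDelay, DaysInHospital, 99th percentile), truncation of
each patient's claims at the 95th percentile of per-patient claim counts
(dropping the rarest — highest-scoring — claims first), removal of patients
carrying highly stigmatized diagnosis/procedure codes, and suppression of
provider/vendor/PCP identifiers whose practice pattern is estimated to be
shared by fewer than 20 providers in the member population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import Dataset, LEVEL2_QIS
from .exceptions import ConfigurationError, DomainError
from .risk_metrics import estimate_population_class_size
from .tables import _data_path

__all__ = [
    "TruncationPlan",
    "HighRiskCodeList",
    "top_code",
    "nearest_rank",
    "score_claims",
    "truncate_claims",
    "remove_high_risk_patients",
    "load_high_risk_codes",
    "suppress_provider_ids",
]

#: the 4-tuple practice pattern used for provider/vendor/PCP suppression
SUPPRESSION_PATTERN = ("specialty", "place_of_service", "cpt_code", "diagnosis")


@dataclass
class TruncationPlan:
    """Record of one truncation pass: the cutoff, per-claim rarity scores,
    and the claim row labels that were removed."""

    cutoff: int
    scores: pd.Series
    removed: list = field(default_factory=list)


@dataclass
class HighRiskCodeList:
    """Stigmatized-condition code patterns; exact codes or prefixes."""

    icd9_codes: frozenset[str] = frozenset()
    cpt_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for pat in set(self.icd9_codes) | set(self.cpt_codes):
            if not isinstance(pat, str) or not pat.strip():
                raise ConfigurationError(f"malformed code pattern: {pat!r}")


def nearest_rank(values, percentile: float):
    """Nearest-rank percentile: the ceil(p·n)-th order statistic."""
    values = np.asarray(values)
    if values.size == 0:
        raise DomainError("percentile of an empty vector")
    if not 0 < percentile <= 1:
        raise DomainError(f"percentile must be in (0, 1], got {percentile}")
    rank = math.ceil(percentile * values.size)
    return np.sort(values)[rank - 1]


def top_code(values, percentile: float = 0.99):
    """Cap values above the nearest-rank percentile at that percentile.

    Returns ``(capped array, cap value)``; values at or below the cap are
    unchanged, so the transform is idempotent.
    """
    values = np.asarray(values)
    cap = nearest_rank(values, percentile)
    return np.minimum(values, cap), cap


def top_code_dataset(
    ds: Dataset,
    percentile: float = 0.99,
    columns=(("patients", "dih_y2"), ("patients", "dih_y3"), ("claims", "pay_delay")),
) -> Dataset:
    """Top-code the PayDelay and DaysInHospital columns in place of a copy."""
    out = ds.copy()
    for table, col in columns:
        df = out.patients if table == "patients" else out.claims
        vals = df[col].dropna()
        if vals.empty:
            continue
        _, cap = top_code(vals.to_numpy(dtype=float), percentile)
        df[col] = df[col].map(lambda v: v if pd.isna(v) else min(v, type(v)(cap)))
    return out


def score_claims(ds: Dataset, qis=LEVEL2_QIS) -> pd.Series:
    """Per-claim rarity score: Σ over level-2 QIs of −log2(relative
    frequency of the claim's value), computed on the full claims table.

    Claims whose every value is universal score 0; rare value combinations
    score high and are deleted first during truncation.
    """
    if ds.claims.empty:
        raise DomainError("cannot score an empty claims table")
    n = len(ds.claims)
    score = pd.Series(0.0, index=ds.claims.index)
    for qi in qis:
        freq = ds.claims[qi].map(ds.claims[qi].value_counts(dropna=False)) / n
        score += -np.log2(freq.astype(float))
    return score


def truncate_claims(
    ds: Dataset, percentile: float = 0.95, qis=LEVEL2_QIS
) -> tuple[Dataset, TruncationPlan]:
    """Cap per-patient claim counts at the given percentile of the count
    distribution, removing each over-limit patient's highest-scored claims.

    Ties on score are broken by larger DSFC, then larger row position, so
    the earliest clinical history is preserved and output is deterministic.
    Returns the truncated (releasable) dataset and the plan; the caller
    keeps the untruncated original for attack simulation.
    """
    counts = ds.claims.groupby("member_id", sort=False).size()
    counts = counts.reindex(ds.patients["member_id"], fill_value=0)
    cutoff = int(nearest_rank(counts.to_numpy(), percentile))
    scores = score_claims(ds, qis=qis)
    removed: list = []
    pos = pd.Series(range(len(ds.claims)), index=ds.claims.index)
    dsfc_num = pd.to_numeric(ds.claims["dsfc"], errors="coerce").fillna(-1)
    for member, g in ds.claims.groupby("member_id", sort=False):
        excess = len(g) - cutoff
        if excess <= 0:
            continue
        order = sorted(
            g.index,
            key=lambda i: (-scores[i], -dsfc_num[i], -pos[i]),
        )
        removed.extend(order[:excess])
    out = ds.copy()
    out.claims = out.claims.drop(index=removed)
    return out, TruncationPlan(cutoff=cutoff, scores=scores, removed=removed)


def load_high_risk_codes(path=None) -> HighRiskCodeList:
    """Read a (code_system, pattern) CSV; the bundled default is a synthetic
    demonstration list, not any release's authoritative criteria."""
    if path is None:
        path = _data_path("high_risk_codes_demo.csv")
    df = pd.read_csv(path, dtype=str)
    if not {"code_system", "pattern"} <= set(df.columns):
        raise ConfigurationError("code list needs columns code_system, pattern")
    sys = df["code_system"].str.strip().str.lower()
    pat = df["pattern"].str.strip()
    return HighRiskCodeList(
        icd9_codes=frozenset(pat[sys == "icd9"]),
        cpt_codes=frozenset(pat[sys == "cpt"]),
    )


def _matches(code, patterns) -> bool:
    if pd.isna(code):
        return False
    c = str(code)
    cs = c.replace(".", "")
    return any(c == p or c.startswith(p) or cs.startswith(p.replace(".", "")) for p in patterns)


def remove_high_risk_patients(ds: Dataset, codes: HighRiskCodeList) -> Dataset:
    """Drop every patient (and all their claims) who has at least one claim
    whose ICD-9 or CPT code matches the list, by exact or prefix match."""
    if not codes.icd9_codes and not codes.cpt_codes:
        return ds.copy()
    flagged = ds.claims["diagnosis"].map(lambda c: _matches(c, codes.icd9_codes))
    flagged |= ds.claims["cpt_code"].map(lambda c: _matches(c, codes.cpt_codes))
    bad_members = set(ds.claims.loc[flagged, "member_id"])
    out = ds.copy()
    out.patients = out.patients[~out.patients["member_id"].isin(bad_members)]
    out.claims = out.claims[~out.claims["member_id"].isin(bad_members)]
    return out


def suppress_provider_ids(
    ds: Dataset,
    alpha: float | None = None,
    min_count: int = 20,
    fields=("provider_id", "vendor", "pcp"),
    estimator: str = "large_sample",
    diagnosis_group=None,
) -> Dataset:
    """Blank provider/vendor/PCP IDs on claims whose practice pattern is too
    distinctive.

    For each observed (Specialty, PlaceOfService, CPTCode, diagnosis-group)
    pattern, count the distinct providers having at least one claim with
    that pattern, scale the count to the member population by 1/α, and
    suppress the ID wherever the estimate falls below ``min_count``.  The
    same procedure runs independently for each field.

    ``diagnosis_group`` optionally maps raw diagnosis codes to the grouped
    vocabulary before pattern counting; by default the column is used as-is.
    """
    if alpha is None:
        alpha = ds.sampling_fraction
    if not 0 < alpha <= 1:
        raise DomainError(f"sampling fraction must be in (0, 1], got {alpha}")
    if min_count < 1:
        raise DomainError(f"min_count must be >= 1, got {min_count}")
    out = ds.copy()
    diag = out.claims["diagnosis"]
    if diagnosis_group is not None:
        diag = diag.map(lambda v: v if pd.isna(v) else diagnosis_group(v))
    pattern = list(zip(
        out.claims["specialty"], out.claims["place_of_service"],
        out.claims["cpt_code"], diag,
    ))
    pattern = pd.Series(pattern, index=out.claims.index)
    for fld in fields:
        ids = out.claims[fld]
        observed = pd.DataFrame({"pattern": pattern, "id": ids}).dropna(subset=["id"])
        n_providers = observed.groupby("pattern")["id"].nunique()
        suppressed_patterns = {
            pat
            for pat, cnt in n_providers.items()
            if estimate_population_class_size(int(cnt), alpha, estimator) < min_count
        }
        mask = pattern.isin(suppressed_patterns) & ids.notna()
        out.claims.loc[mask, fld] = pd.NA
    return out
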