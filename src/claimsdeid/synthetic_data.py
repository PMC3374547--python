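"""Synthetic longitudinal claims generator.

Real claims datasets of this shape are proprietary, so every other module
is exercised on synthetic populations with controllable identifiability
structure: per-patient claim counts with a long right tail (negative
binomial), *chronic* patients whose diagnosis repeats across claims (low
diversity, hence high adversary power), Zipf-skewed code vocabularies so
that rare value combinations exist, and day-level DSFC that is 0-based
within each patient-year.  An optional *blueprint* pins the level-1
(demographic) equivalence-class structure exactly, which oracle tests use
to compare against closed-form risk values.

The generator emulates structure, not clinical reality: code co-occurrence
is independent, visit timing is uniform, and the marginals of any real
claims release are not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .claims_model import CLAIM_HEADERS, Dataset
from .exceptions import ConfigurationError, DomainError

__all__ = ["SynthConfig", "generate_population", "sample_dataset", "make_oracle_fixture"]

SPECIALTIES = (
    "Internal", "GeneralPractice", "Pediatrics", "Surgery", "Anesthesiology",
    "Emergency", "DiagnosticImaging", "Laboratory", "Obstetrics", "Other",
)
PLACES = (
    "Office", "Home", "UrgentCare", "Emergency", "Ambulance",
    "OutpatientHospital", "IndependentLab", "InpatientHospital",
)
CPT_CODES = (
    "99213", "99214", "99203", "99204", "99285", "99221", "71020", "71250",
    "74150", "80053", "80061", "85025", "36415", "93000", "97110", "90471",
    "45378", "27447", "59400", "66984",
)
DIAGNOSES = (
    "250.00", "250.60", "401.9", "402.90", "428.0", "414.01", "486",
    "491.21", "493.90", "540.9", "571.5", "585.9", "162.9", "174.9",
    "153.9", "296.20", "311", "331.0", "410.9", "715.90", "724.2",
    "780.79", "V70.0",
)
#: chronic conditions a patient's repeating diagnosis is drawn from
CHRONIC_DIAGNOSES = ("250.00", "401.9", "428.0", "493.90", "585.9", "296.20")
#: stigmatized codes matched by the demonstration high-risk list
HIGH_RISK_DIAGNOSES = ("042", "635.92")

YEARS = ("Y1", "Y2", "Y3")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic population."""

    n_patients: int = 300
    alpha: float = 0.2
    seed: int = 0
    claim_mean: float = 12.0  # mean claims per patient (long right tail)
    claim_dispersion: float = 2.0  # negative-binomial shape; smaller = heavier tail
    chronic_fraction: float = 0.3  # patients whose diagnosis repeats
    high_risk_fraction: float = 0.0  # patients given one stigmatized code
    zipf_exponent: float = 1.1  # frequency skew of code vocabularies
    n_providers: int = 60
    n_vendors: int = 30
    n_pcps: int = 40
    blueprint: list | None = None  # [(patient-field dict, size), ...]

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.claim_mean <= 0 or self.claim_dispersion <= 0:
            raise ConfigurationError("counts and distribution parameters must be positive")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")


def _zipf_probs(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def _pick(rng, vocab, s, size):
    return [vocab[i] for i in rng.choice(len(vocab), size=size, p=_zipf_probs(len(vocab), s))]


def generate_population(cfg: SynthConfig) -> Dataset:
    """Generate a member population (sampling fraction 1.0), deterministic
    under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.blueprint is not None:
        specs = []
        for fields, size in cfg.blueprint:
            specs.extend([dict(fields)] * int(size))
        n = len(specs)
        if n != cfg.n_patients:
            raise ConfigurationError(
                f"blueprint sizes sum to {n}, config says {cfg.n_patients} patients"
            )
    else:
        n = cfg.n_patients
        specs = [{} for _ in range(n)]

    members = [f"M{i:05d}" for i in range(1, n + 1)]
    dih_tail = lambda: int(rng.geometric(0.35)) if rng.random() < 0.25 else 0  # noqa: E731
    patients = pd.DataFrame(
        {
            "member_id": members,
            "age": [s.get("age", int(rng.integers(0, 100))) for s in specs],
            "sex": [s.get("sex", "M" if rng.random() < 0.5 else "F") for s in specs],
            "dih_y2": [s.get("dih_y2", dih_tail()) for s in specs],
            "dih_y3": [s.get("dih_y3", dih_tail()) for s in specs],
        }
    )
    for col in ("age", "dih_y2", "dih_y3"):
        patients[col] = patients[col].astype("Int64")

    nb_p = cfg.claim_dispersion / (cfg.claim_dispersion + cfg.claim_mean - 1)
    counts = 1 + rng.negative_binomial(cfg.claim_dispersion, nb_p, size=n)
    chronic = rng.random(n) < cfg.chronic_fraction
    high_risk = rng.random(n) < cfg.high_risk_fraction
    providers = [f"P{i:04d}" for i in range(1, cfg.n_providers + 1)]
    vendors = [f"V{i:04d}" for i in range(1, cfg.n_vendors + 1)]
    pcps = [f"C{i:04d}" for i in range(1, cfg.n_pcps + 1)]
    s = cfg.zipf_exponent

    rows = []
    for i, member in enumerate(members):
        m = int(counts[i])
        years = [YEARS[j] for j in rng.integers(0, 3, size=m)]
        # 0-based days since first claim within each patient-year
        dsfc = np.sort(rng.integers(0, 364, size=m))
        year_min = {}
        for y, d in zip(years, dsfc):
            year_min[y] = min(year_min.get(y, 10**9), int(d))
        pcp = pcps[int(rng.choice(len(pcps), p=_zipf_probs(len(pcps), s)))]
        if chronic[i]:
            diag = [CHRONIC_DIAGNOSES[int(rng.integers(len(CHRONIC_DIAGNOSES)))]] * m
        else:
            diag = _pick(rng, DIAGNOSES, s, m)
        if high_risk[i]:
            diag[int(rng.integers(m))] = HIGH_RISK_DIAGNOSES[
                int(rng.integers(len(HIGH_RISK_DIAGNOSES)))
            ]
        places = _pick(rng, PLACES, s, m)
        for j in range(m):
            inpatient = places[j] == "InpatientHospital"
            rows.append(
                {
                    "member_id": member,
                    "provider_id": providers[
                        int(rng.choice(len(providers), p=_zipf_probs(len(providers), s)))
                    ],
                    "vendor": vendors[
                        int(rng.choice(len(vendors), p=_zipf_probs(len(vendors), s)))
                    ],
                    "pcp": pcp,
                    "year": years[j],
                    "specialty": _pick(rng, SPECIALTIES, s, 1)[0],
                    "place_of_service": places[j],
                    "cpt_code": _pick(rng, CPT_CODES, s, 1)[0],
                    "los": int(rng.geometric(0.3)) if inpatient else 0,
                    "dsfc": int(dsfc[j]) - year_min[years[j]],
                    "pay_delay": int(rng.integers(10, 60) + (rng.geometric(0.05) if rng.random() < 0.05 else 0)),
                    "diagnosis": diag[j],
                }
            )
    claims = pd.DataFrame(rows, columns=list(CLAIM_HEADERS))
    for col in ("los", "dsfc", "pay_delay"):
        claims[col] = claims[col].astype("Int64")
    return Dataset(patients, claims, sampling_fraction=1.0)


def sample_dataset(pop: Dataset, alpha: float, seed: int | None = None) -> Dataset:
    """Simple random sample of round(α·N) patients, with all their claims."""
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    rng = np.random.default_rng(seed)
    n = pop.n_patients
    size = int(round(alpha * n))
    keep = np.sort(rng.choice(n, size=size, replace=False))
    patients = pop.patients.iloc[keep].reset_index(drop=True)
    members = set(patients["member_id"])
    claims = pop.claims[pop.claims["member_id"].isin(members)].reset_index(drop=True)
    return Dataset(patients, claims, sampling_fraction=alpha)


def _empty_claims() -> pd.DataFrame:
    df = pd.DataFrame(columns=list(CLAIM_HEADERS))
    for col in ("los", "dsfc", "pay_delay"):
        df[col] = df[col].astype("Int64")
    return df


def _patients_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["member_id", "age", "sex", "dih_y2", "dih_y3"])
    for col in ("age", "dih_y2", "dih_y3"):
        df[col] = df[col].astype("Int64")
    return df


def make_oracle_fixture(name: str):
    """Hand-constructed micro-datasets with closed-form expected values.

    ``uniform_classes_c4``
        16 patients in 4 demographic classes of 4, no claims; the simulated
        attack succeeds with probability α/4.
    ``all_unique``
        8 patients each demographically unique; maximum risk 1.0.
    ``boundary_maxsup``
        125 patients, exactly one of them unique (the rest in classes of
        31): the high-risk proportion is 1/125 = 0.008, sitting exactly on
        the MaxSup boundary, hence acceptable.
    """
    if name == "uniform_classes_c4":
        rows = []
        tuples = [(20, "M"), (20, "F"), (40, "M"), (40, "F")]
        i = 0
        for age, sex in tuples:
            for _ in range(4):
                i += 1
                rows.append((f"U{i:03d}", age, sex, 0, 0))
        ds = Dataset(_patients_frame(rows), _empty_claims(), 1.0)
        return ds, {"class_size": 4, "n_classes": 4, "attack1_rate_factor": 0.25}
    if name == "all_unique":
        rows = [(f"Q{i}", 10 * i, "M" if i % 2 else "F", 0, 0) for i in range(1, 9)]
        ds = Dataset(_patients_frame(rows), _empty_claims(), 1.0)
        return ds, {"max_risk": 1.0, "n_patients": 8}
    if name == "boundary_maxsup":
        rows = [("B000", 99, "F", 14, 14)]  # the lone population unique
        i = 0
        for age in (20, 30, 40, 50):
            for _ in range(31):
                i += 1
                rows.append((f"B{i:03d}", age, "M", 0, 0))
        ds = Dataset(_patients_frame(rows), _empty_claims(), 1.0)
        return ds, {"prop_high_risk": 1 / 125, "acceptable": True, "n_patients": 125}
    raise DomainError(f"unknown oracle fixture {name!r}")
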