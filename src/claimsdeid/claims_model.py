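"""Data model for linked longitudinal claims tables.

The release layout is two linked CSV tables: a *patients* table with one row
per patient (MemberID, Age, Sex, DaysInHospital Y2, DaysInHospital Y3) and a
*claims* table with one row per claim (MemberID, ProviderID, Vendor, PCP,
Year, Specialty, PlaceOfService, CPTCode, LOS, DSFC, PayDelay, Diagnosis).
The two tables are joined on MemberID.  Internally both tables are held as
:class:`pandas.DataFrame` objects with snake_case column names; quasi-
identifier columns may hold either raw values (integers, codes) or, after
generalization, string labels.

ID fields (MemberID, ProviderID, Vendor, PCP) are direct identifiers and are
replaced by irreversible keyed pseudonyms before any release; see
:func:`pseudonymize`.
"""

from __future__ import annotations

import hashlib
import hmac
import os
import re
from dataclasses import dataclass, replace

import pandas as pd

from .exceptions import ConfigurationError, IntegrityError, SchemaError

#: canonical column name -> CSV header, patients table
PATIENT_HEADERS = {
    "member_id": "MemberID",
    "age": "Age",
    "sex": "Sex",
    "dih_y2": "DaysInHospital Y2",
    "dih_y3": "DaysInHospital Y3",
}

#: canonical column name -> CSV header, claims table
CLAIM_HEADERS = {
    "member_id": "MemberID",
    "provider_id": "ProviderID",
    "vendor": "Vendor",
    "pcp": "PCP",
    "year": "Year",
    "specialty": "Specialty",
    "place_of_service": "PlaceOfService",
    "cpt_code": "CPTCode",
    "los": "LOS",
    "dsfc": "DSFC",
    "pay_delay": "PayDelay",
    "diagnosis": "Diagnosis",
}

#: level-1 quasi-identifiers (patients table)
LEVEL1_QIS = ("age", "sex", "dih_y2", "dih_y3")

#: level-2 quasi-identifiers (claims table)
LEVEL2_QIS = ("specialty", "place_of_service", "cpt_code", "los", "dsfc", "diagnosis")

#: ID fields eligible for pseudonymization
ID_FIELDS = ("member_id", "provider_id", "vendor", "pcp")

# columns that hold integers in raw data but may become labels after
# generalization; parsed as integers only when every value looks like one
_NUMERICISH = {"age", "dih_y2", "dih_y3", "los", "dsfc", "pay_delay"}

_INT_RE = re.compile(r"^-?\d+$")


@dataclass
class Dataset:
    """Two linked tables plus the sampling fraction of the release.

    ``sampling_fraction`` is the ratio of released patients to the member
    population the release was drawn from (the α used throughout the risk
    calculus); 1.0 means a census.
    """

    patients: pd.DataFrame
    claims: pd.DataFrame
    sampling_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_claims(self) -> int:
        return len(self.claims)

    def claims_of(self, member_id) -> pd.DataFrame:
        return self.claims[self.claims["member_id"] == member_id]

    def copy(self) -> "Dataset":
        return replace(
            self, patients=self.patients.copy(), claims=self.claims.copy()
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for col in PATIENT_HEADERS:
            if col not in self.patients.columns:
                raise SchemaError(f"patients table missing column {col!r}")
        for col in CLAIM_HEADERS:
            if col not in self.claims.columns:
                raise SchemaError(f"claims table missing column {col!r}")
        if not (0 < self.sampling_fraction <= 1):
            raise ConfigurationError(
                f"sampling fraction must be in (0, 1], got {self.sampling_fraction}"
            )
        if self.patients["member_id"].duplicated().any():
            dupes = self.patients.loc[
                self.patients["member_id"].duplicated(), "member_id"
            ].tolist()
            raise IntegrityError(f"duplicate member_id in patients table: {dupes}")
        known = set(self.patients["member_id"])
        orphans = set(self.claims["member_id"]) - known
        if orphans:
            raise IntegrityError(
                "claims reference unknown member_id values: "
                + ", ".join(map(str, sorted(orphans)[:10]))
            )
        for col in ("dih_y2", "dih_y3"):
            vals = pd.to_numeric(self.patients[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise IntegrityError(f"negative values in {col}")


def _normalize_headers(df: pd.DataFrame, headers: dict, table: str) -> pd.DataFrame:
    """Map CSV headers to canonical names, case- and whitespace-insensitively."""
    lookup = {h.lower().replace(" ", ""): c for c, h in headers.items()}
    rename = {}
    for col in df.columns:
        key = str(col).lower().replace(" ", "").replace("_", "")
        if key in lookup:
            rename[col] = lookup[key]
        else:
            # also accept canonical snake_case headers
            key2 = str(col).lower()
            if key2 in headers:
                rename[col] = key2
    df = df.rename(columns=rename)
    missing = [c for c in headers if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table} table missing required column(s): "
            + ", ".join(headers[c] for c in missing)
        )
    return df[list(headers)]


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    """Parse numeric-capable columns to int64 when every value is an integer
    literal; otherwise leave them as strings (generalized labels)."""
    for col in df.columns:
        if col not in _NUMERICISH:
            continue
        s = df[col]
        nonnull = s.dropna().astype(str)
        if len(nonnull) and nonnull.map(lambda v: bool(_INT_RE.match(v))).all():
            df[col] = pd.to_numeric(s).astype("Int64")
    return df


def read_dataset(patients_path, claims_path, sampling_fraction: float = 1.0) -> Dataset:
    """Read the two linked CSV tables into a validated :class:`Dataset`.

    Headers are matched case-insensitively and column order is free.  Empty
    cells in the ID columns are read as missing (already suppressed).
    """
    patients = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    claims = pd.read_csv(claims_path, dtype=str, keep_default_na=False)
    patients = _normalize_headers(patients, PATIENT_HEADERS, "patients")
    claims = _normalize_headers(claims, CLAIM_HEADERS, "claims")
    for df in (patients, claims):
        for col in df.columns:
            df[col] = df[col].replace("", pd.NA)
    patients = _coerce_types(patients)
    claims = _coerce_types(claims)
    return Dataset(patients, claims, sampling_fraction)


def write_dataset(ds: Dataset, out_dir) -> tuple[str, str]:
    """Write ``patients.csv`` and ``claims.csv`` in the release layout.

    Missing values (suppressed IDs) are written as empty fields; the
    round trip ``read_dataset(*write_dataset(ds))`` reproduces ``ds``
    field-for-field.
    """
    os.makedirs(out_dir, exist_ok=True)
    p_path = os.path.join(out_dir, "patients.csv")
    c_path = os.path.join(out_dir, "claims.csv")
    ds.patients.rename(columns=PATIENT_HEADERS).to_csv(p_path, index=False, na_rep="")
    ds.claims.rename(columns=CLAIM_HEADERS).to_csv(c_path, index=False, na_rep="")
    return p_path, c_path


def _pseudonym(secret: bytes, domain: str, value: str, width: int = 16) -> str:
    token = hmac.new(secret, f"{domain}:{value}".encode(), hashlib.sha256)
    return token.hexdigest()[:width]


def pseudonymize(ds: Dataset, fields=ID_FIELDS, secret: bytes = b"") -> Dataset:
    """Replace ID fields by irreversible keyed pseudonyms.

    The mapping is an HMAC-SHA256 of the original value under ``secret``,
    truncated to a 16-hex-digit token: deterministic for a fixed secret,
    injective in practice, and not invertible without the secret.  member_id
    uses one keyed domain shared by both tables so the linkage survives.

    Raises
    ------
    ConfigurationError
        If ``secret`` is empty (an unkeyed hash would be dictionary-attackable)
        or a field name is not an ID field.
    """
    if not secret:
        raise ConfigurationError("pseudonymization requires a non-empty secret")
    bad = [f for f in fields if f not in ID_FIELDS]
    if bad:
        raise ConfigurationError(f"not pseudonymizable ID fields: {bad}")
    out = ds.copy()
    for f in fields:
        tables = [out.patients, out.claims] if f == "member_id" else [out.claims]
        for df in tables:
            if f in df.columns:
                df[f] = df[f].map(
                    lambda v: v if pd.isna(v) else _pseudonym(secret, f, str(v))
                )
    out.validate()
    return out
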