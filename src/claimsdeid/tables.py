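"""Loaders for the configurable code tables.

Grouping tables (Specialty, PlaceOfService, CPT, primary condition groups),
Charlson weights and the high-risk code list are deployment-specific; the
CSVs shipped under ``claimsdeid/data`` are small *synthetic demonstration
tables* that cover the vocabulary of the synthetic generator.  Real releases
supply their own tables through the same two-column CSV layout.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

from .exceptions import ConfigurationError

_GROUPING_FILES = {
    "specialty": "specialty_groups_demo.csv",
    "place_of_service": "place_of_service_groups_demo.csv",
    "cpt_code": "cpt_groups_demo.csv",
    "diagnosis": "pcg_groups_demo.csv",
}


def _data_path(name: str):
    return resources.files("claimsdeid").joinpath("data", name)


def load_grouping_table(path) -> dict[str, str]:
    """Read a two-column (original_code, group_label) CSV into a dict."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ConfigurationError(f"grouping table {path} needs two columns")
    code, label = df.columns[:2]
    return dict(zip(df[code].str.strip(), df[label].str.strip()))


@functools.lru_cache(maxsize=1)
def default_grouping_tables() -> dict[str, dict[str, str]]:
    return {
        qi: load_grouping_table(_data_path(fname))
        for qi, fname in _GROUPING_FILES.items()
    }


@functools.lru_cache(maxsize=1)
def default_charlson_weights() -> dict[str, int]:
    """ICD-9 prefix -> Charlson condition weight (demonstration table)."""
    df = pd.read_csv(_data_path("charlson_weights_demo.csv"), dtype=str)
    return {
        p.strip(): int(w) for p, w in zip(df["icd9_prefix"], df["weight"])
    }


def charlson_score(codes, weights: dict[str, int] | None = None) -> int:
    """Sum Charlson weights over the distinct conditions in ``codes``.

    Each weight-table prefix counts at most once per patient-year however
    many claims carry a matching code.
    """
    if weights is None:
        weights = default_charlson_weights()
    hit = set()
    for code in codes:
        stripped = str(code).replace(".", "")
        for n in range(len(stripped), 0, -1):
            if stripped[:n] in weights:
                hit.add(stripped[:n])
                break
    return sum(weights[p] for p in hit)


def charlson_category(score: int) -> str:
    """Categorize a Charlson comorbidity score as 0 / 1-2 / 3-4 / 5+."""
    if score <= 0:
        return "0"
    if score <= 2:
        return "1-2"
    if score <= 4:
        return "3-4"
    return "5+"
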