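"""Run configuration: one YAML/JSON-agnostic key-value file drives the CLI.

Only keys that are present override the defaults; unknown keys raise, so a
typo in a threshold never silently reverts to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import yaml

from .exceptions import ConfigurationError
from .risk_metrics import RiskParams


@dataclass
class DeidConfig:
    """Everything a de-identification run needs besides the data."""

    alpha: float = 0.2
    theta: float = 0.05
    f_min: int = 20
    maxsup: float = 0.008
    safe_harbor_u: float = 0.0004
    p_m: int = 5
    topcode_percentile: float = 0.99
    truncate_percentile: float = 0.95
    suppression_min_count: int = 20
    estimator: str = "large_sample"
    iterations: int = 200
    patients_per_iteration: int | None = 2000
    seed: int = 0
    secret: str = ""  # pseudonymization key; must be set for a real release
    high_risk_codes: str | None = None  # CSV path; None = bundled demo list
    grouping_tables: dict | None = None  # qi -> CSV path overrides

    def risk_params(self) -> RiskParams:
        return RiskParams(
            theta=self.theta,
            f_min=self.f_min,
            alpha=self.alpha,
            maxsup=self.maxsup,
            safe_harbor_u=self.safe_harbor_u,
        )

    @classmethod
    def from_yaml(cls, path) -> "DeidConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return replace(cls(), **data)
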