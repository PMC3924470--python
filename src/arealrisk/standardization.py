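"""Indirect standardization: expected counts, standardized ratios, rates.

Expected counts are computed by applying the study-wide overall admission
rate to each area's population, so the expected total always equals the
observed total.  The standardized ratio SR_i = O_i / E_i is the raw
relative-risk surface every later stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arealrisk.errors import DegenerateInputError, DomainError

__all__ = [
    "CountTable",
    "admission_rate",
    "compute_expected",
    "compute_sr",
    "sr_table",
]


@dataclass
class CountTable:
    """Per-area observed counts, populations, expected counts, covariates."""

    area_ids: list[str]
    observed: np.ndarray
    population: np.ndarray
    expected: np.ndarray | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.area_ids = [str(a) for a in self.area_ids]
        self.observed = np.asarray(self.observed, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        n = len(self.area_ids)
        if self.observed.shape != (n,) or self.population.shape != (n,):
            raise ValueError("observed/population length mismatch with area_ids")
        if np.any(self.observed < 0):
            raise ValueError("observed counts must be non-negative")
        if np.any(self.population < 0):
            raise ValueError("populations must be non-negative")
        if self.expected is not None:
            self.expected = np.asarray(self.expected, dtype=float)
        self.covariates = {
            k: np.asarray(v, dtype=float) for k, v in self.covariates.items()
        }

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        skip = {"area_id", "observed", "population", "expected", "x", "y"}
        covs = {
            c: df[c].to_numpy(float)
            for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        }
        return cls(
            area_ids=df["area_id"].astype(str).tolist(),
            observed=df["observed"].to_numpy(float),
            population=df["population"].to_numpy(float),
            expected=df["expected"].to_numpy(float) if "expected" in df else None,
            covariates=covs,
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict = {
            "area_id": self.area_ids,
            "population": self.population,
            "observed": self.observed,
        }
        if self.expected is not None:
            data["expected"] = self.expected
        for k, v in self.covariates.items():
            data[k] = v
        return pd.DataFrame(data)


def compute_expected(table: CountTable) -> CountTable:
    """Fill in E_i = n_i * (sum O / sum n); conserves the observed total."""
    total_pop = table.population.sum()
    if total_pop <= 0:
        raise DegenerateInputError("total population is zero")
    overall_rate = table.observed.sum() / total_pop
    expected = table.population * overall_rate
    return CountTable(
        area_ids=list(table.area_ids),
        observed=table.observed.copy(),
        population=table.population.copy(),
        expected=expected,
        covariates={k: v.copy() for k, v in table.covariates.items()},
    )


def compute_sr(observed: float, expected: float) -> float:
    """Standardized ratio O/E for one area; expected must be positive."""
    if expected <= 0:
        raise DomainError(f"expected count must be positive, got {expected}")
    if observed < 0:
        raise DomainError("observed count must be non-negative")
    return observed / expected


def admission_rate(observed: float, population: float, per: float = 1000.0) -> float:
    """Cases per `per` residents."""
    if population <= 0:
        raise DomainError(f"population must be positive, got {population}")
    return observed / population * per


def sr_table(table: CountTable, per: float = 1000.0) -> pd.DataFrame:
    """Area table with expected, sr, and admission_rate columns added.

    Zero-population areas get E = 0 and missing SR/rate (excluded from
    downstream statistics rather than producing division errors).
    """
    if table.expected is None:
        table = compute_expected(table)
    expected = table.expected
    sr = np.where(expected > 0, table.observed / np.where(expected > 0, expected, 1.0), np.nan)
    rate = np.where(
        table.population > 0,
        table.observed / np.where(table.population > 0, table.population, 1.0) * per,
        np.nan,
    )
    df = table.to_frame()
    df["expected"] = expected
    df["sr"] = sr
    df["admission_rate"] = rate
    return df
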