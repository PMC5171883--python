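"""Summary-statistic plumbing for two-line comparisons.

Selection experiments are typically reported as per-line group summaries
(mean ± SEM with a group size) rather than raw phenotypes.  This module
converts those summaries into the quantities the drift test consumes: group
standard deviations, df-weighted pooled SDs, the signed standardized
divergence D_y between a selected (high-active) line and its control, drug
"effect" traits built by subtracting a vehicle-group mean, and the unpaired
t-test on summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidGroupSizeError,
)

__all__ = [
    "GroupSummary",
    "TraitRecord",
    "sd_from_sem",
    "pooled_sd",
    "standardized_divergence",
    "amph_effect",
    "unpaired_t",
    "summarize",
    "read_trait_table",
    "write_trait_table",
    "TRAIT_TABLE_COLUMNS",
]

TRAIT_TABLE_COLUMNS = [
    "trait_name",
    "experiment",
    "ha_mean",
    "ha_sem",
    "ha_n",
    "c_mean",
    "c_sem",
    "c_n",
    "h2",
    "n_families",
]


@dataclass(frozen=True)
class GroupSummary:
    """One line's printed summary for a trait: mean ± SEM over n individuals."""

    label: str = field(compare=False)
    mean: float
    sem: float
    n_individuals: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError(f"SEM must be non-negative, got {self.sem}")
        if self.n_individuals < 1:
            raise InvalidGroupSizeError(
                f"group size must be positive, got {self.n_individuals}"
            )

    @property
    def sd(self) -> float:
        """Group standard deviation recovered from the SEM."""
        return sd_from_sem(self.sem, self.n_individuals)


@dataclass(frozen=True)
class TraitRecord:
    """Paired high-active/control summaries for one trait.

    ``h2`` is a literature heritability (never estimated here) and
    ``n_families`` the number of families represented in the measured
    cohort; both may be absent, in which case the trait is reported but not
    drift-testable.
    """

    trait_name: str
    high_active: GroupSummary
    control: GroupSummary
    experiment: str = ""
    h2: Optional[float] = None
    n_families: Optional[int] = None
    direction_note: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.h2 is not None and not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {self.h2}")
        if self.n_families is not None and self.n_families < 2:
            raise ValueError(
                f"n_families must be >= 2 when present, got {self.n_families}"
            )

    @property
    def testable(self) -> bool:
        return self.h2 is not None and self.n_families is not None


def sd_from_sem(sem: float, n: int) -> float:
    """Recover a group SD from its standard error of the mean.

    ``sd = sem * sqrt(n)``.  Requires ``n >= 2`` because a single
    observation carries no dispersion information.
    """
    if n < 2:
        raise InvalidGroupSizeError(f"need n >= 2 to convert SEM to SD, got n={n}")
    if sem < 0:
        raise ValueError(f"SEM must be non-negative, got {sem}")
    return sem * math.sqrt(n)


def pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    """Degrees-of-freedom-weighted pooled standard deviation of two groups.

    The Cohen's-d-style pooling
    ``sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))``.
    """
    if g1.n_individuals + g2.n_individuals < 4:
        raise InsufficientDataError(
            "pooled SD needs at least 4 individuals across both groups"
        )
    s1 = g1.sd
    s2 = g2.sd
    n1, n2 = g1.n_individuals, g2.n_individuals
    return math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))


def standardized_divergence(record: TraitRecord) -> float:
    """Signed between-line divergence D_y in pooled phenotypic SD units.

    ``D_y = (mean_selected - mean_control) / pooled_sd``; negative when the
    selected line scores below the control.
    """
    sp = pooled_sd(record.high_active, record.control)
    if sp == 0:
        raise DegenerateVarianceError(
            f"pooled SD is zero for trait {record.trait_name!r}"
        )
    return (record.high_active.mean - record.control.mean) / sp


def amph_effect(
    individual_drug_values: Sequence[float], saline_group_mean: float
) -> list[float]:
    """Per-individual drug effect: response minus the vehicle-group mean.

    The resulting values can be summarised (mean, SEM) into a derived
    "drug on trait" group summary.
    """
    values = list(individual_drug_values)
    if not values:
        raise InsufficientDataError("need at least one drug-group value")
    return [v - saline_group_mean for v in values]


def summarize(label: str, values: Sequence[float]) -> GroupSummary:
    """Build a GroupSummary (mean, SEM) from raw individual values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise InsufficientDataError("cannot summarise an empty sample")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, mean=float(arr.mean()), sem=sem,
                        n_individuals=int(arr.size))


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def unpaired_t(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled-variance two-sided unpaired t-test from group summaries."""
    if g1.n_individuals < 2 or g2.n_individuals < 2:
        raise InvalidGroupSizeError("both groups need n >= 2 for a t-test")
    if g1.sd == 0 and g2.sd == 0 and g1.mean != g2.mean:
        raise DegenerateVarianceError("zero variance in both groups")
    res = stats.ttest_ind_from_stats(
        mean1=g1.mean, std1=g1.sd, nobs1=g1.n_individuals,
        mean2=g2.mean, std2=g2.sd, nobs2=g2.n_individuals,
        equal_var=True,
    )
    df = g1.n_individuals + g2.n_individuals - 2
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def records_from_frame(frame: pd.DataFrame) -> list[TraitRecord]:
    """Convert a trait-summary DataFrame into TraitRecords."""
    records = []
    for _, row in frame.iterrows():
        h2 = _opt_float(row.get("h2"))
        nf = _opt_float(row.get("n_families"))
        records.append(
            TraitRecord(
                trait_name=str(row["trait_name"]),
                experiment=str(row.get("experiment", "")),
                high_active=GroupSummary(
                    "high_active", float(row["ha_mean"]), float(row["ha_sem"]),
                    int(row["ha_n"]),
                ),
                control=GroupSummary(
                    "control", float(row["c_mean"]), float(row["c_sem"]),
                    int(row["c_n"]),
                ),
                h2=h2,
                n_families=int(nf) if nf is not None else None,
            )
        )
    return records


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "trait_name": r.trait_name,
                "experiment": r.experiment,
                "ha_mean": r.high_active.mean,
                "ha_sem": r.high_active.sem,
                "ha_n": r.high_active.n_individuals,
                "c_mean": r.control.mean,
                "c_sem": r.control.sem,
                "c_n": r.control.n_individuals,
                "h2": r.h2,
                "n_families": r.n_families,
            }
        )
    return pd.DataFrame(rows, columns=TRAIT_TABLE_COLUMNS)


def read_trait_table(path) -> list[TraitRecord]:
    """Read the trait-summary CSV dialect (one row per trait)."""
    frame = pd.read_csv(
        path,
        dtype={"trait_name": str, "experiment": str},
        float_precision="round_trip",
    )
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    return records_from_frame(frame)


def write_trait_table(records: Iterable[TraitRecord], path) -> None:
    """Write TraitRecords in the same CSV dialect the reader accepts."""
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
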