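"""The genetic-drift test for divergence between two selection lines.

Two reproductively isolated lines drift apart even without selection.  For a
neutral additive trait with heritability h2, a colony inbreeding level F and
n families represented in the measured cohorts, the between-line standardized
divergence D_y expected under drift alone is modelled as

    Var(D_y) = 2 * (2 * F * h2 + 2 / n)

i.e. a between-line drift variance of ``2 F h2`` plus a family-sampling
variance of ``2/n`` per line, doubled for a two-line difference.  The 95%
band is ``z_{0.975} * sqrt(Var)``.  The closed form is reverse-engineered
from the published per-trait confidence intervals (which it reproduces to
the printed precision) rather than taken from a derivation in print — treat
it as an empirical reconstruction of the Henderson-style drift criterion.

Traits whose |D_y| exceeds the band are flagged as likely correlated
responses to selection rather than drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import NotTestableError
from .summaries import (
    TraitRecord,
    standardized_divergence,
    read_trait_table,
    records_from_frame,
    unpaired_t,
)

__all__ = [
    "drift_ci",
    "DriftTestResult",
    "evaluate_trait",
    "drift_table",
    "LineDivergenceDriftTest",
    "DriftTestResults",
]


def drift_ci(h2: float, F: float, n_families: int, alpha: float = 0.05) -> float:
    """Half-width of the (1 - alpha) drift interval for D_y.

    Parameters
    ----------
    h2 : float
        Narrow-sense heritability of the trait, in [0, 1].
    F : float
        Pedigree inbreeding coefficient of the colony, in [0, 1).
    n_families : int
        Number of families represented in the measured cohorts (>= 2).
    alpha : float
        Significance level; 0.05 gives the conventional 95% band.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F must lie in [0, 1), got {F}")
    if n_families < 2:
        raise ValueError(f"n_families must be >= 2, got {n_families}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(z * np.sqrt(2.0 * (2.0 * F * h2 + 2.0 / n_families)))


@dataclass(frozen=True)
class DriftTestResult:
    """Outcome of the drift test for one trait.

    ``exceeds_drift`` compares |d_y| with the band at full precision; any
    rounding is display-only.  For traits without h2 or a family count the
    record carries ``testable=False`` and None statistics (the dash rows of
    a published drift table).
    """

    trait_name: str
    testable: bool
    d_y: Optional[float] = None
    ci95: Optional[float] = None
    exceeds_drift: Optional[bool] = None
    F: Optional[float] = None
    h2: Optional[float] = None
    n_families: Optional[int] = None
    alpha: float = 0.05


def evaluate_trait(
    record: TraitRecord, F: float, alpha: float = 0.05
) -> DriftTestResult:
    """Run the drift test on one trait record.

    Raises
    ------
    NotTestableError
        If the record lacks h2 or n_families.  ``drift_table`` (and the
        model class) instead report such rows with a not-testable status.
    """
    if not record.testable:
        raise NotTestableError(
            f"trait {record.trait_name!r} has no h2/n_families; not drift-testable"
        )
    d_y = standardized_divergence(record)
    ci = drift_ci(record.h2, F, record.n_families, alpha=alpha)
    return DriftTestResult(
        trait_name=record.trait_name,
        testable=True,
        d_y=d_y,
        ci95=ci,
        exceeds_drift=bool(abs(d_y) > ci),
        F=F,
        h2=record.h2,
        n_families=record.n_families,
        alpha=alpha,
    )


class LineDivergenceDriftTest:
    """Drift-test model over a table of two-line trait summaries.

    Parameters
    ----------
    records : sequence of TraitRecord
        One record per trait (selected-line and control-line summaries plus
        literature h2 and family count where available).
    inbreeding : float
        Colony-level pedigree inbreeding coefficient F supplied to every
        trait's test (e.g. computed by :mod:`linedrift.pedigree` or taken
        from an animal-model fit of the real colony pedigree).
    alpha : float
        Significance level of the drift band.

    Examples
    --------
    >>> from linedrift.datasets import load_highactive_example
    >>> model = LineDivergenceDriftTest(load_highactive_example(), 0.06217)
    >>> res = model.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        records: Sequence[TraitRecord],
        inbreeding: float,
        alpha: float = 0.05,
    ) -> None:
        if not 0.0 <= inbreeding < 1.0:
            raise ValueError(f"inbreeding F must lie in [0, 1), got {inbreeding}")
        self.records = list(records)
        self.inbreeding = float(inbreeding)
        self.alpha = float(alpha)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, inbreeding: float, alpha: float = 0.05
    ) -> "LineDivergenceDriftTest":
        return cls(records_from_frame(frame), inbreeding, alpha=alpha)

    @classmethod
    def from_csv(
        cls, path, inbreeding: float, alpha: float = 0.05
    ) -> "LineDivergenceDriftTest":
        return cls(read_trait_table(path), inbreeding, alpha=alpha)

    def fit(self) -> "DriftTestResults":
        results = []
        for rec in self.records:
            if rec.testable:
                results.append(evaluate_trait(rec, self.inbreeding, self.alpha))
            else:
                results.append(
                    DriftTestResult(trait_name=rec.trait_name, testable=False,
                                    alpha=self.alpha)
                )
        return DriftTestResults(self, results)


class DriftTestResults:
    """Fitted drift-test results: per-trait D_y, band, and exceed flags."""

    def __init__(
        self, model: LineDivergenceDriftTest, results: list[DriftTestResult]
    ) -> None:
        self.model = model
        self.results = results

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, key) -> DriftTestResult:
        if isinstance(key, str):
            for r in self.results:
                if r.trait_name == key:
                    return r
            raise KeyError(key)
        return self.results[key]

    @property
    def exceeding(self) -> list[DriftTestResult]:
        """Traits flagged as likely correlated responses to selection."""
        return [r for r in self.results if r.testable and r.exceeds_drift]

    def to_frame(self) -> pd.DataFrame:
        """Full-precision report table, one row per trait.

        Columns mirror a published drift table: line summaries, the t-test
        p-value, h2, F, n, the 95% band, D_y and the exceeds flag.
        Not-testable rows carry NaN statistics.
        """
        rows = []
        for rec, res in zip(self.model.records, self.results):
            t = unpaired_t(rec.high_active, rec.control)
            rows.append(
                {
                    "trait_name": rec.trait_name,
                    "experiment": rec.experiment,
                    "ha_mean": rec.high_active.mean,
                    "ha_sem": rec.high_active.sem,
                    "c_mean": rec.control.mean,
                    "c_sem": rec.control.sem,
                    "p_value": t.pvalue,
                    "h2": rec.h2 if res.testable else np.nan,
                    "F": res.F if res.testable else np.nan,
                    "n_families": rec.n_families if res.testable else np.nan,
                    "ci95": res.ci95 if res.testable else np.nan,
                    "d_y": res.d_y if res.testable else np.nan,
                    "exceeds_drift": res.exceeds_drift if res.testable else None,
                }
            )
        columns = [
            "trait_name", "experiment", "ha_mean", "ha_sem", "c_mean", "c_sem",
            "p_value", "h2", "F", "n_families", "ci95", "d_y", "exceeds_drift",
        ]
        return pd.DataFrame(rows, columns=columns)

    def summary(self) -> str:
        """Human-readable report; CI and D_y rounded to 2 decimals for
        display (the exceed flag always uses full precision)."""
        frame = self.to_frame()
        lines = [
            "Line-divergence drift test "
            f"(F = {self.model.inbreeding:.5f}, alpha = {self.model.alpha:g})",
            "",
        ]
        header = (
            f"{'trait':<24}{'HA mean':>10}{'C mean':>10}{'h2':>6}{'n':>5}"
            f"{'CI':>7}{'D_y':>8}  flag"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for _, row in frame.iterrows():
            if pd.isna(row["ci95"]):
                lines.append(
                    f"{row['trait_name']:<24}{row['ha_mean']:>10.2f}"
                    f"{row['c_mean']:>10.2f}{'—':>6}{'—':>5}{'—':>7}{'—':>8}  —"
                )
            else:
                flag = "*" if row["exceeds_drift"] else ""
                lines.append(
                    f"{row['trait_name']:<24}{row['ha_mean']:>10.2f}"
                    f"{row['c_mean']:>10.2f}{row['h2']:>6.2f}"
                    f"{int(row['n_families']):>5d}{row['ci95']:>7.2f}"
                    f"{row['d_y']:>8.2f}  {flag}"
                )
        n_flag = len(self.exceeding)
        lines.append("")
        lines.append(
            f"* |D_y| exceeds the drift band; {n_flag} trait(s) flagged as "
            "likely correlated responses to selection."
        )
        return "\n".join(lines)

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_markdown(self) -> str:
        """Markdown report with **bold** D_y where the band is exceeded."""
        frame = self.to_frame()
        out = [
            "| trait | HA mean (±SEM) | C mean (±SEM) | h2 | n | 95% CI | D_y |",
            "|---|---|---|---|---|---|---|",
        ]
        for _, row in frame.iterrows():
            ha = f"{row['ha_mean']:.2f} (±{row['ha_sem']:.2f})"
            c = f"{row['c_mean']:.2f} (±{row['c_sem']:.2f})"
            if pd.isna(row["ci95"]):
                out.append(f"| {row['trait_name']} | {ha} | {c} | — | — | — | — |")
            else:
                dy = f"{row['d_y']:.2f}"
                if row["exceeds_drift"]:
                    dy = f"**{dy}**"
                out.append(
                    f"| {row['trait_name']} | {ha} | {c} | {row['h2']:g} "
                    f"| {int(row['n_families'])} | {row['ci95']:.2f} | {dy} |"
                )
        return "\n".join(out)


def drift_table(
    records: Iterable[TraitRecord], F: float, alpha: float = 0.05
) -> pd.DataFrame:
    """One-call report table: fit the drift test over ``records``.

    Thin functional wrapper over :class:`LineDivergenceDriftTest`.
    """
    return LineDivergenceDriftTest(list(records), F, alpha=alpha).fit().to_frame()
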