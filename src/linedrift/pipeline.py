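"""End-to-end pipeline runner, format validation, and run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .drift import LineDivergenceDriftTest
from .errors import ConfigError
from .pedigree import inbreeding_coefficients, read_pedigree
from .summaries import TRAIT_TABLE_COLUMNS

__all__ = ["RunManifest", "run_pipeline", "validate_formats", "ValidationReport"]


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    config_hash: str
    seed: Optional[int]
    input_paths: list[str]
    output_paths: list[str]
    timestamp: str
    package_version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config_path, out_dir, quiet: bool = False) -> RunManifest:
    """Run the summaries -> drift -> report pipeline from a YAML config.

    Config keys: ``traits`` (trait-summary CSV path), and either
    ``inbreeding`` (a number) or ``pedigree`` (+ ``generation``/``line``)
    from which the colony F is computed; optional ``alpha``.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text()) or {}
    missing = []
    if "traits" not in config:
        missing.append("traits")
    if "inbreeding" not in config and "pedigree" not in config:
        missing.append("inbreeding (or pedigree)")
    if missing:
        raise ConfigError(f"pipeline config missing fields: {missing}")

    base = config_path.parent
    traits_path = (base / config["traits"]).resolve()
    inputs = [str(traits_path)]
    if "inbreeding" in config:
        f_value = float(config["inbreeding"])
    else:
        ped_path = (base / config["pedigree"]).resolve()
        inputs.append(str(ped_path))
        ped = read_pedigree(ped_path)
        coeffs = inbreeding_coefficients(ped)
        generation = config.get("generation", int(ped.frame["generation"].max()))
        lines = config.get("line")
        mask = ped.frame["generation"] == generation
        if lines is not None:
            mask &= ped.frame["line"] == lines
        members = ped.frame.loc[mask, "id"]
        f_value = float(pd.Series([coeffs[m] for m in members]).mean())

    alpha = float(config.get("alpha", 0.05))
    model = LineDivergenceDriftTest.from_csv(traits_path, f_value, alpha=alpha)
    results = model.fit()
    if not quiet:
        n_skip = sum(1 for r in results.results if not r.testable)
        if n_skip:
            print(
                f"[linedrift] {n_skip} trait(s) lack h2/family count; "
                "reported as not testable",
                file=sys.stderr,
            )
        if not model.records:
            print("[linedrift] warning: empty trait table", file=sys.stderr)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "drift_report.tsv"
    md_path = out_dir / "drift_report.md"
    results.save_tsv(tsv_path)
    md_path.write_text(results.to_markdown() + "\n")

    manifest = RunManifest(
        command="run",
        config_hash=_config_hash(config),
        seed=config.get("seed"),
        input_paths=inputs,
        output_paths=[str(tsv_path), str(md_path)],
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


@dataclass
class ValidationReport:
    path: str
    kind: str
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_formats(path, kind: str) -> ValidationReport:
    """Schema-check one input file; errors carry 1-based data row numbers."""
    path = Path(path)
    report = ValidationReport(str(path), kind)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        report.errors.append(f"unreadable file: {exc}")
        return report
    checkers = {
        "traits": _check_traits,
        "pedigree": _check_pedigree,
        "eventlog": _check_eventlog,
        "arms": _check_arms,
        "rotarod": _check_rotarod,
    }
    if kind not in checkers:
        raise ValueError(f"unknown format kind {kind!r}")
    checkers[kind](frame, report.errors)
    return report


def _require(frame, columns, errors) -> bool:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return False
    return True


def _numeric(value: str) -> bool:
    try:
        float(value)
        return True
    except ValueError:
        return False


def _check_traits(frame, errors):
    if not _require(frame, TRAIT_TABLE_COLUMNS, errors):
        return
    for i, row in frame.iterrows():
        for col in ("ha_mean", "ha_sem", "ha_n", "c_mean", "c_sem", "c_n"):
            if not _numeric(row[col]):
                errors.append(f"row {i + 1}: non-numeric {col} {row[col]!r}")
        for col in ("h2", "n_families"):
            if row[col].strip() and not _numeric(row[col]):
                errors.append(f"row {i + 1}: non-numeric {col} {row[col]!r}")


def _check_pedigree(frame, errors):
    from .pedigree import PEDIGREE_COLUMNS, Pedigree
    from .errors import PedigreeError

    if not _require(frame, PEDIGREE_COLUMNS, errors):
        return
    ids = set(frame["id"])
    for i, row in frame.iterrows():
        for col in ("sire", "dam"):
            parent = row[col].strip()
            if parent not in ("", "0") and parent not in ids:
                errors.append(f"row {i + 1}: dangling {col} id {parent!r}")
        if not _numeric(row["generation"]):
            errors.append(f"row {i + 1}: non-numeric generation")
    if not errors:
        try:
            f2 = frame.copy()
            f2["generation"] = f2["generation"].astype(int)
            Pedigree(f2)
        except PedigreeError as exc:
            errors.append(str(exc))


def _check_eventlog(frame, errors):
    if not _require(frame, ["t_seconds", "kind", "detail"], errors):
        return
    from .behavior import EVENT_KINDS

    last_t = None
    for i, row in frame.iterrows():
        if not _numeric(row["t_seconds"]):
            errors.append(f"row {i + 1}: non-numeric t_seconds")
            continue
        t = float(row["t_seconds"])
        if last_t is not None and t < last_t:
            errors.append(f"row {i + 1}: decreasing timestamp {t}")
            break
        last_t = t
        if row["kind"] not in EVENT_KINDS:
            errors.append(f"row {i + 1}: unknown event kind {row['kind']!r}")


def _check_arms(frame, errors):
    if not _require(frame, ["arm"], errors):
        return
    for i, row in frame.iterrows():
        if row["arm"] not in ("A", "B", "C"):
            errors.append(f"row {i + 1}: invalid arm label {row['arm']!r}")


def _check_rotarod(frame, errors):
    if not _require(frame, ["animal", "day", "trial", "latency", "is_extra"], errors):
        return
    for i, row in frame.iterrows():
        for col in ("day", "trial", "latency"):
            if not _numeric(row[col]):
                errors.append(f"row {i + 1}: non-numeric {col}")
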