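"""End-to-end pipeline: parse -> spectra -> filter -> compare -> summarize.

Reads one or more per-case tables, extracts translocations, builds spectra
for the requested stratification (entity, group, or entity-by-sex), applies
the inclusion filter, computes the pairwise R2 matrix with characteristic-
translocation exclusion, runs the cutoff sensitivity analysis, and writes
all tables plus a manifest that suffices to re-run the analysis
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .compare import (
    ComparisonConfig,
    ComparisonResult,
    StrengthSummary,
    cutoff_sensitivity,
    pairwise_matrix,
    results_to_long_frame,
    results_to_triangle,
    strength_summary,
)
from .iscn import CaseRecord, annotate_table, parse_cases, read_case_table
from .spectrum import (
    EntitySpectrum,
    apply_inclusion_filter,
    build_spectrum,
    cases_vs_translocations_r2,
    enumerate_types,
    frequency_categories,
    spectra_to_matrix,
)

STRATA = ("entity", "group", "sex")


@dataclass(slots=True)
class RunConfig:
    """Configuration for one pipeline run.

    Defaults reproduce the reference analysis settings: inclusion at >= 100
    cases and >= 100 translocations, a 10% characteristic-translocation
    cutoff, and sensitivity cutoffs 10/5/2/1%.
    """

    inputs: list[str]
    outdir: str
    delimiter: str = "\t"
    stratify: str = "entity"  # entity | group | sex
    group_map: dict[str, str] = field(default_factory=dict)
    min_cases: int = 100
    min_translocations: int = 100
    cutoff_pct: float = 10.0
    sensitivity_cutoffs: list[float] = field(default_factory=lambda: [10.0, 5.0, 2.0, 1.0])
    count_nested: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stratify not in STRATA:
            raise ValueError(f"invalid config field 'stratify': must be one of {STRATA}")
        if not self.inputs:
            raise ValueError("invalid config field 'inputs': at least one input required")
        if not 0 < self.cutoff_pct <= 100:
            raise ValueError("invalid config field 'cutoff_pct': must be in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"invalid config field(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass(slots=True)
class RunArtifacts:
    """In-memory results of a pipeline run plus the paths written."""

    config: RunConfig
    cases: list[CaseRecord]
    spectra: list[EntitySpectrum]
    included: list[EntitySpectrum]
    excluded: list[EntitySpectrum]
    results: list[ComparisonResult]
    summary: StrengthSummary
    sensitivity: list[ComparisonResult]
    paths: dict[str, str]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stratum_label(case: CaseRecord, stratify: str, group_map: dict[str, str]) -> str:
    if stratify == "entity":
        return case.entity
    if stratify == "group":
        return group_map.get(case.entity, case.group or case.entity)
    # sex: entity split by sex, unknown sexes dropped from strata
    return f"{case.entity}/{case.sex}" if case.sex in ("F", "M") else ""


def build_strata_spectra(
    cases: Sequence[CaseRecord],
    stratify: str = "entity",
    group_map: Optional[dict[str, str]] = None,
) -> list[EntitySpectrum]:
    """Group cases by stratum label and build one spectrum per stratum,
    ordered by first appearance."""
    group_map = group_map or {}
    buckets: dict[str, list[CaseRecord]] = {}
    for case in cases:
        label = _stratum_label(case, stratify, group_map)
        if label:
            buckets.setdefault(label, []).append(case)
    return [build_spectrum(members, label) for label, members in buckets.items()]


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute the full pipeline and write all run artifacts.

    Raises
    ------
    ValueError
        On unreadable/empty input, invalid config, or when fewer than two
        strata pass the inclusion filter ("nothing to compare").
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    tables = []
    for inp in config.inputs:
        df = read_case_table(inp, delimiter=config.delimiter)
        if df.empty:
            raise ValueError(f"empty input file: {inp}")
        tables.append(df)
    table = pd.concat(tables, ignore_index=True)

    annotated, skip_report = annotate_table(table, count_nested=config.count_nested)
    cases = parse_cases(table, count_nested=config.count_nested)
    _write(annotated, outdir / "cases_annotated.tsv", paths, "cases_annotated")
    _write(skip_report, outdir / "skip_report.tsv", paths, "skip_report")

    spectra = build_strata_spectra(cases, config.stratify, config.group_map)
    _write(spectra_to_matrix(spectra, pct=False), outdir / "spectra_abs.tsv", paths,
           "spectra_abs", index=True)
    _write(
        spectra_to_matrix(spectra, pct=True).round(2), outdir / "spectra_pct.tsv",
        paths, "spectra_pct", index=True,
    )

    included, excluded = apply_inclusion_filter(
        spectra, config.min_cases, config.min_translocations
    )
    if len(included) < 2:
        raise ValueError("nothing to compare: fewer than 2 strata pass inclusion")

    cmp_config = ComparisonConfig(cutoff_pct=config.cutoff_pct)
    results = pairwise_matrix(included, cmp_config)
    summary = strength_summary(results)
    _write(results_to_long_frame(results), outdir / "pairwise_long.tsv", paths,
           "pairwise_long")
    _write(results_to_triangle(results), outdir / "pairwise_triangle.tsv", paths,
           "pairwise_triangle", index=True)

    sensitivity: list[ComparisonResult] = []
    for res in results:
        a = next(s for s in included if s.label == res.label_a)
        b = next(s for s in included if s.label == res.label_b)
        sensitivity.extend(
            cutoff_sensitivity(a, b, config.sensitivity_cutoffs, cmp_config)
        )
    _write(results_to_long_frame(sensitivity), outdir / "sensitivity.tsv", paths,
           "sensitivity")

    manifest = {
        "tool": "karyosig",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {str(p): _sha256(p) for p in config.inputs},
        "n_cases": len(cases),
        "n_strata": len(spectra),
        "n_included": len(included),
        "n_comparisons": len(results),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = str(manifest_path)

    artifacts = RunArtifacts(
        config=config,
        cases=cases,
        spectra=spectra,
        included=included,
        excluded=excluded,
        results=results,
        summary=summary,
        sensitivity=sensitivity,
        paths=paths,
    )
    report_path = outdir / "report.md"
    report_path.write_text(summarize_run(artifacts))
    paths["report"] = str(report_path)
    artifacts.paths = paths
    return artifacts


def _write(
    df: pd.DataFrame, path: Path, paths: dict[str, str], key: str, *, index: bool = False
) -> None:
    df.to_csv(path, sep="\t", index=index)
    paths[key] = str(path)


def summarize_run(artifacts: RunArtifacts) -> str:
    """Human-readable markdown report for one run: per-stratum totals,
    frequency-category table, characteristic translocations above the
    cutoff, strength tallies, and the sensitivity table."""
    cfg = artifacts.config
    lines: list[str] = []
    lines.append("# Translocation signature report\n")
    lines.append(
        f"Inputs: {', '.join(cfg.inputs)} | stratification: {cfg.stratify} | "
        f"inclusion: >={cfg.min_cases} cases and >={cfg.min_translocations} "
        f"translocations | cutoff: >{cfg.cutoff_pct}%\n"
    )

    lines.append("## Strata\n")
    lines.append("| stratum | cases | translocations | included |")
    lines.append("|---|---:|---:|---|")
    included_labels = {s.label for s in artifacts.included}
    for s in artifacts.spectra:
        mark = "yes" if s.label in included_labels else "no"
        lines.append(f"| {s.label} | {s.n_cases} | {s.n_translocations} | {mark} |")
    if len(artifacts.spectra) >= 3:
        try:
            r2 = cases_vs_translocations_r2(artifacts.spectra)
            lines.append(
                f"\nAssociation between cases and translocations across strata: "
                f"R2 = {r2:.3f}\n"
            )
        except ValueError:
            pass

    lines.append("## Frequency categories (of 253 types)\n")
    lines.append("| stratum | 0% | <1% | 1-<=10% | >10% |")
    lines.append("|---|---:|---:|---:|---:|")
    for s in artifacts.spectra:
        if s.n_translocations == 0:
            continue
        cat = frequency_categories(s)
        lines.append(
            f"| {s.label} | {cat.n_zero} | {cat.n_lt1} | {cat.n_1to10} | {cat.n_gt10} |"
        )

    lines.append("\n## Characteristic translocations (> cutoff)\n")
    any_char = False
    for s in artifacts.spectra:
        offenders = [
            (t.label, pct)
            for t, pct in zip(enumerate_types(), s.pct_freq)
            if pct > cfg.cutoff_pct
        ]
        for lab, pct in offenders:
            lines.append(f"- {s.label}: {lab} at {pct:.1f}%")
            any_char = True
    if not any_char:
        lines.append("- none")

    lines.append("\n## Pairwise comparison strength\n")
    summ = artifacts.summary
    lines.append(f"Comparisons: {summ.n_total} ({summ.n_computable} computable)\n")
    for cls, n in summ.by_class.items():
        if n:
            lines.append(f"- {cls}: {n}")
    lines.append(
        f"\nR2 <= 0.3 in {summ.n_le_03} of {summ.n_computable} comparisons "
        f"({summ.pct_le_03}%); R2 < 0.1 in {summ.n_lt_01}.\n"
    )

    if artifacts.sensitivity:
        lines.append("## Cutoff sensitivity\n")
        lines.append("| pair | cutoff % | retained | R2 |")
        lines.append("|---|---:|---:|---:|")
        for res in artifacts.sensitivity:
            r2txt = f"{res.r2:.3f}" if res.r2 is not None else "n.c."
            lines.append(
                f"| {res.label_a} vs {res.label_b} | {res.cutoff_pct:g} "
                f"| {res.n_retained} | {r2txt} |"
            )
    lines.append("")
    return "\n".join(lines)
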