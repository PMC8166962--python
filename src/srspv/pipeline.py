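"""End-to-end orchestration: dataset → signals, latencies, comparisons, outcomes.

One structured config drives a full run.  Input is either a directory of
the four tables or an embedded synthetic-data config; outputs are
delimited text tables plus a run log with the seed and exclusion
accounting, so every number in the rendered report traces to a file.
Re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import spawn_seed
from .casedef import DrugVocabulary, aggregate_by_atc, assemble_analysis_set, flag_cases
from .disproportionality import run_signal_screen
from .outcomes import mosaic_data, outcome_screen, tabulate_outcomes
from .survival import compare_onset_profiles
from .synthetic import SimConfig, generate_dataset
from .tables import SrsDataset, default_paths, read_dataset, write_dataset
from .time_to_onset import DEFAULT_WINDOW_DAYS, tto_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    pt_codes: list[int]
    targets: list[str]
    output_dir: str
    input_paths: Optional[dict[str, str]] = None
    simulate: Optional[SimConfig] = None
    vocabulary_path: Optional[str] = None
    atc_level: Optional[int] = None  # additionally screen/profile at this class level
    compare: Optional[tuple[str, str]] = None
    window_days: int = DEFAULT_WINDOW_DAYS
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulate is None):
            raise ValueError("exactly one of input_paths / simulate must be given")
        if not self.pt_codes:
            raise ValueError("pt_codes must be non-empty")
        if not self.targets:
            raise ValueError("targets must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "simulate" in data and data["simulate"] is not None:
            data["simulate"] = SimConfig.from_dict(data["simulate"])
        if "compare" in data and data["compare"] is not None:
            data["compare"] = tuple(data["compare"])
        return cls(**data)


@dataclass
class ReportBundle:
    """Machine-readable outputs of one run."""

    signal_table: pd.DataFrame
    tto: pd.DataFrame
    outcome_table: pd.DataFrame
    mosaic: pd.DataFrame
    comparison_summary: Optional[str]
    run_log: dict
    output_dir: Path
    failures: list[str] = field(default_factory=list)


def _load_vocabulary(config: RunConfig, dataset: SrsDataset) -> DrugVocabulary:
    if config.vocabulary_path:
        return DrugVocabulary.from_csv(config.vocabulary_path)
    if config.simulate is not None:
        return DrugVocabulary(
            {d.name: (d.name, d.atc_code) for d in config.simulate.drugs}
        )
    # identity vocabulary: product names pass through, ATC unassigned
    return DrugVocabulary({})


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute simulate/load → screen → time-to-onset → comparison → outcomes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: list[str] = []
    run_log: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    # ----- input ---------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = spawn_seed(config.seed, "simulate") if config.seed else sim.seed
        dataset = generate_dataset(sim)
        write_dataset(dataset, default_paths(out / "dataset"))
        provenance = {"config": sim.to_dict(), "seed": sim.seed}
        (out / "dataset" / "provenance.json").write_text(json.dumps(provenance, indent=2))
        run_log["stages"].append({"stage": "simulate", "n_reports": dataset.n_reports})
    else:
        dataset = read_dataset(config.input_paths)
        run_log["stages"].append(
            {"stage": "read", "n_reports": dataset.n_reports,
             "n_rejected": dict(dataset.n_rejected)}
        )

    vocab = _load_vocabulary(config, dataset)
    pt_codes = set(config.pt_codes)
    records = assemble_analysis_set(dataset, vocab, pt_codes)
    if config.atc_level:
        records = pd.concat(
            [records, aggregate_by_atc(records, config.atc_level)], ignore_index=True
        )
    total_reports = dataset.n_reports
    total_cases = int(flag_cases(dataset, pt_codes).sum())
    run_log["stages"].append(
        {"stage": "assemble", "n_records": len(records),
         "total_reports": total_reports, "total_cases": total_cases}
    )

    # ----- disproportionality screen -------------------------------------
    signal_table = run_signal_screen(
        records, config.targets, total_reports, total_cases, config.ci_level
    )
    signal_table.to_csv(out / "signals.csv", index=False)
    run_log["stages"].append(
        {"stage": "screen", "n_targets": len(config.targets),
         "n_signals": int(signal_table["is_signal"].sum())}
    )

    # ----- time-to-onset --------------------------------------------------
    tto = tto_table(records, config.targets, config.window_days, config.ci_level)
    tto.to_csv(out / "time_to_onset.csv", index=False)
    run_log["stages"].append({"stage": "tto", "n_rows": len(tto)})

    # ----- two-arm comparison ---------------------------------------------
    comparison_summary = None
    if config.compare is not None:
        drug1, drug2 = config.compare
        try:
            comp = compare_onset_profiles(records, drug1, drug2, config.window_days)
            comp.curve1.to_frame().assign(arm=drug1).pipe(
                lambda df: pd.concat([df, comp.curve2.to_frame().assign(arm=drug2)])
            ).to_csv(out / "km_curves.csv", index=False)
            comparison_summary = comp.summary()
            (out / "comparison.txt").write_text(comparison_summary + "\n")
            run_log["stages"].append(
                {"stage": "compare-onset", "arms": [drug1, drug2],
                 "p_value": comp.logrank.p_value}
            )
        except ValueError as exc:
            failures.append(f"compare-onset: {exc}")
            logger.error("comparison failed: %s", exc)

    # ----- outcomes -------------------------------------------------------
    outcome_table = outcome_screen(records, config.targets)
    outcome_table.to_csv(out / "outcomes.csv", index=False)
    tables = [tabulate_outcomes(records, t) for t in config.targets]
    nonempty = [t for t in tables if t.denominator > 0]
    mosaic = mosaic_data(nonempty) if nonempty else pd.DataFrame()
    mosaic.to_csv(out / "mosaic.csv", index=False)
    run_log["stages"].append({"stage": "outcomes", "n_rows": len(outcome_table)})

    run_log["config_hash"] = hashlib.sha256(
        json.dumps(_config_fingerprint(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    if failures:
        (out / "failure_manifest.json").write_text(json.dumps(failures, indent=2))

    return ReportBundle(
        signal_table=signal_table,
        tto=tto,
        outcome_table=outcome_table,
        mosaic=mosaic,
        comparison_summary=comparison_summary,
        run_log=run_log,
        output_dir=out,
        failures=failures,
    )


def _config_fingerprint(config: RunConfig) -> dict:
    return {
        "pt_codes": config.pt_codes,
        "targets": config.targets,
        "input_paths": config.input_paths,
        "simulate": config.simulate.to_dict() if config.simulate else None,
        "window_days": config.window_days,
        "ci_level": config.ci_level,
        "seed": config.seed,
        "atc_level": config.atc_level,
        "compare": list(config.compare) if config.compare else None,
    }


def render_report(bundle: ReportBundle) -> str:
    """Human-readable summary; every figure traces to a bundle table."""
    missing = [
        name
        for name, df in (
            ("signal_table", bundle.signal_table),
            ("tto", bundle.tto),
            ("outcome_table", bundle.outcome_table),
        )
        if df is None
    ]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {missing}")

    lines = [
        "Spontaneous-report analysis",
        f"  package version {bundle.run_log['package_version']}, "
        f"seed {bundle.run_log['seed']}, config {bundle.run_log.get('config_hash', '?')}",
        "",
        "Signal screen (reporting odds ratio):",
    ]
    evaluable = bundle.signal_table[bundle.signal_table["evaluable"]]
    if evaluable.empty:
        lines.append("  no evaluable targets")
    else:
        for row in evaluable.itertuples():
            star = " *" if row.is_signal else ""
            lines.append(
                f"  {row.drug_or_class}: n={row.n_case}, "
                f"ROR {row.ror_1dp} ({row.ci_low_1dp}-{row.ci_high_1dp}){star}"
            )
    lines.append("")
    lines.append("Time-to-onset (days):")
    for row in bundle.tto.itertuples():
        if hasattr(row, "median_days") and not pd.isna(getattr(row, "median_days", float("nan"))):
            item = (
                f"  {row.drug_or_class}: n={row.n}, median {row.median_days} "
                f"(IQR {row.q1_days}-{row.q3_days})"
            )
            if getattr(row, "hazard_class", None) and not pd.isna(row.hazard_class):
                item += f", {row.hazard_class}"
            lines.append(item)
        else:
            lines.append(f"  {row.drug_or_class}: no complete-date onsets retained")
    if bundle.comparison_summary:
        lines.append("")
        lines.append(bundle.comparison_summary)
    lines.append("")
    lines.append("Outcomes (unknown/blank excluded):")
    for row in bundle.outcome_table.itertuples():
        if row.denominator:
            lines.append(
                f"  {row.drug_or_class}: n={row.denominator}, "
                f"unfavourable {row.unfavourable_pct}%, favourable {row.favourable_pct}%"
            )
        else:
            lines.append(f"  {row.drug_or_class}: no evaluable outcomes")
    if bundle.failures:
        lines.append("")
        lines.append("Failures:")
        lines.extend(f"  {f}" for f in bundle.failures)
    return "\n".join(lines) + "\n"
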