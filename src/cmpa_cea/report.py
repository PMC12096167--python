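"""Pipeline orchestration and report writers.

``run_base_case`` chains cohort derivation, both strategy arms, the
incremental comparison and the one-way sensitivity analysis, and writes
``report.json`` plus the two CSV tables (incremental results and tornado).
Numbers are serialized at full precision; rounding happens only in display.
"""
from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Sequence

from . import __version__
from . import cohort as cohort_mod
from .cea import compare, summary_table
from .model import AAF_FIRST, EHF_FIRST, evaluate_arm
from .parameters import ModelParameters, default_parameters, load_parameters
from .sensitivity import DSARange, default_ranges, one_way, tornado_table

log = logging.getLogger("cmpa_cea")


def _params(config: str | Path | None) -> ModelParameters:
    return load_parameters(config) if config is not None else default_parameters()


def build_report(
    params: ModelParameters,
    *,
    ranges: Sequence[DSARange] | None = None,
    trace: bool = False,
    timestamp: bool = True,
    seed: int | None = None,
) -> dict:
    log.info("deriving cohort")
    breakdown = cohort_mod.breakdown(params.demographics)
    log.info("evaluating strategy arms (suspected cohort: %d)", breakdown.suspected)
    results = {arm.name: evaluate_arm(params, arm) for arm in (AAF_FIRST, EHF_FIRST)}
    cea = compare(results[AAF_FIRST.name], results[EHF_FIRST.name])
    log.info(
        "incremental result: delta_cost=%.0f USD, delta_effect=%.1f months (%s)",
        cea.delta_cost,
        cea.delta_effect,
        cea.label,
    )
    log.info("one-way sensitivity analysis")
    entries = one_way(params, default_ranges(params) if ranges is None else ranges)

    report: dict = {
        "provenance": {"package": "cmpa-cea", "version": __version__, "seed": seed},
        "parameters": params.to_plain(),
        "cohort": breakdown.to_plain(),
        "strategies": {name: r.to_plain() for name, r in results.items()},
        "cea": cea.to_plain(),
        "months_gained": -cea.delta_effect,
        "cost_saved": cea.delta_cost,
        "dsa": [
            {
                "name": e.name,
                "low": e.low,
                "base": e.base,
                "high": e.high,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "spread": e.spread,
                "label_low": e.label_low,
                "label_high": e.label_high,
            }
            for e in entries
        ],
    }
    if timestamp:
        report["provenance"]["timestamp"] = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    if trace:
        report["trace"] = {
            name: [row.__dict__ for row in r.trace] for name, r in results.items()
        }
    report["_tables"] = {
        "table2": summary_table(results[AAF_FIRST.name], results[EHF_FIRST.name]),
        "table3": tornado_table(entries),
    }
    return report


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = report.pop("_tables")
    paths = {"report": out / "report.json"}
    with paths["report"].open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, frame in tables.items():
        paths[name] = out / f"{name}.csv"
        frame.to_csv(paths[name], index=False, float_format="%.2f")
    return paths


def run_base_case(
    config: str | Path | None,
    out_dir: str | Path,
    *,
    trace: bool = False,
    timestamp: bool = True,
    seed: int | None = None,
) -> dict:
    report = build_report(_params(config), trace=trace, timestamp=timestamp, seed=seed)
    write_report(dict(report), out_dir)
    report.pop("_tables", None)
    return report


def run_dsa(
    config: str | Path | None,
    ranges_path: str | Path | None,
    out_dir: str | Path,
) -> Path:
    params = _params(config)
    ranges = default_ranges(params) if ranges_path is None else load_ranges(ranges_path)
    entries = one_way(params, ranges)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "table3.csv"
    tornado_table(entries).to_csv(path, index=False, float_format="%.2f")
    return path


def load_ranges(path: str | Path) -> list[DSARange]:
    """Read a list of {name, path, low, base, high} rows from YAML/JSON."""
    import yaml

    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: ranges file must be a list of mappings")
    ranges = []
    for i, row in enumerate(raw):
        try:
            ranges.append(
                DSARange(
                    name=row["name"],
                    path=row["path"],
                    low=float(row["low"]),
                    base=float(row["base"]),
                    high=float(row["high"]),
                )
            )
        except (TypeError, KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed range row {i} ({row!r}): {exc}") from exc
    return ranges
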