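"""End-to-end model run: screening -> pooling -> derivation -> projection.

``run_model`` wires the stages for a scenario file and optionally writes
the full artifact set: report JSON + CSV, per-group meta-analysis JSON with
forest-plot tables, and a screening audit log.  Identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

from .derivation import DerivationSpec, GroupEstimate, resolve_estimates
from .errors import ScenarioError, TraumacastError
from .io import (
    Scenario,
    load_rules,
    load_scenario,
    read_corpus,
    write_report_csv,
    write_report_json,
)
from .meta import MetaAnalysisResult, run_meta
from .projection import (
    ModelReport,
    aggregate,
    project_group,
    resolve_sizes,
    validate_reassignment_direction,
)
from .screening import DEFAULT_RULES, ScreeningRuleSet

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RunConfig:
    scenario: PathLike
    rules: Optional[PathLike] = None
    scale: str = "raw"
    estimator: str = "REML"
    interval_kind: str = "ci"
    out_dir: Optional[PathLike] = None
    strict_reassignment: bool = False


@dataclass(frozen=True)
class RunResult:
    report: ModelReport
    estimates: dict[str, GroupEstimate]
    meta_results: dict[str, MetaAnalysisResult]
    scenario: Scenario


def _load_corpus(handle, base_dir: Optional[Path]):
    if isinstance(handle, (list, tuple)):
        return list(handle)
    path = Path(handle)
    if not path.is_absolute() and base_dir is not None:
        path = base_dir / path
    if not path.exists():
        raise ScenarioError(f"corpus file not found: {path}")
    return read_corpus(path)


def run_model(config: RunConfig) -> RunResult:
    """Execute the full model for a scenario and write artifacts if asked."""
    scenario = (
        config.scenario
        if isinstance(config.scenario, Scenario)
        else load_scenario(config.scenario)
    )
    rules = load_rules(config.rules) if config.rules else DEFAULT_RULES

    # 1. resolve exclusive group sizes
    groups = resolve_sizes(scenario.groups, scenario.national_population)
    size_of = {g.group_id: g.resolved_size for g in groups}

    # 2. derive estimates in dependency order, running meta-analyses on demand
    meta_results: dict[str, MetaAnalysisResult] = {}

    def meta_runner(spec: DerivationSpec) -> MetaAnalysisResult:
        corpus = _load_corpus(spec.corpus, scenario.base_dir)
        try:
            result = run_meta(
                corpus, rules, scale=config.scale, estimator=config.estimator
            )
        except TraumacastError as exc:
            raise type(exc)(f"group {spec.group_id}: {exc}") from exc
        meta_results[spec.group_id] = result
        return result

    specs = []
    for spec in scenario.derivations:
        if spec.carried is not None:
            # scenario files carry printed integer counts; turn them into
            # unrounded rates against the resolved size
            size = size_of[spec.group_id]
            if size <= 0:
                raise ScenarioError(
                    f"group {spec.group_id}: counts given but resolved size is {size}"
                )
            spec = replace(spec, carried=tuple(c / size for c in spec.carried))
        specs.append(spec)
    estimates = resolve_estimates(specs, meta_runner)

    # 3. validate reassignment direction now that estimates exist
    validate_reassignment_direction(groups, estimates, strict=config.strict_reassignment)

    # 4. project and aggregate
    rows = [
        project_group(g, estimates[g.group_id], config.interval_kind) for g in groups
    ]
    report = aggregate(rows, scenario.national_population, config.interval_kind)
    result = RunResult(
        report=report,
        estimates=estimates,
        meta_results=meta_results,
        scenario=scenario,
    )
    if config.out_dir is not None:
        write_artifacts(result, Path(config.out_dir), rules)
    return result


def _meta_result_to_dict(res: MetaAnalysisResult) -> dict:
    doc = dataclasses.asdict(res)
    return doc


def write_artifacts(result: RunResult, out_dir: Path, rules: ScreeningRuleSet) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {g.group_id: g.name for g in result.scenario.groups}
    write_report_json(result.report, result.estimates, out_dir / "report.json", names)
    write_report_csv(result.report, result.estimates, out_dir / "report.csv", names)
    audit = {}
    for gid, res in sorted(result.meta_results.items()):
        (out_dir / f"meta_{gid}.json").write_text(
            json.dumps(_meta_result_to_dict(res), indent=2, sort_keys=True, default=float)
            + "\n"
        )
        audit[gid] = res.provenance.get("decisions", [])
    (out_dir / "screening_audit.json").write_text(
        json.dumps(audit, indent=2, sort_keys=True) + "\n"
    )
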