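"""File formats: study corpora, screening rules, scenarios, reports.

Corpora travel as CSV (header row, empty field = missing) or JSON-lines
(null = missing).  Rules and scenarios are YAML or JSON.  Reports are
written as a JSON document plus a CSV table mirroring the model's results
layout (group, size, range, estimate, expected, lower, upper, totals row).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from ._rounding import round_half_up_to
from .derivation import DerivationSpec, GroupEstimate
from .errors import ScenarioError, ValidationError
from .projection import ExposureGroup, ModelReport, Reassignment
from .screening import ScreeningDecision, ScreeningRuleSet, StudyEstimate, decision_to_dict, rules_from_dict

PathLike = Union[str, Path]

CORPUS_COLUMNS = [
    "study_id",
    "sample_id",
    "events",
    "n",
    "prevalence",
    "method",
    "months_post_exposure",
    "prevalence_type",
    "population",
    "exposure_specific",
    "wave",
    "reanalysis_of",
]

_OPTIONAL_FLOATS = ("events", "prevalence", "months_post_exposure")
_OPTIONAL_INTS = ("wave",)
_OPTIONAL_STRS = ("reanalysis_of",)
_DEFAULTED = {
    "method": "clinical",
    "prevalence_type": "point",
    "population": "general",
    "exposure_specific": "yes",
}


def _record_from_mapping(row: dict) -> StudyEstimate:
    kwargs: dict = {}
    for key in ("study_id", "sample_id"):
        val = row.get(key)
        if val is None or val == "":
            raise ValidationError(f"corpus row missing {key}: {row}")
        kwargs[key] = str(val)
    n = row.get("n")
    if n is None or n == "":
        raise ValidationError(f"corpus row missing n: {row}")
    kwargs["n"] = int(float(n))
    for key in _OPTIONAL_FLOATS:
        val = row.get(key)
        kwargs[key] = None if val is None or val == "" else float(val)
    for key in _OPTIONAL_INTS:
        val = row.get(key)
        kwargs[key] = None if val is None or val == "" else int(float(val))
    for key in _OPTIONAL_STRS:
        val = row.get(key)
        kwargs[key] = None if val is None or val == "" else str(val)
    for key, default in _DEFAULTED.items():
        val = row.get(key)
        kwargs[key] = default if val is None or val == "" else str(val)
    if "corrected" in row and row["corrected"] not in (None, ""):
        kwargs["corrected"] = bool(row["corrected"]) and str(row["corrected"]).lower() not in ("false", "0")
    return StudyEstimate(**kwargs)


def read_corpus(path: PathLike) -> list[StudyEstimate]:
    """Read a study corpus from ``.csv`` or ``.jsonl``/``.ndjson``."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        records = []
        for line in path.read_text().splitlines():
            if line.strip():
                records.append(_record_from_mapping(json.loads(line)))
        return records
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("study_id", "sample_id", "n") if c not in frame.columns]
    if missing:
        raise ValidationError(f"corpus {path} lacks required columns {missing}")
    return [_record_from_mapping(row) for row in frame.to_dict(orient="records")]


def _record_to_mapping(rec: StudyEstimate) -> dict:
    d = dataclasses.asdict(rec)
    return {k: d.get(k) for k in CORPUS_COLUMNS}


def write_corpus(records: Sequence[StudyEstimate], path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with path.open("w") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_mapping(rec), sort_keys=True) + "\n")
        return
    frame = pd.DataFrame([_record_to_mapping(r) for r in records], columns=CORPUS_COLUMNS)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rules and decisions


def load_rules(path: PathLike) -> ScreeningRuleSet:
    data = _load_structured(path)
    if not isinstance(data, dict):
        raise ValidationError(f"rules file {path} must hold a mapping")
    return rules_from_dict(data)


def write_decisions(decisions: Sequence[ScreeningDecision], path: PathLike) -> None:
    Path(path).write_text(
        json.dumps([decision_to_dict(d) for d in decisions], indent=2, sort_keys=True)
        + "\n"
    )


def _load_structured(path: PathLike):
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# scenarios


@dataclasses.dataclass(frozen=True)
class Scenario:
    """A national exposure scenario: population, groups, derivation specs."""

    name: str
    national_population: int
    groups: tuple[ExposureGroup, ...]
    derivations: tuple[DerivationSpec, ...]
    base_dir: Optional[Path] = None  # for resolving relative corpus paths

    def derivation_for(self, group_id: str) -> DerivationSpec:
        for spec in self.derivations:
            if spec.group_id == group_id:
                return spec
        raise ScenarioError(f"no derivation spec for group {group_id!r}")


def _triple(mapping: dict, keys: tuple[str, str, str], ctx: str):
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ScenarioError(f"{ctx}: missing keys {missing}")
    return tuple(float(mapping[k]) for k in keys)


def _parse_group(entry: dict, ctx: str) -> tuple[ExposureGroup, DerivationSpec]:
    if "id" not in entry:
        raise ScenarioError(f"{ctx}: group entry lacks an id")
    gid = str(entry["id"])
    reassignments = tuple(
        Reassignment(
            count=int(r["count"]),
            to=(str(r["to"]) if r.get("to") is not None else None),
            counted_in_destination=bool(r.get("counted_in_destination", True)),
        )
        for r in entry.get("reassignments", []) or []
    )
    group = ExposureGroup(
        group_id=gid,
        name=str(entry.get("name", gid)),
        raw_size=(int(entry["raw_size"]) if entry.get("raw_size") is not None else None),
        reassignments_out=reassignments,
        residual=bool(entry.get("residual", False)),
        data_type=str(entry.get("data_type", "")),
    )
    deriv = entry.get("derivation")
    if not isinstance(deriv, dict) or "mode" not in deriv:
        raise ScenarioError(f"group {gid}: missing derivation mode")
    estimate = carried = pi = None
    if deriv.get("estimate") is not None:
        estimate = _triple(deriv["estimate"], ("point", "low", "high"), f"group {gid} estimate")
    if deriv.get("counts") is not None:
        # printed integer counts; converted to carried rates once sizes resolve
        carried = _triple(deriv["counts"], ("expected", "lower", "upper"), f"group {gid} counts")
    if deriv.get("pi") is not None:
        lohi = deriv["pi"]
        pi = (float(lohi["low"]), float(lohi["high"]))
    spec = DerivationSpec(
        group_id=gid,
        mode=str(deriv["mode"]),
        sources=tuple(str(s) for s in deriv.get("sources", []) or []),
        corpus=deriv.get("corpus"),
        estimate=estimate,
        carried=carried,  # holds raw counts here; pipeline divides by size
        pi=pi,
        k=(int(deriv["k"]) if deriv.get("k") is not None else None),
    )
    return group, spec


def load_scenario(path: PathLike) -> Scenario:
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, dict):
        raise ScenarioError(f"scenario file {path} must hold a mapping")
    if "national_population" not in data:
        raise ScenarioError(f"scenario {path}: missing national_population")
    entries = data.get("groups") or []
    if not entries:
        raise ScenarioError(f"scenario {path}: no groups defined")
    groups, specs = [], []
    for i, entry in enumerate(entries):
        group, spec = _parse_group(entry, f"scenario {path} group #{i}")
        groups.append(group)
        specs.append(spec)
    return Scenario(
        name=str(data.get("name", path.stem)),
        national_population=int(data["national_population"]),
        groups=tuple(groups),
        derivations=tuple(specs),
        base_dir=path.parent,
    )


def packaged_scenario_path(name: str) -> Path:
    """Path of a scenario shipped inside the package (``fixtures/``)."""
    ref = resources.files("traumacast.fixtures").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as p:
        if not p.exists():
            raise FileNotFoundError(f"no packaged scenario named {name!r}")
        return Path(p)


# ---------------------------------------------------------------------------
# report output


def _fmt(x: Optional[float], ndigits: int = 2) -> Optional[float]:
    return None if x is None else round_half_up_to(x, ndigits)


def report_to_dict(report: ModelReport, estimates: dict[str, GroupEstimate],
                   group_names: Optional[dict[str, str]] = None) -> dict:
    group_names = group_names or {}
    rows = []
    for row in report.rows:
        est = estimates[row.group_id]
        rows.append(
            {
                "group_id": row.group_id,
                "name": group_names.get(row.group_id, row.group_id),
                "size": row.size,
                "estimate": _fmt(est.point),
                "low": _fmt(est.low),
                "high": _fmt(est.high),
                "expected_n": row.expected_n,
                "lower_n": row.lower_n,
                "upper_n": row.upper_n,
                "mode": est.mode,
                "sources": list(est.sources),
                "provenance": {
                    "point_carried": est.point_carried,
                    "low_carried": est.low_carried,
                    "high_carried": est.high_carried,
                    "expected_raw": row.expected_raw,
                    "lower_raw": row.lower_raw,
                    "upper_raw": row.upper_raw,
                    "k": est.k,
                    "note": est.note,
                },
            }
        )
    return {
        "rows": rows,
        "totals": {
            "expected_n": report.total_expected,
            "lower_n": report.total_lower,
            "upper_n": report.total_upper,
        },
        "national_population": report.national_population,
        "national_pct": report.national_pct_display,
        "national_pct_range": list(report.pct_range_display),
        "interval_kind": report.interval_kind,
        "provenance": {"national_pct_unrounded": report.national_pct},
    }


def write_report_json(report: ModelReport, estimates: dict[str, GroupEstimate],
                      path: PathLike, group_names: Optional[dict[str, str]] = None) -> None:
    doc = report_to_dict(report, estimates, group_names)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_report_csv(report: ModelReport, estimates: dict[str, GroupEstimate],
                     path: PathLike, group_names: Optional[dict[str, str]] = None) -> None:
    group_names = group_names or {}
    records = []
    for row in report.rows:
        est = estimates[row.group_id]
        records.append(
            {
                "group": group_names.get(row.group_id, row.group_id),
                "size": row.size,
                "prevalence_range": f"{_fmt(est.low):.2f}-{_fmt(est.high):.2f}",
                "prevalence_estimate": f"{_fmt(est.point):.2f}",
                "expected_n": row.expected_n,
                "lower_n": row.lower_n,
                "upper_n": row.upper_n,
            }
        )
    records.append(
        {
            "group": "Total",
            "size": report.national_population,
            "prevalence_range": "",
            "prevalence_estimate": "",
            "expected_n": report.total_expected,
            "lower_n": report.total_lower,
            "upper_n": report.total_upper,
        }
    )
    pd.DataFrame.from_records(records).to_csv(path, index=False)
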