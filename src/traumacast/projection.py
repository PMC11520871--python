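"""Exposure-group size resolution and caseload projection.

Resolves raw group sizes into a mutually exclusive, exhaustive partition of
the national population (people with multifaceted exposure are reassigned
toward the higher-prevalence group; a designated residual group absorbs the
remainder), multiplies each resolved size by its group's prevalence
estimate, and aggregates national expected-caseload totals, ranges, and the
national percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from ._rounding import round_half_up, round_half_up_to
from .derivation import GroupEstimate
from .errors import ScenarioError, ValidationError

INTERVAL_KINDS = ("ci", "pi")


@dataclass(frozen=True)
class Reassignment:
    """People moved out of a group.

    ``counted_in_destination`` is true when the destination's raw size
    already includes these people (sizes compiled from independent sources),
    in which case no inflow is added on the destination side.  ``to`` may be
    ``None`` when the destination breakdown is unknown (outflow only).
    """

    count: int
    to: Optional[str] = None
    counted_in_destination: bool = True

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("reassignment count must be >= 0")


@dataclass(frozen=True)
class ExposureGroup:
    group_id: str
    name: str = ""
    raw_size: Optional[int] = None
    reassignments_out: tuple[Reassignment, ...] = ()
    residual: bool = False
    resolved_size: Optional[int] = None
    data_type: str = ""  # free-text provenance (e.g. "Clinical assessments")

    def __post_init__(self) -> None:
        if self.raw_size is None and not self.residual:
            raise ValidationError(f"group {self.group_id}: raw_size required")
        if self.raw_size is not None and self.raw_size < 0:
            raise ValidationError(f"group {self.group_id}: raw_size must be >= 0")


@dataclass(frozen=True)
class ProjectionRow:
    """size x estimate -> expected case count and range for one stratum."""

    group_id: str
    size: int
    estimate: GroupEstimate
    expected_n: int
    lower_n: int
    upper_n: int
    expected_raw: float = 0.0  # unrounded values carried for provenance
    lower_raw: float = 0.0
    upper_raw: float = 0.0

    def __post_init__(self) -> None:
        if not self.lower_n <= self.expected_n <= self.upper_n:
            raise ValidationError(
                f"group {self.group_id}: bounds out of order "
                f"({self.lower_n}, {self.expected_n}, {self.upper_n})"
            )


@dataclass(frozen=True)
class ModelReport:
    rows: tuple[ProjectionRow, ...]
    total_expected: int
    total_lower: int
    total_upper: int
    national_population: int
    national_pct: float  # full precision; presentation is 1-decimal half-up
    interval_kind: str = "ci"

    @property
    def national_pct_display(self) -> float:
        return round_half_up_to(self.national_pct, 1)

    @property
    def pct_range_display(self) -> tuple[float, float]:
        return (
            round_half_up_to(100.0 * self.total_lower / self.national_population, 1),
            round_half_up_to(100.0 * self.total_upper / self.national_population, 1),
        )


# ---------------------------------------------------------------------------
# size resolution


def resolve_sizes(
    groups: Sequence[ExposureGroup], national_population: int
) -> list[ExposureGroup]:
    """Resolve exclusive group sizes partitioning the national population.

    resolved = raw - sum(outflows) + sum(inflows not pre-counted in the
    destination's raw size); the residual group (at most one) absorbs
    ``national_population - sum(others)``.  Raises on negative sizes,
    unknown destinations, or a non-exhaustive partition.
    """
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ScenarioError("duplicate group ids in scenario")
    known = set(ids)
    residuals = [g for g in groups if g.residual]
    if len(residuals) > 1:
        raise ScenarioError("at most one residual group is allowed")

    inflow: dict[str, int] = {gid: 0 for gid in ids}
    for g in groups:
        for r in g.reassignments_out:
            if r.to is not None and r.to not in known:
                raise ScenarioError(
                    f"group {g.group_id}: reassignment to unknown group {r.to!r}"
                )
            if r.to is not None and not r.counted_in_destination:
                inflow[r.to] += r.count

    resolved: dict[str, int] = {}
    for g in groups:
        if g.residual:
            continue
        size = g.raw_size - sum(r.count for r in g.reassignments_out) + inflow[g.group_id]
        if size < 0:
            raise ScenarioError(
                f"group {g.group_id}: resolved size is negative ({size})"
            )
        resolved[g.group_id] = size

    allocated = sum(resolved.values())
    if residuals:
        residual_size = national_population - allocated
        if residual_size < 0:
            raise ScenarioError(
                f"residual group {residuals[0].group_id}: resolved size is negative "
                f"({residual_size})"
            )
        resolved[residuals[0].group_id] = residual_size
    elif allocated != national_population:
        raise ScenarioError(
            f"group sizes sum to {allocated}, not the national population "
            f"{national_population}, and no residual group is designated"
        )
    return [replace(g, resolved_size=resolved[g.group_id]) for g in groups]


def validate_reassignment_direction(
    groups: Sequence[ExposureGroup],
    estimates: Mapping[str, GroupEstimate],
    strict: bool = False,
) -> list[str]:
    """Check that every reassignment moves people toward a strictly
    higher-prevalence group.  Returns the offending messages; warns
    (default) or raises (``strict``)."""
    problems = []
    for g in groups:
        for r in g.reassignments_out:
            if r.to is None:
                continue
            src, dst = estimates.get(g.group_id), estimates.get(r.to)
            if src is None or dst is None:
                continue
            if dst.point_carried <= src.point_carried:
                problems.append(
                    f"reassignment {g.group_id} -> {r.to} moves {r.count} people "
                    f"toward a group with no higher prevalence "
                    f"({dst.point_carried:.4f} <= {src.point_carried:.4f})"
                )
    for msg in problems:
        if strict:
            raise ScenarioError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    return problems


# ---------------------------------------------------------------------------
# projection


def project_group(
    group: ExposureGroup, est: GroupEstimate, interval_kind: str = "ci"
) -> ProjectionRow:
    """Multiply a resolved group size by its carried prevalence rates.

    Counts are rounded half-up to whole persons; the unrounded products are
    retained on the row.  ``interval_kind='pi'`` projects the prediction
    interval instead of the confidence bounds (same point estimate).
    """
    if group.resolved_size is None:
        raise ScenarioError(f"group {group.group_id}: sizes not resolved yet")
    if interval_kind not in INTERVAL_KINDS:
        raise ValidationError(f"bad interval kind {interval_kind!r}")
    if interval_kind == "pi":
        if est.pi_low_carried is None or est.pi_high_carried is None:
            raise ScenarioError(
                f"group {group.group_id}: no prediction interval available "
                "(k <= 2 or injected estimate without pi bounds)"
            )
        low, high = est.pi_low_carried, est.pi_high_carried
    else:
        low, high = est.low_carried, est.high_carried
    size = group.resolved_size
    expected_raw = size * est.point_carried
    lower_raw = size * low
    upper_raw = size * high
    return ProjectionRow(
        group_id=group.group_id,
        size=size,
        estimate=est,
        expected_n=round_half_up(expected_raw),
        lower_n=round_half_up(lower_raw),
        upper_n=round_half_up(upper_raw),
        expected_raw=expected_raw,
        lower_raw=lower_raw,
        upper_raw=upper_raw,
    )


def aggregate(
    rows: Sequence[ProjectionRow],
    national_population: int,
    interval_kind: str = "ci",
) -> ModelReport:
    """Sum the per-row rounded counts into national totals and percentage."""
    ids = [r.group_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ScenarioError(f"duplicate group(s) in projection rows: {dupes}")
    if not rows:
        raise ScenarioError("aggregate: no projection rows")
    if national_population <= 0:
        raise ScenarioError("national_population must be > 0")
    total = sum(r.expected_n for r in rows)
    return ModelReport(
        rows=tuple(rows),
        total_expected=total,
        total_lower=sum(r.lower_n for r in rows),
        total_upper=sum(r.upper_n for r in rows),
        national_population=national_population,
        national_pct=100.0 * total / national_population,
        interval_kind=interval_kind,
    )
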