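"""Assembly of per-group prevalence estimates.

Each exposure group gets its prevalence point and range from one of four
modes: a meta-analysis of its own corpus (``meta``), a questionnaire-only
meta-analysis with the correction factor applied upstream
(``meta_adjusted``), borrowing another group's estimate wholesale
(``borrow``), or averaging two groups' points and interval endpoints
(``average``).  Borrow/average dependencies must form a DAG and are
resolved topologically.

Alongside the displayed (typically rounded, as-published) ``point/low/high``
values, every estimate carries unrounded ``*_carried`` rates used for
projection arithmetic; borrowing and averaging propagate the carried rates,
which is what makes a borrowed group's expected count differ from
``size x rounded point``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

from .errors import CycleError, DerivationError, ValidationError
from .meta import MetaAnalysisResult

MODES = ("meta", "meta_adjusted", "borrow", "average")


@dataclass(frozen=True)
class GroupEstimate:
    """A stratum's prevalence point + range with derivation provenance."""

    group_id: str
    point: float
    low: float
    high: float
    mode: str
    sources: tuple[str, ...] = ()
    k: Optional[int] = None
    point_carried: Optional[float] = None
    low_carried: Optional[float] = None
    high_carried: Optional[float] = None
    pi_low: Optional[float] = None
    pi_high: Optional[float] = None
    pi_low_carried: Optional[float] = None
    pi_high_carried: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.point <= self.high <= 1.0:
            raise ValidationError(
                f"group {self.group_id}: need 0 <= low <= point <= high <= 1, "
                f"got ({self.low}, {self.point}, {self.high})"
            )
        if self.mode not in MODES:
            raise ValidationError(f"group {self.group_id}: bad mode {self.mode!r}")
        if self.mode == "borrow" and len(self.sources) != 1:
            raise ValidationError(
                f"group {self.group_id}: borrow requires exactly one source"
            )
        if self.mode == "average" and len(self.sources) != 2:
            raise ValidationError(
                f"group {self.group_id}: average requires exactly two sources"
            )
        # carried rates default to the displayed values
        for name in (
            "point_carried",
            "low_carried",
            "high_carried",
            "pi_low_carried",
            "pi_high_carried",
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, getattr(self, name.removesuffix("_carried")))


def from_meta_result(
    group_id: str, result: MetaAnalysisResult, mode: Optional[str] = None
) -> GroupEstimate:
    """Wrap a pooled result as a group estimate (mode per correction flag)."""
    if mode is None:
        mode = "meta_adjusted" if result.corrected else "meta"
    return GroupEstimate(
        group_id=group_id,
        point=result.mu_hat,
        low=result.ci_low,
        high=result.ci_high,
        mode=mode,
        k=result.k,
        pi_low=result.pi_low,
        pi_high=result.pi_high,
    )


def derive_borrow(target_group: str, source: GroupEstimate) -> GroupEstimate:
    """Inherit the source group's point, bounds and carried rates unchanged."""
    if source is None:
        raise DerivationError(f"group {target_group}: missing borrow source")
    return replace(
        source,
        group_id=target_group,
        mode="borrow",
        sources=(source.group_id,),
        k=None,
        note=f"borrowed from {source.group_id}",
    )


def _mean_opt(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return (a + b) / 2.0


def derive_average(
    target_group: str, a: GroupEstimate, b: GroupEstimate
) -> GroupEstimate:
    """Average two groups' points and interval endpoints, member by member.

    The resulting range is a heuristic (averaged endpoints), not a
    variance-propagated confidence interval; this is recorded in ``note``.
    """
    if a is None or b is None:
        raise DerivationError(f"group {target_group}: missing average source")
    return GroupEstimate(
        group_id=target_group,
        point=(a.point + b.point) / 2.0,
        low=(a.low + b.low) / 2.0,
        high=(a.high + b.high) / 2.0,
        mode="average",
        sources=(a.group_id, b.group_id),
        point_carried=(a.point_carried + b.point_carried) / 2.0,
        low_carried=(a.low_carried + b.low_carried) / 2.0,
        high_carried=(a.high_carried + b.high_carried) / 2.0,
        pi_low=_mean_opt(a.pi_low, b.pi_low),
        pi_high=_mean_opt(a.pi_high, b.pi_high),
        pi_low_carried=_mean_opt(a.pi_low_carried, b.pi_low_carried),
        pi_high_carried=_mean_opt(a.pi_high_carried, b.pi_high_carried),
        note="endpoint average of sources; range is heuristic, not a CI",
    )


@dataclass(frozen=True)
class DerivationSpec:
    """How one group's estimate is obtained.

    ``meta``/``meta_adjusted`` groups either carry a corpus (pooled at
    resolution time via the supplied runner) or injected constants
    (``estimate`` = displayed point/low/high, optional ``carried`` rates,
    optional ``pi`` bounds).  ``borrow``/``average`` groups name their
    source group ids.
    """

    group_id: str
    mode: str
    sources: tuple[str, ...] = ()
    corpus: Optional[object] = None  # opaque handle given to the meta runner
    estimate: Optional[tuple[float, float, float]] = None  # (point, low, high)
    carried: Optional[tuple[float, float, float]] = None
    pi: Optional[tuple[float, float]] = None
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"group {self.group_id}: bad mode {self.mode!r}")
        if self.mode in ("borrow", "average"):
            want = 1 if self.mode == "borrow" else 2
            if len(self.sources) != want:
                raise ValidationError(
                    f"group {self.group_id}: mode {self.mode} needs {want} source(s)"
                )
        elif self.corpus is None and self.estimate is None:
            raise ValidationError(
                f"group {self.group_id}: meta modes need a corpus or injected estimate"
            )


def _estimate_from_spec(spec: DerivationSpec, meta_runner) -> GroupEstimate:
    if spec.estimate is not None:
        point, low, high = spec.estimate
        carried = spec.carried or (None, None, None)
        pi = spec.pi or (None, None)
        return GroupEstimate(
            group_id=spec.group_id,
            point=point,
            low=low,
            high=high,
            mode=spec.mode,
            sources=spec.sources,
            k=spec.k,
            point_carried=carried[0],
            low_carried=carried[1],
            high_carried=carried[2],
            pi_low=pi[0],
            pi_high=pi[1],
            note="injected constants",
        )
    if meta_runner is None:
        raise DerivationError(
            f"group {spec.group_id}: corpus-backed derivation needs a meta runner"
        )
    result = meta_runner(spec)
    if spec.mode == "meta_adjusted" and not result.corrected:
        raise DerivationError(
            f"group {spec.group_id}: mode meta_adjusted but the corpus was not "
            "questionnaire-only (no correction applied)"
        )
    return from_meta_result(spec.group_id, result, mode=spec.mode)


def derive_group(
    spec: DerivationSpec,
    meta_results: Optional[Mapping[str, MetaAnalysisResult]] = None,
    prior_estimates: Optional[Mapping[str, GroupEstimate]] = None,
) -> GroupEstimate:
    """Derive a single group whose dependencies are already available."""
    prior_estimates = prior_estimates or {}
    if spec.estimate is not None:  # injected constants win over recomputation
        return _estimate_from_spec(spec, None)
    if spec.mode == "borrow":
        return derive_borrow(spec.group_id, prior_estimates.get(spec.sources[0]))
    if spec.mode == "average":
        return derive_average(
            spec.group_id,
            prior_estimates.get(spec.sources[0]),
            prior_estimates.get(spec.sources[1]),
        )
    if meta_results and spec.group_id in meta_results:
        return from_meta_result(spec.group_id, meta_results[spec.group_id], spec.mode)
    return _estimate_from_spec(spec, None)


def resolve_estimates(
    specs: Sequence[DerivationSpec],
    meta_runner: Optional[Callable[[DerivationSpec], MetaAnalysisResult]] = None,
) -> dict[str, GroupEstimate]:
    """Derive all groups in topological order over borrow/average edges.

    Resolution is independent of the listing order of ``specs``; a
    dependency cycle raises :class:`CycleError` naming the cycle.
    """
    by_id = {s.group_id: s for s in specs}
    if len(by_id) != len(specs):
        raise ValidationError("duplicate group ids in derivation specs")
    estimates: dict[str, GroupEstimate] = {}
    in_progress: list[str] = []

    def visit(gid: str) -> GroupEstimate:
        if gid in estimates:
            return estimates[gid]
        if gid in in_progress:
            cycle = in_progress[in_progress.index(gid):] + [gid]
            raise CycleError(f"derivation cycle: {' -> '.join(cycle)}")
        if gid not in by_id:
            raise DerivationError(f"unknown source group {gid!r}")
        spec = by_id[gid]
        in_progress.append(gid)
        try:
            if spec.estimate is not None:  # injected constants win
                est = _estimate_from_spec(spec, meta_runner)
            elif spec.mode == "borrow":
                est = derive_borrow(gid, visit(spec.sources[0]))
            elif spec.mode == "average":
                est = derive_average(gid, visit(spec.sources[0]), visit(spec.sources[1]))
            else:
                est = _estimate_from_spec(spec, meta_runner)
        finally:
            in_progress.pop()
        estimates[gid] = est
        return est

    for gid in sorted(by_id):  # order-independent traversal
        visit(gid)
    return estimates
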