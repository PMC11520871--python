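"""Eligibility screening of study-level prevalence records.

Turns a corpus of literature-extracted prevalence observations into the set
of records eligible for pooling: timing after exposure, point- vs period-
prevalence, sample provenance, exposure-specific measurement, re-analysis
flags, a corpus-wide preference for clinical assessments over self-report
questionnaires, a highest-prevalence wave selection for longitudinal
samples, and a multiplicative correction factor for questionnaire-only
corpora.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .errors import EmptySelectionError, ValidationError

# ---------------------------------------------------------------------------
# enumerations and exclusion codes

METHODS = ("clinical", "questionnaire")
PREVALENCE_TYPES = ("point", "period", "unknown")
POPULATIONS = ("general", "help_seeking", "clinical_setting")
EXPOSURE_SPECIFIC = ("yes", "no", "unknown")

TIMING_LT_MIN = "TIMING_LT_1MO"
QUESTIONNAIRE_WHEN_CLINICAL = "QUESTIONNAIRE_WHEN_CLINICAL_AVAILABLE"
HELP_SEEKING = "HELP_SEEKING"
PERIOD_PREVALENCE = "PERIOD_PREVALENCE"
NOT_EXPOSURE_SPECIFIC = "NOT_EXPOSURE_SPECIFIC"
REANALYSIS = "REANALYSIS"
SUPERSEDED_WAVE = "SUPERSEDED_WAVE"

#: canonical ordering used when several codes apply to one record
REASON_ORDER = (
    TIMING_LT_MIN,
    PERIOD_PREVALENCE,
    HELP_SEEKING,
    NOT_EXPOSURE_SPECIFIC,
    REANALYSIS,
    QUESTIONNAIRE_WHEN_CLINICAL,
    SUPERSEDED_WAVE,
)


def _sort_reasons(reasons: Iterable[str]) -> tuple[str, ...]:
    uniq = set(reasons)
    return tuple(r for r in REASON_ORDER if r in uniq)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StudyEstimate:
    """One study's prevalence observation plus its screening metadata.

    Either ``events`` or ``prevalence`` must be given (with ``n``); when both
    are present they must agree to 1e-9.
    """

    study_id: str
    sample_id: str
    n: int
    events: Optional[float] = None
    prevalence: Optional[float] = None
    method: str = "clinical"
    months_post_exposure: Optional[float] = None
    prevalence_type: str = "point"
    population: str = "general"
    exposure_specific: str = "yes"
    wave: Optional[int] = None
    reanalysis_of: Optional[str] = None
    corrected: bool = False  # provenance: correction factor already applied

    def __post_init__(self) -> None:
        label = f"{self.study_id}/{self.sample_id}"
        if self.n < 1:
            raise ValidationError(f"record {label}: n must be >= 1, got {self.n}")
        if self.events is None and self.prevalence is None:
            raise ValidationError(f"record {label}: needs events or prevalence")
        if self.events is not None:
            if self.events < 0:
                raise ValidationError(f"record {label}: events must be >= 0")
            p = self.events / self.n
            if self.prevalence is None:
                object.__setattr__(self, "prevalence", p)
            elif abs(self.prevalence - p) > 1e-9:
                raise ValidationError(
                    f"record {label}: prevalence {self.prevalence} != events/n {p}"
                )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(
                f"record {label}: prevalence {self.prevalence} outside [0, 1]"
            )
        if self.method not in METHODS:
            raise ValidationError(f"record {label}: bad method {self.method!r}")
        if self.prevalence_type not in PREVALENCE_TYPES:
            raise ValidationError(
                f"record {label}: bad prevalence_type {self.prevalence_type!r}"
            )
        if self.population not in POPULATIONS:
            raise ValidationError(f"record {label}: bad population {self.population!r}")
        if self.exposure_specific not in EXPOSURE_SPECIFIC:
            raise ValidationError(
                f"record {label}: bad exposure_specific {self.exposure_specific!r}"
            )
        if self.months_post_exposure is not None and self.months_post_exposure < 0:
            raise ValidationError(f"record {label}: negative months_post_exposure")


@dataclass(frozen=True)
class ScreeningRuleSet:
    """Configurable screening rules with the model's defaults."""

    min_months_post_exposure: float = 1.0
    require_point_prevalence: bool = True
    exclude_help_seeking: bool = True
    require_exposure_specific_for_questionnaires: bool = True
    exclude_reanalyses: bool = True
    correction_factor: float = 0.71

    def __post_init__(self) -> None:
        if not 0.0 < self.correction_factor <= 1.0:
            raise ValidationError(
                f"correction_factor must be in (0, 1], got {self.correction_factor}"
            )
        if self.min_months_post_exposure < 0:
            raise ValidationError("min_months_post_exposure must be >= 0")


@dataclass(frozen=True)
class ScreeningDecision:
    """Inclusion verdict for one record; included iff ``reasons`` is empty."""

    study_id: str
    sample_id: str
    included: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValidationError("included must be true iff reasons is empty")


DEFAULT_RULES = ScreeningRuleSet()


# ---------------------------------------------------------------------------
# rule application


def _record_reasons(rec: StudyEstimate, rules: ScreeningRuleSet) -> list[str]:
    """Per-record exclusion codes, before the corpus-wide rules."""
    reasons: list[str] = []
    # unknown timing is treated as ineligible (conservative)
    if (
        rec.months_post_exposure is None
        or rec.months_post_exposure < rules.min_months_post_exposure
    ):
        reasons.append(TIMING_LT_MIN)
    if rules.require_point_prevalence and rec.prevalence_type != "point":
        reasons.append(PERIOD_PREVALENCE)
    if rules.exclude_help_seeking and rec.population in ("help_seeking", "clinical_setting"):
        reasons.append(HELP_SEEKING)
    if (
        rules.require_exposure_specific_for_questionnaires
        and rec.method == "questionnaire"
        and rec.exposure_specific != "yes"
    ):
        reasons.append(NOT_EXPOSURE_SPECIFIC)
    if rules.exclude_reanalyses and rec.reanalysis_of is not None:
        reasons.append(REANALYSIS)
    return reasons


def _wave_sort_key(item: tuple[int, StudyEstimate]):
    idx, rec = item
    wave = rec.wave if rec.wave is not None else float("inf")
    months = (
        rec.months_post_exposure if rec.months_post_exposure is not None else float("inf")
    )
    # highest prevalence first; ties resolved toward the earliest eligible
    # wave; the full record repr makes the ranking content-based and thus
    # independent of input order
    return (-rec.prevalence, wave, months, repr(rec), idx)


def screen_corpus(
    records: Sequence[StudyEstimate], rules: ScreeningRuleSet = DEFAULT_RULES
) -> list[ScreeningDecision]:
    """Screen a corpus, returning one decision per record in input order.

    The clinical-preference rule is corpus-wide: if any clinical-method
    record survives the per-record filters, every questionnaire record is
    excluded.  Wave selection then keeps, per sample, only the surviving
    record with the highest prevalence.  Decisions are independent of input
    order (deterministic tie-breaking).
    """
    if not records:
        raise ValidationError("screen_corpus: empty corpus")
    reasons_by_idx: dict[int, list[str]] = {
        i: _record_reasons(rec, rules) for i, rec in enumerate(records)
    }

    # corpus-wide clinical preference
    any_clinical = any(
        rec.method == "clinical" and not reasons_by_idx[i]
        for i, rec in enumerate(records)
    )
    if any_clinical:
        for i, rec in enumerate(records):
            if rec.method == "questionnaire":
                reasons_by_idx[i].append(QUESTIONNAIRE_WHEN_CLINICAL)

    # per-sample wave selection among survivors
    by_sample: dict[tuple[str, str], list[tuple[int, StudyEstimate]]] = {}
    for i, rec in enumerate(records):
        if not reasons_by_idx[i]:
            by_sample.setdefault((rec.study_id, rec.sample_id), []).append((i, rec))
    for survivors in by_sample.values():
        if len(survivors) > 1:
            ranked = sorted(survivors, key=_wave_sort_key)
            for i, _ in ranked[1:]:
                reasons_by_idx[i].append(SUPERSEDED_WAVE)

    return [
        ScreeningDecision(
            study_id=rec.study_id,
            sample_id=rec.sample_id,
            included=not reasons_by_idx[i],
            reasons=_sort_reasons(reasons_by_idx[i]),
        )
        for i, rec in enumerate(records)
    ]


def included_records(
    records: Sequence[StudyEstimate], decisions: Sequence[ScreeningDecision]
) -> list[StudyEstimate]:
    """Subset of ``records`` whose decision is an inclusion."""
    return [rec for rec, dec in zip(records, decisions) if dec.included]


def select_wave(
    records_of_one_sample: Sequence[StudyEstimate], min_months: float = 1.0
) -> StudyEstimate:
    """Pick one record per longitudinal sample: the highest prevalence among
    waves measured at least ``min_months`` after exposure.

    Ties go to the earliest eligible wave.  Raises
    :class:`EmptySelectionError` when no wave is eligible.
    """
    if not records_of_one_sample:
        raise EmptySelectionError("select_wave: no records given")
    sample_ids = {r.sample_id for r in records_of_one_sample}
    if len(sample_ids) != 1:
        raise ValidationError(
            f"select_wave: records span several samples: {sorted(sample_ids)}"
        )
    eligible = [
        (i, r)
        for i, r in enumerate(records_of_one_sample)
        if r.months_post_exposure is not None
        and r.months_post_exposure >= min_months
    ]
    if not eligible:
        raise EmptySelectionError(
            f"select_wave: no wave of sample {next(iter(sample_ids))!r} measured "
            f">= {min_months} months after exposure"
        )
    return min(eligible, key=_wave_sort_key)[1]


# ---------------------------------------------------------------------------
# questionnaire correction


def apply_correction(prevalence: float, rules: ScreeningRuleSet = DEFAULT_RULES) -> float:
    """Deflate a questionnaire-derived prevalence by the correction factor."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValidationError(f"prevalence {prevalence} outside [0, 1]")
    return prevalence * rules.correction_factor


def correct_corpus(
    records: Sequence[StudyEstimate], rules: ScreeningRuleSet = DEFAULT_RULES
) -> list[StudyEstimate]:
    """Apply the correction factor to every questionnaire record, once.

    Records already carrying the ``corrected`` provenance flag are returned
    unchanged, so the operation is idempotent.  Clinical records are never
    touched.  Event counts are dropped on corrected records (the adjusted
    prevalence no longer corresponds to an integer count); downstream
    variances are recomputed from the adjusted proportion.
    """
    out: list[StudyEstimate] = []
    for rec in records:
        if rec.method != "questionnaire" or rec.corrected:
            out.append(rec)
            continue
        out.append(
            replace(
                rec,
                events=None,
                prevalence=apply_correction(rec.prevalence, rules),
                corrected=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# (de)serialization helpers used by io and the CLI


def decision_to_dict(dec: ScreeningDecision) -> dict:
    return {
        "study_id": dec.study_id,
        "sample_id": dec.sample_id,
        "included": dec.included,
        "reasons": list(dec.reasons),
    }


def rules_from_dict(d: dict) -> ScreeningRuleSet:
    known = {f.name for f in dataclasses.fields(ScreeningRuleSet)}
    extra = set(d) - known
    if extra:
        raise ValidationError(f"unknown screening rule keys: {sorted(extra)}")
    return ScreeningRuleSet(**d)
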