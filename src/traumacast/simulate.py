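"""Synthetic inputs with known ground truth.

Generates (a) study corpora whose true prevalences follow a random-effects
distribution, with screening metadata planted to violate chosen rules and
ground-truth inclusion labels attached, and (b) full multi-group national
scenarios (including one borrow-mode and one average-mode group) with known
true prevalences and expected caseloads, written in the same CSV/YAML
dialects the pipeline reads.

All randomness flows from a mandatory integer seed through
``numpy.random.default_rng``; no wall-clock seeding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml


from .errors import ValidationError
from .screening import (
    HELP_SEEKING,
    NOT_EXPOSURE_SPECIFIC,
    PERIOD_PREVALENCE,
    QUESTIONNAIRE_WHEN_CLINICAL,
    TIMING_LT_MIN,
    ScreeningDecision,
    StudyEstimate,
)

EFFECT_SCALES = ("logit_normal", "additive_truncated")


@dataclass(frozen=True)
class Contamination:
    """How many records violate each screening rule (disjoint assignment)."""

    sub_month: int = 0
    help_seeking: int = 0
    period_prevalence: int = 0
    non_exposure_specific: int = 0

    @property
    def total(self) -> int:
        return (
            self.sub_month
            + self.help_seeking
            + self.period_prevalence
            + self.non_exposure_specific
        )


@dataclass(frozen=True)
class SyntheticMetaConfig:
    k: int
    true_mu: float
    true_tau: float
    seed: int
    effects_scale: str = "logit_normal"
    n_range: tuple[int, int] = (50, 500)
    questionnaire_fraction: float = 0.0
    contamination: Contamination = field(default_factory=Contamination)

    def __post_init__(self) -> None:
        if not 0.0 < self.true_mu < 1.0:
            raise ValidationError("true_mu must be in (0, 1)")
        if self.true_tau < 0:
            raise ValidationError("true_tau must be >= 0")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.n_range[0] < 10 or self.n_range[1] < self.n_range[0]:
            raise ValidationError("n_range must satisfy 10 <= min <= max")
        if self.effects_scale not in EFFECT_SCALES:
            raise ValidationError(f"bad effects_scale {self.effects_scale!r}")
        if not 0.0 <= self.questionnaire_fraction <= 1.0:
            raise ValidationError("questionnaire_fraction must be in [0, 1]")
        if self.contamination.total > self.k:
            raise ValidationError(
                f"contamination assigns {self.contamination.total} violations "
                f"to only {self.k} records"
            )


@dataclass(frozen=True)
class SyntheticCorpus:
    """Generated records plus the generator's own ground-truth labels."""

    records: tuple[StudyEstimate, ...]
    true_decisions: tuple[ScreeningDecision, ...]
    theta: tuple[float, ...]  # true per-study prevalences
    config: SyntheticMetaConfig


def draw_theta(cfg: SyntheticMetaConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """True per-study prevalences under the configured random-effects law."""
    if cfg.effects_scale == "logit_normal":
        mu_l = np.log(cfg.true_mu / (1.0 - cfg.true_mu))
        return 1.0 / (1.0 + np.exp(-rng.normal(mu_l, cfg.true_tau, size)))
    # additive_truncated: normal around true_mu, redrawn until inside (0, 1)
    theta = rng.normal(cfg.true_mu, cfg.true_tau, size)
    eps = 1e-12
    while np.any((theta <= 0.0) | (theta >= 1.0)):
        bad = (theta <= 0.0) | (theta >= 1.0)
        if cfg.true_tau == 0:
            theta = np.clip(theta, eps, 1 - eps)
            break
        theta[bad] = rng.normal(cfg.true_mu, cfg.true_tau, int(bad.sum()))
    return theta


def generate_meta_corpus(cfg: SyntheticMetaConfig) -> SyntheticCorpus:
    """Draw a corpus of binomially sampled study prevalences.

    Contaminated records (violating a planted screening rule) are assigned
    to distinct leading indices after a seeded shuffle; ground-truth labels
    mirror the screening semantics, including the corpus-wide clinical
    preference.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    theta = draw_theta(cfg, rng, k)
    n = rng.integers(cfg.n_range[0], cfg.n_range[1] + 1, k)
    events = rng.binomial(n, theta)

    questionnaire = rng.random(k) < cfg.questionnaire_fraction
    months = rng.integers(1, 25, k).astype(float)

    # assign planted violations to a seeded random subset, disjointly
    order = rng.permutation(k)
    cont = cfg.contamination
    slots = iter(order)
    planted: dict[int, str] = {}
    for code, count in (
        (TIMING_LT_MIN, cont.sub_month),
        (HELP_SEEKING, cont.help_seeking),
        (PERIOD_PREVALENCE, cont.period_prevalence),
        (NOT_EXPOSURE_SPECIFIC, cont.non_exposure_specific),
    ):
        for _ in range(count):
            planted[int(next(slots))] = code

    records: list[StudyEstimate] = []
    reasons: list[list[str]] = []
    for i in range(k):
        code = planted.get(i)
        is_q = bool(questionnaire[i]) or code == NOT_EXPOSURE_SPECIFIC
        rec = StudyEstimate(
            study_id=f"S{i:03d}",
            sample_id=f"S{i:03d}a",
            n=int(n[i]),
            events=int(events[i]),
            method="questionnaire" if is_q else "clinical",
            months_post_exposure=(
                float(rng.uniform(0.0, 0.9)) if code == TIMING_LT_MIN else float(months[i])
            ),
            prevalence_type="period" if code == PERIOD_PREVALENCE else "point",
            population="help_seeking" if code == HELP_SEEKING else "general",
            exposure_specific="no" if code == NOT_EXPOSURE_SPECIFIC else "yes",
            wave=1,
        )
        records.append(rec)
        reasons.append([code] if code else [])

    # corpus-wide clinical preference, mirrored independently of screen_corpus
    clean_clinical = any(
        not rs and rec.method == "clinical" for rec, rs in zip(records, reasons)
    )
    if clean_clinical:
        for rec, rs in zip(records, reasons):
            if rec.method == "questionnaire":
                rs.append(QUESTIONNAIRE_WHEN_CLINICAL)

    decisions = tuple(
        ScreeningDecision(
            study_id=rec.study_id,
            sample_id=rec.sample_id,
            included=not rs,
            reasons=tuple(rs),
        )
        for rec, rs in zip(records, reasons)
    )
    return SyntheticCorpus(
        records=tuple(records),
        true_decisions=decisions,
        theta=tuple(float(t) for t in theta),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# full scenarios


@dataclass(frozen=True)
class SyntheticScenario:
    """A generated national scenario plus its ground truth."""

    scenario_dict: dict
    true_prevalence: dict[str, float]
    true_expected: dict[str, float]
    corpora: dict[str, tuple[StudyEstimate, ...]]
    national_population: int
    seed: int

    @property
    def true_total(self) -> float:
        return sum(self.true_expected.values())


def generate_scenario(
    n_groups: int,
    size_profile: Optional[Sequence[int]] = None,
    prevalence_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
    national_population: int = 10_000_000,
    k_per_group: int = 10,
    n_range: tuple[int, int] = (200, 400),
    true_tau: float = 0.1,
    out_dir: Optional[Path] = None,
) -> SyntheticScenario:
    """Build an ``n_groups``-stratum scenario exercising every derivation mode.

    Groups 1..n-2 are meta-analysed from generated corpora; group n-1
    borrows group 1's estimate; the last group is the residual stratum and
    averages groups 1 and 2.  Requires ``n_groups >= 4``.  When ``out_dir``
    is given, writes ``scenario.yaml`` plus one corpus CSV per meta group.
    """
    if n_groups < 4:
        raise ValidationError("generate_scenario needs n_groups >= 4")
    rng = np.random.default_rng(seed)
    ids = [f"g{i + 1}" for i in range(n_groups)]

    if prevalence_profile is None:
        # declining prevalence with exposure rank, echoing a dose-response
        prevalence_profile = list(np.linspace(0.30, 0.02, n_groups - 2))
    if len(prevalence_profile) != n_groups - 2:
        raise ValidationError("prevalence_profile must cover the meta groups (n-2)")

    if size_profile is None:
        shares = rng.dirichlet(np.arange(2, n_groups + 2, dtype=float))
        sizes = [int(s * national_population) for s in shares[:-1]]
        sizes.append(national_population - sum(sizes))
    else:
        sizes = [int(s) for s in size_profile]
        if len(sizes) != n_groups or sum(sizes) != national_population:
            raise ValidationError(
                "size_profile must list one size per group and sum to the "
                "national population"
            )

    meta_ids = ids[: n_groups - 2]
    borrow_id, residual_id = ids[n_groups - 2], ids[n_groups - 1]
    truth = dict(zip(meta_ids, (float(p) for p in prevalence_profile)))
    truth[borrow_id] = truth[meta_ids[0]]
    truth[residual_id] = (truth[meta_ids[0]] + truth[meta_ids[1]]) / 2.0

    corpora: dict[str, tuple[StudyEstimate, ...]] = {}
    entries = []
    for i, gid in enumerate(ids):
        entry: dict = {"id": gid, "name": f"synthetic stratum {gid}"}
        if gid == residual_id:
            entry["residual"] = True
        else:
            entry["raw_size"] = sizes[i]
        if gid in truth and gid in meta_ids:
            sub = SyntheticMetaConfig(
                k=k_per_group,
                true_mu=truth[gid],
                true_tau=true_tau,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_range=n_range,
            )
            corpora[gid] = generate_meta_corpus(sub).records
            entry["derivation"] = {"mode": "meta", "corpus": f"corpus_{gid}.csv"}
        elif gid == borrow_id:
            entry["derivation"] = {"mode": "borrow", "sources": [meta_ids[0]]}
        else:
            entry["derivation"] = {"mode": "average", "sources": [meta_ids[0], meta_ids[1]]}
        entries.append(entry)

    scenario_dict = {
        "name": f"synthetic-{n_groups}g-seed{seed}",
        "national_population": national_population,
        "groups": entries,
    }
    true_expected = {gid: sizes[i] * truth[gid] for i, gid in enumerate(ids)}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_corpus

        for gid, records in corpora.items():
            write_corpus(records, out_dir / f"corpus_{gid}.csv")
        (out_dir / "scenario.yaml").write_text(
            yaml.safe_dump(scenario_dict, sort_keys=False)
        )

    return SyntheticScenario(
        scenario_dict=scenario_dict,
        true_prevalence=truth,
        true_expected=true_expected,
        corpora=corpora,
        national_population=national_population,
        seed=seed,
    )


def meta_config_from_dict(d: dict) -> SyntheticMetaConfig:
    d = dict(d)
    if "contamination" in d and isinstance(d["contamination"], dict):
        d["contamination"] = Contamination(**d["contamination"])
    if "n_range" in d:
        d["n_range"] = tuple(d["n_range"])
    known = {f.name for f in dataclasses.fields(SyntheticMetaConfig)}
    extra = set(d) - known
    if extra:
        raise ValidationError(f"unknown simulation config keys: {sorted(extra)}")
    return SyntheticMetaConfig(**d)
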