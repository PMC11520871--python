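"""Random-effects meta-analysis of prevalence proportions.

Implements the pooling machinery from first principles rather than wrapping
an existing meta-analysis package: per-study effect sizes and variances on
the raw-proportion or logit scale, DerSimonian-Laird and REML estimators of
the between-study variance tau^2, inverse-variance pooling, Q/I^2
heterogeneity statistics, z-based confidence intervals and t-based
prediction intervals for the pooled prevalence.

Notation
--------
For study i with effect ``y_i`` and within-study variance ``v_i``:

* fixed-effect weights      ``w_i = 1 / v_i``
* random-effects weights    ``w_i* = 1 / (v_i + tau^2)``
* pooled effect             ``mu = sum(w* y) / sum(w*)``
* pooled standard error     ``se = sum(w*)**-0.5``
* heterogeneity             ``Q = sum(w (y - mu_FE)^2)``, ``I2 = max(0, (Q-df)/Q) * 100``
* prediction interval       ``mu +/- t_{k-2, 1-alpha/2} * sqrt(tau^2 + se^2)``
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import MetaAnalysisError, ValidationError
from .screening import (
    DEFAULT_RULES,
    ScreeningRuleSet,
    StudyEstimate,
    correct_corpus,
    included_records,
    screen_corpus,
)

SCALES = ("raw", "logit")
ESTIMATORS = ("REML", "DL")

REML_TOL = 1e-8
REML_MAX_ITER = 200


@dataclass(frozen=True)
class EffectSize:
    """Per-study effect on the analysis scale with its within-study variance."""

    y: float
    v: float
    n: int
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValidationError(f"effect variance must be > 0, got {self.v}")
        if self.scale not in SCALES:
            raise ValidationError(f"bad scale {self.scale!r}")
        if self.scale == "raw" and not 0.0 <= self.y <= 1.0:
            raise ValidationError(f"raw-scale effect {self.y} outside [0, 1]")


@dataclass(frozen=True)
class MetaAnalysisResult:
    """Pooled prevalence with uncertainty, heterogeneity, and provenance.

    ``mu_hat`` and the interval bounds live on the proportion scale
    regardless of the analysis scale; ``se`` is on the analysis scale.
    ``pi_low``/``pi_high`` are ``None`` when k <= 2 (the t quantile with
    k-2 degrees of freedom does not exist) rather than fabricated.
    """

    mu_hat: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    tau: float
    Q: float
    df: int
    p_Q: float
    I2: float
    k: int
    pi_low: Optional[float]
    pi_high: Optional[float]
    estimator: str
    scale: str = "raw"
    corrected: bool = False
    provenance: dict = field(default_factory=dict, compare=False, repr=False)


# ---------------------------------------------------------------------------
# effect sizes


def _proportion(study: StudyEstimate) -> tuple[float, float]:
    """(p, n) after the 0.5/1 continuity correction for degenerate cells."""
    n = float(study.n)
    if study.events is not None:
        events = float(study.events)
    else:
        events = study.prevalence * n
    p = events / n
    if p in (0.0, 1.0):
        events, n = events + 0.5, n + 1.0
        p = events / n
    return p, n


def compute_effects(
    studies: Sequence[StudyEstimate], scale: str = "raw"
) -> list[EffectSize]:
    """Per-study effects and variances on the requested scale."""
    if not studies:
        raise ValidationError("compute_effects: empty study list")
    if scale not in SCALES:
        raise ValidationError(f"bad scale {scale!r}")
    effects = []
    for study in studies:
        if study.n < 2:
            raise ValidationError(
                f"record {study.study_id}/{study.sample_id}: n must be >= 2 for pooling"
            )
        p, n = _proportion(study)
        if scale == "raw":
            y, v = p, p * (1.0 - p) / n
        else:
            y = math.log(p / (1.0 - p))
            v = 1.0 / (n * p) + 1.0 / (n * (1.0 - p))
        effects.append(EffectSize(y=y, v=v, n=study.n, scale=scale))
    return effects


def _arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


# ---------------------------------------------------------------------------
# tau^2 estimation


def tau2_dersimonian_laird(effects: Sequence[EffectSize]) -> float:
    """Closed-form DerSimonian-Laird moment estimator, floored at zero."""
    y, v = _arrays(effects)
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(effects)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * math.log(np.sum(w))
        - 0.5 * np.sum(w * (y - mu) ** 2)
    )


def tau2_reml(effects: Sequence[EffectSize]) -> float:
    """REML estimate via Fisher-scoring fixed-point iteration.

    Starts from the DL estimate; converged when successive values differ by
    less than 1e-8, capped at 200 iterations, floored at zero.  On
    non-convergence falls back to DL with a warning.
    """
    y, v = _arrays(effects)
    tau2 = tau2_dersimonian_laird(effects)
    for _ in range(REML_MAX_ITER):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = float(
            np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        )
        new = max(0.0, new)
        if abs(new - tau2) < REML_TOL:
            return new
        tau2 = new
    warnings.warn(
        "REML did not converge within 200 iterations; falling back to DL",
        RuntimeWarning,
        stacklevel=2,
    )
    return tau2_dersimonian_laird(effects)


def estimate_tau2(effects: Sequence[EffectSize], method: str = "REML") -> float:
    """Between-study variance via the requested estimator."""
    if len(effects) < 2:
        raise MetaAnalysisError("estimate_tau2: need at least two effects")
    if method == "DL":
        return tau2_dersimonian_laird(effects)
    if method == "REML":
        return tau2_reml(effects)
    raise ValidationError(f"unknown estimator {method!r}")


# ---------------------------------------------------------------------------
# pooling, heterogeneity, intervals


def pool(effects: Sequence[EffectSize], tau2: float) -> tuple[float, float]:
    """Inverse-variance pooled effect and its standard error (analysis scale)."""
    if len(effects) < 2:
        raise MetaAnalysisError("pool: need at least two effects")
    if tau2 < 0:
        raise ValidationError("pool: tau2 must be >= 0")
    y, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return mu, se


def heterogeneity(effects: Sequence[EffectSize]) -> tuple[float, int, float, float]:
    """Cochran's Q against the fixed-effect mean, its p-value, and I^2 (%)."""
    if len(effects) < 2:
        raise MetaAnalysisError("heterogeneity: need at least two effects")
    y, v = _arrays(effects)
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= df else (q - df) / q * 100.0
    return q, df, p_q, i2


def prediction_interval(
    mu: float, se: float, tau2: float, k: int, level: float = 0.95
) -> tuple[float, float]:
    """t-based interval for the true prevalence of a new setting.

    Uses the t quantile with k-2 degrees of freedom and the combined
    dispersion sqrt(tau^2 + se^2); only defined for k >= 3.
    """
    if k < 3:
        raise MetaAnalysisError("prediction_interval: needs k >= 3")
    t = float(stats.t.ppf((1.0 + level) / 2.0, k - 2))
    half = t * math.sqrt(tau2 + se * se)
    return mu - half, mu + half


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def run_meta(
    corpus: Sequence[StudyEstimate],
    rules: ScreeningRuleSet = DEFAULT_RULES,
    *,
    scale: str = "raw",
    estimator: str = "REML",
    level: float = 0.95,
) -> MetaAnalysisResult:
    """Screen a corpus, pool the survivors, and package the full result.

    Pipeline: screening (including wave selection) -> questionnaire
    correction when the surviving corpus is questionnaire-only -> effect
    sizes -> tau^2 -> pooling -> heterogeneity -> prediction interval.
    The result's provenance records the per-record decisions and whether
    the correction factor was applied.
    """
    if scale not in SCALES:
        raise ValidationError(f"bad scale {scale!r}")
    if estimator not in ESTIMATORS:
        raise ValidationError(f"unknown estimator {estimator!r}")
    decisions = screen_corpus(corpus, rules)
    survivors = included_records(corpus, decisions)
    if len(survivors) < 2:
        raise MetaAnalysisError(
            f"only {len(survivors)} record(s) survive screening; a meta-analysis "
            "needs k >= 2 - derive this group's estimate by borrowing or "
            "averaging instead (estimate derivation module)"
        )
    corrected = False
    if all(r.method == "questionnaire" for r in survivors):
        survivors = correct_corpus(survivors, rules)
        corrected = True

    effects = compute_effects(survivors, scale)
    tau2 = estimate_tau2(effects, estimator)
    mu_scale, se = pool(effects, tau2)
    q, df, p_q, i2 = heterogeneity(effects)
    k = len(effects)

    z = float(stats.norm.ppf((1.0 + level) / 2.0))
    ci_scale = (mu_scale - z * se, mu_scale + z * se)
    pi_scale = prediction_interval(mu_scale, se, tau2, k, level) if k >= 3 else None

    if scale == "logit":
        mu = _expit(mu_scale)
        ci = (_expit(ci_scale[0]), _expit(ci_scale[1]))
        pi = (_expit(pi_scale[0]), _expit(pi_scale[1])) if pi_scale else None
    else:
        mu = _clip01(mu_scale)
        ci = (_clip01(ci_scale[0]), _clip01(ci_scale[1]))
        pi = (_clip01(pi_scale[0]), _clip01(pi_scale[1])) if pi_scale else None

    return MetaAnalysisResult(
        mu_hat=mu,
        se=se,
        ci_low=ci[0],
        ci_high=ci[1],
        tau2=tau2,
        tau=math.sqrt(tau2),
        Q=q,
        df=df,
        p_Q=p_q,
        I2=i2,
        k=k,
        pi_low=pi[0] if pi else None,
        pi_high=pi[1] if pi else None,
        estimator=estimator,
        scale=scale,
        corrected=corrected,
        provenance={
            "decisions": [
                {
                    "study_id": d.study_id,
                    "sample_id": d.sample_id,
                    "included": d.included,
                    "reasons": list(d.reasons),
                }
                for d in decisions
            ],
            "correction_applied": corrected,
            "mu_on_analysis_scale": mu_scale,
        },
    )


def forest_table(effects: Sequence[EffectSize], tau2: float, level: float = 0.95):
    """Per-study rows (y, ci bounds, % weight) for a forest plot export."""
    import pandas as pd

    y, v = _arrays(effects)
    z = float(stats.norm.ppf((1.0 + level) / 2.0))
    w = 1.0 / (v + tau2)
    return pd.DataFrame(
        {
            "y": y,
            "ci_low": y - z * np.sqrt(v),
            "ci_high": y + z * np.sqrt(v),
            "weight_pct": 100.0 * w / w.sum(),
        }
    )
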