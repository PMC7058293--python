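"""Direct head-to-head meta-analysis.

Inverse-variance fixed-effect pooling, DerSimonian-Laird random effects,
Mantel-Haenszel odds-ratio pooling with the Robins-Breslow-Greenland
variance, Cochran's Q / I-squared heterogeneity statistics, and the
heterogeneity-driven model-choice rule (random effects when I2 > 50% or
p_Q < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .data import BinaryArm, RelativeEffect

__all__ = [
    "PairwiseResult",
    "pool_fixed_iv",
    "pool_random_dl",
    "pool_mh_or",
    "cochran_q",
    "choose_model",
    "PairwiseMetaAnalysis",
]


@dataclass(frozen=True)
class PairwiseResult:
    """Pooled direct comparison of one treatment against one reference."""

    treatment: str
    reference: str
    model: str  # "fixed" | "random"
    k_studies: int
    estimate: float  # pooled log effect
    std_err: float
    ci_lower: float  # log scale
    ci_upper: float
    level: float = 0.95
    q: float = math.nan
    df: int = 0
    p_q: float = math.nan
    i2: float = math.nan  # percent
    tau2: float = 0.0

    @property
    def natural_estimate(self) -> float:
        return math.exp(self.estimate)

    @property
    def natural_ci(self) -> tuple:
        return math.exp(self.ci_lower), math.exp(self.ci_upper)


def _check_homogeneous(effects: Sequence[RelativeEffect]):
    if not effects:
        raise ValueError("no effects to pool")
    comps = {(e.treatment_id, e.reference_id) for e in effects}
    if len(comps) > 1:
        raise ValueError(f"mixed comparisons in one pool: {sorted(comps)}")
    if len({e.measure for e in effects}) > 1:
        raise ValueError("mixed measures in one pool")


def _result(effects, model, est, se, level, **extra) -> PairwiseResult:
    z = stats.norm.ppf(0.5 + level / 2)
    e0 = effects[0]
    return PairwiseResult(
        treatment=e0.treatment_id,
        reference=e0.reference_id,
        model=model,
        k_studies=len(effects),
        estimate=est,
        std_err=se,
        ci_lower=est - z * se,
        ci_upper=est + z * se,
        level=level,
        **extra,
    )


def pool_fixed_iv(effects: Sequence[RelativeEffect], level: float = 0.95) -> PairwiseResult:
    """Inverse-variance fixed-effect pool: weights 1/SE_i^2."""
    effects = list(effects)
    _check_homogeneous(effects)
    y = np.array([e.estimate for e in effects])
    w = np.array([1 / e.variance for e in effects])
    est = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    extra = {}
    if len(effects) >= 2:
        q, df, p_q, i2 = cochran_q(effects)
        extra = dict(q=q, df=df, p_q=p_q, i2=i2)
    return _result(effects, "fixed", est, se, level, **extra)


def cochran_q(effects: Sequence[RelativeEffect]):
    """Cochran's Q against the fixed-effect pool, with df, p and I2 (percent)."""
    effects = list(effects)
    _check_homogeneous(effects)
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    y = np.array([e.estimate for e in effects])
    w = np.array([1 / e.variance for e in effects])
    pooled = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - pooled) ** 2))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100) if q > 0 else 0.0
    return q, df, p_q, i2


def pool_random_dl(effects: Sequence[RelativeEffect], level: float = 0.95) -> PairwiseResult:
    """DerSimonian-Laird random-effects pool.

    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w; studies are then re-weighted by 1/(SE_i^2 + tau2).
    """
    effects = list(effects)
    _check_homogeneous(effects)
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs at least 2 studies")
    y = np.array([e.estimate for e in effects])
    w = np.array([1 / e.variance for e in effects])
    q, df, p_q, i2 = cochran_q(effects)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1 / (np.array([e.variance for e in effects]) + tau2)
    est = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    return _result(effects, "random", est, se, level, q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def _tables(arms: Sequence[BinaryArm], treatment: str, reference: str):
    """Per-study 2x2 tables (a, b, c, d) = (trt events, trt non-events,
    ref events, ref non-events)."""
    by_study: dict[str, dict[str, BinaryArm]] = {}
    for a in arms:
        by_study.setdefault(a.study_id, {})[a.treatment_id] = a
    tables = []
    for study in by_study.values():
        if treatment in study and reference in study:
            t, r = study[treatment], study[reference]
            tables.append(
                (float(t.events), float(t.total - t.events),
                 float(r.events), float(r.total - r.events))
            )
    if not tables:
        raise ValueError(f"no study compares {treatment!r} with {reference!r}")
    return tables


def pool_mh_or(
    arms: Sequence[BinaryArm],
    treatment: str,
    reference: str,
    level: float = 0.95,
) -> PairwiseResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio over per-study 2x2 tables.

    SE of the log OR uses the Robins-Breslow-Greenland variance. Tables with a
    zero cell get 0.5 added to all four cells; double-zero tables (no events
    or all events in both arms) are excluded.
    """
    raw = _tables(arms, treatment, reference)
    tables = []
    for a, b, c, d in raw:
        if (a == 0 and c == 0) or (b == 0 and d == 0):
            continue  # double-zero table: no information on the OR
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        tables.append((a, b, c, d))
    if not tables:
        raise ValueError("all tables are double-zero; MH OR undefined")

    R = S = 0.0  # numerator / denominator sums
    pr = ps_qr = qs = 0.0  # RBG variance components
    for a, b, c, d in tables:
        n = a + b + c + d
        r_i = a * d / n
        s_i = b * c / n
        p_i = (a + d) / n
        q_i = (b + c) / n
        R += r_i
        S += s_i
        pr += p_i * r_i
        ps_qr += p_i * s_i + q_i * r_i
        qs += q_i * s_i
    if R == 0 or S == 0:
        raise ValueError("MH OR is degenerate (zero margin in every table)")
    log_or = math.log(R / S)
    var = pr / (2 * R**2) + ps_qr / (2 * R * S) + qs / (2 * S**2)
    se = math.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2)
    return PairwiseResult(
        treatment=treatment,
        reference=reference,
        model="fixed",
        k_studies=len(raw),
        estimate=log_or,
        std_err=se,
        ci_lower=log_or - z * se,
        ci_upper=log_or + z * se,
        level=level,
    )


def choose_model(p_q: float, i2: float) -> str:
    """Model-choice rule: random effects when I2 > 50% and/or p_Q < 0.05."""
    if not (0 <= i2 <= 100):
        raise ValueError(f"I2 must lie in [0, 100], got {i2}")
    if not (0 <= p_q <= 1):
        raise ValueError(f"p_Q must lie in [0, 1], got {p_q}")
    return "random" if (i2 > 50 or p_q < 0.05) else "fixed"


class PairwiseMetaAnalysis(BaseEstimator):
    """Direct meta-analysis of one comparison with automatic model choice.

    Pools a homogeneous set of contrasts with the inverse-variance fixed-effect
    model, switches to DerSimonian-Laird random effects when heterogeneity is
    significant (I2 > 50% or p_Q < 0.05), or applies whichever model is forced
    via ``model``.

    Parameters
    ----------
    model : {"auto", "fixed", "random"}
    level : float, confidence level for the pooled interval.

    Attributes
    ----------
    result_ : PairwiseResult for the selected model.
    fixed_result_, random_result_ : the individual fits (random only for k >= 2).
    """

    def __init__(self, model: str = "auto", level: float = 0.95):
        self.model = model
        self.level = level

    def fit(self, effects: Sequence[RelativeEffect]) -> "PairwiseMetaAnalysis":
        effects = list(effects)
        if self.model not in ("auto", "fixed", "random"):
            raise ValueError(f"unknown model {self.model!r}")
        self.fixed_result_ = pool_fixed_iv(effects, level=self.level)
        self.random_result_ = (
            pool_random_dl(effects, level=self.level) if len(effects) >= 2 else None
        )
        if self.model == "fixed" or self.random_result_ is None:
            self.result_ = self.fixed_result_
        elif self.model == "random":
            self.result_ = self.random_result_
        else:
            chosen = choose_model(self.fixed_result_.p_q, self.fixed_result_.i2)
            self.result_ = (
                self.random_result_ if chosen == "random" else self.fixed_result_
            )
        return self
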