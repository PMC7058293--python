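"""Trial-level data model for contrast-based evidence networks.

Holds the domain types (treatments, study metadata, relative effects, binary
arms, Kaplan-Meier summaries), CSV readers for the package's plain-text
dialects, the Parmar-style reconstructions of a log hazard ratio and its
standard error from published summaries, evidence-network construction, and
the curation summary used to sanity-check a transcribed study table.

All relative effects are stored on the log scale: a
:class:`RelativeEffect` is the pair (estimate, std_err) that the network
meta-analysis likelihood consumes directly.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Treatment",
    "StudyMeta",
    "RelativeEffect",
    "BinaryArm",
    "KMSummary",
    "OutcomeDataset",
    "NetworkSummary",
    "TrialSummary",
    "NetworkConnectivityError",
    "parse_agents",
    "effect_from_ci",
    "effect_from_pvalue_events",
    "effect_from_km",
    "read_contrast_table",
    "read_arm_table",
    "read_study_table",
    "build_network",
    "summarize_trials",
    "load_hcc_trial_table",
]

LOG_HR = "log-hazard-ratio"
LOG_OR = "log-odds-ratio"

_MEASURE_ALIASES = {
    "hr": LOG_HR,
    "loghr": LOG_HR,
    "log-hazard-ratio": LOG_HR,
    "or": LOG_OR,
    "logor": LOG_OR,
    "log-odds-ratio": LOG_OR,
}

_PLACEBO_CODES = {"pla", "placebo", "pbo"}
_DOSE_TOKEN = re.compile(r"\s*\d+(\.\d+)?\s*(mg|mcg|ug|g)\b", re.IGNORECASE)


class NetworkConnectivityError(ValueError):
    """Raised when an evidence network does not form a single connected graph."""

    def __init__(self, components: Sequence[set]):
        self.components = [set(c) for c in components]
        parts = "; ".join(sorted(",".join(sorted(c)) for c in self.components))
        super().__init__(
            f"evidence network is disconnected ({len(self.components)} components: {parts})"
        )


def parse_agents(code: str) -> frozenset[str]:
    """Constituent drug names of a treatment code.

    Combination regimens written ``"A + B"`` list each component; dose
    variants of one drug (``"Van 100mg"``, ``"Van 300mg"``) collapse to the
    same agent; placebo has no agents.
    """
    agents = set()
    for part in code.split("+"):
        name = _DOSE_TOKEN.sub("", part).strip()
        if not name:
            continue
        if name.lower() in _PLACEBO_CODES:
            continue
        agents.add(name)
    return frozenset(agents)


@dataclass(frozen=True)
class Treatment:
    """A node of the evidence network.

    ``agents`` is empty only for the placebo node; dose variants of one drug
    share the agent name so that distinct-drug counts collapse them.
    """

    id: str
    label: str = ""
    agents: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.id:
            raise ValueError("treatment id must be non-empty")
        if self.agents is None:
            object.__setattr__(self, "agents", parse_agents(self.id))
        if not self.agents and self.id.lower() not in _PLACEBO_CODES:
            # a non-placebo node must carry at least one agent
            object.__setattr__(self, "agents", frozenset({self.id}))


@dataclass(frozen=True)
class StudyMeta:
    """Randomized-trial metadata: one (treatment, n, median age) tuple per arm."""

    study_id: str
    year: int
    arms: tuple  # of (treatment_id, n_randomized, median_age or None)

    def __post_init__(self):
        object.__setattr__(self, "arms", tuple(tuple(a) for a in self.arms))
        if len(self.arms) < 2:
            raise ValueError(f"study {self.study_id!r} has fewer than 2 arms")
        seen = set()
        for tid, n, _age in self.arms:
            if n < 1:
                raise ValueError(f"study {self.study_id!r}: arm {tid!r} has n < 1")
            if tid in seen:
                raise ValueError(f"study {self.study_id!r}: duplicate arm {tid!r}")
            seen.add(tid)

    @property
    def total_randomized(self) -> int:
        return sum(n for _, n, _ in self.arms)


@dataclass(frozen=True)
class RelativeEffect:
    """One within-trial contrast on the log scale: the NMA likelihood's datum."""

    study_id: str
    treatment_id: str
    reference_id: str
    measure: str
    estimate: float
    std_err: float
    source: str = "reported_ci"

    def __post_init__(self):
        if self.treatment_id == self.reference_id:
            raise ValueError(
                f"study {self.study_id!r}: contrast of {self.treatment_id!r} with itself"
            )
        if not (math.isfinite(self.std_err) and self.std_err > 0):
            raise ValueError(
                f"study {self.study_id!r}: std_err must be finite and > 0, got {self.std_err}"
            )
        if not math.isfinite(self.estimate):
            raise ValueError(f"study {self.study_id!r}: non-finite estimate")
        if self.measure not in (LOG_HR, LOG_OR):
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def variance(self) -> float:
        return self.std_err**2


@dataclass(frozen=True)
class BinaryArm:
    """Event count out of total for one arm of one study."""

    study_id: str
    treatment_id: str
    events: int
    total: int

    def __post_init__(self):
        if self.total < 1:
            raise ValueError(f"study {self.study_id!r}: arm total must be >= 1")
        if not (0 <= self.events <= self.total):
            raise ValueError(
                f"study {self.study_id!r}: events must lie in [0, total], "
                f"got {self.events}/{self.total}"
            )


@dataclass(frozen=True)
class KMSummary:
    """Tabulated Kaplan-Meier curve for one arm.

    ``time`` is the grid in months, ``survival`` the KM estimate at each grid
    point; ``n_at_risk`` (optional) the numbers at risk at each grid point;
    ``n_enrolled`` the arm's randomized size (used as the censoring-free
    fallback for effective numbers at risk).
    """

    label: str
    time: tuple
    survival: tuple
    n_at_risk: tuple | None = None
    n_enrolled: int | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("time and survival must be equal-length 1-d sequences")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("survival probabilities must lie in (0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing in time")
        object.__setattr__(self, "time", tuple(t))
        object.__setattr__(self, "survival", tuple(s))
        if self.n_at_risk is not None:
            r = np.asarray(self.n_at_risk, dtype=float)
            if r.shape != t.shape:
                raise ValueError("n_at_risk must match the time grid")
            object.__setattr__(self, "n_at_risk", tuple(r))


@dataclass
class OutcomeDataset:
    """A connected evidence network of contrasts and/or binary arms for one endpoint.

    Each study contributes either log-scale contrasts or binary arms, never
    both. ``multiarm_covariance`` optionally maps a study id to the data-level
    covariance matrix between its contrasts (ordered as they appear in
    ``contrasts``) when the trial shares a reference arm.
    """

    measure: str
    treatments: list
    contrasts: list = field(default_factory=list)
    binary_arms: list = field(default_factory=list)
    multiarm_covariance: dict | None = None
    name: str = ""

    def __post_init__(self):
        if self.measure not in (LOG_HR, LOG_OR):
            self.measure = _MEASURE_ALIASES.get(str(self.measure).lower(), None)
            if self.measure is None:
                raise ValueError("measure must be a (log) hazard- or odds-ratio")
        ids = [t.id for t in self.treatments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate treatment ids")
        known = set(ids)
        contrast_studies = {c.study_id for c in self.contrasts}
        arm_studies = {a.study_id for a in self.binary_arms}
        overlap = contrast_studies & arm_studies
        if overlap:
            raise ValueError(
                f"studies {sorted(overlap)} contribute both contrasts and binary arms"
            )
        used = set()
        for c in self.contrasts:
            used.update((c.treatment_id, c.reference_id))
        for a in self.binary_arms:
            used.add(a.treatment_id)
        missing = used - known
        if missing:
            raise ValueError(f"contrasts reference unknown treatments {sorted(missing)}")
        orphans = known - used
        if used and orphans:
            raise ValueError(
                f"treatments {sorted(orphans)} appear in no contrast or arm"
            )

    @property
    def treatment_ids(self) -> list[str]:
        return [t.id for t in self.treatments]

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.contrasts:
            seen.setdefault(c.study_id)
        for a in self.binary_arms:
            seen.setdefault(a.study_id)
        return list(seen)

    @classmethod
    def from_contrasts(cls, contrasts, measure=None, **kw) -> "OutcomeDataset":
        """Build a dataset from contrasts alone, deriving the treatment list."""
        contrasts = list(contrasts)
        if measure is None:
            measure = contrasts[0].measure
        ids: dict[str, None] = {}
        for c in contrasts:
            ids.setdefault(c.reference_id)
            ids.setdefault(c.treatment_id)
        treatments = [Treatment(i) for i in ids]
        return cls(measure=measure, treatments=treatments, contrasts=contrasts, **kw)


# ---------------------------------------------------------------------------
# Effect-size reconstruction (Parmar-style)
# ---------------------------------------------------------------------------


def effect_from_ci(point: float, lower: float, upper: float, level: float = 0.95):
    """Log effect and SE from a natural-scale ratio and its confidence interval.

    SE = (ln upper - ln lower) / (2 z), with z the two-sided normal quantile
    at ``level``.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if not (0 < lower <= point <= upper):
        raise ValueError(
            f"require 0 < lower <= point <= upper, got ({point}, {lower}, {upper})"
        )
    if lower == upper:
        raise ValueError("degenerate interval (lower == upper) gives SE = 0")
    z = stats.norm.ppf(0.5 + level / 2)
    return math.log(point), (math.log(upper) - math.log(lower)) / (2 * z)


def effect_from_pvalue_events(
    p_two_sided: float,
    events_total: int,
    n1: int,
    n2: int,
    favours_treatment: bool = True,
):
    """Log hazard ratio and SE from a two-sided log-rank p-value and event count.

    Uses the approximate variance of the log-rank statistic
    V = e * n1 * n2 / (n1 + n2)^2, so SE = 1/sqrt(V) and the log effect is
    -+ z / sqrt(V) with the sign set by which arm is favoured.
    """
    if not 0 < p_two_sided <= 1:
        raise ValueError(f"p-value must lie in (0, 1], got {p_two_sided}")
    if events_total < 1:
        raise ValueError("events_total must be >= 1")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    v = events_total * n1 * n2 / (n1 + n2) ** 2
    z = stats.norm.ppf(1 - p_two_sided / 2)
    se = 1 / math.sqrt(v)
    est = -z * se if favours_treatment else z * se
    return est, se


def _effective_at_risk(km: KMSummary, interval: int, s_start: float) -> float:
    """Effective number at risk at the start of grid interval ``interval``.

    Interval j spans (t_{j-1}, t_j] with t_{-1} = 0. Prefers reported numbers
    at risk (taken at the previous grid point); falls back to the
    censoring-free expectation n_enrolled * S(t_start).
    """
    if km.n_at_risk is not None:
        return float(km.n_at_risk[interval - 1]) if interval else float(
            km.n_enrolled if km.n_enrolled is not None else km.n_at_risk[0]
        )
    if km.n_enrolled is None:
        raise ValueError(
            f"arm {km.label!r}: need n_at_risk or n_enrolled to form interval variances"
        )
    return km.n_enrolled * s_start


def effect_from_km(control: KMSummary, treated: KMSummary):
    """Pooled log hazard ratio and SE from two tabulated survival curves.

    Each grid interval contributes the log ratio of conditional cumulative
    hazards (which equals the log hazard ratio under proportional hazards)
    with variance 1/e_c + 1/e_t from the expected events per arm
    e = n_eff * (S(t_a) - S(t_b)) / S(t_a). Intervals with fewer than one
    expected event in either arm are dropped; the remainder are pooled by
    inverse variance.
    """
    tc = np.asarray(control.time)
    tt = np.asarray(treated.time)
    if tc.shape != tt.shape or not np.allclose(tc, tt):
        raise ValueError("control and treated curves must share a time grid")
    sc = np.concatenate([[1.0], np.asarray(control.survival)])
    st = np.concatenate([[1.0], np.asarray(treated.survival)])
    if np.any(sc[1:] >= 1) or np.any(st[1:] >= 1):
        raise ValueError("survival must be strictly below 1 beyond time zero")

    ests, variances = [], []
    for j in range(len(tc)):
        rc = sc[j + 1] / sc[j]
        rt = st[j + 1] / st[j]
        if rc >= 1 or rt >= 1:  # no events in the interval in one arm
            continue
        nc = _effective_at_risk(control, j, sc[j])
        nt = _effective_at_risk(treated, j, st[j])
        ec = nc * (1 - rc)
        et = nt * (1 - rt)
        if ec < 1 or et < 1:
            continue
        ests.append(math.log(math.log(rt) / math.log(rc)))
        variances.append(1 / ec + 1 / et)
    if not ests:
        raise ValueError("no usable interval (every interval has < 1 expected event)")
    w = 1 / np.asarray(variances)
    est = float(np.sum(w * np.asarray(ests)) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return est, se


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CONTRAST_KEY_COLS = ["study", "treatment", "reference", "measure"]


def _read_csv(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)) and "\n" in str(source):
        source = io.StringIO(str(source))
    return pd.read_csv(source)


def read_contrast_table(source, name: str = "") -> OutcomeDataset:
    """Read a contrast CSV into an :class:`OutcomeDataset`.

    Columns: ``study, treatment, reference, measure`` and either the
    natural-scale triple ``estimate, ci_lower, ci_upper`` or the log pair
    ``log_estimate, std_err``. Natural-scale rows are converted through
    :func:`effect_from_ci`.
    """
    df = _read_csv(source)
    missing = [c for c in _CONTRAST_KEY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"contrast table is missing required columns {missing}")
    keys = df[["study", "treatment", "reference"]].astype(str)
    dup = keys.duplicated()
    if dup.any():
        rows = keys[dup].apply(tuple, axis=1).tolist()
        raise ValueError(f"duplicate (study, treatment, reference) rows: {rows}")

    has_log = {"log_estimate", "std_err"} <= set(df.columns)
    has_nat = {"estimate", "ci_lower", "ci_upper"} <= set(df.columns)
    if not (has_log or has_nat):
        raise ValueError(
            "contrast table needs (estimate, ci_lower, ci_upper) or (log_estimate, std_err)"
        )

    contrasts = []
    measures = set()
    for _, row in df.iterrows():
        m = _MEASURE_ALIASES.get(str(row["measure"]).strip().lower())
        if m is None:
            raise ValueError(f"unknown measure {row['measure']!r}")
        measures.add(m)
        if has_log and pd.notna(row.get("log_estimate")) and pd.notna(row.get("std_err")):
            est, se = float(row["log_estimate"]), float(row["std_err"])
            source_tag = "reported_ci"
        elif has_nat and pd.notna(row.get("estimate")):
            point, lo, hi = (float(row[c]) for c in ("estimate", "ci_lower", "ci_upper"))
            if lo > hi:
                raise ValueError(
                    f"study {row['study']!r}: ci_lower > ci_upper ({lo} > {hi})"
                )
            est, se = effect_from_ci(point, lo, hi)
            source_tag = "reported_ci"
        else:
            raise ValueError(
                f"study {row['study']!r}: row has neither a CI triple nor a log pair"
            )
        contrasts.append(
            RelativeEffect(
                study_id=str(row["study"]),
                treatment_id=str(row["treatment"]),
                reference_id=str(row["reference"]),
                measure=m,
                estimate=est,
                std_err=se,
                source=source_tag,
            )
        )
    if len(measures) > 1:
        raise ValueError(f"mixed measures in one table: {sorted(measures)}")
    return OutcomeDataset.from_contrasts(contrasts, name=name)


def read_arm_table(source) -> list[BinaryArm]:
    """Read an arm-level CSV (``study, treatment, events, total``)."""
    df = _read_csv(source)
    missing = [c for c in ("study", "treatment", "events", "total") if c not in df.columns]
    if missing:
        raise ValueError(f"arm table is missing required columns {missing}")
    arms = [
        BinaryArm(str(r["study"]), str(r["treatment"]), int(r["events"]), int(r["total"]))
        for _, r in df.iterrows()
    ]
    counts: dict[str, int] = {}
    for a in arms:
        counts[a.study_id] = counts.get(a.study_id, 0) + 1
    lonely = sorted(s for s, k in counts.items() if k < 2)
    if lonely:
        raise ValueError(f"studies with fewer than 2 arms: {lonely}")
    return arms


def read_study_table(source) -> list[StudyMeta]:
    """Read study-metadata CSV (``study, year, treatment, n, median_age``)."""
    df = _read_csv(source)
    missing = [c for c in ("study", "year", "treatment", "n") if c not in df.columns]
    if missing:
        raise ValueError(f"study table is missing required columns {missing}")
    metas = []
    for (study, year), grp in df.groupby(["study", "year"], sort=False):
        arms = []
        for _, r in grp.iterrows():
            age = r.get("median_age")
            age = float(age) if pd.notna(age) else None
            arms.append((str(r["treatment"]), int(r["n"]), age))
        metas.append(StudyMeta(study_id=str(study), year=int(year), arms=tuple(arms)))
    return metas


def load_hcc_trial_table() -> list[StudyMeta]:
    """Bundled metadata of 22 randomized first-line trials in advanced
    hepatocellular carcinoma (study, year, arm treatment, randomized n,
    arm median age; missing ages stored as None)."""
    from importlib import resources

    path = resources.files("bnmeta.datasets").joinpath("hcc_trials.csv")
    with resources.as_file(path) as p:
        return read_study_table(p)


# ---------------------------------------------------------------------------
# Network construction and curation summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    nodes: tuple
    edges: dict  # (a, b) sorted pair -> tuple of study ids
    connected: bool


def _edge_iter(dataset: OutcomeDataset):
    for c in dataset.contrasts:
        yield tuple(sorted((c.treatment_id, c.reference_id))), c.study_id
    by_study: dict[str, list[str]] = {}
    for a in dataset.binary_arms:
        by_study.setdefault(a.study_id, []).append(a.treatment_id)
    for study, arms in by_study.items():
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                yield tuple(sorted((arms[i], arms[j]))), study


def build_network(dataset: OutcomeDataset) -> NetworkSummary:
    """Summarize the evidence graph; error if it is disconnected."""
    if not dataset.contrasts and not dataset.binary_arms:
        raise ValueError("empty dataset")
    g = nx.Graph()
    g.add_nodes_from(dataset.treatment_ids)
    edges: dict[tuple, list] = {}
    for pair, study in _edge_iter(dataset):
        g.add_edge(*pair)
        studies = edges.setdefault(pair, [])
        if study not in studies:
            studies.append(study)
    components = list(nx.connected_components(g))
    if len(components) > 1:
        raise NetworkConnectivityError(components)
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        nodes=tuple(dataset.treatment_ids),
        edges={k: tuple(v) for k, v in sorted(edges.items())},
        connected=True,
    )


@dataclass(frozen=True)
class TrialSummary:
    n_studies: int
    total_patients: int
    min_trial_size: int
    max_trial_size: int
    min_median_age: float
    max_median_age: float
    n_distinct_agents: int


def summarize_trials(metas: Sequence[StudyMeta]) -> TrialSummary:
    """Curation summary of a study-metadata table.

    Total patients sums randomized n over all arms; trial size is the
    within-study arm sum; arm median ages ignore missing values; distinct
    agents count drug names across all treatment nodes with placebo excluded,
    combination components counted individually and dose variants collapsed.
    """
    if not metas:
        raise ValueError("empty study list")
    sizes = [m.total_randomized for m in metas]
    ages = [age for m in metas for _, _, age in m.arms if age is not None]
    agents: set[str] = set()
    for m in metas:
        for tid, _, _ in m.arms:
            agents |= parse_agents(tid)
    return TrialSummary(
        n_studies=len(metas),
        total_patients=int(sum(sizes)),
        min_trial_size=int(min(sizes)),
        max_trial_size=int(max(sizes)),
        min_median_age=float(min(ages)) if ages else math.nan,
        max_median_age=float(max(ages)) if ages else math.nan,
        n_distinct_agents=len(agents),
    )
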