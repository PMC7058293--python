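"""Synthetic evidence networks with known truth.

The generators emulate the structure of a first-line oncology evidence base:
a star/hub geometry in which new agents are compared against an active
standard or placebo, one closed loop (standard vs placebo vs one agent) so
that node-splitting is exercised, 10-22 trials, log-hazard-ratio contrasts
whose standard errors derive from per-arm event counts via the standard
approximation V = 1/e1 + 1/e2, between-trial heterogeneity on the scale
sigma = 0.15-1.0, and the occasional three-arm trial. True basic parameters,
heterogeneity and any injected inconsistency offset are carried in a
:class:`SimTruth` sidecar so every pipeline stage can be tested for recovery
without external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import (
    BinaryArm,
    KMSummary,
    OutcomeDataset,
    RelativeEffect,
    Treatment,
    LOG_HR,
)

__all__ = [
    "TrialDesign",
    "SimTruth",
    "default_truth",
    "simulate_contrast_network",
    "replicate_contrast_draws",
    "simulate_binary_network",
    "inject_inconsistency",
    "simulate_km_tables",
    "triangle_truth",
]


@dataclass(frozen=True)
class TrialDesign:
    """Arms of one simulated trial; the first arm is the baseline.

    ``events`` drive the contrast-level variance (V = 1/e_base + 1/e_arm);
    ``n`` are per-arm sample sizes for the binary-outcome generator.
    """

    study_id: str
    arms: tuple
    events: tuple
    n: tuple

    def __post_init__(self):
        if len(self.arms) < 2:
            raise ValueError(f"trial {self.study_id!r} needs >= 2 arms")
        if len(self.events) != len(self.arms) or len(self.n) != len(self.arms):
            raise ValueError(f"trial {self.study_id!r}: events/n must match arms")


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters of a synthetic network."""

    treatments: tuple
    d: dict  # treatment -> true log effect vs the reference (reference at 0)
    sigma: float
    trials: tuple  # of TrialDesign
    omega: dict = field(default_factory=dict)  # sorted pair -> inconsistency offset
    seed: int = 0
    reference: str = None  # type: ignore[assignment]

    def __post_init__(self):
        ref = self.reference if self.reference is not None else self.treatments[0]
        object.__setattr__(self, "reference", ref)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if abs(self.d.get(ref, 0.0)) > 0:
            raise ValueError("reference treatment must have d = 0")

    def to_json(self) -> str:
        return json.dumps(
            dict(
                treatments=list(self.treatments),
                d=self.d,
                sigma=self.sigma,
                omega={"|".join(k): v for k, v in self.omega.items()},
                seed=self.seed,
                reference=self.reference,
            ),
            indent=2,
        )


def default_truth(sigma: float = 0.15, seed: int = 1, n_extra_trials: int = 0) -> SimTruth:
    """Default star-plus-triangle network: 5 treatments, 12 trials.

    Two hubs (an active standard "Sor" and placebo "Pla") carry the spokes;
    the single closed loop is Pla-Sor-A. One trial has three arms. True
    effects sit in the log-hazard-ratio range typical of targeted-therapy
    trials (natural scale roughly 0.6-1.2).
    """
    treatments = ("Pla", "Sor", "A", "B", "C")
    d = {"Pla": 0.0, "Sor": -0.3, "A": -0.5, "B": 0.15, "C": -0.2}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    # two hubs; A closes the single loop Pla-Sor-A; B and C are spokes of Sor
    pairs = [
        ("Pla", "Sor"),
        ("Pla", "Sor"),
        ("Pla", "Sor"),
        ("Pla", "A"),
        ("Pla", "A"),
        ("Sor", "A"),
        ("Sor", "A"),
        ("Sor", "B"),
        ("Sor", "B"),
        ("Sor", "C"),
        ("Sor", "C"),
    ]
    trials = []
    for i, (base, arm) in enumerate(pairs, start=1):
        e = rng.integers(80, 260, size=2)
        n = e + rng.integers(40, 120, size=2)
        trials.append(
            TrialDesign(f"trial-{i:02d}", (base, arm), tuple(int(x) for x in e), tuple(int(x) for x in n))
        )
    e = rng.integers(80, 260, size=3)
    n = e + rng.integers(40, 120, size=3)
    trials.append(
        TrialDesign("trial-12", ("Sor", "B", "C"), tuple(int(x) for x in e), tuple(int(x) for x in n))
    )
    for j in range(n_extra_trials):
        base, arm = pairs[j % len(pairs)]
        e = rng.integers(80, 260, size=2)
        n = e + rng.integers(40, 120, size=2)
        trials.append(
            TrialDesign(
                f"trial-x{j + 1:02d}", (base, arm), tuple(int(x) for x in e), tuple(int(x) for x in n)
            )
        )
    return SimTruth(
        treatments=treatments, d=d, sigma=sigma, trials=tuple(trials), seed=seed
    )


def triangle_truth(
    omega: float = 0.0,
    seed: int = 1,
    events: int = 200,
    n_per_edge: int = 2,
    sigma: float = 0.0,
) -> SimTruth:
    """Minimal closed-loop network (Pla-Sor-Bri) for node-split validation.

    ``events`` = 200 per arm gives each contrast a standard error of 0.1;
    ``omega`` shifts the direct Pla-Sor evidence away from the loop's
    indirect value.
    """
    trials = tuple(
        TrialDesign(f"t{j}-{i}", pair, (events, events), (events + 100, events + 100))
        for j, pair in enumerate([("Pla", "Sor"), ("Pla", "Bri"), ("Sor", "Bri")])
        for i in range(n_per_edge)
    )
    truth = SimTruth(
        treatments=("Pla", "Sor", "Bri"),
        d={"Pla": 0.0, "Sor": -0.3, "Bri": -0.5},
        sigma=sigma,
        trials=trials,
        seed=seed,
    )
    if omega:
        truth = inject_inconsistency(truth, ("Pla", "Sor"), omega)
    return truth


def _design_graph(truth: SimTruth) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(truth.treatments)
    for t in truth.trials:
        base = t.arms[0]
        for arm in t.arms[1:]:
            g.add_edge(base, arm, study=t.study_id)
    return g


def _check_connected(truth: SimTruth):
    g = _design_graph(truth)
    if not nx.is_connected(nx.Graph(g)):
        comps = list(nx.connected_components(nx.Graph(g)))
        raise ValueError(f"disconnected design ({len(comps)} components)")


def _re_chol(m: int, sigma: float) -> np.ndarray:
    c = 0.5 * (np.eye(m) + np.ones((m, m)))
    return sigma * np.linalg.cholesky(c)


def replicate_contrast_draws(truth: SimTruth, n_rep: int, seed: int | None = None):
    """Vectorized replicate draws of every contrast's observed log effect.

    Returns (y, v, meta): ``y`` with shape (n_rep, n_contrasts), the common
    data-level variances ``v``, and per-contrast (study, treatment, reference)
    tuples. The single-replicate path of :func:`simulate_contrast_network`
    uses exactly these draws.
    """
    _check_connected(truth)
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 2077])
    )
    y_cols, v_cols, meta = [], [], []
    for trial in truth.trials:
        base = trial.arms[0]
        m = len(trial.arms) - 1
        mean = np.empty(m)
        v = np.empty(m)
        for j, arm in enumerate(trial.arms[1:]):
            pair = tuple(sorted((base, arm)))
            mean[j] = truth.d[arm] - truth.d[base] + truth.omega.get(pair, 0.0)
            v[j] = 1.0 / trial.events[0] + 1.0 / trial.events[j + 1]
            meta.append((trial.study_id, arm, base))
        if truth.sigma > 0:
            delta = mean + rng.standard_normal((n_rep, m)) @ _re_chol(m, truth.sigma).T
        else:
            delta = np.broadcast_to(mean, (n_rep, m)).copy()
        y = delta + rng.standard_normal((n_rep, m)) * np.sqrt(v)
        y_cols.append(y)
        v_cols.append(v)
    return np.concatenate(y_cols, axis=1), np.concatenate(v_cols), meta


def simulate_contrast_network(truth: SimTruth, seed: int | None = None):
    """One simulated contrast-level dataset drawn from ``truth``.

    Per trial the true contrasts delta are drawn around d (plus any
    inconsistency offset on flagged edges) with between-trial covariance
    sigma^2 (sigma^2/2 between contrasts of a multi-arm trial); observed
    effects add data-level noise with variance from the design's event counts.
    """
    y, v, meta = replicate_contrast_draws(truth, 1, seed=seed)
    contrasts = [
        RelativeEffect(
            study_id=s,
            treatment_id=t,
            reference_id=r,
            measure=LOG_HR,
            estimate=float(y[0, i]),
            std_err=float(math.sqrt(v[i])),
            source="reported_ci",
        )
        for i, (s, t, r) in enumerate(meta)
    ]
    treatments = [Treatment(t) for t in truth.treatments]
    dataset = OutcomeDataset(
        measure=LOG_HR, treatments=treatments, contrasts=contrasts, name="synthetic"
    )
    return dataset, truth


def simulate_binary_network(
    truth: SimTruth,
    baseline_logit_mean: float = -0.85,
    baseline_logit_sd: float = 0.4,
    seed: int | None = None,
):
    """One simulated arm-level binary dataset drawn from ``truth``.

    Study baseline logits are normal around ``baseline_logit_mean``; arm
    events are binomial with log-odds shifted by the trial's true contrasts
    (same random-effect structure as the contrast generator).
    """
    _check_connected(truth)
    if not -50 < baseline_logit_mean < 50:
        raise ValueError("baseline logit mean out of range")
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 3181])
    )
    arms = []
    for trial in truth.trials:
        base = trial.arms[0]
        m = len(trial.arms) - 1
        mean = np.array(
            [
                truth.d[a] - truth.d[base] + truth.omega.get(tuple(sorted((base, a))), 0.0)
                for a in trial.arms[1:]
            ]
        )
        if truth.sigma > 0:
            delta = mean + _re_chol(m, truth.sigma) @ rng.standard_normal(m)
        else:
            delta = mean
        mu = baseline_logit_mean + baseline_logit_sd * rng.standard_normal()
        logits = np.concatenate([[mu], mu + delta])
        p = 1.0 / (1.0 + np.exp(-logits))
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("degenerate event probabilities")
        r = rng.binomial(np.array(trial.n), p)
        for arm, rr, nn in zip(trial.arms, r, trial.n):
            arms.append(BinaryArm(trial.study_id, arm, int(rr), int(nn)))
    return arms, truth


def inject_inconsistency(truth: SimTruth, edge: tuple, omega: float) -> SimTruth:
    """Shift the direct evidence on ``edge`` by ``omega``; the edge must lie
    on a loop so direct and indirect evidence can disagree."""
    pair = tuple(sorted(edge))
    g = nx.Graph(_design_graph(truth))
    if not g.has_edge(*pair):
        raise ValueError(f"edge {pair} has no direct evidence")
    g.remove_edge(*pair)
    if not nx.has_path(g, pair[0], pair[1]):
        raise ValueError(f"edge {pair} does not lie on a loop")
    new_omega = dict(truth.omega)
    new_omega[pair] = new_omega.get(pair, 0.0) + omega
    return dataclasses.replace(truth, omega=new_omega)


def simulate_km_tables(
    hr: float = 0.5,
    hazard: float = 0.08,
    horizon: float = 24.0,
    grid_step: float = 1.0,
    n_per_arm: int = 1000,
    seed: int = 0,
):
    """Exponential survival in two arms with uniform censoring, tabulated as
    Kaplan-Meier summaries on a regular grid (with numbers at risk).

    The control arm has constant hazard ``hazard`` per month; the treated arm
    ``hazard * hr``. Censoring times are uniform on (horizon/2, horizon),
    mimicking staggered enrolment with administrative cut-off.
    """
    if hr <= 0 or hazard <= 0:
        raise ValueError("hr and hazard must be positive")
    if horizon <= 0 or grid_step <= 0:
        raise ValueError("horizon and grid step must be positive")
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4243]))
    grid = np.arange(grid_step, horizon + 1e-9, grid_step)

    def one_arm(rate, label):
        t = rng.exponential(1.0 / rate, size=n_per_arm)
        c = rng.uniform(horizon / 2, horizon, size=n_per_arm)
        obs = np.minimum(t, c)
        event = t <= c
        kmf = KaplanMeierFitter()
        kmf.fit(obs, event_observed=event)
        surv = kmf.survival_function_at_times(grid).to_numpy()
        at_risk = np.array([(obs >= g).sum() for g in grid], float)
        return surv, at_risk, label

    sc, rc, _ = one_arm(hazard, "control")
    st, rt, _ = one_arm(hazard * hr, "treated")
    # keep the common grid segment where both curves are estimable in (0, 1)
    ok = (sc > 0) & (st > 0) & (sc < 1) & (st < 1)
    if not ok.any():
        raise ValueError("no usable grid point; increase n_per_arm or horizon")
    lo, hi = np.argmax(ok), len(ok) - np.argmax(ok[::-1])
    sl = slice(lo, hi)
    control = KMSummary(
        "control", tuple(grid[sl]), tuple(sc[sl]), tuple(rc[sl]), n_enrolled=n_per_arm
    )
    treated = KMSummary(
        "treated", tuple(grid[sl]), tuple(st[sl]), tuple(rt[sl]), n_enrolled=n_per_arm
    )
    return control, treated, dict(log_hr=math.log(hr), hazard=hazard, seed=seed)
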