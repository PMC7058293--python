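"""Hierarchical Bayesian contrast-based network meta-analysis.

The model follows the standard contrast-based formulation used for evidence
synthesis of randomized trials. For contrast-level data the observed log
effect of trial i is

    y_i ~ Normal(delta_i, V_i)

with, under random effects, delta_i ~ Normal(d_t2(i) - d_t1(i), sigma^2) and
a sigma^2/2 covariance between contrasts of the same multi-arm trial; under
fixed effects delta_i = d_t2 - d_t1. Arm-level binary data enter through
r_ak ~ Binomial(n_ak, p_ak) with logit p_ak = mu_a + delta_ak for non-baseline
arms, sharing the same delta hierarchy. Basic parameters d_k (one per
treatment, reference fixed at zero) carry vague normal priors and the
between-trial standard deviation sigma a Uniform(0, sigma_upper) prior.

The unrelated-mean-effects (UME) structure replaces the consistency relation
d_t2 - d_t1 with a free mean per observed comparison; comparing its deviance
information criterion with the consistency model's is the global
inconsistency check.

Sampling is Markov chain Monte Carlo with conjugate Gibbs updates for d and
delta under the normal likelihood, slice sampling for sigma, and adaptive
random-walk Metropolis steps for binomial-logit parameters. Fixed-effect
models on purely normal data reduce to exact draws from the Gaussian
posterior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .data import OutcomeDataset, build_network

__all__ = [
    "NMAConfig",
    "FitResult",
    "LeagueTable",
    "NetworkMetaAnalysis",
    "fit_nma",
    "dic",
    "league_table",
    "convergence_diagnostics",
    "chain_diagnostics",
]

_INIT_OFFSETS = (0.0, 0.5, -0.5, 1.0)
_MU_PRIOR_SD = 15.0


@dataclass(frozen=True)
class NMAConfig:
    """MCMC and prior configuration.

    ``iterations`` counts total iterations per chain including burn-in, so the
    retained draws per chain are (iterations - burn_in) / thin.
    """

    chains: int = 4
    iterations: int = 100_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 0
    prior_sd_d: float | None = None  # default: 15 * max(1, max |observed log effect|)
    sigma_upper: float = 5.0
    effects: str = "random"  # "fixed" | "random"
    structure: str = "consistency"  # "consistency" | "ume"
    reference: str | None = None

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.effects not in ("fixed", "random"):
            raise ValueError(f"unknown effects model {self.effects!r}")
        if self.structure not in ("consistency", "ume"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.sigma_upper <= 0:
            raise ValueError("sigma_upper must be positive")


# ---------------------------------------------------------------------------
# Internal model representation
# ---------------------------------------------------------------------------


@dataclass
class _NormalStudy:
    rows: np.ndarray  # indices into the global delta vector
    y: np.ndarray
    sigma_inv: np.ndarray  # inverse data-level covariance
    c: np.ndarray  # random-effect correlation block (1 diag, 0.5 off)
    c_inv: np.ndarray


@dataclass
class _BinomStudy:
    study_id: str
    rows: np.ndarray  # delta indices of non-baseline arms
    r: np.ndarray  # events, baseline arm first
    n: np.ndarray  # totals, baseline arm first
    c_inv: np.ndarray


@dataclass
class _Model:
    param_names: list
    X: np.ndarray  # (n_rows, p) relative-effect design
    row_meta: list  # (study_id, treatment_id, reference_id) per delta row
    single_idx: np.ndarray  # singleton normal rows (vectorized Gibbs path)
    single_y: np.ndarray
    single_v: np.ndarray
    multi_normal: list  # _NormalStudy with >= 2 rows or data-level covariance
    binom: list  # _BinomStudy
    c_inv_full: np.ndarray  # block-diagonal RE precision correlation (n x n)
    n_rows: int
    n_data: int  # normal rows + binomial arms
    y_scale: float  # max |observed log effect|, for the default prior scale

    @property
    def has_binom(self) -> bool:
        return bool(self.binom)


def _re_correlation(m: int) -> np.ndarray:
    return 0.5 * (np.eye(m) + np.ones((m, m)))


def _crude_log_or(r, n):
    p = (np.asarray(r, float) + 0.5) / (np.asarray(n, float) + 1.0)
    return np.log(p / (1 - p))


def _build_model(
    dataset: OutcomeDataset,
    structure: str,
    reference: str,
    split_pair: tuple | None = None,
) -> _Model:
    treatments = dataset.treatment_ids
    rows: list = []  # (study, treatment, reference)
    row_study: list = []
    y_list: list = []
    v_list: list = []
    is_normal: list = []

    for c in dataset.contrasts:
        rows.append((c.study_id, c.treatment_id, c.reference_id))
        row_study.append(c.study_id)
        y_list.append(c.estimate)
        v_list.append(c.variance)
        is_normal.append(True)

    binom_by_study: dict[str, list] = {}
    for a in dataset.binary_arms:
        binom_by_study.setdefault(a.study_id, []).append(a)
    binom_structs_raw = []
    for study, arms in binom_by_study.items():
        base = arms[0]
        row_idx = []
        for a in arms[1:]:
            rows.append((study, a.treatment_id, base.treatment_id))
            row_study.append(study)
            y_list.append(np.nan)
            v_list.append(np.nan)
            is_normal.append(False)
            row_idx.append(len(rows) - 1)
        binom_structs_raw.append((study, base, arms[1:], np.array(row_idx)))

    n_rows = len(rows)
    if n_rows == 0:
        raise ValueError("dataset has no relative-effect information")

    # --- design matrix ---------------------------------------------------
    if structure == "consistency":
        param_names = [t for t in treatments if t != reference]
        col = {t: j for j, t in enumerate(param_names)}

        def row_design(t, r):
            x = np.zeros(len(param_names) + (1 if split_pair else 0))
            if t != reference:
                x[col[t]] = 1.0
            if r != reference:
                x[col[r]] = -1.0
            return x

    else:  # UME: one free mean per observed comparison
        pair_order: dict = {}
        for _, t, r in rows:
            pair = tuple(sorted((t, r)))
            pair_order.setdefault(pair, (r, t))
        param_names = [f"{t}.vs.{r}" for (r, t) in pair_order.values()]
        pair_col = {p: j for j, p in enumerate(pair_order)}

        def row_design(t, r):
            x = np.zeros(len(param_names))
            pair = tuple(sorted((t, r)))
            base_r, base_t = pair_order[pair]
            x[pair_col[pair]] = 1.0 if (t, r) == (base_t, base_r) else -1.0
            return x

    direct_col = None
    if split_pair is not None:
        if structure != "consistency":
            raise ValueError("node-splitting requires the consistency structure")
        param_names = list(param_names) + ["__direct__"]
        direct_col = len(param_names) - 1

    X = np.zeros((n_rows, len(param_names)))
    for i, (_, t, r) in enumerate(rows):
        if split_pair is not None and tuple(sorted((t, r))) == tuple(sorted(split_pair)):
            a, b = split_pair  # direct parameter measures b vs a
            X[i, direct_col] = 1.0 if (t, r) == (b, a) else -1.0
        else:
            X[i, : len(param_names) - (1 if split_pair else 0)] = row_design(t, r)[
                : len(param_names) - (1 if split_pair else 0)
            ]

    # --- per-study structure ---------------------------------------------
    study_rows: dict[str, list] = {}
    for i, s in enumerate(row_study):
        study_rows.setdefault(s, []).append(i)

    c_inv_full = np.zeros((n_rows, n_rows))
    single_idx, multi_normal, binom_structs = [], [], []
    user_cov = dataset.multiarm_covariance or {}

    for study, idx in study_rows.items():
        idx_arr = np.array(idx)
        m = len(idx)
        c = _re_correlation(m)
        c_inv = np.linalg.inv(c)
        c_inv_full[np.ix_(idx_arr, idx_arr)] = c_inv
        if is_normal[idx[0]]:
            sd = np.asarray(user_cov[study], float) if study in user_cov else None
            if m == 1 and sd is None:
                single_idx.append(idx[0])
            else:
                cov = sd if sd is not None else np.diag([v_list[i] for i in idx])
                if sd is not None and not np.allclose(sd, sd.T):
                    raise ValueError(f"study {study!r}: covariance must be symmetric")
                multi_normal.append(
                    _NormalStudy(
                        rows=idx_arr,
                        y=np.array([y_list[i] for i in idx]),
                        sigma_inv=np.linalg.inv(cov),
                        c=c,
                        c_inv=c_inv,
                    )
                )

    for study, base, others, row_idx in binom_structs_raw:
        binom_structs.append(
            _BinomStudy(
                study_id=study,
                rows=row_idx,
                r=np.array([base.events] + [a.events for a in others], float),
                n=np.array([base.total] + [a.total for a in others], float),
                c_inv=np.linalg.inv(_re_correlation(len(row_idx))),
            )
        )

    single_idx = np.array(single_idx, dtype=int)
    y_obs = [y for y, ok in zip(y_list, is_normal) if ok]
    scales = [abs(y) for y in y_obs]
    for b in binom_structs:
        lo = _crude_log_or(b.r, b.n)
        scales.extend(np.abs(lo[1:] - lo[0]))
    n_data = len(y_obs) + sum(len(b.r) for b in binom_structs)

    return _Model(
        param_names=param_names,
        X=X,
        row_meta=rows,
        single_idx=single_idx,
        single_y=np.array([y_list[i] for i in single_idx]),
        single_v=np.array([v_list[i] for i in single_idx]),
        multi_normal=multi_normal,
        binom=binom_structs,
        c_inv_full=c_inv_full,
        n_rows=n_rows,
        n_data=n_data,
        y_scale=max(scales) if scales else 1.0,
    )


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def _binom_dev(r, n, p):
    """Saturated residual deviance of binomial observations."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / (n * p)), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - n * p)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


class _SliceSampler:
    """Univariate slice sampler with stepping out, on a bounded support."""

    def __init__(self, width: float, lo: float, hi: float):
        self.w, self.lo, self.hi = width, lo, hi

    def draw(self, x0, logf, rng):
        logy = logf(x0) + math.log(rng.random())
        u = rng.random()
        left = max(self.lo, x0 - u * self.w)
        right = min(self.hi, left + self.w)
        for _ in range(50):
            if left <= self.lo or logf(left) < logy:
                break
            left = max(self.lo, left - self.w)
        for _ in range(50):
            if right >= self.hi or logf(right) < logy:
                break
            right = min(self.hi, right + self.w)
        for _ in range(100):
            x1 = left + rng.random() * (right - left)
            if logf(x1) >= logy:
                return x1
            if x1 < x0:
                left = x1
            else:
                right = x1
        return x0


class _AdaptiveScale:
    def __init__(self, n: int, init: float = 0.5):
        self.scale = np.full(n, init)
        self.accept = np.zeros(n)
        self.count = 0

    def update(self):
        self.count += 1
        if self.count % 50 == 0:
            rate = self.accept / 50.0
            self.scale *= np.exp(1.2 * (rate - 0.44))
            np.clip(self.scale, 1e-3, 20.0, out=self.scale)
            self.accept[:] = 0.0


def _run_chain(model: _Model, cfg: NMAConfig, prior_sd: float, chain: int):
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), chain]))
    p = len(model.param_names)
    n = model.n_rows
    random_effects = cfg.effects == "random"
    X = model.X
    prior_prec = 1.0 / prior_sd**2

    # initial values: spread starting points per chain, seeded
    beta = np.full(p, _INIT_OFFSETS[chain % 4] * 0.1 * prior_sd)
    sigma = cfg.sigma_upper * (chain + 1) / (cfg.chains + 1)
    delta = X @ beta
    if model.single_idx.size:
        delta[model.single_idx] = model.single_y
    for st in model.multi_normal:
        delta[st.rows] = st.y
    mu = np.array([math.log((b.r[0] + 0.5) / (b.n[0] - b.r[0] + 0.5)) for b in model.binom])

    pure_normal_fixed = (not random_effects) and not model.has_binom
    if pure_normal_fixed:
        # exact Gaussian posterior: precompute its Cholesky factor once
        prec = prior_prec * np.eye(p)
        rhs = np.zeros(p)
        if model.single_idx.size:
            Xs = X[model.single_idx]
            prec += (Xs / model.single_v[:, None]).T @ Xs
            rhs += Xs.T @ (model.single_y / model.single_v)
        for st in model.multi_normal:
            Xb = X[st.rows]
            prec += Xb.T @ st.sigma_inv @ Xb
            rhs += Xb.T @ (st.sigma_inv @ st.y)
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)

    A0 = X.T @ model.c_inv_full @ X  # for the conjugate beta update (random effects)
    slice_sigma = _SliceSampler(width=0.25, lo=1e-9, hi=cfg.sigma_upper)
    mh_delta = _AdaptiveScale(n)
    mh_mu = _AdaptiveScale(len(model.binom))
    mh_beta = _AdaptiveScale(p)

    n_keep = (cfg.iterations - cfg.burn_in) // cfg.thin
    beta_out = np.empty((n_keep, p))
    sigma_out = np.empty(n_keep) if random_effects else None
    dev_out = np.empty(n_keep)
    theta_sum = np.zeros(n)  # posterior-mean shrunken effects (normal rows)
    eta_sums = [np.zeros(len(b.r)) for b in model.binom]
    kept = 0

    def binom_loglik_study(k, mu_k, dl):
        b = model.binom[k]
        eta = np.concatenate([[mu_k], mu_k + dl])
        pr = expit(eta)
        pr = np.clip(pr, 1e-12, 1 - 1e-12)
        return float(np.sum(b.r * np.log(pr) + (b.n - b.r) * np.log(1 - pr)))

    def full_loglik_fixed(bvec):
        """Log joint (up to a constant) for fixed effects with binomial data."""
        th = X @ bvec
        ll = -0.5 * prior_prec * float(bvec @ bvec)
        if model.single_idx.size:
            ll -= 0.5 * float(
                np.sum((model.single_y - th[model.single_idx]) ** 2 / model.single_v)
            )
        for st in model.multi_normal:
            e = st.y - th[st.rows]
            ll -= 0.5 * float(e @ st.sigma_inv @ e)
        for k, b in enumerate(model.binom):
            ll += binom_loglik_study(k, mu[k], th[b.rows])
        return ll

    for it in range(cfg.iterations):
        adapting = it < cfg.burn_in
        if pure_normal_fixed:
            beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
            theta = X @ beta
        elif not random_effects:
            # fixed effects with binomial arms: componentwise random-walk MH
            ll = full_loglik_fixed(beta)
            for j in range(p):
                prop = beta.copy()
                prop[j] += mh_beta.scale[j] * rng.standard_normal()
                ll_prop = full_loglik_fixed(prop)
                if math.log(rng.random()) < ll_prop - ll:
                    beta, ll = prop, ll_prop
                    mh_beta.accept[j] += 1
            theta = X @ beta
            delta = theta
        else:
            m_rows = X @ beta
            s2 = sigma * sigma
            # delta | beta, sigma, data (conjugate for normal rows)
            if model.single_idx.size:
                prec_i = 1.0 / s2 + 1.0 / model.single_v
                mean_i = (m_rows[model.single_idx] / s2 + model.single_y / model.single_v) / prec_i
                delta[model.single_idx] = mean_i + rng.standard_normal(
                    model.single_idx.size
                ) / np.sqrt(prec_i)
            for st in model.multi_normal:
                prec_b = st.c_inv / s2 + st.sigma_inv
                rhs_b = st.c_inv @ m_rows[st.rows] / s2 + st.sigma_inv @ st.y
                chol_b = np.linalg.cholesky(prec_b)
                mean_b = np.linalg.solve(prec_b, rhs_b)
                delta[st.rows] = mean_b + np.linalg.solve(
                    chol_b.T, rng.standard_normal(len(st.rows))
                )
            # delta for binomial rows: random-walk MH with conditional prior
            for k, b in enumerate(model.binom):
                lam = b.c_inv / s2
                for jj, i in enumerate(b.rows):
                    var_c = 1.0 / lam[jj, jj]
                    dev_others = delta[b.rows] - m_rows[b.rows]
                    mean_c = m_rows[i] - var_c * (
                        lam[jj] @ dev_others - lam[jj, jj] * dev_others[jj]
                    )
                    cur = delta[i]
                    prop = cur + mh_delta.scale[i] * rng.standard_normal()
                    dl = delta[b.rows].copy()
                    ll_cur = binom_loglik_study(k, mu[k], dl)
                    dl[jj] = prop
                    ll_prop = binom_loglik_study(k, mu[k], dl)
                    lr = (
                        ll_prop
                        - ll_cur
                        - 0.5 * ((prop - mean_c) ** 2 - (cur - mean_c) ** 2) / var_c
                    )
                    if math.log(rng.random()) < lr:
                        delta[i] = prop
                        mh_delta.accept[i] += 1
            # beta | delta, sigma (conjugate)
            prec = A0 / s2 + prior_prec * np.eye(p)
            rhs = X.T @ (model.c_inv_full @ delta) / s2
            chol_p = np.linalg.cholesky(prec)
            beta = np.linalg.solve(prec, rhs) + np.linalg.solve(
                chol_p.T, rng.standard_normal(p)
            )
            # sigma | delta, beta (slice)
            e = delta - X @ beta
            qf = float(e @ model.c_inv_full @ e)
            sigma = slice_sigma.draw(
                sigma, lambda s: -n * math.log(s) - qf / (2 * s * s), rng
            )
            theta = delta

        # baseline logits of binomial studies
        for k, b in enumerate(model.binom):
            cur = mu[k]
            prop = cur + mh_mu.scale[k] * rng.standard_normal()
            lr = (
                binom_loglik_study(k, prop, delta[b.rows])
                - binom_loglik_study(k, cur, delta[b.rows])
                - 0.5 * (prop**2 - cur**2) / _MU_PRIOR_SD**2
            )
            if math.log(rng.random()) < lr:
                mu[k] = prop
                mh_mu.accept[k] += 1

        if adapting:
            mh_delta.update()
            mh_mu.update()
            mh_beta.update()
            continue
        if (it - cfg.burn_in) % cfg.thin:
            continue

        dev = 0.0
        if model.single_idx.size:
            dev += float(
                np.sum((model.single_y - theta[model.single_idx]) ** 2 / model.single_v)
            )
        for st in model.multi_normal:
            e = st.y - theta[st.rows]
            dev += float(e @ st.sigma_inv @ e)
        for k, b in enumerate(model.binom):
            eta = np.concatenate([[mu[k]], mu[k] + delta[b.rows]])
            dev += _binom_dev(b.r, b.n, expit(eta))
            eta_sums[k] += eta
        theta_sum += theta
        beta_out[kept] = beta
        if random_effects:
            sigma_out[kept] = sigma
        dev_out[kept] = dev
        kept += 1

    return beta_out[:kept], (sigma_out[:kept] if random_effects else None), dev_out[:kept], theta_sum / max(kept, 1), [s / max(kept, 1) for s in eta_sums], kept


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Posterior samples and deviance summaries of one NMA fit."""

    treatments: list
    reference: str
    param_names: list
    structure: str
    effects: str
    measure: str
    config: NMAConfig
    beta_chains: np.ndarray  # (chains, draws, p)
    sigma_chains: np.ndarray | None  # (chains, draws) for random effects
    deviance_chains: np.ndarray  # (chains, draws)
    dbar: float
    p_d: float
    dic_: float
    n_data: int
    prior_sd_d: float

    @property
    def beta_samples(self) -> np.ndarray:
        """Pooled basic-parameter draws, (draws, p)."""
        c, s, p = self.beta_chains.shape
        return self.beta_chains.reshape(c * s, p)

    @property
    def sigma_samples(self) -> np.ndarray | None:
        if self.sigma_chains is None:
            return None
        return self.sigma_chains.reshape(-1)

    @property
    def d_samples(self) -> np.ndarray:
        """Treatment-effect draws vs the reference, (draws, K), reference
        column identically zero, columns ordered as ``treatments``."""
        if self.structure != "consistency":
            raise ValueError("basic parameters are defined only under consistency")
        pooled = self.beta_samples
        cols = {name: j for j, name in enumerate(self.param_names)}
        out = np.zeros((pooled.shape[0], len(self.treatments)))
        for k, t in enumerate(self.treatments):
            if t != self.reference:
                out[:, k] = pooled[:, cols[t]]
        return out

    def contrast_samples(self, treatment: str, reference: str) -> np.ndarray:
        d = self.d_samples
        idx = {t: k for k, t in enumerate(self.treatments)}
        return d[:, idx[treatment]] - d[:, idx[reference]]

    def sigma_summary(self, level: float = 0.95):
        s = self.sigma_samples
        if s is None:
            return None
        lo, hi = np.quantile(s, [(1 - level) / 2, (1 + level) / 2])
        return float(np.median(s)), float(lo), float(hi)


def _default_prior_sd(model: _Model, cfg: NMAConfig) -> float:
    if cfg.prior_sd_d is not None:
        return float(cfg.prior_sd_d)
    return 15.0 * max(1.0, model.y_scale)


def _fit(dataset: OutcomeDataset, cfg: NMAConfig, split_pair=None) -> FitResult:
    build_network(dataset)  # raises on disconnected networks
    reference = cfg.reference or dataset.treatment_ids[0]
    if reference not in dataset.treatment_ids:
        raise ValueError(f"reference treatment {reference!r} not in dataset")
    model = _build_model(dataset, cfg.structure, reference, split_pair=split_pair)
    prior_sd = _default_prior_sd(model, cfg)

    betas, sigmas, devs, theta_means, eta_means = [], [], [], [], []
    for chain in range(cfg.chains):
        b, s, d, th, et, kept = _run_chain(model, cfg, prior_sd, chain)
        betas.append(b)
        sigmas.append(s)
        devs.append(d)
        theta_means.append(th)
        eta_means.append(et)

    beta_chains = np.stack(betas)
    sigma_chains = np.stack(sigmas) if cfg.effects == "random" else None
    dev_chains = np.stack(devs)

    # plug-in deviance at the posterior mean of the shrunken effects
    theta_bar = np.mean(np.stack(theta_means), axis=0)
    dhat = 0.0
    if model.single_idx.size:
        dhat += float(
            np.sum((model.single_y - theta_bar[model.single_idx]) ** 2 / model.single_v)
        )
    for st in model.multi_normal:
        e = st.y - theta_bar[st.rows]
        dhat += float(e @ st.sigma_inv @ e)
    for k, b in enumerate(model.binom):
        eta_bar = np.mean(np.stack([em[k] for em in eta_means]), axis=0)
        dhat += _binom_dev(b.r, b.n, expit(eta_bar))
    dbar = float(np.mean(dev_chains))
    p_d = dbar - dhat

    return FitResult(
        treatments=list(dataset.treatment_ids),
        reference=reference,
        param_names=list(model.param_names),
        structure=cfg.structure,
        effects=cfg.effects,
        measure=dataset.measure,
        config=cfg,
        beta_chains=beta_chains,
        sigma_chains=sigma_chains,
        deviance_chains=dev_chains,
        dbar=dbar,
        p_d=p_d,
        dic_=dbar + p_d,
        n_data=model.n_data,
        prior_sd_d=prior_sd,
    )


class NetworkMetaAnalysis(BaseEstimator):
    """Bayesian contrast-based network meta-analysis estimator.

    Parameters mirror :class:`NMAConfig`; ``fit`` takes an
    :class:`~bnmeta.data.OutcomeDataset` and exposes the posterior through
    fitted attributes.

    Attributes
    ----------
    result_ : FitResult with pooled posterior draws.
    d_samples_ : (draws, K) array of treatment effects vs the reference.
    sigma_samples_ : between-trial SD draws (random effects only).
    dic_, dbar_, p_d_ : deviance summaries.
    """

    def __init__(
        self,
        effects: str = "random",
        structure: str = "consistency",
        chains: int = 4,
        iterations: int = 100_000,
        burn_in: int = 50_000,
        thin: int = 10,
        seed: int = 0,
        prior_sd_d: float | None = None,
        sigma_upper: float = 5.0,
        reference: str | None = None,
    ):
        self.effects = effects
        self.structure = structure
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_sd_d = prior_sd_d
        self.sigma_upper = sigma_upper
        self.reference = reference

    def _config(self) -> NMAConfig:
        return NMAConfig(
            chains=self.chains,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            prior_sd_d=self.prior_sd_d,
            sigma_upper=self.sigma_upper,
            effects=self.effects,
            structure=self.structure,
            reference=self.reference,
        )

    def fit(self, dataset: OutcomeDataset) -> "NetworkMetaAnalysis":
        self.result_ = _fit(dataset, self._config())
        self.treatments_ = self.result_.treatments
        self.reference_ = self.result_.reference
        if self.structure == "consistency":
            self.d_samples_ = self.result_.d_samples
        self.sigma_samples_ = self.result_.sigma_samples
        self.dbar_ = self.result_.dbar
        self.p_d_ = self.result_.p_d
        self.dic_ = self.result_.dic_
        return self


def fit_nma(dataset: OutcomeDataset, config: NMAConfig | None = None, **kw) -> FitResult:
    """Functional wrapper over :class:`NetworkMetaAnalysis`."""
    cfg = config if config is not None else NMAConfig(**kw)
    if kw and config is not None:
        cfg = replace(config, **kw)
    return _fit(dataset, cfg)


def dic(fit: FitResult):
    """(Dbar, pD, DIC): posterior mean residual deviance, effective number of
    parameters, and their sum."""
    return fit.dbar, fit.p_d, fit.dic_


# ---------------------------------------------------------------------------
# League table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeagueTable:
    """All pairwise posterior relative effects on the natural scale.

    ``cell(r, c)`` is the effect of the column treatment relative to the row
    treatment: median and credible interval of exp(d_col - d_row). Medians are
    taken on the log scale, so reciprocal cells multiply to one exactly.
    """

    treatments: tuple
    median: np.ndarray
    cri_lower: np.ndarray
    cri_upper: np.ndarray
    level: float

    def cell(self, row: str, col: str):
        i, j = self.treatments.index(row), self.treatments.index(col)
        return self.median[i, j], self.cri_lower[i, j], self.cri_upper[i, j]

    def to_frame(self):
        import pandas as pd

        labels = list(self.treatments)
        out = pd.DataFrame(index=labels, columns=labels, dtype=object)
        for i, r in enumerate(labels):
            for j, c in enumerate(labels):
                out.iloc[i, j] = (
                    r
                    if i == j
                    else f"{self.median[i, j]:.2f} "
                    f"({self.cri_lower[i, j]:.2f}, {self.cri_upper[i, j]:.2f})"
                )
        return out

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for i, r in enumerate(self.treatments):
            for j, c in enumerate(self.treatments):
                if i == j:
                    continue
                rows.append(
                    dict(
                        treatment=c,
                        reference=r,
                        median=self.median[i, j],
                        cri_low=self.cri_lower[i, j],
                        cri_high=self.cri_upper[i, j],
                    )
                )
        return pd.DataFrame(rows)


def league_table(fit: FitResult, order: Sequence[str] | None = None, level: float = 0.95) -> LeagueTable:
    """League table from posterior draws of the basic parameters."""
    treatments = list(order) if order is not None else list(fit.treatments)
    unknown = set(treatments) - set(fit.treatments)
    if unknown:
        raise ValueError(f"unknown treatments in order: {sorted(unknown)}")
    d = fit.d_samples
    idx = {t: k for k, t in enumerate(fit.treatments)}
    k = len(treatments)
    med = np.ones((k, k))
    lo = np.ones((k, k))
    hi = np.ones((k, k))
    alpha = (1 - level) / 2
    for i, r in enumerate(treatments):
        for j, c in enumerate(treatments):
            if i >= j:
                continue
            diff = d[:, idx[c]] - d[:, idx[r]]
            m = float(np.median(diff))
            ql, qh = np.quantile(diff, [alpha, 1 - alpha])
            med[i, j], lo[i, j], hi[i, j] = math.exp(m), math.exp(ql), math.exp(qh)
            med[j, i], lo[j, i], hi[j, i] = math.exp(-m), math.exp(-qh), math.exp(-ql)
    return LeagueTable(
        treatments=tuple(treatments), median=med, cri_lower=lo, cri_upper=hi, level=level
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def _autocorr_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    var = float(x @ x)
    if var == 0:
        return np.zeros(max_lag)
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[: max_lag + 1].real / var
    return acf[1 : max_lag + 1]


def chain_diagnostics(samples: np.ndarray, max_lag: int = 50):
    """Split-chain PSRF, pooled autocorrelation (lags 1..max_lag) and ESS for
    one scalar parameter sampled as a (chains, draws) array.

    PSRF is unavailable (None) for a single chain; chains frozen at different
    constants yield an infinite PSRF. ESS uses the rank-normalized bulk
    estimate.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    c, s = samples.shape
    acf = np.mean([_autocorr_1d(ch, min(max_lag, s - 1)) for ch in samples], axis=0)

    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(az.convert_to_dataset(samples))["x"])

    if c < 2:
        return None, acf, ess
    half = s // 2
    split = samples[:, : 2 * half].reshape(c * 2, half)
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = float(np.mean(variances))
    b = half * float(np.var(means, ddof=1))
    if w == 0:
        psrf = 1.0 if b == 0 else math.inf
    else:
        psrf = math.sqrt(((half - 1) / half * w + b / half) / w)
    return psrf, acf, ess


def convergence_diagnostics(fit: FitResult, max_lag: int = 50) -> dict:
    """Per-parameter PSRF, autocorrelation (lags 1..max_lag) and ESS."""
    out = {}
    for j, name in enumerate(fit.param_names):
        out[name] = chain_diagnostics(fit.beta_chains[:, :, j], max_lag)
    if fit.sigma_chains is not None:
        out["sigma"] = chain_diagnostics(fit.sigma_chains, max_lag)
    return out
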