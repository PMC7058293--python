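"""Bayesian NMA: closed-form limits, GLS agreement, DIC, diagnostics, league tables."""

import dataclasses
import math

import numpy as np
import pytest

from bnmeta.data import LOG_OR, OutcomeDataset, Treatment
from bnmeta.nma import (
    NMAConfig,
    NetworkMetaAnalysis,
    chain_diagnostics,
    convergence_diagnostics,
    dic,
    fit_nma,
    league_table,
)
from bnmeta.simulate import default_truth, simulate_binary_network, simulate_contrast_network

from conftest import fit_from_d, make_dataset


def gls_solution(dataset, reference):
    """Independent generalized-least-squares oracle for fixed-effect NMA:
    weighted normal equations on the contrast design matrix, no prior."""
    params = [t for t in dataset.treatment_ids if t != reference]
    col = {t: j for j, t in enumerate(params)}
    x = np.zeros((len(dataset.contrasts), len(params)))
    y = np.empty(len(dataset.contrasts))
    w = np.empty(len(dataset.contrasts))
    for i, c in enumerate(dataset.contrasts):
        if c.treatment_id != reference:
            x[i, col[c.treatment_id]] = 1.0
        if c.reference_id != reference:
            x[i, col[c.reference_id]] = -1.0
        y[i] = c.estimate
        w[i] = 1.0 / c.variance
    a = x.T @ (x * w[:, None])
    b = x.T @ (w * y)
    return dict(zip(params, np.linalg.solve(a, b)))


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(chains=1),
            dict(burn_in=200, iterations=100),
            dict(thin=0),
            dict(effects="mixed"),
            dict(structure="loop"),
            dict(sigma_upper=-1.0),
        ],
    )
    def test_invalid_config(self, kw):
        with pytest.raises(ValueError):
            NMAConfig(**kw)


class TestClosedFormPosteriors:
    def test_single_datum_posterior_tracks_likelihood(self):
        """With a vague prior, one contrast's posterior is its likelihood."""
        ds = make_dataset([("s1", "B", "A", -0.5, 0.1)])
        fit = fit_nma(
            ds, chains=2, iterations=3000, burn_in=1000, thin=1,
            effects="fixed", prior_sd_d=15.0, seed=3,
        )
        d_b = fit.d_samples[:, fit.treatments.index("B")]
        assert np.mean(d_b) == pytest.approx(-0.5, abs=0.01)
        assert np.std(d_b) == pytest.approx(0.1, abs=0.01)

    def test_chain_indirect_estimate_adds_normals(self):
        """A-B-C chain: d_C = y1 + y2 with sd sqrt(V1 + V2)."""
        ds = make_dataset([("s1", "B", "A", 0.3, 0.1), ("s2", "C", "B", 0.2, 0.1)])
        fit = fit_nma(
            ds, chains=2, iterations=3000, burn_in=1000, thin=1,
            effects="fixed", prior_sd_d=15.0, seed=3,
        )
        d_c = fit.d_samples[:, fit.treatments.index("C")]
        assert np.mean(d_c) == pytest.approx(0.5, abs=0.012)
        assert np.std(d_c) == pytest.approx(math.sqrt(0.02), abs=0.012)

    def test_fixed_effect_matches_gls_oracle(self, reduced_cfg):
        """Fixed-effect posterior means match independent GLS within 0.02."""
        rng = np.random.default_rng(17)
        rows = []
        pairs = [("B", "A"), ("C", "A"), ("C", "B"), ("D", "B"), ("D", "C"), ("B", "A")]
        for i, (t, r) in enumerate(pairs):
            rows.append((f"s{i}", t, r, rng.normal(0, 0.5), rng.uniform(0.08, 0.25)))
        ds = make_dataset(rows)
        cfg = dataclasses.replace(
            reduced_cfg, effects="fixed", iterations=4000, burn_in=1000, thin=1
        )
        fit = fit_nma(ds, cfg)
        oracle = gls_solution(ds, fit.reference)
        d = fit.d_samples
        for t, val in oracle.items():
            assert np.mean(d[:, fit.treatments.index(t)]) == pytest.approx(val, abs=0.02)


class TestSamplerProperties:
    def test_same_seed_bit_identical(self, reduced_cfg):
        ds, _ = simulate_contrast_network(default_truth(seed=3))
        f1 = fit_nma(ds, reduced_cfg)
        f2 = fit_nma(ds, reduced_cfg)
        assert np.array_equal(f1.beta_chains, f2.beta_chains)
        assert np.array_equal(f1.sigma_chains, f2.sigma_chains)

    def test_reference_invariance_of_contrasts(self, reduced_cfg):
        """Refitting with another reference shifts all d but leaves every
        pairwise contrast's posterior median within Monte-Carlo error."""
        ds, _ = simulate_contrast_network(default_truth(seed=5))
        cfg = dataclasses.replace(reduced_cfg, iterations=3000, burn_in=1000, thin=1)
        f_pla = fit_nma(ds, dataclasses.replace(cfg, reference="Pla"))
        f_sor = fit_nma(ds, dataclasses.replace(cfg, reference="Sor"))
        for t, r in [("A", "B"), ("Sor", "Pla"), ("C", "A")]:
            m1 = np.median(f_pla.contrast_samples(t, r))
            m2 = np.median(f_sor.contrast_samples(t, r))
            assert m1 == pytest.approx(m2, abs=0.03)

    def test_sigma_concentrates_when_data_homogeneous(self, reduced_cfg):
        """sigma posterior median stays small on data simulated with sigma=0."""
        medians = []
        for rep in range(10):
            ds, _ = simulate_contrast_network(default_truth(sigma=0.0, seed=400 + rep))
            fit = fit_nma(ds, dataclasses.replace(reduced_cfg, seed=rep))
            medians.append(fit.sigma_summary()[0])
        assert np.median(medians) < 0.15

    def test_sigma_respects_prior_bound(self, reduced_cfg):
        ds, _ = simulate_contrast_network(default_truth(seed=8))
        fit = fit_nma(ds, dataclasses.replace(reduced_cfg, sigma_upper=0.4))
        assert fit.sigma_samples.max() < 0.4
        assert fit.sigma_samples.min() > 0

    def test_rejects_disconnected_network(self, reduced_cfg):
        ds = make_dataset([("s1", "B", "A", 0.1, 0.1), ("s2", "D", "C", 0.1, 0.1)])
        with pytest.raises(ValueError, match="disconnected"):
            fit_nma(ds, reduced_cfg)

    def test_binary_arm_likelihood_recovers_null(self, reduced_cfg):
        """Arm-level binomial data simulated with all d = 0: every posterior
        mean stays near zero."""
        truth = default_truth(sigma=0.0, seed=21)
        truth = dataclasses.replace(truth, d={t: 0.0 for t in truth.treatments})
        arms, _ = simulate_binary_network(truth)
        ds = OutcomeDataset(
            measure=LOG_OR,
            treatments=[Treatment(t) for t in truth.treatments],
            binary_arms=arms,
        )
        cfg = dataclasses.replace(
            reduced_cfg, iterations=3000, burn_in=1500, thin=1, effects="random"
        )
        fit = fit_nma(ds, cfg)
        assert fit.n_data == sum(len(t.arms) for t in truth.trials)
        d_means = fit.d_samples.mean(axis=0)
        assert np.all(np.abs(d_means) < 0.35)


class TestDIC:
    def test_fixed_vs_random_on_homogeneous_data(self, reduced_cfg):
        """With sigma_true = 0 the models agree (DIC gap < 3) and the random
        model spends more effective parameters."""
        gaps, pd_gaps = [], []
        for rep in range(3):
            ds, _ = simulate_contrast_network(default_truth(sigma=0.0, seed=600 + rep))
            f_fix = fit_nma(ds, dataclasses.replace(reduced_cfg, effects="fixed", seed=rep))
            f_ran = fit_nma(ds, dataclasses.replace(reduced_cfg, effects="random", seed=rep))
            gaps.append(abs(f_fix.dic_ - f_ran.dic_))
            pd_gaps.append(f_ran.p_d - f_fix.p_d)
        assert np.median(gaps) < 3
        assert np.median(pd_gaps) > 0

    def test_dbar_calibrated_on_well_specified_data(self, reduced_cfg):
        """Mean residual deviance per datum near 1 for a correct model."""
        ratios = []
        for rep in range(6):
            ds, _ = simulate_contrast_network(default_truth(sigma=0.15, seed=700 + rep))
            fit = fit_nma(ds, dataclasses.replace(reduced_cfg, seed=rep))
            ratios.append(fit.dbar / fit.n_data)
        assert 0.8 < np.mean(ratios) < 1.2

    def test_ume_saturates_single_study_star(self, reduced_cfg):
        """UME on one study per comparison fits exactly: Dbar = n params."""
        ds = make_dataset(
            [("s1", "B", "A", 0.3, 0.1), ("s2", "C", "A", -0.2, 0.1), ("s3", "D", "A", 0.5, 0.1)]
        )
        cfg = dataclasses.replace(
            reduced_cfg, effects="fixed", structure="ume", iterations=4000, burn_in=1000, thin=1
        )
        fit = fit_nma(ds, cfg)
        assert fit.dbar == pytest.approx(len(ds.contrasts), abs=0.5)
        dbar, p_d, dic_val = dic(fit)
        assert dic_val == pytest.approx(dbar + p_d)
        assert p_d >= -0.1


class TestLeagueTable:
    def test_three_draw_enumeration(self):
        fit = fit_from_d(["A", "B"], "A", [[0.1], [0.2], [0.3]])
        lt = league_table(fit)
        assert lt.cell("A", "B")[0] == pytest.approx(math.exp(0.2))
        assert lt.cell("B", "A")[0] == pytest.approx(math.exp(-0.2))

    def test_identical_treatments_give_unity(self):
        fit = fit_from_d(["A", "B"], "A", [[0.0]] * 5)
        lt = league_table(fit)
        assert lt.cell("A", "B")[0] == 1.0 and lt.cell("B", "A")[0] == 1.0

    def test_reciprocity_machine_precision(self, reduced_cfg):
        ds, _ = simulate_contrast_network(default_truth(seed=2))
        lt = league_table(fit_nma(ds, reduced_cfg))
        prod = lt.median * lt.median.T
        assert np.max(np.abs(prod - 1)) < 1e-12
        # CrI bounds mirror as well: lower(r,c) = 1/upper(c,r)
        assert np.max(np.abs(lt.cri_lower * lt.cri_upper.T - 1)) < 1e-12

    def test_unknown_treatment_rejected(self):
        fit = fit_from_d(["A", "B"], "A", [[0.1], [0.2]])
        with pytest.raises(ValueError):
            league_table(fit, order=["A", "Z"])


class TestDiagnostics:
    def test_iid_chains_look_converged(self):
        rng = np.random.default_rng(9)
        psrf, acf, ess = chain_diagnostics(rng.standard_normal((4, 5000)))
        assert psrf < 1.01
        assert abs(acf[0]) < 0.05
        assert ess > 5000

    def test_disjoint_constant_chains_flagged(self):
        chains = np.stack([np.zeros(100), np.ones(100)])
        psrf, _, _ = chain_diagnostics(chains)
        assert math.isinf(psrf)

    def test_ar1_chain_has_low_ess(self):
        rng = np.random.default_rng(4)
        n = 5000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        psrf, acf, ess = chain_diagnostics(x[None, :])
        assert psrf is None  # single chain: PSRF unavailable
        assert acf[0] == pytest.approx(0.9, abs=0.05)
        assert ess / n < 0.15

    def test_fit_diagnostics_cover_all_parameters(self, reduced_cfg):
        ds, _ = simulate_contrast_network(default_truth(seed=6))
        fit = fit_nma(ds, reduced_cfg)
        diag = convergence_diagnostics(fit)
        assert set(diag) == set(fit.param_names) | {"sigma"}
        for psrf, acf, ess in diag.values():
            assert psrf < 1.2 and len(acf) == 50 and ess > 50


class TestEstimatorInterface:
    def test_sklearn_params_and_fitted_attributes(self, reduced_cfg):
        ds, _ = simulate_contrast_network(default_truth(seed=4))
        est = NetworkMetaAnalysis(
            chains=2, iterations=1200, burn_in=400, thin=2, seed=1
        )
        assert est.get_params()["chains"] == 2
        est.set_params(seed=9)
        est.fit(ds)
        assert est.reference_ == "Pla"
        assert est.d_samples_.shape[1] == len(est.treatments_)
        assert est.dic_ == pytest.approx(est.dbar_ + est.p_d_)
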