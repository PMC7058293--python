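import numpy as np
import pytest

from bnmeta.data import LOG_HR, OutcomeDataset, RelativeEffect
from bnmeta.nma import FitResult, NMAConfig


@pytest.fixture
def worked_effects():
    """The two landmark sorafenib-vs-placebo overall-survival contrasts
    (HR 0.69, 0.55-0.87 and HR 0.68, 0.50-0.93) converted to the log scale."""
    from bnmeta.data import effect_from_ci

    e1 = effect_from_ci(0.69, 0.55, 0.87)
    e2 = effect_from_ci(0.68, 0.50, 0.93)
    return [
        RelativeEffect("SHARP", "Sor", "Pla", LOG_HR, e1[0], e1[1]),
        RelativeEffect("AsiaPacific", "Sor", "Pla", LOG_HR, e2[0], e2[1]),
    ]


@pytest.fixture
def reduced_cfg():
    """Reduced MCMC settings for fast, well-mixing fits on small networks."""
    return NMAConfig(chains=2, iterations=1500, burn_in=500, thin=2, seed=42)


def make_contrasts(rows):
    """rows: (study, treatment, reference, y, se)."""
    return [RelativeEffect(s, t, r, LOG_HR, y, se) for s, t, r, y, se in rows]


def make_dataset(rows):
    return OutcomeDataset.from_contrasts(make_contrasts(rows))


def triangle_dataset(omega=0.0, se=0.1, n_per_edge=2, seed=0, means=(-0.3, -0.5, -0.2)):
    """Consistent triangle Pla-Sor-Bri with optional inconsistency offset
    added to the Pla-Sor direct evidence."""
    rng = np.random.default_rng(seed)
    m_sor, m_bri, m_bs = means  # Sor vs Pla, Bri vs Pla, Bri vs Sor = m_bri - m_sor
    rows = []
    for j in range(n_per_edge):
        rows.append((f"sp{j}", "Sor", "Pla", m_sor + omega + se * rng.standard_normal(), se))
        rows.append((f"bp{j}", "Bri", "Pla", m_bri + se * rng.standard_normal(), se))
        rows.append((f"bs{j}", "Bri", "Sor", m_bs + se * rng.standard_normal(), se))
    return make_dataset(rows)


def fit_from_d(treatments, reference, d_samples):
    """Wrap explicit posterior draws of the basic parameters in a FitResult
    so league-table and ranking operations can be tested by enumeration."""
    d_samples = np.asarray(d_samples, float)
    params = [t for t in treatments if t != reference]
    cfg = NMAConfig(chains=2, iterations=20, burn_in=10, thin=1)
    return FitResult(
        treatments=list(treatments),
        reference=reference,
        param_names=params,
        structure="consistency",
        effects="fixed",
        measure=LOG_HR,
        config=cfg,
        beta_chains=d_samples[None, :, :],
        sigma_chains=None,
        deviance_chains=np.zeros((1, len(d_samples))),
        dbar=0.0,
        p_d=0.0,
        dic_=0.0,
        n_data=0,
        prior_sd_d=15.0,
    )
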