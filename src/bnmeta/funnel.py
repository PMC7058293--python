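"""Comparison-adjusted funnel-plot data for small-study-effect inspection.

Each contrast is centered on the fixed-effect pooled direct estimate of its
own comparison, so that scatter of the centered effect against its standard
error can be inspected for asymmetry across the whole network. Fixed-effect
centering is used regardless of the heterogeneity rule: the funnel asks about
small-study asymmetry around the common effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OutcomeDataset
from .pairwise import pool_fixed_iv

__all__ = ["FunnelPoint", "funnel_points", "funnel_guide_lines"]


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    treatment: str
    reference: str
    centered_effect: float
    std_err: float


def funnel_points(dataset: OutcomeDataset) -> list:
    """One centered point per contrast; single-study comparisons center to 0.

    Within each comparison the inverse-variance weighted mean of the centered
    effects is zero by construction.
    """
    if not dataset.contrasts:
        raise ValueError("dataset has no contrasts")
    groups: dict[tuple, list] = {}
    for c in dataset.contrasts:
        groups.setdefault((c.treatment_id, c.reference_id), []).append(c)
    out = []
    for (t, r), effects in groups.items():
        # single-study comparisons center to exactly zero
        pooled = effects[0].estimate if len(effects) == 1 else pool_fixed_iv(effects).estimate
        for c in effects:
            out.append(
                FunnelPoint(
                    study_id=c.study_id,
                    treatment=t,
                    reference=r,
                    centered_effect=c.estimate - pooled,
                    std_err=c.std_err,
                )
            )
    return out


def funnel_guide_lines(points, level_z: float = 1.959964, n_grid: int = 50):
    """Pseudo-95% guide lines: (se, -z*se, +z*se) over the observed SE range."""
    ses = np.array([p.std_err for p in points])
    grid = np.linspace(0, float(ses.max()), n_grid)
    return pd.DataFrame(dict(se=grid, lower=-level_z * grid, upper=level_z * grid))


def funnel_frame(points) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            study=[p.study_id for p in points],
            treatment=[p.treatment for p in points],
            reference=[p.reference for p in points],
            centered_effect=[p.centered_effect for p in points],
            se=[p.std_err for p in points],
        )
    )
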