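"""Treatment ranking: rank probabilities, SUCRA, and clustered two-outcome ranking.

SUCRA (surface under the cumulative ranking curve) summarizes a treatment's
rank distribution as a single number in [0, 1]: 1 when the treatment is
certain to be best, 0 when certain to be worst, and equal to
(a - expected rank) / (a - 1) for a treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nma import FitResult

__all__ = ["RankResult", "rank_probabilities", "sucra", "cluster_plot_data"]


@dataclass(frozen=True)
class RankResult:
    """Rank-probability matrix and SUCRA per treatment.

    ``probabilities[k, j]`` is the probability that treatment k holds rank
    j+1, where rank 1 is the preferred end given ``direction``.
    """

    treatments: tuple
    probabilities: np.ndarray
    sucra: np.ndarray
    direction: str

    @property
    def p_best(self) -> np.ndarray:
        return self.probabilities[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(treatment=self.treatments, sucra=self.sucra, p_best=self.p_best)
        )


def rank_probabilities(fit: FitResult, direction: str = "lower-better") -> RankResult:
    """Tally treatment ranks over the retained posterior draws.

    Each draw orders the treatments by effect vs the common reference (the
    reference's own d = 0 is included); ties are broken by treatment order,
    a measure-zero event for continuous posteriors.
    """
    if direction not in ("lower-better", "higher-better"):
        raise ValueError(f"unknown direction {direction!r}")
    d = fit.d_samples
    if direction == "higher-better":
        d = -d
    s, k = d.shape
    # stable argsort breaks exact ties by treatment order
    order = np.argsort(d, axis=1, kind="stable")
    probs = np.zeros((k, k))
    ranks = np.empty_like(order)
    rows = np.arange(s)[:, None]
    ranks[rows, order] = np.arange(k)[None, :]
    for j in range(k):
        probs[:, j] = np.bincount(np.where(ranks == j)[1], minlength=k)
    probs /= s
    return RankResult(
        treatments=tuple(fit.treatments),
        probabilities=probs,
        sucra=sucra(probs),
        direction=direction,
    )


def sucra(rank_matrix: np.ndarray) -> np.ndarray:
    """SUCRA per treatment from a doubly stochastic rank-probability matrix:
    the mean of the cumulative rank probabilities over ranks 1..a-1."""
    p = np.asarray(rank_matrix, float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("rank matrix must be square")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rank matrix rows must sum to 1")
    a = p.shape[0]
    if a == 1:
        return np.ones(1)
    cum = np.cumsum(p, axis=1)
    return cum[:, : a - 1].sum(axis=1) / (a - 1)


@dataclass(frozen=True)
class ClusterPlotData:
    """Plot-ready pairing of two SUCRA rankings per treatment."""

    treatments: tuple
    sucra_x: np.ndarray  # safety axis
    sucra_y: np.ndarray  # efficacy axis
    labels: np.ndarray | None  # k-means cluster labels (optional)
    dominated: np.ndarray  # True when some other point is >= on both axes

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            dict(
                treatment=self.treatments,
                sucra_x=self.sucra_x,
                sucra_y=self.sucra_y,
                dominated=self.dominated,
            )
        )
        if self.labels is not None:
            out["cluster"] = self.labels
        return out


def _dominated_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(x)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if x[j] >= x[i] and y[j] >= y[i] and (x[j] > x[i] or y[j] > y[i]):
                out[i] = True
                break
    return out


def cluster_plot_data(
    sucra_safety: dict,
    sucra_efficacy: dict,
    k_clusters: int | None = 3,
    seed: int = 0,
) -> ClusterPlotData:
    """Per-treatment (safety SUCRA, efficacy SUCRA) points for the clustered
    ranking plot, with optional seeded k-means labels and the non-dominated
    (upper-right) set flagged.

    Both inputs map treatment -> SUCRA and must share the same treatment set.
    """
    if set(sucra_safety) != set(sucra_efficacy):
        raise ValueError("safety and efficacy rankings cover different treatments")
    treatments = tuple(sucra_safety)
    x = np.array([sucra_safety[t] for t in treatments], float)
    y = np.array([sucra_efficacy[t] for t in treatments], float)
    labels = None
    if k_clusters is not None and len(treatments) >= k_clusters:
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(seed)
        pts = np.column_stack([x, y])
        centroids = pts[rng.choice(len(pts), size=k_clusters, replace=False)]
        km = KMeans(n_clusters=k_clusters, init=centroids, n_init=1, max_iter=300)
        labels = km.fit_predict(pts)
    return ClusterPlotData(
        treatments=treatments,
        sucra_x=x,
        sucra_y=y,
        labels=labels,
        dominated=_dominated_mask(x, y),
    )
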