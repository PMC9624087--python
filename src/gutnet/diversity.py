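"""Hill-number (order 1) diversity partitioning, Bray-Curtis dissimilarity
and non-metric multidimensional scaling.

Diversity is reported in "effective numbers" (genus equivalents): the order-1
Hill number exp(H) where H is the Shannon entropy with natural logs.  Total
(gamma) diversity is multiplicatively partitioned as gamma = alpha x beta,
with equal unit weights so the identity holds exactly: alpha is the
exponential of the mean within-unit entropy and beta the effective number of
completely distinct communities (1 <= beta <= number of units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from gutnet.io import ReadCountTable


def hill_shannon(rel_abundance) -> float:
    """Order-1 Hill number exp(-sum p ln p); zero-probability terms contribute 0."""
    p = np.asarray(rel_abundance, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("relative abundances must sum to 1")
    return float(np.exp(entropy(p)))


@dataclass
class DiversityPartition:
    """Multiplicative alpha/beta/gamma partition with optional bootstrap CIs."""

    alpha: float
    beta: float
    gamma: float
    groups: list[str]
    ci: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.gamma, self.alpha * self.beta, rtol=1e-10, atol=1e-10):
            raise ValueError("gamma must equal alpha * beta")
        if self.alpha < 1 - 1e-9 or self.beta < 1 - 1e-9:
            raise ValueError("effective numbers are >= 1")
        if self.beta > len(self.groups) + 1e-9:
            raise ValueError("beta cannot exceed the number of groups")


def _unit_profiles(table: ReadCountTable, grouping: Mapping[str, str] | None) -> pd.DataFrame:
    """Equal-weight community profile per unit (group); samples are first
    converted to relative abundances, then averaged within their group."""
    rel = table.relative_abundance
    if grouping is None:
        return rel
    ser = pd.Series({s: grouping[s] for s in table.sample_ids})
    profiles = rel.groupby(ser).mean()
    if (profiles.sum(axis=1) == 0).any():
        raise ValueError("empty group")
    return profiles


def partition_diversity(
    table: ReadCountTable, grouping: Mapping[str, str] | None = None
) -> DiversityPartition:
    """Partition gamma into alpha and beta over units (groups of samples).

    Without a grouping every sample is its own unit.  With equal unit
    weights: alpha = exp(mean within-unit entropy), gamma = exp(entropy of
    the mean profile), beta = gamma / alpha.
    """
    profiles = _unit_profiles(table, grouping)
    if profiles.shape[0] < 1:
        raise ValueError("need at least one unit")
    within = np.array([entropy(row) for row in profiles.to_numpy()])
    alpha = float(np.exp(within.mean()))
    gamma = float(np.exp(entropy(profiles.to_numpy().mean(axis=0))))
    beta = gamma / alpha
    return DiversityPartition(alpha=alpha, beta=beta, gamma=gamma,
                              groups=[str(g) for g in profiles.index])


def pairwise_beta(table: ReadCountTable, sample_a: str, sample_b: str) -> float:
    """Beta diversity between two samples; ranges from 1 (identical) to 2
    (completely distinct)."""
    if sample_a == sample_b:
        raise ValueError("pairwise beta needs two distinct samples")
    sub = table.subset_samples([sample_a, sample_b])
    return partition_diversity(sub).beta


def bootstrap_partition(
    table: ReadCountTable,
    grouping: Mapping[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    resample_reads_only: bool = False,
) -> DiversityPartition:
    """Hierarchical bootstrap CIs for alpha, beta and gamma.

    Each replicate resamples samples within units with replacement and then
    resamples each chosen sample's reads multinomially at its observed depth
    (``resample_reads_only=True`` skips the sample level).  CIs are 2.5/97.5
    percentiles; the point estimate is from the original table.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point = partition_diversity(table, grouping)
    rng = np.random.default_rng(seed)
    if grouping is None:
        grouping_eff = {s: s for s in table.sample_ids}
    else:
        grouping_eff = dict(grouping)
    units: dict[str, list[str]] = {}
    for s in table.sample_ids:
        units.setdefault(grouping_eff[s], []).append(s)
    rel = table.relative_abundance
    depths = table.depths
    stats = {"alpha": [], "beta": [], "gamma": []}
    for _ in range(n_boot):
        profiles = []
        for unit, members in units.items():
            if resample_reads_only:
                chosen = members
            else:
                chosen = [members[i] for i in rng.integers(len(members), size=len(members))]
            ps = []
            for s in chosen:
                depth = int(depths[s])
                c = rng.multinomial(depth, rel.loc[s].to_numpy())
                ps.append(c / depth)
            profiles.append(np.mean(ps, axis=0))
        profiles = np.asarray(profiles)
        within = np.array([entropy(p) for p in profiles])
        alpha = float(np.exp(within.mean()))
        gamma = float(np.exp(entropy(profiles.mean(axis=0))))
        stats["alpha"].append(alpha)
        stats["gamma"].append(gamma)
        stats["beta"].append(gamma / alpha)
    ci = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in stats.items()
    }
    point.ci = ci
    return point


def bray_curtis(table: ReadCountTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix on relative abundances."""
    rel = table.relative_abundance.to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _kruskal_stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone (isotonic) disparities on ranks."""
    iu = np.triu_indices_from(d_obs, k=1)
    dis = d_obs[iu]
    emb = squareform(
        np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)), checks=False
    )
    order = np.argsort(dis, kind="stable")
    dhat = np.empty_like(emb)
    dhat[order] = IsotonicRegression().fit_transform(np.arange(len(order)), emb[order])
    denom = float((emb**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((emb - dhat) ** 2).sum() / denom))


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling by iterative majorization (SMACOF)
    with isotonic regression on dissimilarity ranks.

    The best of ``n_starts`` configurations is kept: one start from classical
    (Torgerson) scaling, the rest random.  ``stress_`` is Kruskal stress-1 in
    [0, 1].
    """

    def __init__(
        self,
        n_components: int = 2,
        n_starts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-7,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _classical_start(self, d: np.ndarray) -> np.ndarray:
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        vals, vecs = np.linalg.eigh(b)
        idx = np.argsort(vals)[::-1][: self.n_components]
        vals_k = np.clip(vals[idx], 0, None)
        return vecs[:, idx] * np.sqrt(vals_k)

    def fit(self, dissimilarity, y=None):
        if isinstance(dissimilarity, pd.DataFrame):
            self.labels_ = list(dissimilarity.index)
            d = dissimilarity.to_numpy(dtype=float)
        else:
            d = np.asarray(dissimilarity, dtype=float)
            self.labels_ = list(range(d.shape[0]))
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("dissimilarity must be square symmetric")
        if (d < 0).any():
            raise ValueError("dissimilarity must be non-negative")
        best_coords, best_stress = None, np.inf
        starts: list[np.ndarray | None] = [self._classical_start(d)]
        starts += [None] * max(0, self.n_starts - 1)
        for i, init in enumerate(starts):
            coords, _, _ = smacof(
                d,
                metric=False,
                n_components=self.n_components,
                init=init,
                n_init=1,
                max_iter=self.max_iter,
                eps=self.tol,
                random_state=self.random_state + i,
                normalized_stress=True,
                return_n_iter=True,
            )
            stress = _kruskal_stress1(d, coords)
            if stress < best_stress:
                best_stress, best_coords = stress, coords
        self.embedding_ = best_coords
        self.stress_ = float(best_stress)
        return self

    def fit_transform(self, dissimilarity, y=None):
        return self.fit(dissimilarity).embedding_


def nmds(
    dissimilarity,
    ndim: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float]:
    """Functional wrapper over :class:`NMDS`: returns (coordinates, stress-1)."""
    est = NMDS(
        n_components=ndim,
        n_starts=n_starts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(dissimilarity)
    return est.embedding_, est.stress_
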