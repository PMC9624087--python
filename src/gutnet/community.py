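"""Community structure: bipartite graph construction, leading-eigenvector
modularity, ensemble consensus, and the Gaussian latent block model.

Two clustering routes are provided.  Presence-absence matrices are treated
as bipartite sample-genus networks and partitioned by Newman's
leading-eigenvector modularity maximization; an ensemble of rarefied
matrices is then summarized by a co-clustering (consensus) matrix.  The
weighted (read-count) matrix is biclustered directly with a Gaussian latent
block model on log-transformed counts, selected by the ICL criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from gutnet.io import BinaryIncidence


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """Assignment of nodes to groups, optionally with modularity Q and roles."""

    groups: dict[Hashable, int]
    q: float | None = None
    roles: dict[Hashable, str] | None = None

    def __post_init__(self) -> None:
        if self.q is not None and not (-0.5 - 1e-9 <= self.q <= 1 + 1e-9):
            raise ValueError(f"modularity Q={self.q} outside [-0.5, 1]")

    @property
    def nodes(self) -> list:
        return list(self.groups)

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def labels_for(self, nodes: Iterable[Hashable]) -> np.ndarray:
        return np.array([self.groups[n] for n in nodes])

    def canonical(self) -> "Partition":
        """Relabel groups 0,1,... ordered by decreasing size, ties broken by
        the smallest member label."""
        members: dict[int, list] = {}
        for node, g in self.groups.items():
            members.setdefault(g, []).append(node)
        order = sorted(members, key=lambda g: (-len(members[g]), min(map(str, members[g]))))
        relabel = {g: i for i, g in enumerate(order)}
        return Partition(
            {n: relabel[g] for n, g in self.groups.items()}, q=self.q, roles=self.roles
        )

    @classmethod
    def from_labels(cls, nodes: Sequence[Hashable], labels: Sequence, role: str | None = None):
        uniq = {l: i for i, l in enumerate(dict.fromkeys(labels))}
        roles = {n: role for n in nodes} if role else None
        return cls({n: uniq[l] for n, l in zip(nodes, labels)}, roles=roles)


def incidence_to_graph(inc: BinaryIncidence) -> nx.Graph:
    """Bipartite graph with sample and genus nodes, one edge per 1 entry.

    Sample nodes keep their labels; genus nodes are prefixed with ``"g:"`` to
    avoid collisions.  Node attribute ``role`` is ``"sample"`` or ``"genus"``.
    """
    inc.require_no_empty_samples()
    g = nx.Graph()
    for s in inc.sample_ids:
        g.add_node(s, role="sample")
    for t in inc.genus_ids:
        g.add_node(f"g:{t}", role="genus")
    rows, cols = np.nonzero(inc.matrix)
    samples = inc.sample_ids
    genera = inc.genus_ids
    g.add_edges_from((samples[i], f"g:{genera[j]}") for i, j in zip(rows, cols))
    return g


def modularity(graph: nx.Graph, partition: Partition) -> float:
    """Direct Newman-Girvan modularity: Q = sum_g (e_g/m - (d_g/2m)^2)."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in graph.edges():
        if partition.groups[u] == partition.groups[v]:
            intra[partition.groups[u]] = intra.get(partition.groups[u], 0) + 1
    for n, d in graph.degree():
        g = partition.groups[n]
        degsum[g] = degsum.get(g, 0) + d
    return sum(
        intra.get(g, 0) / m - (degsum[g] / (2 * m)) ** 2 for g in degsum
    )


def _kl_refine(b_mod: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style refinement of a bisection: repeated sweeps in
    which every node is flipped once (greedily) and the best prefix of flips
    is kept; stops when a full sweep yields no improvement."""
    n = len(s)
    s = s.copy()
    diag = np.diag(b_mod)
    while True:
        moved = np.zeros(n, dtype=bool)
        trial = s.copy()
        best_s, best_gain = s.copy(), 0.0
        gain = 0.0
        for _ in range(n):
            # flipping s_i changes s^T B s by -4 s_i (B s)_i + 4 B_ii
            bs = b_mod @ trial
            deltas = -4.0 * trial * bs + 4.0 * diag
            deltas[moved] = -np.inf
            i = int(np.argmax(deltas))
            gain += deltas[i]
            trial[i] = -trial[i]
            moved[i] = True
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_s = trial.copy()
        if best_gain <= 1e-12:
            return s
        s = best_s


def _spectral_labels(a: np.ndarray, fine_tune: bool = False) -> np.ndarray:
    """Leading-eigenvector community labels for a dense adjacency matrix."""
    m = a.sum() / 2.0
    n = a.shape[0]
    if m == 0:
        return np.zeros(n, dtype=int)
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / (2.0 * m)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        idx = stack.pop()
        if len(idx) < 2:
            continue
        sub = b[np.ix_(idx, idx)]
        b_mod = sub - np.diag(sub.sum(axis=1))
        vals, vecs = np.linalg.eigh(b_mod)
        if vals[-1] <= 1e-10:
            continue
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        if fine_tune:
            s = _kl_refine(b_mod, s)
        if np.all(s == s[0]):
            continue
        dq = float(s @ b_mod @ s) / (4.0 * m)
        if dq <= 1e-12:
            continue
        pos = idx[s > 0]
        neg = idx[s < 0]
        labels[neg] = next_label
        next_label += 1
        stack.append(pos)
        stack.append(neg)
    if fine_tune:
        labels = _move_refine(b, labels)
    return labels


def leading_eigenvector(graph: nx.Graph, fine_tune: bool = False) -> Partition:
    """Partition a graph by recursive spectral bisection of the modularity
    matrix (Newman's leading-eigenvector method).

    At each step the group with indices C is split by the sign pattern of the
    dominant eigenvector of the generalized modularity matrix
    ``B^(C) = B[C,C] - diag(sum_k B[C,k in C])``; the split is accepted only
    if the dominant eigenvalue is positive and the split increases Q.  The
    returned partition covers all nodes and carries Q recomputed by the
    direct formula.  ``fine_tune`` enables Kernighan-Lin sweeps after each
    spectral split plus a final greedy node-moving pass.
    """
    nodes = list(graph.nodes())
    if not nodes:
        raise ValueError("empty graph")
    roles = {n: graph.nodes[n].get("role") for n in nodes}
    a = nx.to_numpy_array(graph, nodelist=nodes)
    labels = _spectral_labels(a, fine_tune=fine_tune)
    part = Partition(dict(zip(nodes, labels.tolist())), roles=roles)
    part.q = modularity(graph, part)
    return part.canonical()


def _modularity_dense(a: np.ndarray, labels: np.ndarray) -> float:
    m = a.sum() / 2.0
    if m == 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    for g in np.unique(labels):
        mask = labels == g
        q += a[np.ix_(mask, mask)].sum() / (2 * m) - (k[mask].sum() / (2 * m)) ** 2
    return float(q)


def bipartite_sample_labels(
    incidence: np.ndarray, fine_tune: bool = False, return_q: bool = False
):
    """Fast path: leading-eigenvector labels of the sample nodes of a
    presence-absence matrix, without building a graph object.

    Equivalent to ``sample_partition(leading_eigenvector(incidence_to_graph(inc)))``
    up to group relabeling (NMI-, consensus- and count-invariant).  With
    ``return_q`` also returns the modularity of the full bipartite partition.
    """
    m = np.asarray(incidence)
    n, p = m.shape
    a = np.zeros((n + p, n + p))
    a[:n, n:] = m
    a[n:, :n] = m.T
    labels = _spectral_labels(a, fine_tune=fine_tune)
    if return_q:
        return labels[:n], _modularity_dense(a, labels)
    return labels[:n]


def _move_refine(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedy node moves between existing groups until Q stops improving."""
    labels = labels.copy()
    n = len(labels)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            groups = list(np.unique(labels))
            # gain of keeping/moving i into group g: sum_{j in g, j != i} B_ij;
            # an empty (new) group has gain 0
            gains = np.array(
                [b[i, labels == g].sum() - (b[i, i] if labels[i] == g else 0.0)
                 for g in groups] + [0.0]
            )
            current = gains[groups.index(labels[i])]
            best = int(np.argmax(gains))
            if gains[best] > current + 1e-12:
                labels[i] = groups[best] if best < len(groups) else labels.max() + 1
                improved = True
    return labels


def sample_partition(p: Partition) -> Partition:
    """Restrict a bipartite partition to its sample nodes, canonically relabeled."""
    if p.roles is None:
        raise ValueError("partition carries no node roles")
    groups = {n: g for n, g in p.groups.items() if p.roles[n] == "sample"}
    if not groups:
        raise ValueError("no sample nodes in partition")
    roles = {n: "sample" for n in groups}
    return Partition(groups, q=p.q, roles=roles).canonical()


# ---------------------------------------------------------------------------
# Consensus over the rarefied ensemble
# ---------------------------------------------------------------------------


@dataclass
class ConsensusMatrix:
    """Samples x samples co-clustering probabilities over an ensemble."""

    matrix: pd.DataFrame
    n_matrices: int

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")


def consensus(partitions: Sequence[Partition]) -> ConsensusMatrix:
    """Fraction of ensemble members in which each pair of samples co-clusters."""
    if not partitions:
        raise ValueError("no partitions")
    sample_sets = [tuple(sorted(map(str, p.groups))) for p in partitions]
    if len(set(sample_sets)) != 1:
        raise ValueError("partitions cover different sample sets")
    samples = sorted(partitions[0].groups, key=str)
    acc = np.zeros((len(samples), len(samples)))
    for p in partitions:
        lab = p.labels_for(samples)
        acc += (lab[:, None] == lab[None, :]).astype(float)
    acc /= len(partitions)
    np.fill_diagonal(acc, 1.0)
    df = pd.DataFrame(acc, index=samples, columns=samples)
    return ConsensusMatrix(df, n_matrices=len(partitions))


def consensus_partition(cm: ConsensusMatrix, cut: float = 0.5) -> Partition:
    """Average-linkage clustering of 1 - co-clustering probability, cut at
    distance ``1 - cut``."""
    d = 1.0 - cm.matrix.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    samples = list(cm.matrix.index)
    if len(samples) == 1:
        return Partition({samples[0]: 0}, roles={samples[0]: "sample"})
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=1.0 - cut, criterion="distance")
    return Partition.from_labels(samples, labels, role="sample").canonical()


def modal_partition(partitions: Sequence[Partition]) -> Partition:
    """The most frequent exact partition in the ensemble (ties: first seen)."""
    if not partitions:
        raise ValueError("no partitions")
    samples = sorted(partitions[0].groups, key=str)
    counts: dict[tuple, int] = {}
    first: dict[tuple, Partition] = {}
    for p in partitions:
        key = tuple(p.canonical().labels_for(samples).tolist())
        counts[key] = counts.get(key, 0) + 1
        first.setdefault(key, p)
    best = max(counts, key=lambda k: counts[k])
    return first[best].canonical()


# ---------------------------------------------------------------------------
# Scikit-learn style ensemble consensus clustering
# ---------------------------------------------------------------------------


class ConsensusClustering(BaseEstimator):
    """Ensemble community detection on rarefied presence-absence matrices.

    ``fit`` takes a :class:`~gutnet.io.ReadCountTable`, draws ``n_matrices``
    independent rarefaction+threshold presence-absence matrices, partitions
    each bipartite sample-genus network by leading-eigenvector modularity,
    and aggregates the sample partitions into a consensus co-clustering
    matrix.

    Attributes (after fit)
    ----------------------
    consensus_matrix_ : ConsensusMatrix
    labels_ : ndarray of consensus group labels, aligned to sample order
    partitions_ : list of per-matrix sample partitions
    mean_n_groups_, se_n_groups_ : mean and SE of sample-group counts
    mean_modularity_, se_modularity_ : mean and SE of Q over the ensemble
    """

    def __init__(
        self,
        depth: int = 3000,
        threshold: int = 3,
        n_matrices: int = 1000,
        cut: float = 0.5,
        fine_tune: bool = False,
        random_state: int = 0,
    ):
        self.depth = depth
        self.threshold = threshold
        self.n_matrices = n_matrices
        self.cut = cut
        self.fine_tune = fine_tune
        self.random_state = random_state

    def fit(self, X, y=None):
        from gutnet.rarefaction import make_ensemble

        ensemble = make_ensemble(
            X,
            depth=self.depth,
            threshold=self.threshold,
            n=self.n_matrices,
            seed=self.random_state,
        )
        samples = list(X.sample_ids)
        parts = []
        qs_list = []
        for inc in ensemble:
            inc.require_no_empty_samples()
            lab, q = bipartite_sample_labels(
                inc.matrix, fine_tune=self.fine_tune, return_q=True
            )
            p = Partition.from_labels(samples, lab, role="sample")
            p.q = q
            parts.append(p)
            qs_list.append(q)
        self.partitions_ = parts
        self.consensus_matrix_ = consensus(parts)
        cons = consensus_partition(self.consensus_matrix_, cut=self.cut)
        self.sample_ids_ = samples
        self.labels_ = cons.labels_for(self.sample_ids_)
        self.consensus_partition_ = cons
        n_groups = np.array([p.n_groups for p in parts], dtype=float)
        qs = np.array(qs_list, dtype=float)
        self.mean_n_groups_ = float(n_groups.mean())
        self.se_n_groups_ = float(n_groups.std(ddof=1) / np.sqrt(len(parts))) if len(parts) > 1 else 0.0
        self.mean_modularity_ = float(qs.mean())
        self.se_modularity_ = float(qs.std(ddof=1) / np.sqrt(len(parts))) if len(parts) > 1 else 0.0
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# Gaussian latent block model
# ---------------------------------------------------------------------------


@dataclass
class LBMFit:
    """Result of a Gaussian latent block model fit."""

    row_groups: pd.Series
    col_groups: pd.Series
    means: np.ndarray
    variances: np.ndarray
    row_proportions: np.ndarray
    col_proportions: np.ndarray
    icl: float
    elbo: float
    K: int
    L: int
    converged: bool
    icl_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.icl):
            raise ValueError("non-finite ICL")


class GaussianLBM(BaseEstimator):
    """Gaussian latent block model fitted by mean-field variational EM.

    Rows and columns of a real-valued matrix (here log-transformed read
    counts) are simultaneously clustered into ``n_row_groups`` x
    ``n_col_groups`` blocks, each with its own Gaussian mean and variance.
    The variational bound is maximized over ``n_init`` restarts; model choice
    across (K, L) uses the ICL criterion (see :func:`select_lbm`).

    Attributes (after fit): ``row_labels_``, ``column_labels_``, ``means_``,
    ``variances_``, ``row_proportions_``, ``col_proportions_``, ``elbo_``,
    ``icl_``, ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_row_groups: int = 1,
        n_col_groups: int = 1,
        n_init: int = 25,
        max_iter: int = 500,
        tol: float = 1e-6,
        var_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_row_groups = n_row_groups
        self.n_col_groups = n_col_groups
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _softmax_rows(logp: np.ndarray) -> np.ndarray:
        logp = logp - logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def _gauss_coefs(self, mu, var):
        # log N(x; mu, var) = a + b x + c x^2
        a = -0.5 * (np.log(2 * np.pi * var) + mu**2 / var)
        b = mu / var
        c = -0.5 / var
        return a, b, c

    def _m_step(self, x, x2, tau, nu):
        t = tau.sum(axis=0)
        s = nu.sum(axis=0)
        pi = np.clip(t / t.sum(), 1e-12, None)
        rho = np.clip(s / s.sum(), 1e-12, None)
        denom = np.outer(t, s)
        denom = np.clip(denom, 1e-12, None)
        mu = tau.T @ x @ nu / denom
        var = tau.T @ x2 @ nu / denom - mu**2
        floored = bool((var < self.var_floor).any())
        var = np.clip(var, self.var_floor, None)
        return pi, rho, mu, var, floored

    def _elbo(self, x, x2, tau, nu, pi, rho, mu, var):
        a, b, c = self._gauss_coefs(mu, var)
        t = tau.sum(axis=0)
        s = nu.sum(axis=0)
        like = (a * np.outer(t, s)).sum()
        like += (b * (tau.T @ x @ nu)).sum()
        like += (c * (tau.T @ x2 @ nu)).sum()
        ent_r = (tau * (np.log(pi)[None, :] - np.log(np.clip(tau, 1e-300, None)))).sum()
        ent_c = (nu * (np.log(rho)[None, :] - np.log(np.clip(nu, 1e-300, None)))).sum()
        return like + ent_r + ent_c

    def _fit_once(self, x, x2, tau, nu):
        n, p = x.shape
        elbo_prev = -np.inf
        converged = False
        n_iter = 0
        trace = []
        pi, rho, mu, var, floored = self._m_step(x, x2, tau, nu)
        for n_iter in range(1, self.max_iter + 1):
            a, b, c = self._gauss_coefs(mu, var)
            # VE-step: alternate exact coordinate updates of tau and nu
            for _ in range(3):
                s = nu.sum(axis=0)
                log_tau = (
                    np.log(pi)[None, :]
                    + (a @ s)[None, :]
                    + x @ nu @ b.T
                    + x2 @ nu @ c.T
                )
                tau = self._softmax_rows(log_tau)
                t = tau.sum(axis=0)
                log_nu = (
                    np.log(rho)[None, :]
                    + (t @ a)[None, :]
                    + x.T @ tau @ b
                    + x2.T @ tau @ c
                )
                nu = self._softmax_rows(log_nu)
            pi, rho, mu, var, floored = self._m_step(x, x2, tau, nu)
            elbo = self._elbo(x, x2, tau, nu, pi, rho, mu, var)
            if not floored and elbo < elbo_prev - 1e-6 * max(1.0, abs(elbo_prev)):
                raise AssertionError(
                    f"variational bound decreased: {elbo_prev} -> {elbo}"
                )
            trace.append(elbo)
            if abs(elbo - elbo_prev) < self.tol * max(1.0, abs(elbo)):
                converged = True
                elbo_prev = elbo
                break
            elbo_prev = elbo
        return dict(
            tau=tau, nu=nu, pi=pi, rho=rho, mu=mu, var=var,
            elbo=elbo_prev, converged=converged, n_iter=n_iter, trace=trace,
        )

    def _init_posteriors(self, x, rng, init_idx):
        n, p = x.shape
        K, L = self.n_row_groups, self.n_col_groups
        if init_idx == 0 and K > 1 and n > K:
            seed = int(rng.integers(2**31 - 1))
            rl = KMeans(n_clusters=K, n_init=4, random_state=seed).fit_predict(x)
        else:
            rl = rng.integers(K, size=n)
        if init_idx == 0 and L > 1 and p > L:
            seed = int(rng.integers(2**31 - 1))
            cl = KMeans(n_clusters=L, n_init=4, random_state=seed).fit_predict(x.T)
        else:
            cl = rng.integers(L, size=p)
        tau = np.full((n, K), 0.1 / max(K - 1, 1) if K > 1 else 1.0)
        tau[np.arange(n), rl] = 0.9 if K > 1 else 1.0
        tau /= tau.sum(axis=1, keepdims=True)
        nu = np.full((p, L), 0.1 / max(L - 1, 1) if L > 1 else 1.0)
        nu[np.arange(p), cl] = 0.9 if L > 1 else 1.0
        nu /= nu.sum(axis=1, keepdims=True)
        return tau, nu

    # -- API ----------------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            x = X.to_numpy(dtype=float)
            row_index, col_index = list(X.index), list(X.columns)
        else:
            x = np.asarray(X, dtype=float)
            row_index = list(range(x.shape[0]))
            col_index = list(range(x.shape[1]))
        if not np.isfinite(x).all():
            raise ValueError("non-finite input")
        n, p = x.shape
        K, L = self.n_row_groups, self.n_col_groups
        if K < 1 or L < 1 or K > n or L > p:
            raise ValueError(f"invalid block counts K={K}, L={L} for {n}x{p} data")
        x2 = x**2
        rng = np.random.default_rng(self.random_state)
        best = None
        for i in range(self.n_init):
            tau, nu = self._init_posteriors(x, rng, i)
            res = self._fit_once(x, x2, tau, nu)
            if best is None or res["elbo"] > best["elbo"]:
                best = res
        z = best["tau"].argmax(axis=1)
        w = best["nu"].argmax(axis=1)
        self.row_labels_ = z
        self.column_labels_ = w
        self.row_index_ = row_index
        self.col_index_ = col_index
        self.means_ = best["mu"]
        self.variances_ = best["var"]
        self.row_proportions_ = best["pi"]
        self.col_proportions_ = best["rho"]
        self.elbo_ = float(best["elbo"])
        self.elbo_trace_ = list(best["trace"])
        self.converged_ = bool(best["converged"])
        self.n_iter_ = int(best["n_iter"])
        self.icl_ = self._icl(x, z, w, best)
        return self

    def _icl(self, x, z, w, best):
        n, p = x.shape
        K, L = self.n_row_groups, self.n_col_groups
        mu, var = best["mu"], best["var"]
        pi, rho = best["pi"], best["rho"]
        ll = np.log(pi[z]).sum() + np.log(rho[w]).sum()
        mu_cells = mu[np.ix_(z, w)]
        var_cells = var[np.ix_(z, w)]
        ll += -0.5 * (
            np.log(2 * np.pi * var_cells) + (x - mu_cells) ** 2 / var_cells
        ).sum()
        penalty = (
            0.5 * (K - 1) * np.log(n)
            + 0.5 * (L - 1) * np.log(p)
            + 0.5 * (2 * K * L) * np.log(n * p)
        )
        return float(ll - penalty)


def fit_lbm(
    log_counts,
    K: int,
    L: int,
    n_init: int = 25,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LBMFit:
    """Fit a Gaussian latent block model with K row groups and L column groups."""
    est = GaussianLBM(
        n_row_groups=K,
        n_col_groups=L,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(log_counts)
    return LBMFit(
        row_groups=pd.Series(est.row_labels_, index=est.row_index_),
        col_groups=pd.Series(est.column_labels_, index=est.col_index_),
        means=est.means_,
        variances=est.variances_,
        row_proportions=est.row_proportions_,
        col_proportions=est.col_proportions_,
        icl=est.icl_,
        elbo=est.elbo_,
        K=K,
        L=L,
        converged=est.converged_,
    )


def select_lbm(
    log_counts,
    K_range: Iterable[int] = range(1, 7),
    L_range: Iterable[int] = range(1, 11),
    n_init: int = 25,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LBMFit:
    """Grid-fit Gaussian latent block models and return the maximum-ICL fit.

    Ties in ICL (within 1e-9) are broken toward the smaller K+L.  The full
    ICL table is attached to the returned fit as ``icl_table``.
    """
    K_range, L_range = list(K_range), list(L_range)
    if not K_range or not L_range:
        raise ValueError("empty model ranges")
    shape = np.asarray(log_counts, dtype=float).shape if not isinstance(
        log_counts, pd.DataFrame
    ) else log_counts.shape
    rows = []
    fits: dict[tuple[int, int], LBMFit] = {}
    for K in K_range:
        if K > shape[0]:
            continue
        for L in L_range:
            if L > shape[1]:
                continue
            f = fit_lbm(
                log_counts, K, L, n_init=n_init, seed=seed, tol=tol, max_iter=max_iter
            )
            fits[(K, L)] = f
            rows.append({"K": K, "L": L, "icl": f.icl, "elbo": f.elbo})
    table = pd.DataFrame(rows)
    best_icl = table["icl"].max()
    near = table[table["icl"] >= best_icl - 1e-9].copy()
    near["complexity"] = near["K"] + near["L"]
    pick = near.sort_values(["complexity", "K", "L"]).iloc[0]
    best = fits[(int(pick["K"]), int(pick["L"]))]
    best.icl_table = table
    return best
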