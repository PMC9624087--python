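"""Congruence and ordination tests linking network structure to host factors.

Three complementary routes quantify how much of the sample clustering is
explained by host phylogeny, host specialization and sampling environment:

- NMI congruence between network-derived sample partitions and external
  classifications, with curveball-null significance;
- (partial) canonical correspondence analysis of the sample-by-group
  indicator matrix on the factors, with row-permutation and edge-permutation
  (degree-preserving null) significance;
- SVD reduction of the incidence matrix followed by redundancy analysis of
  the node factor matrix, with Ezekiel-adjusted R-squared variance
  partitioning over the factor Venn diagram.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gutnet.community import (
    Partition,
    incidence_to_graph,
    leading_eigenvector,
    sample_partition,
)
from gutnet.io import BinaryIncidence, ReadCountTable
from gutnet.nullmodels import curveball_ensemble, empirical_pvalue


# ---------------------------------------------------------------------------
# Normalized mutual information
# ---------------------------------------------------------------------------


def _as_labels(p, nodes: Sequence) -> np.ndarray:
    if isinstance(p, Partition):
        return p.labels_for(nodes)
    if isinstance(p, pd.Series):
        return p.loc[list(nodes)].to_numpy()
    return np.asarray(p)


def nmi(a, b, nodes: Sequence | None = None) -> float:
    """Normalized mutual information 2 I(a,b) / (H(a) + H(b)), natural logs.

    Both partitions trivial (one group each) gives 1; exactly one trivial
    gives 0.  Inputs may be Partitions (with matching node sets), label
    Series, or label arrays.
    """
    if nodes is None:
        if isinstance(a, Partition) and isinstance(b, Partition):
            if set(a.groups) != set(b.groups):
                raise ValueError("partitions cover different node sets")
            nodes = sorted(a.groups, key=str)
        else:
            nodes = None
    la = _as_labels(a, nodes) if nodes is not None else np.asarray(a)
    lb = _as_labels(b, nodes) if nodes is not None else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    n = la.size
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    ka, kb = ia.max() + 1, ib.max() + 1
    if ka == 1 and kb == 1:
        return 1.0
    if ka == 1 or kb == 1:
        return 0.0
    cont = np.zeros((ka, kb))
    np.add.at(cont, (ia, ib), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = (pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])).sum()
    ha = -(pi[pi > 0] * np.log(pi[pi > 0])).sum()
    hb = -(pj[pj > 0] * np.log(pj[pj > 0])).sum()
    return float(np.clip(2 * mi / (ha + hb), 0.0, 1.0))


def detect_sample_partition(inc: BinaryIncidence, fine_tune: bool = False) -> Partition:
    """Leading-eigenvector communities of the bipartite network, restricted
    to sample nodes."""
    return sample_partition(leading_eigenvector(incidence_to_graph(inc), fine_tune=fine_tune))


@dataclass
class CongruenceResult:
    """NMI of network communities against an external classification."""

    mean_nmi: float
    se_nmi: float
    percentile: tuple[float, float]
    mean_p: float | None
    se_p: float | None
    nmis: np.ndarray = field(repr=False, default=None)
    pvalues: np.ndarray = field(repr=False, default=None)


def nmi_congruence_test(
    ensemble: Sequence[BinaryIncidence],
    external: Partition | pd.Series,
    n_obs: int = 100,
    n_null: int = 1000,
    n_trades: int | None = None,
    seed: int = 0,
) -> CongruenceResult:
    """Mean NMI over the ensemble, plus curveball-null mean p-value.

    Per ensemble matrix: detect communities, compute NMI of the sample
    partition against the external classification.  For the first ``n_obs``
    matrices, ``n_null`` degree-preserving (curveball) randomizations are
    re-clustered to build the null NMI distribution and an add-one empirical
    p-value; the mean and SE of those p-values are reported.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    from gutnet.community import bipartite_sample_labels

    samples = ensemble[0].sample_ids
    ext = _as_labels(external, samples)
    for inc in ensemble:
        inc.require_no_empty_samples()
    nmis = np.array(
        [nmi(bipartite_sample_labels(inc.matrix), ext) for inc in ensemble]
    )
    pvals = []
    for i in range(min(n_obs, len(ensemble))):
        nulls = curveball_ensemble(
            ensemble[i], n_null=n_null, n_trades=n_trades, seed=seed + 7919 * (i + 1)
        )
        null_nmis = [nmi(bipartite_sample_labels(nm.matrix), ext) for nm in nulls]
        pvals.append(empirical_pvalue(nmis[i], null_nmis, tail="upper"))
    pvals = np.array(pvals)
    return CongruenceResult(
        mean_nmi=float(nmis.mean()),
        se_nmi=float(nmis.std(ddof=1) / np.sqrt(len(nmis))) if len(nmis) > 1 else 0.0,
        percentile=(float(np.percentile(nmis, 2.5)), float(np.percentile(nmis, 97.5))),
        mean_p=float(pvals.mean()) if len(pvals) else None,
        se_p=float(pvals.std(ddof=1) / np.sqrt(len(pvals))) if len(pvals) > 1 else None,
        nmis=nmis,
        pvalues=pvals,
    )


# ---------------------------------------------------------------------------
# Canonical correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class CCAResult:
    """Constrained chi-square, F statistic and permutation p-values."""

    chi2: float
    total_chi2: float
    f_stat: float
    df1: int
    df2: int
    rank: int
    formula: str = ""
    p_row: float | None = None
    p_edge: float | None = None

    def __post_init__(self) -> None:
        if self.chi2 < -1e-9 or self.chi2 > self.total_chi2 + 1e-9:
            raise ValueError("constrained chi-square outside [0, total]")


def _indicator(response, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Sample x group 0/1 indicator from a Partition, label Series, or
    an already-built indicator DataFrame."""
    if isinstance(response, pd.DataFrame):
        return response.astype(float)
    if isinstance(response, Partition):
        samples = sorted(response.groups, key=str) if samples is None else list(samples)
        labels = response.labels_for(samples)
    elif isinstance(response, pd.Series):
        samples = list(response.index) if samples is None else list(samples)
        labels = response.loc[samples].to_numpy()
    else:
        raise TypeError("response must be a DataFrame, Partition or Series")
    levels = sorted(set(map(str, labels)))
    y = pd.DataFrame(0.0, index=samples, columns=levels)
    for s, l in zip(samples, map(str, labels)):
        y.loc[s, l] = 1.0
    return y


def _design(factors, samples: Sequence[str]) -> np.ndarray:
    """Full-indicator dummy design from one or more categorical factors."""
    if factors is None:
        return None
    if isinstance(factors, pd.Series):
        factors = {str(factors.name or "factor"): factors}
    elif isinstance(factors, pd.DataFrame):
        factors = {c: factors[c] for c in factors.columns}
    cols = []
    for name, ser in factors.items():
        vals = ser.loc[list(samples)].astype(str).to_numpy()
        for lv in sorted(set(vals)):
            cols.append((vals == lv).astype(float))
        if len(set(vals)) < 2:
            raise ValueError(f"factor {name!r} has a single level")
    return np.column_stack(cols)


def _cca_geometry(y: pd.DataFrame):
    total = y.to_numpy().sum()
    p = y.to_numpy() / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("empty rows or columns in response")
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return q, r


def _weighted_basis(x: np.ndarray, r: np.ndarray, resid_basis: np.ndarray | None = None):
    """Orthonormal basis of the row-mass weighted, centered design (optionally
    residualized on a prior basis)."""
    xw = np.sqrt(r)[:, None] * (x - r @ x)
    if resid_basis is not None:
        xw = xw - resid_basis @ (resid_basis.T @ xw)
    u, s, _ = np.linalg.svd(xw, full_matrices=False)
    return u[:, s > 1e-10]


def cca_constrained_inertia(
    response,
    X,
    Z=None,
    samples: Sequence[str] | None = None,
    df_convention: str = "dummy",
    formula: str = "",
) -> CCAResult:
    """(Partial) CCA of a sample-by-group indicator on categorical factors.

    The response is correspondence-standardized; with conditioning factors Z
    their weighted column space is partialled out of both the response and
    the design first.  The constrained chi-square equals, for a single
    unconditioned categorical factor, the Pearson chi-square of the factor x
    group contingency table divided by n.

    ``df_convention``: "dummy" uses df1 = q (factor dummy dfs) and
    df2 = n - 1 - q - q_cond; "rank" uses df1 = rank of the constrained
    solution with df2 = n - 1 - q - rank.
    """
    y = _indicator(response, samples)
    samp = list(y.index)
    q_mat, r = _cca_geometry(y)
    n = len(samp)
    xd = _design(X, samp)
    zb = None
    q_work = q_mat
    q_cond = 0
    if Z is not None:
        zd = _design(Z, samp)
        zb = _weighted_basis(zd, r)
        q_cond = zb.shape[1]
        q_work = q_mat - zb @ (zb.T @ q_mat)
    xb = _weighted_basis(xd, r, resid_basis=zb)
    total = float((q_work**2).sum())
    if xb.shape[1] == 0:
        # design entirely inside the conditioning space: nothing to constrain
        return CCAResult(chi2=0.0, total_chi2=total, f_stat=0.0, df1=0,
                         df2=max(n - 1 - q_cond, 1), rank=0, formula=formula)
    scores = xb.T @ q_work
    ci = float((scores**2).sum())
    q_dfs = xb.shape[1]
    rank = int(np.linalg.matrix_rank(scores)) if scores.size else 0
    resid = max(total - ci, 0.0)
    if df_convention == "dummy":
        df1 = q_dfs
        df2 = n - 1 - q_dfs - q_cond
    elif df_convention == "rank":
        df1 = max(rank, 1)
        df2 = n - 1 - q_dfs - max(rank, 1)
    else:
        raise ValueError(f"unknown df_convention {df_convention!r}")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    f_stat = (ci / df1) / (resid / df2) if resid > 1e-12 else np.inf if ci > 1e-12 else 0.0
    return CCAResult(
        chi2=ci, total_chi2=total, f_stat=f_stat, df1=df1, df2=df2, rank=rank,
        formula=formula,
    )


def cca_permutation_tests(
    response,
    X,
    Z=None,
    null_matrices: Iterable[BinaryIncidence] | None = None,
    n_row_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    samples: Sequence[str] | None = None,
    detector: Callable[[BinaryIncidence], Partition] = detect_sample_partition,
    df_convention: str = "dummy",
    formula: str = "",
) -> CCAResult:
    """Row- and edge-permutation significance for a CCA fraction.

    Row permutations follow the reduced-model scheme: the response is
    residualized on the conditioning factors and its rows are permuted before
    re-projecting on the design.  The edge test re-detects communities on
    each degree-preserving null matrix, rebuilds the indicator response and
    recomputes F; it is only run when the row test is significant at
    ``alpha``, since it asks whether a row-significant effect survives once
    node degrees are held fixed (affinity vs pure richness effect).
    """
    res = cca_constrained_inertia(
        response, X, Z, samples=samples, df_convention=df_convention, formula=formula
    )
    y = _indicator(response, samples)
    samp = list(y.index)
    q_mat, r = _cca_geometry(y)
    n = len(samp)
    xd = _design(X, samp)
    zb = None
    q_work = q_mat
    if Z is not None:
        zd = _design(Z, samp)
        zb = _weighted_basis(zd, r)
        q_work = q_mat - zb @ (zb.T @ q_mat)
    xb = _weighted_basis(xd, r, resid_basis=zb)
    total = float((q_work**2).sum())

    def f_of(qm: np.ndarray) -> float:
        ci = float(((xb.T @ qm) ** 2).sum())
        resid = max(total - ci, 1e-300)
        return (ci / res.df1) / (resid / res.df2)

    rng = np.random.default_rng(seed)
    null_f = [f_of(q_work[rng.permutation(n)]) for _ in range(n_row_perm)]
    res.p_row = empirical_pvalue(res.f_stat, null_f, tail="upper")

    if null_matrices is not None and res.p_row < alpha:
        null_fs = []
        for nm in null_matrices:
            part = detector(nm)
            y_null = _indicator(part, samples=samp)
            r_null = cca_constrained_inertia(
                y_null, X, Z, df_convention=df_convention
            )
            null_fs.append(r_null.f_stat)
        if null_fs:
            res.p_edge = empirical_pvalue(res.f_stat, null_fs, tail="upper")
    return res


#: The sixteen model formulas of the factor decomposition, as
#: (label, constrained factors, conditioning factors) with keys into the
#: factor mapping: "env", "spe", "phy".
CCA_FORMULAS: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("samp env", ("env",), ()),
    ("samp env + Cond(fly spe)", ("env",), ("spe",)),
    ("samp env + Cond(fly phy)", ("env",), ("phy",)),
    ("samp env + Cond(fly spe) + Cond(fly phy)", ("env",), ("spe", "phy")),
    ("fly spe", ("spe",), ()),
    ("fly spe + Cond(samp env)", ("spe",), ("env",)),
    ("fly spe + Cond(fly phy)", ("spe",), ("phy",)),
    ("Cond(samp env) + fly spe + Cond(fly phy)", ("spe",), ("env", "phy")),
    ("fly phy", ("phy",), ()),
    ("fly phy + Cond(samp env)", ("phy",), ("env",)),
    ("fly phy + Cond(fly spe)", ("phy",), ("spe",)),
    ("Cond(samp env) + Cond(fly spe) + fly phy", ("phy",), ("env", "spe")),
    ("samp env + fly spe", ("env", "spe"), ()),
    ("samp env + fly phy", ("env", "phy"), ()),
    ("fly spe + fly phy", ("spe", "phy"), ()),
    ("samp env + fly spe + fly phy", ("env", "spe", "phy"), ()),
]


def cca_fraction_table(
    response,
    factors: Mapping[str, pd.Series],
    null_matrices_fn: Callable[[int], Iterable[BinaryIncidence]] | None = None,
    n_row_perm: int = 0,
    seed: int = 0,
    samples: Sequence[str] | None = None,
    df_convention: str = "dummy",
) -> pd.DataFrame:
    """All sixteen CCA fraction rows (factor alone, conditioned, combined).

    ``factors`` maps "env", "spe", "phy" to per-sample label Series.  With
    ``n_row_perm > 0`` row-permutation p-values are added; with
    ``null_matrices_fn`` (row index -> null matrices) edge p-values are added
    for row-significant fractions.
    """
    missing = {"env", "spe", "phy"} - set(factors)
    if missing:
        raise ValueError(f"missing factors: {sorted(missing)}")
    rows = []
    for i, (label, xs, zs) in enumerate(CCA_FORMULAS):
        x = pd.DataFrame({k: factors[k] for k in xs})
        z = pd.DataFrame({k: factors[k] for k in zs}) if zs else None
        if n_row_perm > 0:
            nulls = null_matrices_fn(i) if null_matrices_fn is not None else None
            r = cca_permutation_tests(
                response, x, z, null_matrices=nulls, n_row_perm=n_row_perm,
                seed=seed + i, samples=samples, df_convention=df_convention,
                formula=label,
            )
        else:
            r = cca_constrained_inertia(
                response, x, z, samples=samples, df_convention=df_convention,
                formula=label,
            )
        rows.append(
            {
                "formula": label,
                "chi2": r.chi2,
                "F": r.f_stat,
                "p_row": r.p_row,
                "p_edge": r.p_edge,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SVD reduction and redundancy analysis
# ---------------------------------------------------------------------------


@dataclass
class SVDFactors:
    """Low-rank factorization of an incidence matrix: L (n x k) and R (p x k)
    with L R^T the rank-k truncated SVD reconstruction."""

    L: np.ndarray
    R: np.ndarray
    singular_values: np.ndarray
    k: int


def svd_reduce(matrix, k: int) -> SVDFactors:
    """Truncated SVD with the singular values split evenly between the two
    factor matrices: L = U_k S_k^1/2, R = V_k S_k^1/2."""
    x = np.asarray(matrix, dtype=float)
    if not 1 <= k <= min(x.shape):
        raise ValueError(f"k={k} out of range for {x.shape} matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    root = np.sqrt(s[:k])
    return SVDFactors(
        L=u[:, :k] * root, R=vt[:k].T * root, singular_values=s[:k], k=k
    )


def reconstruct_network(
    f: SVDFactors, density_target: int, like: BinaryIncidence | None = None
) -> BinaryIncidence:
    """Binary network with the ``density_target`` largest entries of L R^T as
    edges; ties broken by row-major cell order."""
    approx = f.L @ f.R.T
    n, p = approx.shape
    if density_target > n * p or density_target < 0:
        raise ValueError("density_target out of range")
    out = np.zeros(n * p, dtype=np.int8)
    if density_target > 0:
        order = np.argsort(-approx.ravel(), kind="stable")
        out[order[:density_target]] = 1
    out = out.reshape(n, p)
    if like is not None:
        df = pd.DataFrame(out, index=like.incidence.index, columns=like.incidence.columns)
    else:
        df = pd.DataFrame(out)
    return BinaryIncidence(df, provenance={"svd_rank": f.k, "edges": int(density_target)})


def select_rank(
    matrices: ReadCountTable | Sequence[BinaryIncidence],
    k_max: int,
    ensemble_size: int = 20,
    seed: int = 0,
    depth: int = 3000,
    threshold: int = 3,
) -> tuple[int, np.ndarray]:
    """Pick the SVD rank by community congruence with the original network.

    For each rarefied presence-absence matrix and each k = 1..k_max, the
    matrix is SVD-approximated at rank k with the observed edge count and
    both versions are clustered; the mean NMI curve over matrices is scanned
    for its first local maximum.  Returns (k, mean NMI per rank).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if isinstance(matrices, ReadCountTable):
        from gutnet.rarefaction import make_ensemble

        matrices = make_ensemble(matrices, depth=depth, threshold=threshold,
                                 n=ensemble_size, seed=seed)
    matrices = list(matrices)[:ensemble_size]
    curves = np.zeros((len(matrices), k_max))
    for i, inc in enumerate(matrices):
        samples = inc.sample_ids
        orig = detect_sample_partition(inc)
        edges = int(inc.matrix.sum())
        for k in range(1, min(k_max, min(inc.matrix.shape)) + 1):
            rec = reconstruct_network(svd_reduce(inc.matrix, k), edges, like=inc)
            g = incidence_to_graph_allow_empty(rec)
            part = sample_partition(leading_eigenvector(g))
            curves[i, k - 1] = nmi(orig.labels_for(samples), part.labels_for(samples))
    curve = curves.mean(axis=0)
    for k in range(1, k_max + 1):
        left_ok = k == 1 or curve[k - 1] >= curve[k - 2]
        right_ok = k == k_max or curve[k - 1] > curve[k]
        if left_ok and right_ok and k < k_max:
            return k, curve
    warnings.warn("no interior local maximum in the NMI curve; returning argmax")
    return int(np.argmax(curve)) + 1, curve


def incidence_to_graph_allow_empty(inc: BinaryIncidence):
    """Bipartite graph that tolerates empty sample rows (used for SVD
    reconstructions, which need not cover every sample)."""
    import networkx as nx

    g = nx.Graph()
    for s in inc.sample_ids:
        g.add_node(s, role="sample")
    for t in inc.genus_ids:
        g.add_node(f"g:{t}", role="genus")
    rows, cols = np.nonzero(inc.matrix)
    samples, genera = inc.sample_ids, inc.genus_ids
    g.add_edges_from((samples[i], f"g:{genera[j]}") for i, j in zip(rows, cols))
    return g


@dataclass
class VariancePartition:
    """Venn fractions of Ezekiel-adjusted R-squared over three factors."""

    fractions: dict[str, float]
    residual: float
    r2: dict[str, float]
    adjusted_r2: dict[str, float]


def rda_partition(L, factors: Mapping[str, pd.Series] | pd.DataFrame) -> VariancePartition:
    """RDA variance partitioning of a node factor matrix on external factors.

    For every subset S of factors, R2(S) is the share of total sum of
    squares of the column-centered L explained by the dummy design of S;
    Ezekiel adjustment 1 - (1 - R2)(n - 1)/(n - m - 1) with m the rank of
    the centered design (factor levels can be collinear across factors, so
    raw dummy dfs would bias the adjustment).  The Venn fractions solve the
    inclusion-exclusion system on adjusted R2 (individual fractions can be
    negative and are reported as-is); residual = 1 - adjusted R2(all).
    """
    if isinstance(factors, pd.DataFrame):
        factors = {c: factors[c] for c in factors.columns}
    names = list(factors)
    if not 1 <= len(names) <= 3:
        raise ValueError("variance partitioning supports 1-3 factors")
    x = np.asarray(L, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    total_ss = float((xc**2).sum())
    if total_ss == 0:
        raise ValueError("constant factor matrix")
    samp = list(next(iter(factors.values())).index)
    if len(samp) != n:
        raise ValueError("factors not aligned with rows of L")

    def r2_of(subset: tuple[str, ...]) -> float:
        d = _design({k: factors[k] for k in subset}, samp)
        dc = d - d.mean(axis=0)
        coef, *_ = np.linalg.lstsq(dc, xc, rcond=None)
        fitted = dc @ coef
        return float((fitted**2).sum() / total_ss)

    def dfs_of(subset: tuple[str, ...]) -> int:
        d = _design({k: factors[k] for k in subset}, samp)
        return int(np.linalg.matrix_rank(d - d.mean(axis=0)))

    subsets = [
        tuple(c) for size in range(1, len(names) + 1)
        for c in itertools.combinations(names, size)
    ]
    r2 = {}
    adj = {}
    for s in subsets:
        m = dfs_of(s)
        if m >= n - 1:
            raise ValueError(f"saturated design for subset {s}")
        val = r2_of(s)
        r2["+".join(s)] = val
        adj["+".join(s)] = 1 - (1 - val) * (n - 1) / (n - m - 1)

    # Solve the inclusion-exclusion system: adjR2(S) = sum of fractions f_T
    # over all T intersecting S.
    terms = subsets  # Venn regions indexed by the subset of factors they involve
    a_mat = np.array(
        [[1.0 if set(t) & set(s) else 0.0 for t in terms] for s in subsets]
    )
    b_vec = np.array([adj["+".join(s)] for s in subsets])
    f_vec = np.linalg.solve(a_mat, b_vec)
    fractions = {"&".join(t): float(v) for t, v in zip(terms, f_vec)}
    residual = float(1 - adj["+".join(tuple(names))])
    return VariancePartition(
        fractions=fractions, residual=residual, r2=r2, adjusted_r2=adj
    )
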