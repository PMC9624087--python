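"""Null models for network statistics.

Binary presence-absence matrices are randomized with the curveball
algorithm, a Markov chain whose trades exchange genera between pairs of
samples while keeping every row and column sum fixed (the bipartite
configuration model).  Weighted (log-count) matrices are randomized by
Gaussian sampling around the margin product, which preserves expected row
and column means while destroying block structure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from gutnet.io import BinaryIncidence


def default_n_trades(n_rows: int) -> int:
    """Standard mixing heuristic: five trades per matrix row."""
    return 5 * n_rows


def curveball(
    inc: BinaryIncidence, n_trades: int | None = None, seed: int | None = None
) -> BinaryIncidence:
    """One curveball chain from the observed matrix.

    Each trade picks two distinct rows, pools the columns exclusive to each,
    and deals a random subset of the pool (of the original size) back to the
    first row, the rest to the second.  Row and column sums are preserved
    exactly at every step.
    """
    m = inc.matrix.astype(np.int8)
    n_rows = m.shape[0]
    if n_trades is None:
        n_trades = default_n_trades(n_rows)
    if n_trades < 1:
        raise ValueError("n_trades must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [set(np.nonzero(r)[0].tolist()) for r in m]
    for _ in range(n_trades):
        a, b = rng.choice(n_rows, size=2, replace=False)
        ex_a = rows[a] - rows[b]
        ex_b = rows[b] - rows[a]
        if not ex_a or not ex_b:
            continue
        pool = sorted(ex_a | ex_b)
        rng.shuffle(pool)
        new_a = set(pool[: len(ex_a)])
        new_b = set(pool[len(ex_a) :])
        shared_a = rows[a] - ex_a
        shared_b = rows[b] - ex_b
        rows[a] = shared_a | new_a
        rows[b] = shared_b | new_b
    out = np.zeros_like(m)
    for i, cols in enumerate(rows):
        out[i, sorted(cols)] = 1
    prov = dict(inc.provenance)
    prov.update({"null": "curveball", "n_trades": int(n_trades), "null_seed": seed})
    return BinaryIncidence(
        pd.DataFrame(out, index=inc.incidence.index, columns=inc.incidence.columns),
        provenance=prov,
    )


def curveball_ensemble(
    inc: BinaryIncidence,
    n_null: int = 1000,
    n_trades: int | None = None,
    seed: int = 0,
) -> list[BinaryIncidence]:
    """Independent curveball chains from the observed matrix, one per index;
    chain i is seeded with ``seed + i``."""
    return [curveball(inc, n_trades=n_trades, seed=seed + i) for i in range(n_null)]


def gaussian_margin_null(
    log_counts,
    n_null: int = 1000,
    seed: int = 0,
    sd_mode: str = "pooled",
    sd_value: float | None = None,
) -> list[np.ndarray]:
    """Gaussian sampling on the margin product of a log-transformed matrix.

    The expected cell is ``m_ij = rowmean_i * colmean_j / grandmean``; cells
    are drawn Normal(m_ij, sd) and truncated at zero.  With
    ``sd_mode="pooled"`` (default) sd is the pooled standard deviation of the
    observed residuals x - m; ``sd_mode="constant"`` uses ``sd_value``.
    """
    x = np.asarray(log_counts, dtype=float)
    grand = x.mean()
    if grand == 0:
        raise ValueError("zero grand mean")
    m = np.outer(x.mean(axis=1), x.mean(axis=0)) / grand
    if sd_mode == "pooled":
        sd = float(np.std(x - m))
    elif sd_mode == "constant":
        if sd_value is None:
            raise ValueError("sd_value required for sd_mode='constant'")
        sd = float(sd_value)
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    rng = np.random.default_rng(seed)
    return [np.clip(rng.normal(m, sd), 0.0, None) for _ in range(n_null)]


def empirical_pvalue(
    observed_stat: float, null_stats: Sequence[float], tail: str = "upper"
) -> float:
    """Add-one empirical p-value: (1 + #{null at least as extreme}) / (1 + N)."""
    nulls = np.asarray(list(null_stats), dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null set")
    if tail == "upper":
        extreme = int((nulls >= observed_stat).sum())
    elif tail == "lower":
        extreme = int((nulls <= observed_stat).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + extreme) / (1 + nulls.size)
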