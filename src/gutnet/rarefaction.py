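"""Rarefaction to a common depth, mock-calibrated presence thresholds, and
ensembles of presence-absence matrices.

Rarefaction is true without-replacement subsampling (multivariate
hypergeometric), so a sample rarefied to its own depth is returned
unchanged.  Because rarefaction is random, downstream community analyses run
on an ensemble of presence-absence matrices rather than a single one.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from gutnet.io import BinaryIncidence, ReadCountTable
from gutnet.synthetic import MockSpec


def rarefy(table: ReadCountTable, depth: int, seed: int | None = None) -> ReadCountTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    depths = table.depths
    short = depths[depths < depth]
    if len(short):
        raise ValueError(
            f"samples shallower than rarefaction depth {depth}: {list(short.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.matrix)
    for i, row in enumerate(table.matrix):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return ReadCountTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def binarize(table: ReadCountTable, threshold: int, inclusive: bool = False) -> BinaryIncidence:
    """Presence-absence from counts: present iff count > threshold.

    The strict inequality treats counts up to and including the threshold as
    noise (a threshold of 3 means "false positives never exceeded three
    reads").  ``inclusive=True`` switches to count >= threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if inclusive:
        inc = (table.counts >= threshold).astype(np.int8)
    else:
        inc = (table.counts > threshold).astype(np.int8)
    return BinaryIncidence(inc, provenance={"threshold": int(threshold), "inclusive": inclusive})


def calibrate_presence_threshold(
    mock_tables: Sequence[ReadCountTable],
    spec: MockSpec,
    depth: int = 3000,
    n_reps: int = 100,
    seed: int = 0,
) -> int:
    """Presence threshold = the largest count any known false-positive genus
    attains over ``n_reps`` rarefactions of every mock run.

    Counts at or below this value are indistinguishable from false-positive
    noise and are zeroed by :func:`binarize` with the strict inequality.
    """
    fp_genera = set(spec.false_positives)
    observed_fp = False
    worst = 0
    for t_idx, mock in enumerate(mock_tables):
        present = [g for g in fp_genera if g in mock.genus_ids]
        if not present:
            continue
        if (mock.counts[present].to_numpy() > 0).any():
            observed_fp = True
        for rep in range(n_reps):
            rar = rarefy(mock, depth, seed=seed + 10_000 * t_idx + rep)
            worst = max(worst, int(rar.counts[present].to_numpy().max()))
    if not observed_fp:
        warnings.warn("no false-positive reads observed in mock runs; threshold 0")
        return 0
    return worst


def make_ensemble(
    table: ReadCountTable,
    depth: int = 3000,
    threshold: int = 3,
    n: int = 1000,
    seed: int = 0,
) -> list[BinaryIncidence]:
    """``n`` independent rarefaction+threshold presence-absence matrices.

    Matrix i is rarefied with seed ``seed + i`` so the ensemble is
    reproducible and extendable; per-matrix provenance records depth,
    threshold and the derived seed.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    out = []
    for i in range(n):
        rar = rarefy(table, depth, seed=seed + i)
        inc = binarize(rar, threshold)
        inc.provenance.update({"depth": int(depth), "seed": seed + i, "index": i})
        out.append(inc)
    return out
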