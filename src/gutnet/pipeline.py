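"""End-to-end orchestration: from a read-count table (real or synthetic) to
diversity, consensus-clustering, congruence, CCA and SVD+RDA outputs.

All randomness flows from one master seed through fixed per-stage offsets,
so a config plus seed reproduces every output byte-for-byte.  Every run
writes a provenance JSON with the seed, config hash and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import gutnet
from gutnet.community import (
    ConsensusClustering,
    select_lbm,
)
from gutnet.diversity import bootstrap_partition, bray_curtis, nmds, partition_diversity
from gutnet.inference import (
    cca_fraction_table,
    nmi_congruence_test,
    rda_partition,
    select_rank,
    svd_reduce,
)
from gutnet.io import (
    ReadCountTable,
    SampleMetadata,
    TaxonomyTable,
    filter_low_abundance,
    read_count_table,
    read_sample_metadata,
    read_taxonomy,
    write_count_table,
)
from gutnet.rarefaction import make_ensemble
from gutnet.synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("gutnet")

# fixed per-stage seed offsets under the master seed
STAGE_SEEDS = {
    "synthetic": 0,
    "ensemble": 1_000,
    "diversity": 2_000,
    "congruence": 3_000,
    "cca": 4_000,
    "svd": 5_000,
    "lbm": 6_000,
    "subset_field": 7_000,
    "subset_lab": 8_000,
}


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    synthetic: bool = True
    filter_threshold: float = 0.001
    depth: int = 3000
    presence_threshold: int = 3
    n_matrices: int = 1000
    n_obs: int = 100
    n_null: int = 1000
    n_row_perm: int = 1000
    nmds_starts: int = 20
    n_boot: int = 1000
    lbm_k_max: int = 6
    lbm_l_max: int = 10
    lbm_n_init: int = 25
    svd_k_max: int = 6
    svd_ensemble_size: int = 20
    seed: int = 0
    outdir: str = "gutnet-out"

    def validate(self) -> None:
        for name in ("n_matrices", "n_obs", "n_null", "depth", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.synthetic and self.counts_path is None:
            raise ValueError("counts_path required unless synthetic=True")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: AnalysisConfig):
    if cfg.synthetic:
        table, meta, tax, truth = generate_dataset(
            SyntheticConfig(seed=cfg.seed + STAGE_SEEDS["synthetic"])
        )
        return table, meta, tax
    table = read_count_table(cfg.counts_path)
    meta = read_sample_metadata(cfg.metadata_path).aligned_to(table)
    tax = read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None
    return table, meta, tax


def _factors(meta: SampleMetadata) -> dict[str, pd.Series]:
    return {
        "env": meta.table["environment"],
        "spe": meta.table["specialization"],
        "phy": meta.table["phylogeny_group"],
    }


def run_full_analysis(cfg: AnalysisConfig) -> Path:
    """Run every stage and write its outputs under ``cfg.outdir``."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[dict] = []

    def done(stage: str):
        stage_log.append({"stage": stage, "elapsed_s": round(time.time() - t0, 2)})
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

    table, meta, tax = _load_inputs(cfg)
    meta = meta.aligned_to(table)
    filtered = filter_low_abundance(table, cfg.filter_threshold)
    filtered.require_analysable()
    write_count_table(filtered, out / "filtered_counts.tsv")
    done(f"filter {table.counts.shape} -> {filtered.counts.shape}")

    # diversity
    seed_div = cfg.seed + STAGE_SEEDS["diversity"]
    per_sample = bootstrap_partition(filtered, None, n_boot=cfg.n_boot, seed=seed_div)
    rows = [{
        "grouping": "per-sample", "alpha": per_sample.alpha, "beta": per_sample.beta,
        "gamma": per_sample.gamma,
        **{f"{k}_{b}": v[i] for k, v in per_sample.ci.items() for i, b in enumerate(("lo", "hi"))},
    }]
    for name, col in (("environment", "environment"),
                      ("specialization", "specialization"),
                      ("phylogeny", "phylogeny_group")):
        grouping = meta.table[col].to_dict()
        part = partition_diversity(filtered, grouping)
        rows.append({"grouping": name, "alpha": part.alpha, "beta": part.beta,
                     "gamma": part.gamma})
    pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
    bc = bray_curtis(filtered)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")
    coords, stress = nmds(bc, n_starts=cfg.nmds_starts, seed=seed_div)
    pd.DataFrame(coords, index=filtered.sample_ids, columns=["NMDS1", "NMDS2"]).to_csv(
        out / "nmds_coordinates.tsv", sep="\t"
    )
    (out / "nmds_stress.json").write_text(json.dumps({"stress1": stress}))
    done("diversity")

    # ensemble consensus clustering (all samples + environment subsets)
    results_consensus = {}
    for label, sel, stage in (
        ("all", None, "ensemble"),
        ("field", "field", "subset_field"),
        ("laboratory", "laboratory", "subset_lab"),
    ):
        sub = filtered if sel is None else subset_by_environment(filtered, meta, sel)
        cc = ConsensusClustering(
            depth=cfg.depth, threshold=cfg.presence_threshold,
            n_matrices=cfg.n_matrices, random_state=cfg.seed + STAGE_SEEDS[stage],
        ).fit(sub)
        cc.consensus_matrix_.matrix.to_csv(out / f"consensus_{label}.tsv", sep="\t")
        results_consensus[label] = {
            "mean_n_groups": cc.mean_n_groups_, "se_n_groups": cc.se_n_groups_,
            "mean_modularity": cc.mean_modularity_, "se_modularity": cc.se_modularity_,
        }
        done(f"consensus[{label}]")
    (out / "consensus_summary.json").write_text(json.dumps(results_consensus, indent=2))

    # congruence tests (Table-1 analogue)
    seed_con = cfg.seed + STAGE_SEEDS["congruence"]
    ensemble = make_ensemble(
        filtered, depth=cfg.depth, threshold=cfg.presence_threshold,
        n=cfg.n_matrices, seed=cfg.seed + STAGE_SEEDS["ensemble"],
    )
    con_rows = []
    for name, col in (("tribe", "tribe"), ("phylogeny", "phylogeny_group"),
                      ("environment", "environment"), ("specialization", "specialization")):
        res = nmi_congruence_test(
            ensemble, meta.table[col], n_obs=cfg.n_obs, n_null=cfg.n_null, seed=seed_con,
        )
        con_rows.append({
            "factor": name, "mean_nmi": res.mean_nmi, "se_nmi": res.se_nmi,
            "pi_lo": res.percentile[0], "pi_hi": res.percentile[1],
            "mean_p": res.mean_p, "se_p": res.se_p,
        })
    pd.DataFrame(con_rows).to_csv(out / "congruence.tsv", sep="\t", index=False)
    done("congruence")

    # CCA fraction table on the consensus classification (Table-2 analogue)
    cc_all = ConsensusClustering(
        depth=cfg.depth, threshold=cfg.presence_threshold,
        n_matrices=min(cfg.n_matrices, 200),
        random_state=cfg.seed + STAGE_SEEDS["cca"],
    ).fit(filtered)
    classification = pd.Series(cc_all.labels_, index=cc_all.sample_ids_)
    cca_tab = cca_fraction_table(
        classification, _factors(meta), n_row_perm=cfg.n_row_perm,
        seed=cfg.seed + STAGE_SEEDS["cca"],
    )
    cca_tab.to_csv(out / "cca_fractions.tsv", sep="\t", index=False)
    done("cca")

    # SVD + RDA variance partition (Figure-7 analogue)
    seed_svd = cfg.seed + STAGE_SEEDS["svd"]
    k, curve = select_rank(
        filtered, k_max=cfg.svd_k_max, ensemble_size=cfg.svd_ensemble_size,
        seed=seed_svd, depth=cfg.depth, threshold=cfg.presence_threshold,
    )
    logx = np.log10(filtered.matrix + 1.0)
    fac = svd_reduce(logx, k)
    vp = rda_partition(
        pd.DataFrame(fac.L, index=filtered.sample_ids), _factors(meta)
    )
    (out / "variance_partition.json").write_text(json.dumps({
        "svd_rank": int(k), "nmi_curve": curve.tolist(),
        "fractions": vp.fractions, "residual": vp.residual,
        "adjusted_r2": vp.adjusted_r2,
    }, indent=2))
    done("svd-rda")

    # Gaussian LBM on log counts (Figure-5 analogue)
    lbm = select_lbm(
        pd.DataFrame(logx, index=filtered.sample_ids, columns=filtered.genus_ids),
        K_range=range(1, cfg.lbm_k_max + 1), L_range=range(1, cfg.lbm_l_max + 1),
        n_init=cfg.lbm_n_init, seed=cfg.seed + STAGE_SEEDS["lbm"],
    )
    row_order = list(lbm.row_groups.sort_values(kind="stable").index)
    col_order = list(lbm.col_groups.sort_values(kind="stable").index)
    (out / "lbm.json").write_text(json.dumps({
        "K": lbm.K, "L": lbm.L, "icl": lbm.icl,
        "row_groups": {str(k): int(v) for k, v in lbm.row_groups.items()},
        "col_groups": {str(k): int(v) for k, v in lbm.col_groups.items()},
        "block_means": lbm.means.tolist(),
        "block_variances": lbm.variances.tolist(),
        "heatmap_row_order": row_order,
        "heatmap_col_order": col_order,
        "icl_table": lbm.icl_table.to_dict(orient="records"),
    }, indent=2))
    done("lbm")

    provenance = {
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "config": dataclasses.asdict(cfg),
        "gutnet_version": gutnet.__version__,
        "stages": stage_log,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


def subset_by_environment(
    table: ReadCountTable, meta: SampleMetadata, environment: str
) -> ReadCountTable:
    keep = [s for s in table.sample_ids
            if meta.table.loc[s, "environment"] == environment]
    if not keep:
        raise ValueError(f"no samples in environment {environment!r}")
    return table.subset_samples(keep)


def run_subset(cfg: AnalysisConfig, environment: str) -> Path:
    """Run the full pipeline on the samples of one environment only."""
    table, meta, tax = _load_inputs(cfg)
    sub = subset_by_environment(filter_low_abundance(table, cfg.filter_threshold),
                                meta.aligned_to(table), environment)
    if sub.counts.shape[0] < 4:
        raise ValueError("need at least 4 samples after subsetting")
    sub_cfg = dataclasses.replace(cfg, outdir=str(Path(cfg.outdir) / environment))
    # re-enter with the subset written to a temp table
    out = Path(sub_cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(sub, out / "subset_counts.tsv")
    cc = ConsensusClustering(
        depth=cfg.depth, threshold=cfg.presence_threshold,
        n_matrices=cfg.n_matrices,
        random_state=cfg.seed + STAGE_SEEDS[f"subset_{'field' if environment == 'field' else 'lab'}"],
    ).fit(sub)
    cc.consensus_matrix_.matrix.to_csv(out / "consensus.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps({
        "environment": environment,
        "mean_n_groups": cc.mean_n_groups_,
        "mean_modularity": cc.mean_modularity_,
    }, indent=2))
    return out
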