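# gutnet

Network-based structure analysis of host-associated gut microbiota.

`gutnet` takes a samples x bacterial-genera read-count table — the motivating
system is the gut microbiota of the eight sympatric tephritid fruit-fly
species of Reunion Island, each sampled once in the laboratory and once in
the field — and quantifies how much of the community structure is explained
by host phylogeny, host specialization (host-plant range) and sampling
environment.  It is written for microbial ecologists who want the full
chain, from a genus-level count table to significance-tested structure
statements, as reusable, seeded, tested code.

## What it computes

- **Diversity partitioning.**  Order-1 Hill numbers (exp of Shannon
  entropy, "genus equivalents") partitioned multiplicatively,
  γ = ᾱ · β with β the effective number of completely distinct
  communities; hierarchical bootstrap CIs; Bray-Curtis dissimilarity and
  non-metric multidimensional scaling (Kruskal stress-1).
- **Ensemble community detection.**  Because rarefaction is random, the
  count table is converted into an ensemble of presence-absence matrices
  (rarefy to 3000 reads, presence iff count > 3, threshold calibrated from
  mock communities).  Each matrix is a bipartite sample-genus network,
  partitioned by Newman's leading-eigenvector modularity
  (Q = Σ_g [e_g/m − (d_g/2m)²]); the ensemble is summarized by a consensus
  co-clustering matrix.
- **Null models.**  The curveball algorithm (exact fixed-margin
  randomization of binary matrices) and a Gaussian margin-product null for
  log-count matrices; add-one empirical p-values.
- **Congruence and ordination inference.**  NMI (2I/(H₁+H₂)) between
  network communities and host factors with curveball significance;
  (partial) canonical correspondence analysis of the sample classification
  on the factors with row- and edge-permutation tests (richness vs affinity
  effects); SVD reduction of the incidence matrix with NMI-based rank
  selection, followed by redundancy analysis and Ezekiel-adjusted R²
  variance partitioning.
- **Gaussian latent block model.**  Simultaneous biclustering of
  log10(reads+1) by variational EM with block-specific means and variances,
  model choice by ICL.
- **Synthetic data.**  A seeded generator mirroring the 16-sample study
  design (dominant core family ~69% of reads, phylogeny-driven genus
  blocks, environment-linked genera, Dirichlet-multinomial noise, realistic
  depths) with planted ground truth, plus mock-community runs for threshold
  calibration.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

```python
from gutnet import (SyntheticConfig, generate_dataset, partition_diversity,
                    ConsensusClustering, nmi, cca_constrained_inertia)

table, meta, tax, truth = generate_dataset(SyntheticConfig(seed=11))
d = partition_diversity(table)          # every sample its own unit
print(f"gamma {d.gamma:.2f} = alpha {d.alpha:.2f} x beta {d.beta:.2f}")

cc = ConsensusClustering(n_matrices=200, random_state=0).fit(table)
print(f"mean groups {cc.mean_n_groups_:.2f}, mean Q {cc.mean_modularity_:.3f}")
print("NMI vs planted phylogeny groups:",
      round(nmi(cc.labels_, truth.sample_partition.labels_for(cc.sample_ids_)), 3))

res = cca_constrained_inertia(
    meta.table["phylogeny_group"], meta.table["environment"])
print(f"CCA chi2 phylogeny-vs-environment: {res.chi2:.3f}")
```

prints

```
gamma 21.74 = alpha 14.41 x beta 1.51
mean groups 3.29, mean Q 0.158
NMI vs planted phylogeny groups: 0.835
CCA chi2 phylogeny-vs-environment: 0.000
```

Read: the 16 synthetic samples hold 21.7 effective genera in total, of
which 14.4 is the average within-sample diversity; β = 1.51 effective
distinct communities.  Ensemble clustering finds ~3.3 sample groups per
rarefied matrix at modularity 0.16, and the consensus partition is strongly
(NMI 0.84) aligned with the planted phylogeny groups.  The last line is a
sanity check: phylogeny group and environment are orthogonal by design, so
their constrained chi-square is 0.

The same pipeline runs end-to-end from the shell:

```bash
gutnet synth --seed 1 --outdir demo-data
gutnet all --seed 1 --outdir demo-out --n-matrices 200   # all stages
gutnet subset --environment field --outdir demo-out
```

Defaults follow the published scale (1000-matrix ensembles, 100 observed x
1000 null matrices per test), which takes tens of minutes; a YAML config
passed with `--config` controls every size (see `AnalysisConfig`).

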