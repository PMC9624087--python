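import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency
from sklearn.metrics import normalized_mutual_info_score

from gutnet.community import Partition
from gutnet.inference import (
    cca_constrained_inertia,
    cca_fraction_table,
    cca_permutation_tests,
    nmi,
    nmi_congruence_test,
    rda_partition,
    reconstruct_network,
    select_rank,
    svd_reduce,
)
from gutnet.io import BinaryIncidence
from gutnet.nullmodels import curveball_ensemble
from gutnet.rarefaction import make_ensemble
from gutnet.study import study_metadata, weighted_matrix_sample_groups


class TestNMI:
    def test_identical_partitions_one(self):
        assert nmi([0, 0, 1, 1], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_singletons_vs_single_group_zero(self):
        assert nmi([0, 1, 2, 3], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_both_trivial_one(self):
        assert nmi([0, 0, 0], [1, 1, 1]) == pytest.approx(1.0)

    def test_independent_crossed_zero(self):
        assert nmi([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_sklearn_agreement(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=12)
        b = rng.integers(0, 4, size=12)
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)
        if len(set(a)) > 1 and len(set(b)) > 1:
            expected = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert nmi(a, b) == pytest.approx(expected, abs=1e-9)

    def test_refinement_toward_agreement_monotone(self):
        target = np.array([0, 0, 1, 1, 2, 2])
        coarse = np.array([0, 0, 0, 0, 1, 1])
        assert nmi(coarse, target) < nmi(target, target)

    def test_mismatched_nodes_rejected(self):
        a = Partition({"x": 0, "y": 1})
        b = Partition({"x": 0, "z": 1})
        with pytest.raises(ValueError):
            nmi(a, b)


class TestCongruence:
    def test_strong_signal_recovery(self):
        # per-matrix detection needs a crisper presence pattern than the
        # consensus route, hence the larger block enrichment here
        from gutnet.synthetic import SyntheticConfig, generate_dataset

        table, meta, _, truth = generate_dataset(
            SyntheticConfig.planted_recovery(seed=5, block_effect=5.0)
        )
        ens = make_ensemble(table, n=30, seed=0)
        ext = pd.Series(
            truth.sample_partition.labels_for(table.sample_ids),
            index=table.sample_ids,
        )
        res = nmi_congruence_test(ens, ext, n_obs=5, n_null=99, seed=0)
        assert res.mean_nmi >= 0.9
        assert res.mean_p <= 0.05
        assert 0 <= res.percentile[0] <= res.percentile[1] <= 1


class TestCCA:
    def test_orthogonal_design_zero_inertia(self):
        # response groups perfectly balanced across factor levels
        samples = [f"s{i}" for i in range(8)]
        groups = pd.Series(["a", "a", "b", "b"] * 2, index=samples)
        factor = pd.Series(["u"] * 4 + ["v"] * 4, index=samples)
        res = cca_constrained_inertia(groups, factor)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_single_factor_equals_contingency_chi2_over_n(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        samples = [f"s{i}" for i in range(n)]
        groups = pd.Series(rng.integers(0, 3, size=n).astype(str), index=samples)
        factor = pd.Series(rng.integers(0, 4, size=n).astype(str), index=samples)
        if groups.nunique() < 2 or factor.nunique() < 2:
            return
        res = cca_constrained_inertia(groups, factor)
        table = pd.crosstab(factor, groups).to_numpy()
        chi2 = chi2_contingency(table, correction=False)[0]
        assert res.chi2 == pytest.approx(chi2 / n, abs=1e-10)

    def test_fraction_conditioned_on_itself_zero(self):
        meta = study_metadata().table
        cls = weighted_matrix_sample_groups()
        phy = meta["phylogeny_group"]
        res = cca_constrained_inertia(cls, phy, Z=phy)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_printed_fraction_table_reproduced(self):
        # chi-squares of the full 16-row decomposition for the three-group
        # read-count classification of the 16-sample study design
        meta = study_metadata().table
        cls = weighted_matrix_sample_groups()
        factors = {"env": meta["environment"], "spe": meta["specialization"],
                   "phy": meta["phylogeny_group"]}
        tab = cca_fraction_table(cls, factors).set_index("formula")["chi2"]
        expected = {
            "samp env": 0.250,
            "samp env + Cond(fly spe)": 0.250,
            "samp env + Cond(fly phy)": 0.250,
            "samp env + Cond(fly spe) + Cond(fly phy)": 0.250,
            "fly spe": 0.630,
            "fly spe + Cond(samp env)": 0.630,
            "fly spe + Cond(fly phy)": 0.000,
            "Cond(samp env) + fly spe + Cond(fly phy)": 0.000,
            "fly phy": 1.333,
            "fly phy + Cond(samp env)": 1.333,
            "fly phy + Cond(fly spe)": 0.704,
            "Cond(samp env) + Cond(fly spe) + fly phy": 0.704,
            "samp env + fly spe": 0.880,
            "samp env + fly phy": 1.583,
            "fly spe + fly phy": 1.333,
            "samp env + fly spe + fly phy": 1.583,
        }
        for formula, value in expected.items():
            assert tab[formula] == pytest.approx(value, abs=5e-4), formula

    def test_row_permutation_detects_planted_signal(self, synthetic_strong):
        table, meta, _, truth = synthetic_strong
        ens = make_ensemble(table, n=1, seed=0)
        from gutnet.community import bipartite_sample_labels

        labels = bipartite_sample_labels(ens[0].matrix)
        cls = pd.Series(labels, index=table.sample_ids)
        phy = meta.table["phylogeny_group"]
        res = cca_permutation_tests(cls, phy, n_row_perm=499, seed=0)
        assert res.p_row <= 0.01

    def test_edge_permutation_only_when_row_significant(self, synthetic_strong):
        table, meta, _, _ = synthetic_strong
        ens = make_ensemble(table, n=1, seed=0)
        from gutnet.community import bipartite_sample_labels

        cls = pd.Series(bipartite_sample_labels(ens[0].matrix),
                        index=table.sample_ids)
        rng = np.random.default_rng(0)
        random_factor = pd.Series(rng.permutation(["u", "v"] * 8),
                                  index=table.sample_ids)
        nulls = curveball_ensemble(ens[0], n_null=49, seed=1)
        res = cca_permutation_tests(cls, random_factor, null_matrices=nulls,
                                    n_row_perm=199, seed=2)
        if res.p_row >= 0.05:
            assert res.p_edge is None
        phy = meta.table["phylogeny_group"]
        res2 = cca_permutation_tests(cls, phy, null_matrices=nulls,
                                     n_row_perm=199, seed=3)
        assert res2.p_row < 0.05 and res2.p_edge is not None


class TestSVD:
    def test_rank1_exact(self):
        x = np.outer([1.0, 2.0, 3.0], [2.0, 0.5])
        f = svd_reduce(x, 1)
        assert np.allclose(f.L @ f.R.T, x)

    def test_full_rank_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 7))
        f = svd_reduce(x, 5)
        assert np.allclose(f.L @ f.R.T, x)

    def test_eckart_young_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 9))
        s = np.linalg.svd(x, compute_uv=False)
        for k in (1, 3, 5):
            f = svd_reduce(x, k)
            err = ((x - f.L @ f.R.T) ** 2).sum()
            assert err == pytest.approx((s[k:] ** 2).sum(), rel=1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            svd_reduce(np.eye(3), 4)

    def test_reconstruct_exact_rank_recovers_network(self):
        block = np.kron(np.eye(2, dtype=int), np.ones((3, 4), dtype=int))
        inc = BinaryIncidence(pd.DataFrame(block))
        f = svd_reduce(block, 2)
        rec = reconstruct_network(f, int(block.sum()), like=inc)
        assert (rec.matrix == block).all()

    def test_reconstruct_zero_density_empty(self):
        f = svd_reduce(np.ones((3, 3)), 1)
        rec = reconstruct_network(f, 0)
        assert rec.matrix.sum() == 0

    def test_planted_block_matrix_k2_cell_agreement(self):
        rng = np.random.default_rng(3)
        block = np.kron(np.eye(2, dtype=int), np.ones((4, 6), dtype=int))
        noise = (rng.random(block.shape) < 0.05).astype(int)
        m = np.clip(block + noise, 0, 1)
        f = svd_reduce(m, 2)
        rec = reconstruct_network(f, int(m.sum()))
        agreement = (rec.matrix == m).mean()
        assert agreement >= 0.95

    def test_select_rank_on_planted_ensemble(self, synthetic_strong):
        table = synthetic_strong[0]
        k, curve = select_rank(table, k_max=6, ensemble_size=5, seed=0)
        assert 1 <= k <= 6
        assert len(curve) == 6 and (curve >= 0).all() and (curve <= 1).all()


class TestRDA:
    @staticmethod
    def _factors(samples, rng=None):
        meta = study_metadata().table
        return {
            "env": meta["environment"],
            "spe": meta["specialization"],
            "phy": meta["phylogeny_group"],
        }

    def test_group_mean_rows_fully_explained(self):
        meta = study_metadata().table
        samples = list(meta.index)
        phy = meta["phylogeny_group"]
        means = {g: i * 2.0 for i, g in enumerate(sorted(set(phy)))}
        L = pd.DataFrame(
            {"v1": [means[phy[s]] for s in samples],
             "v2": [-means[phy[s]] for s in samples]},
            index=samples,
        )
        vp = rda_partition(L, self._factors(samples))
        assert vp.adjusted_r2["phy"] == pytest.approx(1.0, abs=1e-9)
        assert vp.residual == pytest.approx(0.0, abs=1e-9)

    def test_ezekiel_fixed_point_at_r2_one(self):
        # R2 = 1 => adjusted R2 = 1 regardless of dfs
        meta = study_metadata().table
        env = meta["environment"]
        L = pd.DataFrame({"v": (env == "field").astype(float)}, index=meta.index)
        vp = rda_partition(L, {"env": env})
        assert vp.adjusted_r2["env"] == pytest.approx(1.0)

    def test_random_L_adjusted_r2_unbiased_near_zero(self):
        rng = np.random.default_rng(0)
        meta = study_metadata().table
        factors = self._factors(list(meta.index))
        vals = []
        for _ in range(300):
            L = pd.DataFrame(rng.normal(size=(16, 3)), index=meta.index)
            vp = rda_partition(L, factors)
            vals.append(vp.adjusted_r2["env+spe+phy"])
        assert abs(np.mean(vals)) < 0.03

    def test_fractions_solve_inclusion_exclusion(self):
        rng = np.random.default_rng(4)
        meta = study_metadata().table
        L = pd.DataFrame(rng.normal(size=(16, 4)), index=meta.index)
        vp = rda_partition(L, self._factors(list(meta.index)))
        # fractions involving env must sum back to adjusted R2 of env alone...
        total = sum(v for k, v in vp.fractions.items())
        assert total == pytest.approx(vp.adjusted_r2["env+spe+phy"], abs=1e-9)
        env_sum = sum(v for k, v in vp.fractions.items() if "env" in k.split("&"))
        assert env_sum == pytest.approx(vp.adjusted_r2["env"], abs=1e-9)
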