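import numpy as np
import pytest
from scipy import stats

import countql as cq
from countql.apps import _simes


@pytest.fixture(scope="module")
def null_result():
    ds, _ = cq.simulate.simulate_splice(n_genes=150, gene_logfc=1.0, seed=21)
    dm = cq.DesignMatrix.from_group(ds.samples["group"])
    return cq.diff_splice(ds, dm, contrast=np.array([-1.0, 1.0]))


class TestDiffSplice:

    def test_relative_logfc_near_zero_under_shared_fold_change(self, null_result):
        assert abs(null_result.exon_table["rel_logFC"].mean()) < 0.05

    def test_gene_p_uniformish_under_null(self, null_result):
        p = null_result.gene_table["PValue.Simes"].to_numpy()
        assert 0.3 < np.nanmean(p) < 0.7
        assert np.nanmean(p < 0.05) < 0.12

    def test_weighted_relative_logfc_sums_to_zero(self, null_result):
        ex = null_result.exon_table
        for gene, sub in list(ex.groupby("gene_id"))[:20]:
            wsum = float((sub["weight"] * sub["rel_logFC"]).sum())
            scale = float((sub["weight"] * sub["rel_logFC"].abs()).sum()) + 1e-12
            assert abs(wsum) / scale < 1e-8
        assert null_result.gene_table["n_exons"].min() >= 2

    def test_simes_example(self):
        assert np.isclose(_simes(np.array([0.01, 0.04])), 0.02)

    def test_simes_at_least_min_p_and_single_exon_dropped(self):
        ds, _ = cq.simulate.simulate_splice(n_genes=30, seed=22)
        # make one gene single-exon by dropping its other exons
        keep = np.ones(ds.n_genes, dtype=bool)
        keep[1:5] = False
        sub = ds[keep, :]
        dm = cq.DesignMatrix.from_group(sub.samples["group"])
        res = cq.diff_splice(sub, dm, contrast=np.array([-1.0, 1.0]))
        assert res.n_single_exon_dropped == 1
        merged = res.exon_table.groupby("gene_id")["PValue"].min()
        gt = res.gene_table.set_index("gene_id")
        assert np.all(
            gt.loc[merged.index, "PValue.Simes"].to_numpy() >= merged.to_numpy() - 1e-12
        )

    def test_minority_exon_power_ordering(self):
        wins = 0
        reps = 8
        for r in range(reps):
            ds, _ = cq.simulate.simulate_splice(
                n_genes=40, switched_exons=1, switch_logfc=2.0, seed=400 + r
            )
            dm = cq.DesignMatrix.from_group(ds.samples["group"])
            res = cq.diff_splice(ds, dm, contrast=np.array([-1.0, 1.0]))
            gt = res.gene_table
            wins += np.mean(gt["PValue.Simes"] < gt["PValue.F"]) > 0.5
        assert wins / reps > 0.5


class TestModelMatrixMeth:
    def test_printed_construction_n2_p1(self):
        out = cq.model_matrix_meth(np.ones((2, 1)))
        expect = np.array([[1, 0, 1], [1, 0, 0], [0, 1, 1], [0, 1, 0]], dtype=float)
        assert np.array_equal(out.values, expect)

    def test_rank_is_n_plus_p(self, rng):
        for _ in range(5):
            n, p = int(rng.integers(3, 8)), int(rng.integers(1, 3))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p > 1 else np.ones((n, 1))
            out = cq.model_matrix_meth(X)
            assert out.values.shape == (2 * n, n + p)
            assert np.linalg.matrix_rank(out.values) == n + p

    def test_methylated_row_sums_equal_design_column_sums(self, rng):
        X = np.column_stack([np.ones(4), rng.normal(size=4)])
        out = cq.model_matrix_meth(X)
        me_rows = out.values[0::2, 4:]
        assert np.allclose(me_rows.sum(axis=0), X.sum(axis=0))

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            cq.model_matrix_meth(np.ones((3, 2)))

    def test_recovers_methylation_log_ratio(self):
        # simulated methylation data: expanded design recovers the group
        # difference in log(Me/Un)
        ds, truth = cq.simulate.simulate_meth(
            n_loci=150, n_per_group=4, coverage=200, group_logratio=1.0,
            de_fraction=1.0, bcv=0.02, seed=31,
        )
        n = 8
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 4)])
        dm = cq.model_matrix_meth(X)
        fit = cq.glm_fit(ds, dm, 0.02, prior_count=0)
        delta = fit.coefficients[:, -1]  # group effect on log Me:Un ratio
        assert abs(np.median(delta) - 1.0) < 0.15


class TestRTA:
    def test_identical_resamples_floor_at_one(self):
        m = np.tile(np.array([5.0, 10.0])[:, None], (1, 4))
        est = cq.estimate_rta_overdispersion([m, m])
        assert np.array_equal(est.overdispersion, [1.0, 1.0])

    def test_poisson_resamples_approach_one(self):
        ds, resamples, _ = cq.simulate.simulate_resamples(
            inflation=1.0, n_resamples=100, seed=51
        )
        est = cq.estimate_rta_overdispersion(resamples)
        assert abs(est.overdispersion.mean() - 1.0) < 0.1

    def test_inflation_recovered_and_library_sizes_shrink(self):
        ds, resamples, infl = cq.simulate.simulate_resamples(
            inflation=5.0, n_resamples=100, seed=52
        )
        est = cq.estimate_rta_overdispersion(resamples)
        assert abs(est.overdispersion.mean() - 5.0) / 5.0 < 0.15
        divided = cq.divide_counts(ds, est.overdispersion)
        assert np.all(divided.lib_size < ds.counts.sum(axis=0))

    def test_divided_counts_preserve_relative_abundance(self):
        ds = cq.make_dataset(np.array([[10.0, 20.0], [30.0, 60.0]]))
        divided = cq.divide_counts(ds, np.array([2.0, 2.0]))
        ratio_raw = ds.counts[0] / ds.counts[1]
        ratio_div = divided.counts[0] / divided.counts[1]
        assert np.allclose(ratio_raw, ratio_div)

    def test_needs_two_resamples(self):
        with pytest.raises(ValueError):
            cq.estimate_rta_overdispersion([np.ones((3, 1))])


class TestPseudoBulk:
    def test_column_sums_conserved(self, rng):
        counts = rng.poisson(3, size=(50, 40)).astype(float)
        counts[0, :] += 1  # avoid an all-zero pseudo-bulk column
        samples = rng.choice(["s1", "s2"], 40)
        clusters = rng.choice(["c1", "c2", "c3"], 40)
        pb = cq.pseudo_bulk(cq.make_dataset(counts), samples, clusters)
        assert np.isclose(pb.counts.sum(), counts.sum())

    def test_single_group_equals_row_sums(self, rng):
        counts = rng.poisson(2, size=(20, 10)).astype(float) + 1
        pb = cq.pseudo_bulk(cq.make_dataset(counts), ["s"] * 10, ["c"] * 10)
        assert pb.n_samples == 1
        assert np.array_equal(pb.counts[:, 0], counts.sum(axis=1))
        assert pb.samples["n_cells"].iloc[0] == 10

    def test_cell_permutation_invariance(self, rng):
        counts = rng.poisson(2, size=(20, 30)).astype(float) + 1
        samples = rng.choice(["a", "b"], 30)
        clusters = rng.choice(["x", "y"], 30)
        pb1 = cq.pseudo_bulk(cq.make_dataset(counts), samples, clusters)
        perm = rng.permutation(30)
        pb2 = cq.pseudo_bulk(cq.make_dataset(counts[:, perm]), samples[perm], clusters[perm])
        assert np.array_equal(pb1.counts, pb2.counts)


class TestZScore:
    def test_distributional_calibration(self):
        rng = np.random.default_rng(61)
        a = 1 / 0.1
        y = rng.negative_binomial(a, a / (a + 50.0), size=100_000)
        z = cq.zscore_nbinom(y.astype(float), 50.0, 0.1)
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.05

    def test_median_maps_near_zero(self):
        a = 10.0
        med = stats.nbinom.ppf(0.5, a, a / (a + 20.0))
        z = float(cq.zscore_nbinom(float(med), 20.0, 0.1))
        pstep = stats.nbinom.pmf(med, a, a / (a + 20.0))
        assert abs(z) < stats.norm.isf(0.5 - pstep / 2) + 1e-9

    def test_strictly_increasing_in_y(self):
        ys = np.arange(0, 40, dtype=float)
        z = cq.zscore_nbinom(ys, 10.0, 0.2)
        assert np.all(np.diff(z) > 0)
        z_half = cq.zscore_nbinom(ys[:-1] + 0.5, 10.0, 0.2)
        assert np.all((z_half > z[:-1]) & (z_half < z[1:]))

    def test_extreme_tail_finite(self):
        z = float(cq.zscore_nbinom(500.0, 2.0, 0.0))
        assert np.isfinite(z) and z > 30


class TestMDS:
    def test_duplicated_sample_coincides(self, rng):
        lcpm = rng.normal(5, 2, size=(300, 4))
        lcpm = np.column_stack([lcpm, lcpm[:, 0]])
        D, coords, ve = cq.mds_leading_logfc(lcpm, top=100)
        assert D[0, 4] == 0.0
        assert np.allclose(coords[0], coords[4], atol=1e-8)

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        lcpm = rng.normal(0, 1, size=(200, 5))
        D, _, _ = cq.mds_leading_logfc(lcpm, top=50)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_group_separation_on_dimension_one(self):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(700 + r)
            lcpm = rng.normal(5, 0.5, size=(1000, 6))
            lcpm[:600, 3:] += 3.0  # 8-fold in 600 genes
            _, coords, _ = cq.mds_leading_logfc(lcpm, top=500)
            s1, s2 = coords[:3, 0], coords[3:, 0]
            hits += (s1.max() < s2.min()) or (s2.max() < s1.min())
        assert hits == 10

    def test_top_capped_at_gene_count(self, rng):
        lcpm = rng.normal(size=(50, 4))
        D, _, ve = cq.mds_leading_logfc(lcpm, top=5000)
        assert np.isfinite(D).all()
        assert ve.size == 2
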