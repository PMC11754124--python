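import numpy as np
import pytest
from scipy.stats import rankdata

import countql as cq
from countql.datamodel import CompressedTable
from countql.norm import tmm_pair, tmmwsp_pair


def tmm_oracle(obs, ref, N, Nr, logratio_trim=0.3, abundance_trim=0.05):
    """Independent brute-force trimmed weighted mean of M values."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    pos = (obs > 0) & (ref > 0)
    y, yr = obs[pos], ref[pos]
    M = np.log2((y / N) / (yr / Nr))
    A = 0.5 * np.log2((y / N) * (yr / Nr))
    n = M.size

    def keep(v, tr):
        lo = np.floor(n * tr) + 1
        hi = n + 1 - lo
        r = rankdata(v)
        return (r >= lo) & (r <= hi)

    k = keep(M, logratio_trim) & keep(A, abundance_trim)
    w = 1.0 / ((N - y[k]) / (N * y[k]) + (Nr - yr[k]) / (Nr * yr[k]))
    return np.sum(w * M[k]) / np.sum(w)


class TestTMMPair:
    def test_identical_libraries_give_zero(self):
        y = np.arange(1.0, 21.0)
        assert tmm_pair(y, y, y.sum(), y.sum()) == 0.0

    def test_doubled_counts_same_composition_give_zero(self):
        y = np.arange(1.0, 21.0)
        assert tmm_pair(2 * y, y, 2 * y.sum(), y.sum()) == 0.0

    def test_twenty_gene_toy_matches_bruteforce_oracle(self, rng):
        ref = rng.integers(5, 200, size=20).astype(float)
        obs = ref.copy()
        obs[:10] *= 2.0  # half the genes doubled
        N, Nr = obs.sum(), ref.sum()
        got = tmm_pair(obs, ref, N, Nr)
        assert np.isclose(got, tmm_oracle(obs, ref, N, Nr), atol=1e-10)

    def test_antisymmetry_on_balanced_toy(self, rng):
        a = rng.integers(10, 500, size=50).astype(float)
        b = a * rng.uniform(0.9, 1.1, size=50)
        f_ab = tmm_pair(a, b, a.sum(), b.sum())
        f_ba = tmm_pair(b, a, b.sum(), a.sum())
        assert abs(f_ab + f_ba) < 0.05

    def test_no_surviving_genes_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            f = tmm_pair([0.0, 0.0], [1.0, 2.0], 10.0, 10.0)
        assert f == 0.0


class TestTMMwsp:
    def test_reduces_to_tmm_without_singletons(self, rng):
        obs = rng.integers(1, 100, size=30).astype(float)
        ref = rng.integers(1, 100, size=30).astype(float)
        assert tmmwsp_pair(obs, ref, obs.sum(), ref.sum()) == tmm_pair(
            obs, ref, obs.sum(), ref.sum()
        )

    def test_disjoint_equal_mass_is_symmetric_zero(self):
        obs = np.array([10.0, 8.0, 6.0, 0, 0, 0])
        ref = np.array([0, 0, 0, 10.0, 8.0, 6.0])
        f = tmmwsp_pair(obs, ref, obs.sum(), ref.sum())
        assert abs(f) < 1e-10

    def test_six_gene_sparse_toy_matches_hand_pairing_oracle(self):
        obs = np.array([30.0, 0.0, 5.0, 12.0, 0.0, 7.0])
        ref = np.array([25.0, 9.0, 0.0, 10.0, 4.0, 0.0])
        N, Nr = obs.sum(), ref.sum()
        # hand pairing: obs singletons (7, 5) sorted desc; ref singletons (9, 4)
        # paired largest-with-largest -> synthetic genes (7, 9) and (5, 4)
        y = np.array([30.0, 12.0, 7.0, 5.0])
        yr = np.array([25.0, 10.0, 9.0, 4.0])
        M = np.log2((y / N) / (yr / Nr))
        A = 0.5 * np.log2((y / N) * (yr / Nr))
        n = M.size
        lo = np.floor(n * 0.3) + 1
        hi = n + 1 - lo
        keep = (rankdata(M) >= lo) & (rankdata(M) <= hi)
        lo_a = np.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        keep &= (rankdata(A) >= lo_a) & (rankdata(A) <= hi_a)
        w = 1.0 / ((N - y[keep]) / (N * y[keep]) + (Nr - yr[keep]) / (Nr * yr[keep]))
        oracle = np.sum(w * M[keep]) / np.sum(w)
        got = tmmwsp_pair(obs, ref, N, Nr)
        assert np.isclose(got, oracle, atol=1e-12)


class TestNormLibSizes:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1.0, 31.0)[:, None], (1, 4))
        ds = cq.make_dataset(counts)
        nf = cq.norm_lib_sizes(ds, "TMM")
        assert np.allclose(nf.factors, 1.0)

    def test_factors_have_geometric_mean_one(self, rng):
        counts = rng.poisson(50, size=(100, 5)).astype(float) + 1
        counts[:, 2] *= 3
        nf = cq.norm_lib_sizes(cq.make_dataset(counts), "TMM")
        assert abs(np.log(nf.factors).sum()) < 1e-12

    def test_composition_bias_detected(self, rng):
        # sample 2 has 10% of genes hugely amplified -> its factor < 1
        base = rng.poisson(100, size=(300, 3)).astype(float) + 1
        base[:30, 1] *= 20
        nf = cq.norm_lib_sizes(cq.make_dataset(base), "TMM")
        assert nf.factors[1] < 1.0
        assert nf.factors[0] > 1.0 and nf.factors[2] > 1.0

    def test_gene_order_invariance(self, rng):
        counts = rng.poisson(40, size=(200, 4)).astype(float) + 1
        perm = rng.permutation(200)
        f1 = cq.norm_lib_sizes(cq.make_dataset(counts), "TMM").factors
        f2 = cq.norm_lib_sizes(cq.make_dataset(counts[perm]), "TMM").factors
        assert np.allclose(f1, f2, rtol=1e-12)

    def test_method_none(self, small_dataset):
        assert np.array_equal(cq.norm_lib_sizes(small_dataset, "none").factors, np.ones(4))


class TestFilterByExpr:
    def test_all_zero_gene_dropped(self, small_dataset):
        keep = cq.filter_by_expr(small_dataset, group=small_dataset.samples["group"])
        assert not keep[2]

    def test_boundary_gene_kept(self):
        # groups (3,3); gene at CPM cutoff in exactly 3 samples, total >= 15
        lib = 1e6
        counts = np.full((2, 6), 50.0)
        cutoff_count = 10.0  # CPM cutoff = 10/1e6*1e6 = 10 -> count 10 at lib 1e6
        counts[1] = [cutoff_count, cutoff_count, cutoff_count, 0, 0, 0]
        ds = cq.make_dataset(counts, group=list("AAABBB"), lib_size=np.full(6, lib))
        keep = cq.filter_by_expr(ds, group=ds.samples["group"])
        assert keep[1]

    def test_large_group_adjustment(self):
        # k=20 -> required samples 10 + 10*0.7 = 17
        counts = np.zeros((2, 20))
        counts[0, :17] = 100.0
        counts[1, :16] = 100.0
        counts += 0.0
        ds = cq.make_dataset(counts, group=["A"] * 20, lib_size=np.full(20, 1e4))
        keep = cq.filter_by_expr(ds, group=ds.samples["group"])
        assert keep[0] and not keep[1]

    def test_monotone_in_counts(self, rng):
        counts = rng.poisson(5, size=(100, 6)).astype(float)
        counts[:, 0] += 1
        ds = cq.make_dataset(counts, group=list("AAABBB"), lib_size=np.full(6, 1e5))
        keep1 = cq.filter_by_expr(ds, group=ds.samples["group"])
        ds2 = cq.make_dataset(counts + 5, group=list("AAABBB"), lib_size=np.full(6, 1e5))
        keep2 = cq.filter_by_expr(ds2, group=ds2.samples["group"])
        assert np.all(keep2 | ~keep1)


class TestCPM:
    def test_all_zero_equal_els_constant(self):
        ds = cq.make_dataset(np.zeros((3, 4)), lib_size=np.full(4, 1e6))
        v = cq.cpm_log2(ds)
        assert np.isfinite(v).all()
        assert np.allclose(v, v[0, 0])

    def test_zero_prior_plain_log2_cpm(self):
        ds = cq.make_dataset(np.array([[100.0, 200.0]]), lib_size=[1e6, 1e6])
        v = cq.cpm_log2(ds, prior_count=0)
        assert np.allclose(v, np.log2([100.0, 200.0]))

    def test_scale_invariance_without_prior(self):
        # exact when prior_count=0: doubling ELS and counts changes nothing
        ds1 = cq.make_dataset(np.array([[10.0, 20.0], [5.0, 2.0]]), lib_size=[1e5, 2e5])
        ds2 = cq.make_dataset(2 * ds1.counts, lib_size=[2e5, 4e5])
        assert np.allclose(cq.cpm_log2(ds1, prior_count=0), cq.cpm_log2(ds2, prior_count=0))
        # with a prior the dependence vanishes as counts grow
        d_small = np.abs(cq.cpm_log2(ds1) - cq.cpm_log2(ds2)).max()
        ds3 = cq.make_dataset(100 * ds1.counts, lib_size=[1e5, 2e5])
        ds4 = cq.make_dataset(200 * ds1.counts, lib_size=[2e5, 4e5])
        d_large = np.abs(cq.cpm_log2(ds3) - cq.cpm_log2(ds4)).max()
        assert d_large < d_small

    def test_strictly_increasing_in_counts(self):
        ds1 = cq.make_dataset(np.array([[10.0, 20.0]]), lib_size=[1e5, 1e5])
        ds2 = cq.make_dataset(np.array([[11.0, 20.0]]), lib_size=[1e5, 1e5])
        assert cq.cpm_log2(ds2)[0, 0] > cq.cpm_log2(ds1)[0, 0]


class TestAveLogCPM:
    def test_matches_closed_form_for_equal_els(self, rng):
        counts = rng.poisson(30, size=(20, 4)).astype(float)
        N = 1e5
        ds = cq.make_dataset(counts, lib_size=np.full(4, N))
        got = cq.ave_log_cpm(ds, prior_count=2)
        expect = np.log2((counts.mean(axis=1) + 2) / (N + 4) * 1e6)
        assert np.allclose(got, expect, rtol=1e-8)

    def test_monotone_in_row_sums(self, rng):
        counts = np.array([[5.0, 5.0], [6.0, 5.0], [50.0, 60.0]])
        ds = cq.make_dataset(counts, lib_size=[1e4, 1e4])
        a = cq.ave_log_cpm(ds)
        assert a[0] < a[1] < a[2]

    def test_sample_permutation_invariance(self, rng):
        counts = rng.poisson(20, size=(10, 5)).astype(float)
        lib = rng.uniform(1e4, 2e4, 5)
        a1 = cq.ave_log_cpm(cq.make_dataset(counts, lib_size=lib))
        perm = [3, 1, 4, 0, 2]
        a2 = cq.ave_log_cpm(cq.make_dataset(counts[:, perm], lib_size=lib[perm]))
        assert np.allclose(a1, a2, rtol=1e-10)


class TestScaleOffset:
    def test_centered_offsets_unchanged(self):
        ds = cq.make_dataset(np.ones((2, 3)), lib_size=[100.0, 100.0, 100.0])
        ext = np.full(3, np.log(100.0))
        out = cq.scale_offset(ds, ext)
        assert np.allclose(out.expand(), np.log(100.0))

    def test_shift_invariance(self, small_dataset):
        ext = np.array([1.0, 2.0, 3.0, 4.0])
        o1 = cq.scale_offset(small_dataset, ext).expand()
        o2 = cq.scale_offset(small_dataset, ext + 7.0).expand()
        assert np.allclose(o1, o2, atol=1e-12)

    def test_differences_preserved(self, small_dataset):
        ext = np.array([0.5, 1.5, -2.0, 0.0])
        out = cq.scale_offset(small_dataset, ext).expand()[0]
        assert np.allclose(np.diff(out), np.diff(ext), atol=1e-12)
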