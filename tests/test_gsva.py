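import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm as normal

import mammosig as m
from mammosig.gsva import rank_stats


def _expr(values, scale="log2"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return m.ExpressionTable(df, scale=scale)


def kcdf_oracle(x, h):
    """Direct double-loop evaluation of the Gaussian kernel CDF."""
    n = len(x)
    return np.array(
        [sum(normal.cdf((x[j] - x[w]) / h) for w in range(n)) / n
         for j in range(n)]
    )


def es_oracle(z_col, members, tau_weight=1.0, mode="max_diff"):
    """Naive walk evaluation of the enrichment score for one sample.

    ``members`` are row indices of the set's genes. Sorts (z, original
    position) pairs explicitly and accumulates the hit/miss sums step
    by step.
    """
    p = len(z_col)
    members = set(members)
    order = sorted(range(p), key=lambda i: (-z_col[i], i))
    tau = {g: order.index(g) + 1 for g in range(p)}
    r = {g: abs(p / 2 - tau[g]) for g in range(p)}
    denom = sum(r[i] ** tau_weight for i in members)
    n_out = p - len(members)
    hit = miss = 0.0
    walk = []
    for i in order:
        if i in members:
            # degenerate zero-weight sets fall back to uniform steps
            hit += ((r[i] ** tau_weight) / denom) if denom > 0 \
                else 1.0 / len(members)
        else:
            miss += 1.0 / n_out
        walk.append(hit - miss)
    if mode == "max_diff":
        return max(walk) + min(walk), walk
    return max(walk, key=abs), walk


class TestKcdf:
    def test_constant_gene_maps_to_half(self):
        expr = _expr([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        k = m.kcdf_transform(expr)
        assert np.all(k.z.iloc[0].to_numpy() == 0.5)
        assert k.n_degenerate == 1

    def test_two_samples_sum_to_one(self):
        expr = _expr([[1.0, 4.0]])
        k = m.kcdf_transform(expr)
        a, b = k.z.iloc[0]
        assert a + b == pytest.approx(1.0, abs=1e-12)
        assert a < b

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(5, 2, size=(6, 4))
        k = m.kcdf_transform(_expr(x))
        for i in range(6):
            h = x[i].std(ddof=1) / 4
            np.testing.assert_allclose(
                k.z.iloc[i].to_numpy(), kcdf_oracle(x[i], h), atol=1e-12
            )

    def test_monotone_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 10))
        a = m.kcdf_transform(_expr(x)).z.to_numpy()
        b = m.kcdf_transform(_expr(3.7 * x + 11.0)).z.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            m.kcdf_transform(_expr([[1.0]]))

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            m.kcdf_transform(_expr(np.ones((3, 4))))

    def test_raw_count_scale_rejected(self):
        with pytest.raises(ValueError, match="continuous"):
            m.kcdf_transform(_expr(np.ones((2, 3)), scale="raw-count"))


class TestRankStats:
    def test_symmetrized_ranks_p4(self):
        # tau {1,2,3,4} -> r = |2 - tau| = {1,0,1,2}
        expr = _expr([[4.0], [3.0], [2.0], [1.0]] * 1)
        expr = _expr(np.array([[4.0, 1.0], [3.0, 2.0], [2.0, 3.0], [1.0, 4.0]]))
        rs = rank_stats(m.kcdf_transform(expr))
        np.testing.assert_array_equal(rs.tau[:, 0], [1, 2, 3, 4])
        np.testing.assert_array_equal(rs.r[:, 0], [1, 0, 1, 2])

    def test_reversal_preserves_r_multiset(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(7, 2))
        x[:, 1] = -x[:, 0]
        rs = rank_stats(m.kcdf_transform(_expr(x)))
        assert sorted(rs.r[:, 0]) == sorted(rs.r[:, 1])

    def test_tau_is_permutation_with_checksum(self):
        rng = np.random.default_rng(10)
        rs = rank_stats(m.kcdf_transform(_expr(rng.normal(size=(9, 5)))))
        p = rs.p
        for j in range(5):
            assert rs.tau[:, j].sum() == p * (p + 1) // 2
            assert len(set(rs.tau[:, j])) == p

    def test_z_ties_broken_by_input_gene_order(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 5.0]])
        rs = rank_stats(m.kcdf_transform(_expr(x)))
        # genes 0 and 1 are identical: gene 0 must rank above gene 1
        assert rs.tau[0, 0] < rs.tau[1, 0]


class TestEnrichmentScore:
    def _rs(self, x):
        return rank_stats(m.kcdf_transform(_expr(x)))

    def test_top_positions_give_max_dev_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(8, 3))
        rs = self._rs(x)
        top2 = [rs.genes[i] for i in rs.order[:2, 0]]
        es = m.enrichment_score(rs, top2, 0, mode="max_dev")
        assert es == pytest.approx(1.0)

    def test_bottom_positions_give_max_dev_minus_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(8, 3))
        rs = self._rs(x)
        bottom2 = [rs.genes[i] for i in rs.order[-2:, 0]]
        es = m.enrichment_score(rs, bottom2, 0, mode="max_dev")
        assert es == pytest.approx(-1.0)

    @pytest.mark.parametrize("mode", ["max_diff", "max_dev"])
    @pytest.mark.parametrize("tau_weight", [1.0, 0.5, 2.0])
    def test_matches_naive_walk_oracle(self, mode, tau_weight):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(6, 4))
        rs = self._rs(x)
        gene_set = {rs.genes[0], rs.genes[3]}
        members = {0, 3}
        for j in range(4):
            es = m.enrichment_score(rs, gene_set, j,
                                    tau_weight=tau_weight, mode=mode)
            z = m.kcdf_transform(_expr(x)).z.to_numpy()[:, j]
            expected, _ = es_oracle(z, members, tau_weight, mode)
            assert es == pytest.approx(expected, abs=1e-9)

    def test_empty_and_full_sets_rejected(self):
        rs = self._rs(np.random.default_rng(14).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="no signature genes"):
            m.enrichment_score(rs, {"absent"}, 0)
        with pytest.raises(ValueError, match="whole matrix"):
            m.enrichment_score(rs, set(rs.genes), 0)

    def test_bounded_on_random_instances(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            p = rng.integers(4, 30)
            n = rng.integers(2, 8)
            rs = self._rs(rng.normal(size=(p, n)))
            size = rng.integers(1, p)
            gene_set = set(rng.choice(rs.genes, size=size, replace=False))
            mode = rng.choice(["max_diff", "max_dev"])
            es = m.enrichment_score(rs, gene_set, int(rng.integers(n)),
                                    mode=str(mode))
            assert -1.0 <= es <= 1.0


class TestGsva:
    def test_score_matrix_shape_and_bounds(self):
        rng = np.random.default_rng(16)
        x = rng.normal(6, 2, size=(60, 12))
        expr = _expr(x)
        sigs = m.GeneSetCollection(
            [m.GeneSet(f"set{k}", [f"g{i}" for i in range(5 * k, 5 * k + 5)])
             for k in range(10)]
        )
        res = m.gsva(expr, sigs)
        assert res.scores.shape == (10, 12)
        assert res.scores.to_numpy().min() >= -1.0
        assert res.scores.to_numpy().max() <= 1.0

    def test_missing_genes_counted_and_intersected(self):
        rng = np.random.default_rng(17)
        expr = _expr(rng.normal(size=(10, 4)))
        sigs = m.GeneSetCollection(
            [m.GeneSet("s", ["g0", "g1", "NOT_THERE", "ALSO_MISSING"])]
        )
        res = m.gsva(expr, sigs)
        assert res.missing_genes["s"] == 2
        assert res.set_sizes["s"] == 2

    def test_set_with_no_matrix_genes_errors_with_name(self):
        rng = np.random.default_rng(18)
        expr = _expr(rng.normal(size=(6, 3)))
        sigs = m.GeneSetCollection([m.GeneSet("ghost", ["nope1", "nope2"])])
        with pytest.raises(ValueError, match="ghost"):
            m.gsva(expr, sigs)

    def test_es_invariant_to_gene_row_reordering(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(20, 6))
        genes = [f"g{i}" for i in range(20)]
        df = pd.DataFrame(x, index=genes,
                          columns=[f"s{j}" for j in range(6)])
        sigs = m.GeneSetCollection([m.GeneSet("s", ["g2", "g5", "g11"])])
        a = m.gsva(m.ExpressionTable(df), sigs).scores
        perm = rng.permutation(20)
        b = m.gsva(m.ExpressionTable(df.iloc[perm]), sigs).scores
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_pure_noise_free_tumors_score_own_signature_highest(self, sc3):
        sigs = m.build_signatures(
            m.all_markers(sc3["norm"], sc3["clusters"]), max_genes=100
        )
        from mammosig.synthetic import dominant_type_per_cluster

        profiles = m.type_log2_profiles(
            sc3["umi"], sc3["truth"].cell_type_of_cell
        )
        cfg = m.BulkSimConfig(n_tumors=40, purity=1.0, noise_sd=0.0, seed=20)
        expr, _, truth = m.simulate_bulk(cfg, profiles)
        res = m.gsva(m.ExpressionTable(expr), sigs)
        mapping = dominant_type_per_cluster(
            sc3["clusters"].labels, sc3["truth"].cell_type_of_cell
        )
        sig_of_type = {t: f"cluster{k}" for k, t in mapping.items()}
        argmax = res.scores.idxmax(axis=0)
        for s in expr.columns:
            assert argmax[s] == sig_of_type[truth.generating_type_of_tumor[s]]
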