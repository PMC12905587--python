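"""Meta-program consolidation: filters, NMF, clustering, aggregation arithmetic."""

import numpy as np
import pandas as pd
import pytest

import ecotme as e
from ecotme.synthetic import GEPMatrices


def _gep(sample, loadings: dict, usage_rows=None):
    L = pd.DataFrame(loadings)
    if usage_rows is None:
        usage_rows = np.full((4, L.shape[1]), 1.0 / L.shape[1])
    U = pd.DataFrame(usage_rows, columns=L.columns)
    return GEPMatrices(sample_id=sample, usage=U, loadings=L)


class TestExpressionFilters:
    def test_cell_and_gene_boundaries(self):
        rng = np.random.default_rng(0)
        n_genes = 400
        expr = pd.DataFrame(rng.poisson(2.0, size=(n_genes, 8)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"c{i}" for i in range(8)])
        expr.loc[:, "c0"] = 0
        expr.loc["g0":"g299", "c0"] = 0
        expr.iloc[:299, 0] = 1   # cell c0: 299 detected genes -> dropped
        expr.loc["g399"] = 0
        expr.loc["g399", ["c1", "c2", "c3", "c4", "c5"]] = 1  # exactly 5 cells
        out = e.filter_cells_genes(expr)
        assert "c0" not in out.columns
        assert "g399" in out.index

    def test_all_zero_matrix_raises(self):
        expr = pd.DataFrame(np.zeros((10, 5)))
        with pytest.raises(ValueError):
            e.filter_cells_genes(expr)

    def test_tumor_sample_filter_boundary(self):
        counts = {"a": 99, "b": 100, "c": 150}
        assert e.filter_low_tumor_samples(counts) == ["b", "c"]

    def test_tumor_filter_matches_hand_count(self):
        rng = np.random.default_rng(1)
        counts = {f"s{i}": int(rng.integers(0, 300)) for i in range(30)}
        kept = e.filter_low_tumor_samples(counts)
        assert len(kept) == sum(1 for v in counts.values() if v >= 100)


class TestOverdispersion:
    def test_planted_overdispersed_genes_rank_top(self):
        rng = np.random.default_rng(2)
        n_cells = 300
        base = rng.poisson(5.0, size=(180, n_cells))
        # planted: same mean, inflated variance via mixture
        lam = np.where(rng.random((20, n_cells)) < 0.1, 40.0, 1.0)
        planted = rng.poisson(lam)
        expr = pd.DataFrame(np.vstack([base, planted]),
                            index=[f"bg{i}" for i in range(180)]
                            + [f"od{i}" for i in range(20)])
        top = e.select_overdispersed_genes(expr, n=20)
        assert sum(g.startswith("od") for g in top) >= 19

    def test_clamp_when_n_exceeds_genes(self):
        expr = pd.DataFrame(np.random.default_rng(0).poisson(2, (10, 20)))
        assert len(e.select_overdispersed_genes(expr, n=50)) == 10

    def test_constant_matrix_raises(self):
        expr = pd.DataFrame(np.full((10, 10), 3.0))
        with pytest.raises(ValueError):
            e.select_overdispersed_genes(expr)


class TestConsensusNmf:
    def test_rank_one_reconstruction(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.5, 2.0, size=50)
        h = rng.uniform(0.5, 2.0, size=30)
        expr = pd.DataFrame(np.outer(w, h))
        geps = e.consensus_nmf(expr, k=1, restarts=4, seed=0)
        V = (expr / expr.std(axis=1, ddof=0).to_numpy()[:, None]).to_numpy()
        W = geps.loadings.to_numpy()
        scale = (W.T @ V) / (W.T @ W)
        rel_err = np.linalg.norm(V - W @ scale) / np.linalg.norm(V)
        assert rel_err < 0.05

    def test_planted_programs_recovered(self):
        rng = np.random.default_rng(4)
        arch = np.zeros((90, 3))
        for j in range(3):
            arch[30 * j:30 * (j + 1), j] = rng.uniform(1, 2, 30)
        usage = rng.dirichlet(np.ones(3), size=120)
        expr = pd.DataFrame(arch @ usage.T + rng.uniform(0, 0.05, (90, 120)))
        geps = e.consensus_nmf(expr, k=3, restarts=6, seed=1)
        corr = np.corrcoef(np.hstack([arch, geps.loadings.to_numpy()]).T)[:3, 3:]
        assert (corr.max(axis=1) > 0.9).all()

    def test_same_seed_identical(self):
        expr = pd.DataFrame(np.random.default_rng(5).uniform(0, 1, (40, 25)))
        g1 = e.consensus_nmf(expr, k=2, restarts=3, seed=9)
        g2 = e.consensus_nmf(expr, k=2, restarts=3, seed=9)
        pd.testing.assert_frame_equal(g1.loadings, g2.loadings)
        pd.testing.assert_frame_equal(g1.usage, g2.usage)

    def test_usage_rows_stochastic(self):
        expr = pd.DataFrame(np.random.default_rng(6).uniform(0, 1, (40, 25)))
        geps = e.consensus_nmf(expr, k=3, restarts=3, seed=0)
        np.testing.assert_allclose(geps.usage.sum(axis=1), 1.0, atol=1e-9)


class TestChooseK:
    def test_singleton_range_returned(self):
        expr = pd.DataFrame(np.random.default_rng(7).uniform(0, 1, (30, 20)))
        k, _ = e.choose_k(expr, [3], restarts=3)
        assert k == 3

    def test_planted_rank_selected(self):
        rng = np.random.default_rng(8)
        arch = np.zeros((120, 4))
        for j in range(4):
            arch[30 * j:30 * (j + 1), j] = rng.uniform(1, 2, 30)
        usage = rng.dirichlet(np.ones(4) * 0.3, size=150)
        expr = pd.DataFrame(arch @ usage.T + rng.uniform(0, 0.02, (120, 150)))
        k, diag = e.choose_k(expr, range(2, 7), restarts=4, seed=2)
        assert k == 4

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            e.choose_k(pd.DataFrame(np.ones((5, 5))), [])


class TestUsageFilter:
    def test_strict_threshold(self):
        usage = np.array([[0.01, 0.011, 0.979]] * 3)
        gep = _gep("s1", {"p0": [1.0, 0, 0], "p1": [0, 1.0, 0], "p2": [0, 0, 1.0]},
                   usage_rows=usage)
        kept = e.filter_geps_by_usage([gep])
        assert ("s1", "p0") not in kept      # exactly 0.01 -> dropped
        assert ("s1", "p1") in kept          # 0.011 -> kept

    def test_uniform_usage_analytic(self):
        # uniform usage over p programs keeps all iff 1/p > 0.01
        def uniform_gep(p):
            usage = np.full((3, p), 1.0 / p)
            loadings = {f"p{i}": np.ones(4) for i in range(p)}
            return _gep("s", loadings, usage_rows=usage)

        assert len(e.filter_geps_by_usage([uniform_gep(5)])) == 5
        with pytest.raises(ValueError, match="no programs"):
            e.filter_geps_by_usage([uniform_gep(200)])


class TestClusterGeps:
    def test_duplicate_program_same_cluster(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(0, 1, 60)
        g1 = _gep("s1", {"p0": v, "p1": rng.uniform(0, 1, 60)})
        g2 = _gep("s2", {"p0": v})
        part, _ = e.cluster_geps([g1, g2], k=2)
        assert part[("s1", "p0")] == part[("s2", "p0")]

    def test_planted_archetypes_autok(self, gep_cohort):
        geps, truth = gep_cohort
        kept = e.filter_geps_by_usage(geps)
        part, _ = e.cluster_geps(geps, programs=kept, k="auto")
        assert len(set(part.values())) == 6

    def test_orthogonal_vectors_distance(self):
        g = _gep("s", {"p0": [2.0, 1.0, 0, 0], "p1": [0, 0, 1.0, 2.0]})
        _, L = e.cluster_geps([g], k=2)
        r = np.corrcoef(L.to_numpy())[0, 1]
        assert 1 - r == pytest.approx(2.0, abs=0.5)  # anti-correlated blocks

    def test_too_few_programs_rejected(self):
        g = _gep("s", {"p0": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 2"):
            e.cluster_geps([g])


class TestAggregation:
    def test_shared_and_exclusive_gene_arithmetic(self):
        p1 = pd.Series({"g": 0.4, "h": 0.8, "x": 0.1})
        p2 = pd.Series({"g": 0.6, "y": 0.2, "z": 0.05})
        mp = e.aggregate_meta_program([p1, p2], n_markers=5)
        assert mp.gene_loadings["g"] == pytest.approx(0.5)   # (0.4+0.6)/2
        assert mp.gene_loadings["h"] == pytest.approx(0.4)   # 0.8/2
        assert mp.gene_loadings["y"] == pytest.approx(0.1)

    def test_single_program_unchanged(self):
        rng = np.random.default_rng(10)
        vec = pd.Series(rng.uniform(0, 1, 150),
                        index=[f"g{i}" for i in range(150)])
        mp = e.aggregate_meta_program([vec])
        top100 = vec.sort_values(ascending=False).index[:100]
        assert set(mp.gene_loadings.index) == set(top100)
        pd.testing.assert_series_equal(mp.gene_loadings.sort_index(),
                                       vec[top100].sort_index())
        assert mp.markers == list(vec.sort_values(ascending=False).index[:30])

    def test_markers_are_brute_force_top30(self):
        rng = np.random.default_rng(11)
        vecs = [pd.Series(rng.uniform(0, 1, 200),
                          index=[f"g{i}" for i in range(200)]) for _ in range(4)]
        mp = e.aggregate_meta_program(vecs)
        brute = sorted(mp.gene_loadings.items(), key=lambda kv: (-kv[1], kv[0]))
        assert set(mp.markers) == {g for g, _ in brute[:30]}
        assert (mp.gene_loadings >= 0).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        vecs = [pd.Series(rng.uniform(0, 1, 150),
                          index=[f"g{i}" for i in range(150)]) for _ in range(3)]
        mp1 = e.aggregate_meta_program(vecs)
        mp2 = e.aggregate_meta_program(vecs[::-1])
        pd.testing.assert_series_equal(mp1.gene_loadings, mp2.gene_loadings)
        assert mp1.markers == mp2.markers

    def test_full_chain_marker_jaccard_across_seeds(self):
        good = 0
        for seed in range(20):
            cfg = e.SyntheticConfig(seed=seed, n_samples=20,
                                    n_cells_per_sample=(80, 120))
            geps, truth = e.generate_sample_geps(cfg)
            mps = e.consolidate_meta_programs(geps)
            ok = True
            for mp in mps:
                labels = {truth.program_to_mp[p] for p in mp.member_programs}
                if len(labels) != 1:
                    ok = False
                    continue
                planted = {g for g, m in truth.gene_to_mp.items()
                           if m == next(iter(labels))}
                j = e.jaccard_similarity(mp.markers, planted)
                # planted blocks have 50 genes, markers 30: max J = 30/50
                if j <= 0.6 * 30 / 50:
                    ok = False
            good += ok and len(mps) == 6
        assert good >= 16


class TestProgrammedCells:
    def _mp(self, genes):
        return e.MetaProgram(mp_id="MP1", member_programs=[("s", "p0")],
                             gene_loadings=pd.Series(1.0, index=genes),
                             markers=list(genes))

    def test_seventy_percent_boundary(self):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(0, index=genes, columns=["c21", "c20", "c0"])
        expr.iloc[:21, 0] = 1
        expr.iloc[:20, 1] = 1
        calls = e.assign_programmed_cells(expr, [self._mp(genes)])
        assert bool(calls.loc["c21", "programmed_MP1"])      # 21/30 = 0.70
        assert not bool(calls.loc["c20", "programmed_MP1"])  # 20/30 < 0.70
        assert not bool(calls.loc["c0", "programmed_MP1"])
        assert calls.loc["c0", "primary_mp"] is None

    def test_multi_mp_primary_and_ties(self):
        genes_a = [f"a{i}" for i in range(30)]
        genes_b = [f"b{i}" for i in range(30)]
        expr = pd.DataFrame(0, index=genes_a + genes_b, columns=["cA", "cTie"])
        expr.loc[genes_a, "cA"] = 1
        expr.loc[genes_a[:25], "cTie"] = 1
        expr.loc[genes_b[:25], "cTie"] = 1
        mps = [self._mp(genes_a), self._mp(genes_b)]
        mps[1].mp_id = "MP2"
        calls = e.assign_programmed_cells(expr, mps)
        assert calls.loc["cA", "primary_mp"] == "MP1"
        assert calls.loc["cTie", "primary_mp"] is None  # exact coverage tie
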