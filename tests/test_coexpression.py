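"""Spearman discovery against a rank-then-Pearson oracle; masks; refinement."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

import zonalspace as zsp

from conftest import zscore_matrix_from_z


def spearman_oracle(x, y):
    """Independent brute force: average-tie ranks, then Pearson on ranks."""
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i: j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def norm_from_dense(values):
    values = np.asarray(values, dtype=float)
    return zsp.NormalizedMatrix(
        genes=[f"G{i}" for i in range(values.shape[0])],
        barcodes=[f"B{j}" for j in range(values.shape[1])],
        values=sp.csr_matrix(values),
        scale=np.ones(values.shape[1]),
    )


class TestSpearmanDiscovery:
    def test_identical_candidate_rho_one(self):
        x = np.arange(1.0, 13.0)
        norm = norm_from_dense([x, x, np.ones(12) + (np.arange(12) % 3)])
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        assert r.table.set_index("gene").loc["G1", "rho"] == pytest.approx(1.0)

    def test_rank_reversal_rho_minus_one(self):
        x = np.arange(1.0, 13.0)
        norm = norm_from_dense([x, x[::-1], x])
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        assert r.table.set_index("gene").loc["G1", "rho"] == pytest.approx(-1.0)

    def test_single_swap_hand_value(self):
        # x = 1..10, y = x with the top two swapped: rho = 1 - 6*2/(10*99)
        x = np.arange(1.0, 11.0)
        y = x.copy()
        y[-2], y[-1] = x[-1], x[-2]
        norm = norm_from_dense([x, y])
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        assert r.table.rho.iloc[0] == pytest.approx(1 - 12 / 990, abs=1e-12)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(21)
        values = rng.integers(0, 6, size=(15, 40)).astype(float)  # heavy ties incl. zeros
        values[0] = rng.integers(1, 6, size=40)  # sentinel expressed everywhere
        norm = norm_from_dense(values)
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        tbl = r.table.set_index("gene")
        for gi in range(1, 15):
            g = f"G{gi}"
            if g not in tbl.index:  # constant candidates are untestable
                assert np.all(values[gi] == values[gi][0])
                continue
            assert tbl.loc[g, "rho"] == pytest.approx(
                spearman_oracle(values[0], values[gi]), abs=1e-9
            )

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(22)
        values = rng.poisson(3.0, size=(6, 30)).astype(float)
        values[0] += 1
        norm = norm_from_dense(values)
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        tbl = r.table.set_index("gene")
        for g in tbl.index:
            gi = int(g[1:])
            ref = scipy.stats.spearmanr(values[0], values[gi])
            assert tbl.loc[g, "rho"] == pytest.approx(ref.statistic, abs=1e-9)
            assert tbl.loc[g, "p"] == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    def test_sentinel_excluded_and_sorted_by_abs_rho(self):
        rng = np.random.default_rng(23)
        values = rng.poisson(4.0, size=(8, 25)).astype(float) + 1
        norm = norm_from_dense(values)
        r = zsp.spearman_discovery(norm, "G3", min_expressing_frac=0.0)
        assert "G3" not in set(r.table.gene)
        rhos = r.table.rho.abs().values
        assert np.all(np.diff(rhos) <= 1e-12)

    def test_bh_q_properties(self):
        rng = np.random.default_rng(24)
        values = rng.poisson(4.0, size=(20, 30)).astype(float)
        values[0] += 1
        norm = norm_from_dense(values)
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        tbl = r.table.sort_values("p")
        assert (tbl.q.values >= tbl.p.values - 1e-15).all()
        assert np.all(np.diff(tbl.q.values) >= -1e-15)  # monotone in ranked p

    def test_min_expressing_frac_filters(self):
        x = np.arange(1.0, 21.0)
        rare = np.zeros(20)
        rare[:2] = 5.0
        norm = norm_from_dense([x, rare, x[::-1]])
        r = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.5)
        assert "G1" not in set(r.table.gene) and "G2" in set(r.table.gene)

    def test_small_subset_rejected(self):
        norm = norm_from_dense(np.ones((2, 20)) + np.arange(20))
        with pytest.raises(zsp.ParameterError, match="at least"):
            zsp.spearman_discovery(norm, "G0", subset=[f"B{j}" for j in range(5)])

    def test_unexpressed_sentinel_rejected(self):
        values = np.ones((2, 12))
        values[0] = 0.0
        norm = norm_from_dense(values)
        with pytest.raises(zsp.ParameterError, match="not expressed"):
            zsp.spearman_discovery(norm, "G0")


class TestMultiGeneMask:
    def test_unary_case(self, small_pipeline):
        _, _, _, z, _ = small_pipeline
        mask = zsp.multi_gene_mask(z, ["PRG4"], threshold=1.0)
        np.testing.assert_array_equal(mask, z.gene_z("PRG4") > 1.0)

    def test_adding_genes_monotone_shrinks(self, small_pipeline):
        _, _, _, z, _ = small_pipeline
        m1 = zsp.multi_gene_mask(z, ["PRG4"])
        m2 = zsp.multi_gene_mask(z, ["PRG4", "OGN"])
        m3 = zsp.multi_gene_mask(z, ["PRG4", "OGN", "CHI3L1"])
        assert (m2 <= m1).all() and (m3 <= m2).all()

    def test_order_commutative(self, small_pipeline):
        _, _, _, z, _ = small_pipeline
        a = zsp.multi_gene_mask(z, ["PRG4", "OGN", "IBSP"])
        b = zsp.multi_gene_mask(z, ["IBSP", "PRG4", "OGN"])
        np.testing.assert_array_equal(a, b)

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(25)
        z = zscore_matrix_from_z(rng.normal(size=(3, 50)))
        mask = zsp.multi_gene_mask(z, ["G0", "G1", "G2"], threshold=0.3)
        brute = np.array(
            [all(z.z[g, c] > 0.3 for g in range(3)) for c in range(50)]
        )
        np.testing.assert_array_equal(mask, brute)

    def test_empty_gene_list_rejected(self, small_pipeline):
        _, _, _, z, _ = small_pipeline
        with pytest.raises(zsp.ParameterError):
            zsp.multi_gene_mask(z, [])


class TestRefineCluster:
    def test_all_cells_mask_equals_plain_discovery(self):
        rng = np.random.default_rng(26)
        values = rng.poisson(4.0, size=(6, 30)).astype(float)
        values[0] += 1
        norm = norm_from_dense(values)
        plain = zsp.spearman_discovery(norm, "G0", min_expressing_frac=0.0)
        refined = zsp.refine_cluster(
            norm, np.ones(30, dtype=bool), "G0", min_expressing_frac=0.0
        )
        np.testing.assert_allclose(plain.table.rho.values, refined.table.rho.values)
        assert refined.provenance[0]["type"] == "mask"

    def test_provenance_accumulates(self):
        rng = np.random.default_rng(27)
        values = rng.poisson(4.0, size=(4, 30)).astype(float) + 1
        norm = norm_from_dense(values)
        r1 = zsp.refine_cluster(norm, np.ones(30, dtype=bool), "G0", min_expressing_frac=0.0)
        r2 = zsp.refine_cluster(
            norm, np.ones(30, dtype=bool), "G1",
            min_expressing_frac=0.0, provenance=r1.provenance,
        )
        assert len(r2.provenance) == 2

    def test_planted_cluster_two_round_recovery(self):
        params = zsp.SimulationParams(planted=True)
        matrix, truth = zsp.simulate_zonal_counts(params, seed=1)
        norm = zsp.trimmed_quantile_normalize(matrix)
        z = zsp.zscore(norm)
        sentinel = truth.planted_genes[0]
        planted = set(truth.planted_genes)
        # round 1: discovery on sentinel-high cells finds a second member
        sel = zsp.sentinel_high_cells(z, sentinel, threshold=1.0)
        r1 = zsp.spearman_discovery(norm, sentinel, subset=sel)
        second = r1.table.gene.iloc[0]
        assert second in planted
        # round 2: mask on both genes, re-test with the second as sentinel
        mask = zsp.multi_gene_mask(z, [sentinel, second], threshold=1.0)
        r2 = zsp.refine_cluster(norm, mask, second, provenance=r1.provenance)
        assert set(r2.table.gene.head(3)) <= planted - {second}
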