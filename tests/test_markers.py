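import numpy as np
import pytest
from scipy import stats

import refanno as ra
from refanno import markers as M
from refanno.io import CellAnnotation, CountMatrix, ProfileMatrix, ValidationError


def _profile(values, genes=None, types=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    types = types or [f"t{i}" for i in range(values.shape[1])]
    return ProfileMatrix(genes, types, values)


class TestAggregateProfiles:
    def test_sums_cells_per_label(self, tiny_counts):
        ann = CellAnnotation({"c1": "A", "c2": "A", "c3": "B"})
        prof = M.aggregate_profiles(tiny_counts, ann)
        assert prof.cell_types == ["A", "B"]
        assert list(prof.values[:, 0]) == [5, 5, 0, 2]  # c1 + c2

    def test_single_cell_label_equals_that_cell(self, tiny_counts):
        ann = CellAnnotation({"c3": "solo"})
        prof = M.aggregate_profiles(tiny_counts, ann)
        assert list(prof.values[:, 0]) == [1, 0, 4, 1]

    def test_conserves_totals_random_matrix(self):
        rng = np.random.default_rng(1)
        cm = CountMatrix(
            [f"g{i}" for i in range(20)],
            [f"c{i}" for i in range(30)],
            rng.integers(0, 10, (20, 30)),
        )
        labels = {f"c{i}": f"t{i % 3}" for i in range(30)}
        prof = M.aggregate_profiles(cm, CellAnnotation(labels))
        # brute-force per-label summation
        for j, t in enumerate(prof.cell_types):
            cols = [i for i in range(30) if labels[f"c{i}"] == t]
            assert np.array_equal(prof.values[:, j], cm.dense()[:, cols].sum(axis=1))


class TestSelectHighlyExpressed:
    def test_top_fraction_of_expressed_genes(self):
        vals = np.arange(1, 11, dtype=float).reshape(-1, 1)
        prof = _profile(vals, types=["t"])
        top = M.select_highly_expressed(prof, "t", 0.2)
        assert top == ["g9", "g8"]

    def test_fraction_one_returns_all_expressed(self):
        prof = _profile([[3.0], [0.0], [1.0]], types=["t"])
        assert set(M.select_highly_expressed(prof, "t", 1.0)) == {"g0", "g2"}

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 50, size=(100, 1)).astype(float)
        prof = _profile(vals, types=["t"])
        got = M.select_highly_expressed(prof, "t", 0.2)
        col = vals[:, 0]
        expressed = [i for i in range(100) if col[i] > 0]
        oracle = sorted(expressed, key=lambda i: (-col[i], prof.genes[i]))
        n = int(np.ceil(0.2 * len(expressed)))
        assert got == [prof.genes[i] for i in oracle[:n]]


class TestDEOneVsRest:
    def test_constant_gene_not_returned(self):
        vals = np.vstack([np.full(5, 7.0), [50, 1, 1, 1, 1]])
        prof = _profile(vals)
        res = M.de_up_one_vs_rest(prof, "t0", ["g0", "g1"])
        assert "g0" not in res.up_genes(0.05)

    def test_spiked_gene_agrees_with_t_test_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2, 0.3, size=(60, 8))
        vals[5, 0] *= 8  # spike in target column
        prof = _profile(vals)
        res = M.de_up_one_vs_rest(prof, "t0", list(prof.genes), alpha=0.05)
        assert "g5" in res.up_genes(0.05)
        # plain one-sample t of target vs rest for the spiked gene
        logv = np.log2(M.cp10k(vals) + 1)
        t, p = stats.ttest_1samp(logv[5, 1:], logv[5, 0], alternative="less")
        assert p < 0.05

    def test_alpha_zero_returns_empty(self):
        rng = np.random.default_rng(4)
        prof = _profile(rng.lognormal(1, 0.5, (30, 6)))
        assert M.de_up_one_vs_rest(prof, "t0", list(prof.genes)).up_genes(0.0) == []

    def test_label_permutation_false_positive_rate(self):
        # under the null, up-called genes appear at roughly the alpha level
        rng = np.random.default_rng(5)
        hits = []
        for _ in range(10):
            vals = rng.lognormal(3, 0.2, size=(200, 12))
            prof = _profile(vals)
            res = M.de_up_one_vs_rest(prof, "t0", list(prof.genes), alpha=0.05)
            hits.append(len(res.table[(res.table.lfc > 0) & (res.table.pvalue < 0.05)]))
        # raw one-sided p < 0.05 with positive effect: expect ~0.025 * 200 = 5
        assert np.mean(hits) < 15


class TestRuvAdjust:
    def test_k_zero_is_depth_normalized_identity(self):
        rng = np.random.default_rng(6)
        ref = _profile(rng.lognormal(1, 1, (300, 4)))
        atlas = _profile(rng.lognormal(1, 1, (300, 6)), genes=ref.genes)
        adj = M.ruv_adjust(ref, atlas, k=0)
        order = [ref.genes.index(g) for g in adj.genes]
        expect = np.column_stack(
            [M.log_cp10k(ref.values), M.log_cp10k(atlas.values)]
        )[order, :]
        assert np.allclose(adj.log_values, expect)

    def test_global_shift_reduced_by_adjustment(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(2, 1, (400, 5))
        ref = _profile(base)
        shift = rng.lognormal(0.8, 0.1)  # multiplicative source effect
        atlas = _profile(base * shift, genes=ref.genes,
                         types=[f"a{i}" for i in range(5)])
        raw = np.abs(
            M.log_cp10k(ref.values) - M.log_cp10k(atlas.values)
        ).mean()
        adj = M.ruv_adjust(ref, atlas, k=1)
        n = len(ref.cell_types)
        after = np.abs(adj.log_values[:, :n] - adj.log_values[:, n:]).mean()
        assert after <= raw + 1e-12

    def test_disjoint_gene_sets_error(self):
        ref = _profile(np.ones((5, 3)), genes=[f"r{i}" for i in range(5)])
        atlas = _profile(np.ones((5, 3)), genes=[f"a{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            M.ruv_adjust(ref, atlas, 1)

    def test_k_too_large_is_parameter_error(self):
        prof = _profile(np.ones((10, 3)))
        atlas = _profile(np.ones((10, 2)), genes=prof.genes, types=["a0", "a1"])
        with pytest.raises(ValueError):
            M.ruv_adjust(prof, atlas, k=5)


class TestAtlasContrast:
    def _pair(self, seed=8):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(2, 1, 500)
        ref = _profile(np.column_stack([base * rng.lognormal(0, 0.1, 500)
                                        for _ in range(4)]))
        atlas = _profile(np.column_stack([base * rng.lognormal(0, 0.3, 500)
                                          for _ in range(20)]),
                         genes=ref.genes, types=[f"a{i}" for i in range(20)])
        return ref, atlas

    def test_uniform_gene_not_returned(self):
        ref, atlas = self._pair()
        adj = M.ruv_adjust(ref, atlas, 2)
        res, _ = M.de_up_vs_atlas(adj, "t0", ["g0"], 0.001)
        assert res.up_genes(0.001) == []

    def test_spiked_gene_returned(self):
        ref, atlas = self._pair()
        ref.values[7, 0] *= 10
        adj = M.ruv_adjust(ref, atlas, 2)
        res, _ = M.de_up_vs_atlas(adj, "t0", [f"g{i}" for i in range(20)], 0.001)
        assert "g7" in res.up_genes(0.001)

    def test_gene_absent_from_atlas_skipped(self):
        ref, atlas = self._pair()
        ref2 = ProfileMatrix(ref.genes + ["extra"], ref.cell_types,
                             np.vstack([ref.values, np.ones(4)]))
        adj = M.ruv_adjust(ref2, atlas, 2)
        res, skipped = M.de_up_vs_atlas(adj, "t0", ["g0", "extra"], 0.001)
        assert skipped == ["extra"]
        assert set(res.table.gene) == {"g0"}


class TestMarkerRounds:
    def test_round1_recovers_planted_markers(self, small_scenario):
        cfg, (ref, ann, q, truth, atlas) = small_scenario
        prof = M.aggregate_profiles(ref, ann)
        ms = M.identify_markers_round1(prof, atlas)
        mk = cfg.marker_indices()
        sets = []
        for t in cfg.ref_types:
            planted = {cfg.gene_names[i] for i in mk[t]}
            got = set(ms.markers[t])
            sets.append(got)
            assert len(got & planted) / len(planted) >= 0.8
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_round1_self_atlas_near_empty(self, small_scenario):
        cfg, (ref, ann, q, truth, atlas) = small_scenario
        prof = M.aggregate_profiles(ref, ann)
        self_atlas = ProfileMatrix(
            prof.genes, [f"copy_{t}" for t in prof.cell_types], prof.values
        )
        ms = M.identify_markers_round1(prof, self_atlas)
        assert sum(len(v) for v in ms.markers.values()) <= 5

    def test_round1_single_type_reference_errors(self):
        prof = _profile(np.ones((10, 1)), types=["only"])
        with pytest.raises(ValidationError):
            M.identify_markers_round1(prof, None)

    def test_round1_invariant_to_column_order(self, small_scenario):
        cfg, (ref, ann, q, truth, atlas) = small_scenario
        prof = M.aggregate_profiles(ref, ann)
        perm = [2, 0, 1]
        prof_perm = ProfileMatrix(
            prof.genes,
            [prof.cell_types[i] for i in perm],
            prof.values[:, perm],
        )
        a = M.identify_markers_round1(prof, atlas)
        b = M.identify_markers_round1(prof_perm, atlas)
        assert a.markers == b.markers

    def test_round2_planted_fold_change_retained(self):
        rng = np.random.default_rng(9)
        n_genes = 120
        base = rng.lognormal(1, 0.5, n_genes)
        means_a = base.copy()
        means_a[0] *= 4  # planted marker for label A
        cols, labels = [], {}
        for i in range(30):
            cols.append(rng.poisson(means_a))
            labels[f"a{i}"] = "A"
        for i in range(30):
            cols.append(rng.poisson(base))
            labels[f"b{i}"] = "B"
        cm = CountMatrix([f"g{i}" for i in range(n_genes)],
                         list(labels), np.column_stack(cols))
        ms = M.identify_markers_round2(cm, CellAnnotation(labels), {}, None)
        assert "g0" in ms.markers["A"]

    def test_round2_infinite_lfc_empty(self, small_scenario):
        cfg, (ref, ann, q, truth, atlas) = small_scenario
        ms = M.identify_markers_round2(ref, ann, {}, None, lfc=np.inf)
        assert all(len(v) == 0 for v in ms.markers.values())

    def test_round2_null_negative_controls_alpha_level(self):
        # negative controls drawn from the same distribution as the label's
        # cells should remove markers only at roughly the alpha level
        rng = np.random.default_rng(10)
        n_genes = 100
        base = rng.lognormal(1, 0.5, n_genes)
        means_a = base.copy()
        means_a[:10] *= 6
        cols, labels = [], {}
        for i in range(30):
            cols.append(rng.poisson(means_a))
            labels[f"a{i}"] = "A"
        for i in range(30):
            cols.append(rng.poisson(base))
            labels[f"b{i}"] = "B"
        cm = CountMatrix([f"g{i}" for i in range(n_genes)],
                         list(labels), np.column_stack(cols))
        ann = CellAnnotation(labels)
        nc = CountMatrix(
            cm.genes, [f"n{i}" for i in range(30)],
            np.column_stack([rng.poisson(means_a) for _ in range(30)]),
        )
        with_nc = M.identify_markers_round2(cm, ann, {"A": nc}, None)
        without = M.identify_markers_round2(cm, ann, {}, None)
        # same-distribution controls: stage (b) keeps almost nothing
        # (fold change vs identical distribution rarely exceeds 1.5)
        assert len(with_nc.markers["A"]) <= len(without.markers["A"])

    def test_marker_sets_anti_monotone_in_alpha(self, small_scenario):
        cfg, (ref, ann, q, truth, atlas) = small_scenario
        prof = M.aggregate_profiles(ref, ann)
        strict = M.identify_markers_round1(prof, atlas, alpha_ref=0.005)
        loose = M.identify_markers_round1(prof, atlas, alpha_ref=0.05)
        for t in cfg.ref_types:
            assert set(strict.markers[t]) <= set(loose.markers[t])
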