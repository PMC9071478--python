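import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import refanno as ra
from refanno import assignment as A
from refanno.io import CountMatrix, ProfileMatrix, ValidationError


def brute_force_tau_b(x, y):
    """O(n^2) pair-counting tau-b oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else 0.0


class TestKendallTau:
    def test_perfect_concordance(self):
        assert A.kendall_tau([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert A.kendall_tau([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_constant_vector_flagged_zero(self):
        tau, flagged = A.kendall_tau([1, 1, 1], [1, 2, 3])
        assert tau == 0.0 and flagged

    def test_matches_quadratic_oracle_on_tie_heavy_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 60)
            x = rng.integers(0, 5, n)
            y = rng.integers(0, 5, n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, _ = A.kendall_tau(x, y)
            assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=3, max_size=30))
    def test_symmetric_and_monotone_invariant(self, xs):
        rng = np.random.default_rng(1)
        ys = rng.integers(0, 20, len(xs))
        tau_xy, _ = A.kendall_tau(xs, ys)
        tau_yx, _ = A.kendall_tau(ys, xs)
        assert tau_xy == pytest.approx(tau_yx)
        assert -1.0 <= tau_xy <= 1.0
        # strictly monotone transform of one argument leaves tau unchanged
        tau_t, _ = A.kendall_tau(np.exp(np.asarray(xs, float) / 5), ys)
        assert tau_t == pytest.approx(tau_xy, abs=1e-12)


class TestVariableGenes:
    def test_only_varying_genes_selected(self):
        vals = np.array(
            [[5, 5, 5], [1, 9, 3], [2, 2, 2], [0, 4, 8], [7, 1, 6.0]]
        )
        # normalize columns to equal depth so constant rows stay constant
        vals = vals / vals.sum(axis=0, keepdims=True)
        prof = ProfileMatrix([f"g{i}" for i in range(5)], ["a", "b", "c"], vals)
        vg = A.find_variable_genes(prof, 3)
        assert set(vg.genes) == {"g1", "g3", "g4"}

    def test_n_clamped_to_available(self):
        rng = np.random.default_rng(2)
        prof = ProfileMatrix(
            [f"g{i}" for i in range(10)], ["a", "b"],
            rng.lognormal(0, 1, (10, 2)),
        )
        vg = A.find_variable_genes(prof, 500)
        assert len(vg.genes) <= 10

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(1, 1, (200, 4))
        prof = ProfileMatrix([f"g{i}" for i in range(200)],
                             list("abcd"), vals)
        vg = A.find_variable_genes(prof, 50)
        logv = np.log2(ra.markers.cp10k(vals) + 1)
        var = logv.var(axis=1, ddof=1)
        oracle = sorted(
            (i for i in range(200) if var[i] > 0),
            key=lambda i: (-var[i], prof.genes[i]),
        )[:50]
        assert vg.genes == [prof.genes[i] for i in oracle]

    def test_constant_profile_errors(self):
        prof = ProfileMatrix(["g0", "g1"], ["a", "b"], np.ones((2, 2)))
        with pytest.raises(ValidationError, match="no variable genes"):
            A.find_variable_genes(prof)


class TestMultinomialLogprob:
    def test_closed_forms(self):
        assert A.multinomial_logprob([2, 0], [0.5, 0.5]) == pytest.approx(
            np.log(0.25)
        )
        assert A.multinomial_logprob([1, 1], [0.5, 0.5]) == pytest.approx(
            np.log(0.5)
        )

    def test_exact_factorial_oracle(self):
        from fractions import Fraction

        rng = np.random.default_rng(4)
        p = np.array([0.2, 0.3, 0.1, 0.4])
        for _ in range(20):
            x = rng.integers(0, 6, 4)
            n = int(x.sum())
            if n == 0:
                continue
            coef = Fraction(math.factorial(n))
            for xi in x:
                coef /= math.factorial(int(xi))
            expect = math.log(float(coef)) + float((x * np.log(p)).sum())
            assert A.multinomial_logprob(x, p) == pytest.approx(expect, rel=1e-12)

    def test_sums_to_one_over_outcome_space(self):
        p = np.array([0.5, 0.3, 0.2])
        for n in range(1, 5):
            total = 0.0
            for x in itertools.product(range(n + 1), repeat=3):
                if sum(x) == n:
                    total += np.exp(A.multinomial_logprob(np.array(x), p))
            assert total == pytest.approx(1.0)

    def test_never_positive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 10, 5)
            p = rng.dirichlet(np.ones(5))
            assert A.multinomial_logprob(x, p) <= 1e-12


class TestCandidateAssignment:
    def _profile(self, seed=6, n_genes=100, n_types=3):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(2, 1, (n_genes, n_types))
        return ProfileMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"t{i}" for i in range(n_types)],
            vals,
        )

    def test_profile_column_maps_to_itself(self):
        prof = self._profile()
        q = CountMatrix(prof.genes, ["cell"],
                        np.round(prof.values[:, [1]]).astype(int))
        vg = A.find_variable_genes(prof, 100)
        out = A.assign_candidates_round1(q, prof, vg)
        assert out[0].candidate_label == "t1"
        assert out[0].similarity > 0.9

    def test_identical_columns_lexicographic_tie_break(self):
        vals = np.tile(np.arange(1, 11, dtype=float).reshape(-1, 1), (1, 2))
        prof = ProfileMatrix([f"g{i}" for i in range(10)], ["zeta", "alpha"], vals)
        q = CountMatrix(prof.genes, ["c"], np.arange(1, 11).reshape(-1, 1))
        vg = A.VariableGeneSet(list(prof.genes), np.ones(10))
        out = A.assign_candidates_round1(q, prof, vg)
        assert out[0].candidate_label == "alpha"

    def test_generator_truth_agreement(self, small_scenario):
        cfg, (ref, ann, q, truth, atlas) = small_scenario
        prof = ra.aggregate_profiles(ref, ann)
        vg = A.find_variable_genes(prof, 2000)
        out = A.assign_candidates_round1(q, prof, vg)
        correct = np.mean(
            [c.candidate_label == truth.labels[c.barcode] for c in out]
        )
        assert correct >= 0.95

    def test_round2_multinomial_sampled_cells_recovered(self):
        rng = np.random.default_rng(7)
        prof = self._profile(seed=8, n_genes=50, n_types=3)
        probs = prof.values / prof.values.sum(axis=0)
        cells, names, true = [], [], []
        for i in range(100):
            t = int(rng.integers(0, 3))
            cells.append(rng.multinomial(500, probs[:, t]))
            names.append(f"c{i}")
            true.append(f"t{t}")
        q = CountMatrix(prof.genes, names, np.column_stack(cells))
        out = A.assign_candidates_round2(q, prof, list(prof.genes))
        acc = np.mean([c.candidate_label == t for c, t in zip(out, true)])
        assert acc >= 0.95

    def test_round2_all_zero_cell_flagged_lexicographic(self):
        prof = ProfileMatrix(["g0", "g1"], ["b", "a"],
                             np.array([[5.0, 5.0], [5.0, 5.0]]))
        q = CountMatrix(["g0", "g1"], ["c"], np.zeros((2, 1), dtype=int))
        out = A.assign_candidates_round2(q, prof, ["g0", "g1"])
        assert out[0].candidate_label == "a"
        assert out[0].low_evidence
        assert out[0].similarity == pytest.approx(0.0)

    def test_assignment_invariant_to_gene_and_cell_order(self):
        prof = self._profile(seed=9)
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 20, (100, 5))
        q = CountMatrix(prof.genes, [f"c{i}" for i in range(5)], counts)
        gperm = rng.permutation(100)
        cperm = rng.permutation(5)
        q2 = CountMatrix(
            [prof.genes[i] for i in gperm],
            [f"c{i}" for i in cperm],
            counts[np.ix_(gperm, cperm)],
        )
        vg = A.find_variable_genes(prof, 100)
        out1 = {c.barcode: c.candidate_label
                for c in A.assign_candidates_round1(q, prof, vg)}
        out2 = {c.barcode: c.candidate_label
                for c in A.assign_candidates_round1(q2, prof, vg)}
        assert out1 == out2
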