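from itertools import permutations

import numpy as np
import pytest

from coldclade.pangenome import (
    PresenceAbsenceMatrix,
    categorize_genes,
    fit_heaps,
    predict_per_genome_change,
    rarefy_core,
    rarefy_pan,
)


def rarefaction_oracle(occ):
    """Set-based pan/core curves over every genome order (independent of numpy)."""
    n_genes, G = occ.shape
    gene_sets = [frozenset(g for g in range(n_genes) if occ[g, j]) for j in range(G)]
    pan_curves, core_curves = [], []
    for order in permutations(range(G)):
        pan, core = set(), None
        pan_row, core_row = [], []
        for j in order:
            pan |= gene_sets[j]
            core = set(gene_sets[j]) if core is None else core & gene_sets[j]
            pan_row.append(len(pan))
            core_row.append(len(core))
        pan_curves.append(pan_row)
        core_curves.append(core_row)
    return np.array(pan_curves), np.array(core_curves)


def random_matrix(rng, n_genomes, n_genes=30):
    occ = rng.random((n_genes, n_genomes)) < rng.uniform(0.1, 0.9, size=(n_genes, 1))
    occ = occ[occ.any(axis=1)]
    ids = [f"g{i}" for i in range(occ.shape[0])]
    return PresenceAbsenceMatrix(ids, [f"s{j}" for j in range(n_genomes)], occ)


class TestCategorization:
    def test_all_shared_is_strict_core(self):
        m = PresenceAbsenceMatrix(["a", "b"], ["x", "y"], np.ones((2, 2), dtype=bool))
        cats = categorize_genes(m)
        assert cats.counts == {"cloud": 0, "shell": 0, "soft_core": 0, "strict_core": 2}

    def test_hand_thresholds(self, toy_matrix):
        cats = categorize_genes(toy_matrix)
        assert cats.counts == {"cloud": 0, "shell": 2, "soft_core": 0, "strict_core": 1}

    def test_fractions_sum_to_one(self, rng):
        for _ in range(10):
            cats = categorize_genes(random_matrix(rng, int(rng.integers(2, 30))))
            assert sum(cats.fractions.values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(cats.counts.values()) == cats.total

    def test_all_zero_rows_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            PresenceAbsenceMatrix(["a"], ["x", "y"], np.zeros((1, 2), dtype=bool))


class TestRarefaction:
    def test_identical_genomes_flat_curves(self):
        m = PresenceAbsenceMatrix(
            [f"g{i}" for i in range(5)], ["a", "b", "c"], np.ones((5, 3), dtype=bool)
        )
        pan = rarefy_pan(m, 50, seed=1)
        core = rarefy_core(m, 50, seed=1)
        assert (pan.curve.median_values == 5).all()
        assert (core.curve.median_values == 5).all()

    def test_exhaustive_medians_match_oracle(self, toy_matrix, rng):
        matrices = [toy_matrix] + [random_matrix(rng, g) for g in (3, 4, 5)]
        for m in matrices:
            pan_oracle, core_oracle = rarefaction_oracle(m.occupancy)
            pan = rarefy_pan(m, exhaustive=True)
            core = rarefy_core(m, exhaustive=True)
            assert np.array_equal(pan.curve.median_values, np.median(pan_oracle, axis=0))
            assert np.array_equal(core.curve.median_values, np.median(core_oracle, axis=0))
            # exhaustive orders are itertools order: compare curves row by row
            assert np.array_equal(np.sort(pan.per_permutation, axis=0), np.sort(pan_oracle, axis=0))

    def test_sampled_medians_approach_exhaustive(self, rng):
        m = random_matrix(rng, 5)
        exact = rarefy_pan(m, exhaustive=True).curve.median_values
        sampled = rarefy_pan(m, 2000, seed=9).curve.median_values
        assert np.abs(exact - sampled).max() <= 1.0

    def test_per_permutation_monotonicity_and_endpoints(self, rng):
        for _ in range(5):
            m = random_matrix(rng, int(rng.integers(3, 12)))
            pan = rarefy_pan(m, 50, seed=3)
            core = rarefy_core(m, 50, seed=3)
            assert (np.diff(pan.per_permutation, axis=1) >= 0).all()
            assert (np.diff(core.per_permutation, axis=1) <= 0).all()
            assert (pan.per_permutation[:, -1] == m.n_genes).all()
            strict_core = int(m.occupancy.all(axis=1).sum())
            assert (core.per_permutation[:, -1] == strict_core).all()
            assert categorize_genes(m).counts["strict_core"] == strict_core

    def test_conservation_per_order(self, toy_matrix):
        # pan(N) + genes absent from the first N genomes == total, every order
        pan = rarefy_pan(toy_matrix, exhaustive=True)
        occ = toy_matrix.occupancy
        for row, order in zip(pan.per_permutation, permutations(range(3))):
            for N in range(1, 4):
                absent = int((~occ[:, list(order[:N])].any(axis=1)).sum())
                assert row[N - 1] + absent == toy_matrix.n_genes

    def test_input_validation(self, toy_matrix):
        with pytest.raises(ValueError, match="n_permutations"):
            rarefy_pan(toy_matrix, 0)


class TestHeapsFit:
    def test_exact_powerlaw_recovered(self):
        n = np.arange(2, 51)
        fit = fit_heaps(1000.0 * n**-0.5, n_values=n)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.kappa == pytest.approx(1000.0, rel=1e-6)
        assert fit.open

    def test_constant_counts_fit_flat_open(self):
        fit = fit_heaps(np.full(20, 37.0))
        assert fit.alpha == pytest.approx(0.0, abs=1e-6)
        assert fit.open

    def test_truncation_and_insufficient_signal(self):
        with pytest.raises(ValueError, match="insufficient signal"):
            fit_heaps([10.0, 5.0, 0.0, 4.0, 3.0])

    def test_loglog_initializer_close_to_full_fit(self):
        n = np.arange(2, 40, dtype=float)
        y = 500.0 * n**-0.7
        slope, _ = np.polyfit(np.log(n), np.log(y), 1)
        fit = fit_heaps(y, n_values=n)
        assert abs(-slope - fit.alpha) < 0.02

    def test_noisy_recovery_within_3_se(self):
        rng = np.random.default_rng(5)
        n = np.arange(2, 51, dtype=float)
        hits = 0
        reps = 500
        for _ in range(reps):
            y = 800.0 * n**-0.45 * rng.lognormal(0.0, 0.05, size=n.size)
            fit = fit_heaps(y, n_values=n)
            hits += abs(fit.alpha - 0.45) <= 3 * fit.alpha_se
        assert hits / reps >= 0.95


class TestPrediction:
    def test_closed_form(self):
        from coldclade.pangenome import HeapsFit

        assert predict_per_genome_change(HeapsFit(1000.0, 0.5, 0.0), 100) == pytest.approx(100.0)
        assert predict_per_genome_change(HeapsFit(42.0, 0.0, 0.0), 7) == pytest.approx(42.0)

    def test_invalid_n_rejected(self):
        from coldclade.pangenome import HeapsFit

        with pytest.raises(ValueError):
            predict_per_genome_change(HeapsFit(1.0, 0.5, 0.0), 0)


class TestIO:
    def test_binary_and_tool_dialects(self, tmp_path, toy_matrix):
        p1 = tmp_path / "wide.tsv"
        toy_matrix.to_tsv(p1)
        back = PresenceAbsenceMatrix.from_tsv(p1)
        assert np.array_equal(back.occupancy, toy_matrix.occupancy)
        assert back.genome_ids == toy_matrix.genome_ids
        p2 = tmp_path / "tool.tsv"
        p2.write_text(
            "Gene\tAnnotation\tA\tB\tC\n"
            "g1\thyp\tg1_a\t\t\n"
            "g2\thyp\tg2_a\tg2_b\t\n"
            "g3\thyp\tg3_a\tg3_b\tg3_c\n"
        )
        back2 = PresenceAbsenceMatrix.from_tsv(p2)
        assert np.array_equal(back2.occupancy, toy_matrix.occupancy)
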