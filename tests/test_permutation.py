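"""Circular-rotation null: shifts, counts, empirical p and enrichment."""

import numpy as np
import pytest

from circenrich.overlap import OverlapMatrix
from circenrich.permutation import (
    NullDistribution,
    PermutationConfig,
    circular_shift_labels,
    draw_offsets,
    empirical_pvalue,
    permutation_enrichment,
    run_permutations,
)


def matrix_from_array(values):
    values = np.asarray(values, dtype=bool)
    return OverlapMatrix(
        snp_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        annotations=tuple(f"t{j}" for j in range(values.shape[1])),
        values=values,
    )


class TestCircularShift:
    @pytest.mark.parametrize(
        "labels, offset, expected",
        [
            ([1, 0, 0, 0], 1, [0, 1, 0, 0]),
            ([1, 0, 1], 3, [1, 0, 1]),  # offset = length is the identity
            ([1, 1, 0, 0, 0], 2, [0, 0, 1, 1, 0]),
        ],
    )
    def test_examples(self, labels, offset, expected):
        got = circular_shift_labels(np.array(labels, bool), offset)
        np.testing.assert_array_equal(got, np.array(expected, bool))

    def test_index_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        labels = rng.random(17) < 0.3
        for offset in range(1, 18):
            got = circular_shift_labels(labels, offset)
            want = np.zeros_like(labels)
            for i in range(17):
                want[(i + offset) % 17] = labels[i]
            np.testing.assert_array_equal(got, want)

    def test_conserves_true_count(self):
        labels = np.array([1, 0, 1, 1, 0, 0], bool)
        assert circular_shift_labels(labels, 4).sum() == labels.sum()

    @pytest.mark.parametrize("offset", [0, 5])
    def test_offset_out_of_range_errors(self, offset):
        with pytest.raises(ValueError):
            circular_shift_labels(np.array([1, 0, 0, 0], bool), offset)


class TestRunPermutations:
    def test_exhaustive_rotations_single_chromosome(self):
        # 4 SNPs, status [1,0,0,0], incidence [1,1,0,0]: the four rotations
        # put the label at rows 1,2,3,0 giving hit counts 1,0,0,1; mean 0.5
        matrix = matrix_from_array([[1], [1], [0], [0]])
        status = np.array([1, 0, 0, 0], bool)
        offsets = np.array([[1], [2], [3], [4]])
        cfg = PermutationConfig(n_permutations=4, seed=0)
        (null,) = run_permutations(matrix, status, {"1": slice(0, 4)}, cfg, offsets)
        np.testing.assert_array_equal(null.counts, [1, 0, 0, 1])
        assert null.counts.mean() == 0.5
        assert null.observed == 1

    def test_all_true_incidence_counts_conserved(self):
        matrix = matrix_from_array(np.ones((6, 2)))
        status = np.array([1, 1, 0, 0, 0, 1], bool)
        cfg = PermutationConfig(n_permutations=50, seed=1)
        nulls = run_permutations(matrix, status, {"1": slice(0, 6)}, cfg)
        for null in nulls:
            assert (null.counts == 3).all()

    def test_per_chromosome_label_totals_conserved(self):
        # verify through a brute-force replay that rotations preserve the
        # per-chromosome associated-SNP counts for every permutation
        rng = np.random.default_rng(2)
        values = rng.random((40, 3)) < 0.4
        matrix = matrix_from_array(values)
        status = rng.random(40) < 0.25
        status[0] = True
        slices = {"1": slice(0, 15), "2": slice(15, 40)}
        cfg = PermutationConfig(n_permutations=30, seed=3)
        offsets = draw_offsets([15, 25], 30, np.random.default_rng(3))
        run_permutations(matrix, status, slices, cfg, offsets)
        for p in range(30):
            for c, sl in enumerate(slices.values()):
                shifted = circular_shift_labels(status[sl], int(offsets[p, c]))
                assert shifted.sum() == status[sl].sum()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        matrix = matrix_from_array(rng.random((100, 4)) < 0.3)
        status = rng.random(100) < 0.2
        status[3] = True
        slices = {"1": slice(0, 60), "2": slice(60, 100)}
        cfg = PermutationConfig(n_permutations=200, seed=9)
        a = run_permutations(matrix, status, slices, cfg)
        b = run_permutations(matrix, status, slices, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_no_associated_snps_errors(self):
        matrix = matrix_from_array([[1], [0]])
        with pytest.raises(ValueError):
            run_permutations(
                matrix, np.zeros(2, bool), {"1": slice(0, 2)},
                PermutationConfig(n_permutations=5),
            )


class TestEmpiricalPvalue:
    def _null(self, counts, observed, n_assoc=100):
        return NullDistribution("t", np.asarray(counts), observed, n_assoc)

    def test_zero_exceedances_reports_floor(self):
        null = self._null(np.zeros(20_000, int), observed=5)
        p, is_bound = empirical_pvalue(null, PermutationConfig())
        assert p == pytest.approx(5e-5)
        assert is_bound

    def test_19_exceedances_among_20000(self):
        counts = np.zeros(20_000, int)
        counts[:19] = 10  # >= observed
        null = self._null(counts, observed=10)
        p, is_bound = empirical_pvalue(null, PermutationConfig())
        assert p == pytest.approx(9.5e-4)
        assert not is_bound

    def test_all_counts_equal_observed_gives_one(self):
        null = self._null(np.full(1000, 7), observed=7)
        p, _ = empirical_pvalue(null, PermutationConfig(n_permutations=1000))
        assert p == 1.0

    def test_depletion_uses_lower_tail(self):
        counts = np.full(1000, 50)
        counts[:10] = 1  # <= observed
        null = self._null(counts, observed=1)
        p, _ = empirical_pvalue(null, PermutationConfig(n_permutations=1000))
        assert p == pytest.approx(0.01)

    def test_two_sided_doubles_smaller_tail(self):
        counts = np.arange(1000) % 100
        null = self._null(counts, observed=99)
        cfg = PermutationConfig(n_permutations=1000, tail_mode="two_sided_doubled")
        p, _ = empirical_pvalue(null, cfg)
        one_sided, _ = empirical_pvalue(null, PermutationConfig(n_permutations=1000))
        assert p == pytest.approx(min(1.0, 2 * one_sided))


class TestPermutationEnrichment:
    def test_point_or_from_null_mean(self):
        counts = np.full(1000, 10)
        counts[0] = 30  # keeps quantiles near 10, mean ~10.02
        null = NullDistribution("t", counts, observed=30, n_assoc=100)
        cfg = PermutationConfig(n_permutations=1000)
        res = permutation_enrichment(null, cfg)
        mean = counts.mean()
        want = (30 * (100 - mean)) / (70 * mean)
        assert res.odds_ratio == pytest.approx(want)
        assert res.fold_enrichment == pytest.approx(30 / mean)

    def test_observed_equal_null_mean_is_unity(self):
        null = NullDistribution("t", np.full(500, 20), observed=20, n_assoc=100)
        res = permutation_enrichment(null, PermutationConfig(n_permutations=500))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.pvalue == 1.0

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        counts = rng.binomial(100, 0.1, size=2000)
        null = NullDistribution("t", counts, observed=25, n_assoc=100)
        res = permutation_enrichment(null, PermutationConfig(n_permutations=2000))
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_literal_order_statistic_mode_is_wider(self):
        rng = np.random.default_rng(6)
        counts = rng.binomial(100, 0.1, size=20_000)
        null = NullDistribution("t", counts, observed=25, n_assoc=100)
        conv = permutation_enrichment(
            null, PermutationConfig(n_permutations=20_000)
        )
        lit = permutation_enrichment(
            null,
            PermutationConfig(n_permutations=20_000,
                              ci_mode="literal_order_statistic_5_95"),
        )
        # 5th/95th largest of 20,000 counts is a ~99.95% interval
        assert lit.ci_low <= conv.ci_low
        assert lit.ci_high >= conv.ci_high


class TestOracleEquivalence:
    def test_rotation_counts_equal_brute_force_recount(self, toy_study):
        """Label rotation on the precomputed matrix must equal re-deriving
        LD-expanded overlap for the relabelled SNP set, permutation by
        permutation under a shared offset stream."""
        catalog, ld, tracks, matrix, status, _ = toy_study
        slices = catalog.chrom_slices()
        n_perm = 50
        cfg = PermutationConfig(n_permutations=n_perm, seed=21)
        offsets = draw_offsets(
            [s.stop - s.start for s in slices.values()], n_perm,
            np.random.default_rng(21),
        )
        nulls = run_permutations(matrix, status, slices, cfg, offsets)

        for p in range(n_perm):
            relabelled = np.zeros(len(catalog), bool)
            for c, sl in enumerate(slices.values()):
                relabelled[sl] = circular_shift_labels(status[sl], int(offsets[p, c]))
            brute = matrix.values[relabelled].sum(axis=0)
            for j, null in enumerate(nulls):
                assert null.counts[p] == brute[j]
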