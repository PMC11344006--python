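"""Tajima's D, binning, percentile flags, permutation null, HWE, chi-square."""

import numpy as np
import pytest

from conftest import brute_tajimas_d, random_hapmatrix
from vntrkit.popgen import (
    MISSING,
    HaplotypeMatrix,
    PermutationNull,
    bin_scan,
    build_permutation_null,
    classify_vntr_lengths,
    contingency_chisq,
    hwe_test,
    percentile_flags,
    permutation_test,
    tajima_constants,
    tajimas_d,
)


class TestTajimasD:
    def test_monomorphic_region_undefined(self):
        m = HaplotypeMatrix("c", [5, 10], np.zeros((4, 2), dtype=np.int8))
        assert tajimas_d(m).D is None

    def test_two_haplotypes_variance_vanishes(self):
        # at n=2 the c1/c2 constants are exactly zero, so D is undefined
        k = tajima_constants(2)
        assert k["c1"] == pytest.approx(0.0, abs=1e-15)
        assert k["c2"] == pytest.approx(0.0, abs=1e-15)
        m = HaplotypeMatrix("c", [1, 2, 3], np.array([[0, 0, 1], [1, 1, 0]]))
        assert tajimas_d(m).D is None

    def test_four_haplotype_ladder_matches_oracle(self):
        A = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int8)
        m = HaplotypeMatrix("c", [1, 2, 3], A)
        res = tajimas_d(m)
        # frozen from the brute-force pairwise enumeration (6 pairs, pi=10/6)
        assert res.pi == pytest.approx(10 / 6)
        assert res.D == pytest.approx(brute_tajimas_d(A), abs=1e-12)
        assert res.D == pytest.approx(0.16765579503394930, abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 11))
            S = int(rng.integers(1, 21))
            m = random_hapmatrix(rng, n, S)
            got = tajimas_d(m).D
            want = brute_tajimas_d(m.alleles)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_missing_handled_pairwise_complete(self, rng):
        m = random_hapmatrix(rng, 8, 10)
        A = m.alleles.copy()
        A[0, 3] = MISSING
        m2 = HaplotypeMatrix("c", m.site_positions, A)
        res = tajimas_d(m2)
        assert res.D is None or np.isfinite(res.D)

    def test_high_missingness_site_excluded(self):
        A = np.array([[1, 0], [0, 0], [MISSING, 1], [MISSING, 1]], dtype=np.int8)
        m = HaplotypeMatrix("c", [1, 2], A)
        assert tajimas_d(m, max_missing_fraction=0.25).S == 1

    def test_single_haplotype_rejected(self):
        m = HaplotypeMatrix("c", [1], np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError):
            tajimas_d(m)


class TestBinScan:
    def make_uniform(self, positions, n_hap=6):
        rngl = np.random.default_rng(7)
        A = np.zeros((n_hap, len(positions)), dtype=np.int8)
        for s in range(len(positions)):
            A[rngl.choice(n_hap, size=int(rngl.integers(1, n_hap)), replace=False), s] = 1
        return HaplotypeMatrix("c", np.asarray(positions), A)

    def test_three_full_bins(self):
        positions = np.linspace(0, 29_999, 30, dtype=int)
        m = self.make_uniform(positions)
        bins = bin_scan(m, 30_000, bin_size=10_000, min_snps=10)
        assert [(b.start, b.end) for b in bins] == [(0, 10_000), (10_000, 20_000), (20_000, 30_000)]

    def test_half_open_boundary(self):
        m = self.make_uniform([10_000 + i for i in range(10)])
        bins = bin_scan(m, 30_000, min_snps=1)
        assert len(bins) == 1 and bins[0].start == 10_000

    def test_sparse_bin_dropped(self):
        m = self.make_uniform(list(range(9)))
        assert bin_scan(m, 10_000, min_snps=10) == []

    def test_bad_bin_size(self):
        m = self.make_uniform([1, 2])
        with pytest.raises(ValueError):
            bin_scan(m, 100, bin_size=0)


class TestPercentileFlags:
    def mkbin(self, D):
        m = random_hapmatrix(np.random.default_rng(3), 6, 12)
        b = bin_scan(m, m.site_positions[-1] + 1, bin_size=int(m.site_positions[-1] + 1), min_snps=1)[0]
        from dataclasses import replace
        return replace(b, tajima=replace(b.tajima, D=D))

    def test_extreme_low(self):
        bg = np.linspace(-2, 2, 100)
        (b,) = percentile_flags([self.mkbin(-5.0)], bg)
        assert b.percentile_rank == 0.0 and b.flags == {"bottom10", "bottom5"}

    def test_median_unflagged(self):
        bg = np.linspace(-2, 2, 101)
        (b,) = percentile_flags([self.mkbin(0.0)], bg)
        assert b.flags == frozenset() and 0.4 < b.percentile_rank < 0.6

    def test_strict_tie_handling_matches_brute_force(self, rng):
        bg = rng.choice(np.round(rng.normal(size=30), 1), size=100)
        for D in np.round(rng.normal(size=10), 1):
            (b,) = percentile_flags([self.mkbin(float(D))], bg)
            assert b.percentile_rank == sum(v < D for v in bg) / len(bg)

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            percentile_flags([self.mkbin(0.0)], [])


class TestPermutationTest:
    def test_degenerate_constant_background(self):
        bg = np.full(100, 1.5)
        cfg = PermutationNull(tail="lower", n_bins_per_replicate=50,
                              n_replicates=200, seed=9)
        b = TestPercentileFlags().mkbin(0.0)  # D below the constant c
        (res,), _ = permutation_test([b], bg, cfg)
        assert res.p_empirical == pytest.approx(1 / 201)

    def test_seed_reproducibility(self, rng):
        bg = rng.normal(size=500)
        cfg = PermutationNull(tail="lower", n_bins_per_replicate=100,
                              n_replicates=50, seed=42)
        a = build_permutation_null(bg, cfg)
        b = build_permutation_null(bg, cfg)
        np.testing.assert_array_equal(a.null_values, b.null_values)

    def test_bonferroni_and_bounds(self, rng):
        bg = rng.normal(size=2000)
        cfg = PermutationNull(tail="lower", n_bins_per_replicate=500,
                              n_replicates=100, seed=1)
        bins = [TestPercentileFlags().mkbin(float(d)) for d in rng.normal(size=5)]
        out, _ = permutation_test(bins, bg, cfg, n_tests=10)
        for b in out:
            assert 0 < b.p_empirical <= 1
            assert b.p_adjusted == pytest.approx(min(1.0, b.p_empirical * 10))

    def test_upper_tail_direction(self, rng):
        bg = rng.normal(size=2000)
        cfg = PermutationNull(tail="upper", n_bins_per_replicate=500,
                              n_replicates=100, seed=1)
        hi = TestPercentileFlags().mkbin(5.0)
        lo = TestPercentileFlags().mkbin(-5.0)
        out, _ = permutation_test([hi, lo], bg, cfg)
        assert out[0].p_empirical < out[1].p_empirical

    def test_bad_replicates(self):
        with pytest.raises(ValueError):
            PermutationNull(tail="lower", n_replicates=0)


class TestHWE:
    def test_exact_equilibrium(self):
        res = hwe_test((25, 50, 25))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_all_heterozygotes(self):
        res = hwe_test((0, 100, 0))
        assert res.chi_square == pytest.approx(100.0)
        assert res.expected == pytest.approx((25.0, 50.0, 25.0))

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test((10, 0, 0))

    def test_expected_counts_sum(self, rng):
        for _ in range(20):
            obs = tuple(int(x) for x in rng.integers(1, 50, size=3))
            res = hwe_test(obs)
            assert sum(res.expected) == pytest.approx(sum(obs))
            assert res.chi_square >= 0


class TestContingency:
    def test_uniform_table(self):
        x2, df, p, warn = contingency_chisq([[10, 10], [10, 10]])
        assert (x2, df, p) == (0.0, 1, pytest.approx(1.0))

    def test_perfect_association(self):
        x2, df, p, warn = contingency_chisq([[20, 0], [0, 20]])
        assert (x2, df) == (40.0, 1) and not warn

    def test_low_expected_warning(self):
        *_, warn = contingency_chisq([[4, 1], [1, 4]])
        assert warn

    def test_scipy_cross_check(self, rng):
        from scipy.stats import chi2_contingency

        T = rng.integers(1, 40, size=(3, 4))
        x2, df, p, _ = contingency_chisq(T)
        ref = chi2_contingency(T, correction=False)
        assert x2 == pytest.approx(ref.statistic)
        assert df == ref.dof and p == pytest.approx(ref.pvalue)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chisq([[0, 0], [5, 5]])


class TestVntrLengthClasses:
    def test_strict_thresholds(self):
        classes = classify_vntr_lengths(
            {"a": 1_499, "b": 1_500, "c": 2_000, "d": 2_001}
        )
        assert classes == {"a": "short", "b": "intermediate",
                           "c": "intermediate", "d": "long"}

    def test_single_class_gives_zero_statistic(self):
        lengths = {f"h{i}": 1_000 for i in range(10)}
        groups = {f"h{i}": "A" if i < 5 else "B" for i in range(10)}
        _, _, (x2, *_rest) = classify_vntr_lengths(lengths, groups=groups)
        assert x2 == 0.0

    def test_complete_separation_is_significant(self, rng):
        lengths = {}
        groups = {}
        for i in range(50):
            lengths[f"a{i}"] = float(rng.integers(500, 1_400))
            groups[f"a{i}"] = "A"
            lengths[f"b{i}"] = float(rng.integers(2_100, 4_000))
            groups[f"b{i}"] = "B"
        _, table, (x2, df, p, _) = classify_vntr_lengths(lengths, groups=groups)
        assert p < 0.001 and x2 > 0

    def test_nonpositive_length_raises(self):
        with pytest.raises(ValueError):
            classify_vntr_lengths({"a": 0})
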