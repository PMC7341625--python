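"""QC cascade: call rate, duplicates, HWE exact test, outlier flags, MAF."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoepi.io import GenotypeMatrix, VariantInfo
from mitoepi.qc import (
    deduplicate_samples,
    filter_call_rate,
    heterozygosity_outliers,
    hwe_filter,
    hwe_test,
    maf_filter,
    pca_outliers,
)
from mitoepi.simulate import SimulationConfig, simulate_genotypes


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Independent full-enumeration oracle in exact integer arithmetic."""
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0

    def weight(h: int) -> int:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        n = a + h + b
        return (
            math.factorial(n)
            // (math.factorial(a) * math.factorial(h) * math.factorial(b))
            * 2**h
        )

    rare = min(n_a, n_b)
    hs = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    w_obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(p, total))


class TestCallRateFilter:
    def test_sample_below_threshold_removed(self):
        # 94/100 calls at a 0.95 threshold -> out
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(3, 100)).astype(float)
        d[0, :6] = np.nan  # call rate 0.94
        g = GenotypeMatrix(
            ["lo", "ok1", "ok2"],
            [VariantInfo(f"v{j}", "1", j + 1) for j in range(100)],
            d,
        )
        kept, report = filter_call_rate(g, 0.95, 0.5)
        assert kept.sample_ids == ["ok1", "ok2"]
        assert "lo" in report.removed_samples

    def test_complete_matrix_untouched(self, tiny_matrix):
        complete = tiny_matrix.subset_samples(["s1", "s5"])
        kept, report = filter_call_rate(complete, 0.95, 0.95)
        assert kept == complete
        assert not report.removed_samples and not report.removed_variants

    def test_hand_built_removal_set(self, tiny_matrix):
        # s4 is all-missing (rate 0); after its removal v2 has 3/4 calls
        kept, report = filter_call_rate(tiny_matrix, 0.5, 0.8)
        assert report.removed_samples == {
            "s4": "sample call rate 0.0000 < 0.5"
        }
        assert set(report.removed_variants) == {"v2", "v3"}
        assert kept.sample_ids == ["s1", "s2", "s3", "s5"]
        assert kept.variant_ids == ["v1", "m1"]

    def test_all_samples_removed_errors(self, tiny_matrix):
        only_missing = tiny_matrix.subset_samples(["s4"])
        with pytest.raises(ValueError, match="every sample"):
            filter_call_rate(only_missing, 0.95, 0.95)


class TestDeduplicate:
    def _matrix(self, call_pattern):
        # one variant column per call slot; NaN marks a missed call
        n = len(call_pattern)
        m = len(call_pattern[0])
        d = np.array(
            [[np.nan if c == "." else 1.0 for c in row] for row in call_pattern]
        )
        return GenotypeMatrix(
            [f"s{i}" for i in range(n)],
            [VariantInfo(f"v{j}", "1", j + 1) for j in range(m)],
            d,
        )

    def test_lower_call_rate_member_removed(self):
        g = self._matrix(["1111", "11.."])
        kept, report = deduplicate_samples(g, [("s0", "s1")])
        assert kept.sample_ids == ["s0"]
        assert "s1" in report.removed_samples

    def test_tie_keeps_lexicographically_smaller(self):
        g = self._matrix(["1111", "1111"])
        kept, _ = deduplicate_samples(g, [("s1", "s0")])
        assert kept.sample_ids == ["s0"]

    def test_chained_duplicates_leave_one_survivor(self):
        g = self._matrix(["111.", "1111", "11.."])
        kept, report = deduplicate_samples(g, [("s0", "s1"), ("s1", "s2")])
        assert kept.sample_ids == ["s1"]  # highest call rate of the group
        assert set(report.removed_samples) == {"s0", "s2"}


class TestHweExact:
    def test_modal_configuration_has_p_one(self):
        assert hwe_test(25, 50, 25).pval == pytest.approx(1.0, abs=1e-12)

    def test_extreme_heterozygote_deficit_significant(self):
        res = hwe_test(50, 0, 50)
        assert res.pval < 1e-5  # removed at the cascade threshold

    def test_monomorphic_flagged_p_one(self):
        res = hwe_test(10, 0, 0)
        assert res.pval == 1.0 and res.monomorphic

    def test_large_total_uses_chi2_fallback(self):
        res = hwe_test(3000, 2000, 1000)
        assert res.method == "chi2"

    @given(
        st.integers(min_value=0, max_value=25),
        st.integers(min_value=0, max_value=25),
        st.integers(min_value=0, max_value=25),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_test(a, h, b).pval == pytest.approx(
            hwe_exact_oracle(a, h, b), abs=1e-12
        )

    def test_hwe_filter_spares_haploid_variants(self):
        d = np.array([[0, 1], [2, 0], [0, 1], [2, 0], [0, 1], [2, 0]], dtype=float)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(6)],
            [VariantInfo("v", "1", 1), VariantInfo("m", "chrMT", 2)],
            d,
        )
        kept, report = hwe_filter(g, 0.5)
        assert "v" in report.removed_variants  # 3 AA / 0 Aa / 3 aa deviates
        assert "m" in kept.variant_ids


class TestHeterozygosityOutliers:
    def _cohort(self, seed=0):
        cfg = SimulationConfig(
            n_samples=200, n_nuclear_snps=100, n_mito_snps=1, seed=seed,
        )
        return simulate_genotypes(cfg)

    def test_all_het_sample_flagged(self):
        g = self._cohort()
        d = g.dosages.copy()
        d[0, ~g.haploid] = 1.0  # fully heterozygous injected sample
        g2 = GenotypeMatrix(g.sample_ids, g.variants, d, g.haploid)
        report = heterozygosity_outliers(g2, sd_window=3.0)
        assert g.sample_ids[0] in report.removed_samples

    def test_infinite_window_flags_nobody(self):
        report = heterozygosity_outliers(self._cohort(), sd_window=np.inf)
        assert not report.removed_samples

    def test_homogeneous_cohort_flags_gaussian_tail(self):
        report = heterozygosity_outliers(self._cohort(seed=3), sd_window=3.0)
        # ~0.3% expected; allow generous stochastic margin at n = 200
        assert len(report.removed_samples) <= 6

    def test_needs_ten_diploid_variants(self, tiny_matrix):
        with pytest.raises(ValueError, match="10 diploid"):
            heterozygosity_outliers(tiny_matrix)


class TestPcaOutliers:
    def test_shifted_allele_frequency_sample_flagged(self):
        rng = np.random.default_rng(21)
        n, m = 100, 200
        base = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        # one sample drawn from a very different frequency regime
        base[0] = rng.binomial(2, 0.9, size=m)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(n)],
            [VariantInfo(f"v{j}", "1", j + 1) for j in range(m)],
            base,
        )
        report = pca_outliers(g, n_components=2, sd_window=3.0)
        assert "s0" in report.removed_samples

    def test_zero_components_is_noop(self, tiny_matrix):
        report = pca_outliers(tiny_matrix, n_components=0)
        assert not report.removed_samples

    def test_homogeneous_cohort_flags_few(self):
        cfg = SimulationConfig(
            n_samples=300, n_nuclear_snps=150, n_mito_snps=1, seed=22,
        )
        g = simulate_genotypes(cfg)
        report = pca_outliers(g, n_components=2, sd_window=3.0)
        assert len(report.removed_samples) <= 12  # ~1% expected over 2 PCs


class TestMafFilter:
    def _haploid_two_alt(self):
        d = np.zeros((40, 1))
        d[:2, 0] = 1.0
        return GenotypeMatrix(
            [f"s{i}" for i in range(40)], [VariantInfo("m", "chrMT", 5)], d
        )

    def test_boundary_is_inclusive_for_haploid(self):
        kept, _ = maf_filter(self._haploid_two_alt(), 0.05)
        assert kept.variant_ids == ["m"]  # 2/40 = 0.05 kept at 0.05

    def test_diploid_maf_boundary(self):
        d = np.concatenate([np.zeros(90), np.ones(10)])[:, None]
        g = GenotypeMatrix(
            [f"s{i}" for i in range(100)], [VariantInfo("v", "1", 1)], d
        )
        kept_at, _ = maf_filter(g, 0.05)
        assert kept_at.variant_ids == ["v"]  # maf exactly 0.05
        kept_above, report = maf_filter(g, 0.051)
        assert kept_above.n_variants == 0
        assert "maf 0.05 <" in report.removed_variants["v"]

    def test_all_missing_variant_removed_with_reason(self):
        d = np.full((5, 1), np.nan)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(5)], [VariantInfo("v", "1", 1)], d
        )
        _, report = maf_filter(g, 0.0)
        assert report.removed_variants == {"v": "no calls"}


def test_qc_cascade_deterministic(tiny_matrix):
    a = filter_call_rate(tiny_matrix, 0.5, 0.8)[1].to_json()
    b = filter_call_rate(tiny_matrix, 0.5, 0.8)[1].to_json()
    assert a == b
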