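"""Variant QC, HWE exact test, locus definition, instrument pruning, power, dimorphism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actigwas.gwas import (
    bonferroni_threshold,
    define_loci,
    hwe_exact_test,
    novelty_check,
    replication_power,
    replication_sample_size,
    select_instruments,
    sex_dimorphism_z,
    variant_qc,
)
from helpers import brute_force_greedy_selection, hwe_enumeration


def _stats(pos, p, chrom=1, **extra):
    n = len(pos)
    base = dict(
        chr=[chrom] * n if np.isscalar(chrom) else chrom,
        pos=pos,
        effect_allele=["A"] * n,
        other_allele=["G"] * n,
        eaf=[0.4] * n,
        beta=[0.05] * n,
        se=[0.01] * n,
        p=p,
    )
    base.update(extra)
    return pd.DataFrame(base)


class TestVariantQc:
    def test_maf_boundary(self):
        df = _stats([1, 2, 3], [0.5] * 3, maf=[0.0009, 0.001, 0.3])
        out = variant_qc(df)
        assert list(out["maf"]) == [0.001, 0.3]

    def test_info_boundary_exact_value_retained(self):
        df = _stats([1, 2], [0.5] * 2, info=[0.3, 0.299])
        out = variant_qc(df)
        assert list(out["info"]) == [0.3]

    def test_hand_filter_counts(self):
        df = _stats([1, 2, 3, 4, 5], [0.5] * 5,
                    maf=[0.0005, 0.2, 0.3, 0.1, 0.05], info=[0.9, 0.2, 0.9, 0.9, 0.9])
        out = variant_qc(df)
        assert len(out) == 3
        assert out.attrs["qc_counts"]["removed_maf"] == 1
        assert out.attrs["qc_counts"]["removed_info"] == 1

    def test_maf_derived_from_eaf_when_absent(self):
        df = _stats([1, 2], [0.5] * 2)
        df["eaf"] = [0.0005, 0.4]
        assert len(variant_qc(df)) == 1


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0

    @pytest.mark.parametrize("counts", [(1, 2, 1), (5, 0, 5), (10, 5, 2), (0, 3, 7)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_enumeration(*counts), rel=1e-10)

    def test_extreme_het_deficit_significant(self):
        assert hwe_exact_test(50, 0, 50) < 1e-7

    def test_chi2_mode_agrees_at_large_counts(self):
        # large balanced counts: exact and chi-square converge
        p_exact = hwe_exact_test(2500, 5000, 2500)
        p_chi2 = hwe_exact_test(2500, 5000, 2500, method="chi2")
        assert p_exact > 0.5 and p_chi2 > 0.5

    def test_uniform_conservative_under_null(self, rng):
        # genotypes drawn under HWE: p-values stochastically >= uniform
        n, q = 200, 0.3
        pvals = []
        for _ in range(2000):
            g = rng.binomial(2, q, size=n)
            pvals.append(hwe_exact_test(int(np.sum(g == 2)), int(np.sum(g == 1)),
                                        int(np.sum(g == 0))))
        pvals = np.array(pvals)
        for t in (0.01, 0.05, 0.1):
            assert np.mean(pvals <= t) <= t + 3 * np.sqrt(t * (1 - t) / len(pvals))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestDefineLoci:
    def test_no_significant_variants_gives_empty_list(self):
        assert define_loci(_stats([100], [1e-3])) == []

    def test_three_peaks_two_loci(self):
        df = _stats([1_000_000, 1_200_000, 1_500_000], [1e-12, 1e-10, 1e-11])
        loci = define_loci(df)
        assert [l.pos for l in loci] == [1_000_000, 1_500_000]

    def test_boundary_exactly_400kb_merges(self):
        df = _stats([1_000_000, 1_400_000], [1e-12, 1e-10])
        loci = define_loci(df)
        assert len(loci) == 1

    def test_just_beyond_400kb_splits(self):
        df = _stats([1_000_000, 1_400_001], [1e-12, 1e-10])
        assert len(define_loci(df)) == 2

    def test_index_variant_is_smallest_p_and_members_in_window(self):
        df = _stats([1_000_000, 1_100_000, 1_900_000], [1e-10, 1e-15, 5e-4])
        loci = define_loci(df)
        assert len(loci) == 1
        assert loci[0].pos == 1_100_000
        assert set(loci[0].members["pos"]) == {1_000_000, 1_100_000}

    def test_pairwise_separation_property_random_panels(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            pos = np.sort(rng.choice(np.arange(1, 5_000_000, 1000), size=n, replace=False))
            p = 10.0 ** rng.uniform(-15, 0, size=n)
            loci = define_loci(_stats(pos, p))
            idx = sorted(l.pos for l in loci)
            assert all(b - a > 400_000 for a, b in zip(idx, idx[1:]))

    def test_matches_brute_force_oracle_small_panels(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 11))
            pos = np.sort(rng.choice(np.arange(1, 3_000_001, 10_000), size=n, replace=False))
            p = 10.0 ** rng.uniform(-15, -9.5, size=n)
            loci = define_loci(_stats(pos, p), p_threshold=5e-9)
            conflict = np.abs(pos[:, None] - pos[None, :]) <= 400_000
            np.fill_diagonal(conflict, False)
            expect = brute_force_greedy_selection(p, conflict)
            assert sorted(l.pos for l in loci) == sorted(pos[j] for j in expect)


class TestNoveltyCheck:
    def test_window_conventions(self):
        idx = [(1, 1_000_000)] * 3
        assert novelty_check([idx[0]], [(1, 1_000_000 - 399_000)]) == [False]
        assert novelty_check([idx[0]], [(1, 1_000_000 + 401_000)]) == [True]
        assert novelty_check([idx[0]], [(2, 1_000_000)]) == [True]  # other chromosome

    def test_empty_known_list_all_novel(self):
        assert novelty_check([(1, 5), (2, 10)], []) == [True, True]


class TestSelectInstruments:
    def test_single_candidate(self):
        df = _stats([100], [1e-7], snp=["a"])
        out = select_instruments(df, {})
        assert list(out["snp"]) == ["a"]

    def test_distance_rule_drops_nearby(self):
        df = _stats([1_000_000, 6_000_000], [1e-8, 1e-7], snp=["a", "b"])
        out = select_instruments(df, {})
        assert list(out["snp"]) == ["a"]

    def test_exactly_10mb_is_excluded_strictly_more_required(self):
        df = _stats([1, 10_000_001], [1e-8, 1e-7], snp=["a", "b"])
        assert list(select_instruments(df, {})["snp"]) == ["a"]
        df2 = _stats([1, 10_000_002], [1e-8, 1e-7], snp=["a", "b"])
        assert list(select_instruments(df2, {})["snp"]) == ["a", "b"]

    def test_ld_rule_drops_correlated(self):
        df = _stats([1, 20_000_000], [1e-8, 1e-7], snp=["a", "b"])
        out = select_instruments(df, {("a", "b"): 0.5})
        assert list(out["snp"]) == ["a"]

    def test_p_threshold_filters_candidates(self):
        df = _stats([1, 20_000_000], [1e-8, 1e-5], snp=["a", "b"])
        assert list(select_instruments(df, {})["snp"]) == ["a"]

    def test_matches_brute_force_oracle_random_panels(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            pos = np.sort(rng.choice(np.arange(1, 60_000_001, 100_000), size=n, replace=False))
            p = 10.0 ** rng.uniform(-12, -6.5, size=n)
            snp = [f"v{j}" for j in range(n)]
            # random symmetric LD among some pairs
            ld = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        ld[(snp[i], snp[j])] = float(rng.uniform(0, 0.8))
            df = _stats(pos, p, snp=snp)
            out = select_instruments(df, ld)
            conflict = np.zeros((n, n), dtype=bool)
            for i in range(n):
                for j in range(i + 1, n):
                    r2 = ld.get((snp[i], snp[j]), 0.0)
                    if r2 >= 0.001 or abs(pos[i] - pos[j]) <= 10_000_000:
                        conflict[i, j] = conflict[j, i] = True
            expect = brute_force_greedy_selection(p, conflict)
            assert sorted(out["snp"]) == sorted(snp[j] for j in expect)


class TestPowerAndMultiplicity:
    def test_discussion_endpoints(self):
        alpha = 0.05 / 15
        assert replication_sample_size(alpha, 0.9, 5.0e-4) == pytest.approx(36_000, rel=0.03)
        assert replication_sample_size(alpha, 0.9, 1.5e-4) == pytest.approx(119_000, rel=0.03)

    def test_inverse_consistency(self):
        alpha = 3.3e-3
        n = replication_sample_size(alpha, 0.9, 2e-4)
        assert replication_power(alpha, n, 2e-4) == pytest.approx(0.9, abs=0.005)

    def test_normal_approximation_within_one_percent(self):
        alpha, power = 3.3e-3, 0.9
        approx_ncp = (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) ** 2
        r2 = 5e-4
        n_exact = replication_sample_size(alpha, power, r2)
        n_approx = approx_ncp * (1 - r2) / r2
        assert n_approx == pytest.approx(n_exact, rel=0.01)

    def test_doubling_r2_roughly_halves_n(self):
        n1 = replication_sample_size(3.3e-3, 0.9, 2e-4)
        n2 = replication_sample_size(3.3e-3, 0.9, 4e-4)
        assert n1 / n2 == pytest.approx(2.0, rel=0.01)

    def test_out_of_range_rejected(self):
        for bad in [(-0.1, 0.9, 1e-4), (0.05, 1.5, 1e-4), (0.05, 0.9, 0.0)]:
            with pytest.raises(ValueError):
                replication_sample_size(*bad)

    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 15) == pytest.approx(3.3e-3, rel=0.02)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 4160) == pytest.approx(1.2e-5, rel=0.02)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSexDimorphismZ:
    def test_equal_heritability_zero_z(self):
        z, p = sex_dimorphism_z(0.2, 3e-4, 0.2, 1e-4)
        assert z == 0.0
        assert p == 1.0

    def test_as_printed_negative_radicand_errors(self):
        with pytest.raises(ValueError, match="var_f - var_m"):
            sex_dimorphism_z(0.23, 1e-4, 0.20, 2e-4)

    def test_sum_mode_matches_normal_tail(self):
        z, p = sex_dimorphism_z(0.23, 2e-4, 0.20, 1e-4, mode="sum")
        expect_z = 0.03 / np.sqrt(3e-4)
        assert z == pytest.approx(expect_z)
        assert p == pytest.approx(2 * stats.norm.sf(expect_z))

    def test_as_printed_evaluates_when_defined(self):
        z, _ = sex_dimorphism_z(0.23, 2e-4, 0.20, 1e-4)
        assert z == pytest.approx(0.03 / np.sqrt(1e-4))
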