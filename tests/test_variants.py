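"""Variant filters, densities, spectrum, MAF classes and the rate test."""

import math
from fractions import Fraction

import numpy as np
import pytest

from capstrat.coverage import DepthTrack
from capstrat.regions import GenomicInterval, SubregionSet
from capstrat.variants import (
    DensitySummary,
    VariantCall,
    apply_variant_filters,
    callable_bases,
    conservation_distribution,
    maf_classify,
    mutation_spectrum,
    rate_ratio_test,
    read_vcf,
    relative_density,
    restrict_calls,
    variant_density,
    write_vcf,
)


def call(
    pos=0, ref="A", alt="G", qual=60.0, depth=20, alt_depth=10,
    low_mapq=0.0, maf=None, chrom="chr1",
):
    return VariantCall(chrom, pos, ref, alt, qual, depth, alt_depth, low_mapq, maf)


class TestVariantCall:
    def test_invariants(self):
        with pytest.raises(ValueError):
            call(ref="A", alt="A")
        with pytest.raises(ValueError):
            call(depth=5, alt_depth=6)
        with pytest.raises(ValueError):
            call(qual=-1)

    def test_alt_fraction(self):
        assert call(depth=20, alt_depth=3).alt_fraction == pytest.approx(0.15)


class TestVcfIO:
    def test_round_trip_preserves_calls(self, tmp_path):
        calls = [
            call(pos=5, maf=0.25),
            call(pos=17, ref="C", alt="T", qual=31.5, maf=None),
            call(pos=3, ref="G", alt="T", low_mapq=0.08, chrom="chr2"),
        ]
        p = tmp_path / "c.vcf"
        write_vcf(calls, p, contigs={"chr1": 100, "chr2": 100})
        back = read_vcf(p)
        assert sorted(back, key=lambda c: (c.chrom, c.pos)) == sorted(
            calls, key=lambda c: (c.chrom, c.pos)
        )

    def test_indel_records_are_skipped(self, tmp_path, caplog):
        p = tmp_path / "c.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=100>\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##INFO=<ID=VD,Number=1,Type=Integer,Description="v">\n'
            '##INFO=<ID=LMQ,Number=1,Type=Float,Description="l">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\t.\tA\tG\t60\t.\tDP=20;VD=10;LMQ=0\n"
            "chr1\t20\t.\tAT\tA\t60\t.\tDP=20;VD=10;LMQ=0\n"
        )
        with caplog.at_level("INFO"):
            calls = read_vcf(p)
        assert len(calls) == 1
        assert "skipped 1" in caplog.text

    def test_missing_required_info_key_errors(self, tmp_path):
        p = tmp_path / "c.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(ValueError, match="VD"):
            read_vcf(p)


class TestFilters:
    def test_boundaries_are_inclusive(self):
        kept, _ = apply_variant_filters([call(qual=30.0, depth=20, alt_depth=3)])
        assert len(kept) == 1  # quality 30 and alt fraction 0.15 both pass

    @pytest.mark.parametrize(
        "kwargs,rule",
        [
            (dict(qual=29.0), "removed_quality"),
            (dict(depth=20, alt_depth=2), "removed_alt_fraction"),
        ],
    )
    def test_boundary_failures(self, kwargs, rule):
        kept, tally = apply_variant_filters([call(**kwargs)])
        assert kept == []
        assert getattr(tally, rule) == 1

    def test_alt_fraction_just_below_threshold(self):
        kept, tally = apply_variant_filters(
            [call(depth=1000, alt_depth=149)]
        )  # 0.149
        assert kept == [] and tally.removed_alt_fraction == 1

    def test_zero_depth_has_own_tally(self):
        kept, tally = apply_variant_filters([call(depth=0, alt_depth=0)])
        assert kept == [] and tally.removed_zero_depth == 1

    def test_low_mapq_filter_off_by_default(self):
        kept, _ = apply_variant_filters([call(low_mapq=0.9)])
        assert len(kept) == 1
        kept, tally = apply_variant_filters(
            [call(low_mapq=0.9)], max_low_mapq_fraction=0.5
        )
        assert kept == [] and tally.removed_low_mapq == 1

    def test_tally_conserves_counts(self, rng):
        calls = [
            call(
                pos=i,
                qual=float(rng.uniform(0, 60)),
                depth=int(rng.integers(0, 40)),
                alt_depth=0,
                low_mapq=float(rng.uniform(0, 1)),
            )
            for i in range(200)
        ]
        calls = [
            VariantCall(
                c.chrom, c.pos, c.ref, c.alt, c.quality, c.depth,
                int(rng.integers(0, c.depth + 1)), c.low_mapq_fraction,
            )
            for c in calls
        ]
        kept, tally = apply_variant_filters(calls, max_low_mapq_fraction=0.5)
        assert tally.input == 200
        assert tally.retained + tally.removed_total == tally.input
        assert tally.retained == len(kept)


class TestCallableBases:
    def test_inclusive_boundary(self):
        sub = SubregionSet("x", [GenomicInterval("chr1", 0, 50)])
        assert callable_bases(DepthTrack({"chr1": np.full(50, 10)}), sub) == 50
        assert callable_bases(DepthTrack({"chr1": np.full(50, 9)}), sub) == 0

    def test_matches_per_base_oracle(self, rng):
        arr = rng.poisson(10.0, 300)
        sub = SubregionSet(
            "x", [GenomicInterval("chr1", 10, 120), GenomicInterval("chr1", 200, 290)]
        )
        got = callable_bases(DepthTrack({"chr1": arr}), sub)
        expected = sum(
            1
            for iv in sub.intervals
            for p in range(iv.start, iv.end)
            if arr[p] >= 10
        )
        assert got == expected


class TestDensity:
    def test_one_in_x_arithmetic(self):
        d = variant_density([call(pos=i) for i in range(10)], 15_000, "CCDS")
        assert d.one_in_x == pytest.approx(1500)
        assert d.density * d.one_in_x == pytest.approx(1.0)

    def test_zero_variants(self):
        d = variant_density([], 1000, "x")
        assert d.density == 0 and math.isnan(d.one_in_x)

    def test_zero_callable_errors(self):
        with pytest.raises(ValueError):
            variant_density([], 0, "x")

    def test_restrict_excludes_undercovered_sites(self):
        arr = np.full(100, 20)
        arr[30] = 9
        track = DepthTrack({"chr1": arr})
        sub = SubregionSet("x", [GenomicInterval("chr1", 0, 100)])
        calls = [call(pos=30), call(pos=40)]
        assert [c.pos for c in restrict_calls(calls, sub, track)] == [40]

    def test_relative_density_self_is_one(self):
        d = variant_density([call(pos=i) for i in range(10)], 15_000, "CCDS")
        assert relative_density(d, d).relative_density == 1.0

    @pytest.mark.parametrize(
        "x_sub,x_ccds,expected",
        [(714, 1808, 2.53), (925, 2300, 2.49)],
    )
    def test_relative_density_fold_changes(self, x_sub, x_ccds, expected):
        # one-in-714 vs one-in-1808 (predicted exons vs coding) ~ 2.5-fold;
        # one-in-925 vs one-in-2300 (UTR classes) likewise
        sub = DensitySummary("sub", 1000, int(1000 * x_sub), 1 / x_sub, x_sub)
        ccds = DensitySummary("CCDS", 1000, int(1000 * x_ccds), 1 / x_ccds, x_ccds)
        assert relative_density(sub, ccds).relative_density == pytest.approx(
            expected, abs=0.01
        )


class TestSpectrum:
    def test_ratio_three_to_one(self):
        calls = [
            call(pos=0, ref="A", alt="G"),
            call(pos=1, ref="C", alt="T"),
            call(pos=2, ref="G", alt="A"),
            call(pos=3, ref="A", alt="C"),
        ]
        s = mutation_spectrum(calls)
        assert (s.transitions, s.transversions) == (3, 1)
        assert s.ts_tv == pytest.approx(3.0)

    def test_no_transversions_gives_nan_not_inf(self):
        s = mutation_spectrum([call(pos=i, ref="A", alt="G") for i in range(5)])
        assert math.isnan(s.ts_tv)

    def test_counts_sum_and_directed_types(self, rng):
        bases = "ACGT"
        calls = []
        for i in range(300):
            r = bases[rng.integers(4)]
            a = bases[rng.integers(4)]
            if a == r:
                continue
            calls.append(call(pos=i, ref=r, alt=a))
        s = mutation_spectrum(calls)
        assert sum(s.counts.values()) == len(calls)
        assert s.transitions + s.transversions == len(calls)
        assert sum(s.proportions.values()) == pytest.approx(1.0)
        # strands are not collapsed
        assert "C>T" in s.counts and "G>A" in s.counts


class TestMafClassify:
    def test_all_missing_is_all_private(self):
        s = maf_classify([call(pos=i, maf=None) for i in range(4)])
        assert s.frac_private == 1.0

    def test_three_way_split(self):
        s = maf_classify(
            [call(pos=0, maf=0.0), call(pos=1, maf=0.3), call(pos=2, maf=1.0)]
        )
        assert s.frac_private == pytest.approx(1 / 3)
        assert s.frac_fixed == pytest.approx(1 / 3)
        assert sum(s.bin_fractions) == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self, rng):
        calls = [
            call(pos=i, maf=float(m) if m >= 0 else None)
            for i, m in enumerate(rng.uniform(-0.2, 1.0, size=500))
        ]
        calls.append(call(pos=999, maf=1.0))
        s = maf_classify(calls)
        assert s.frac_private + s.frac_fixed + sum(s.bin_fractions) == pytest.approx(1.0)

    def test_bad_maf_errors(self):
        c = call(pos=0)
        object.__setattr__(c, "panel_maf", 1.5)
        with pytest.raises(ValueError):
            maf_classify([c])

    def test_bad_edges_error(self):
        with pytest.raises(ValueError):
            maf_classify([call(maf=0.5)], bin_edges=(0.5, 0.2))


class TestConservationDistribution:
    def test_constant_score_single_bin(self):
        scores = {"chr1": np.full(100, 1.5)}
        sub = SubregionSet("x", [GenomicInterval("chr1", 0, 100)])
        props = conservation_distribution(scores, sub, [-2, 0, 1, 2, 4])
        assert props.tolist() == [0, 0, 1.0, 0]

    def test_proportions_sum_to_one(self, rng):
        scores = {"chr1": rng.normal(size=1000) * 3}
        sub = SubregionSet("x", [GenomicInterval("chr1", 0, 1000)])
        props = conservation_distribution(scores, sub, [-2, -1, 0, 1, 2])
        assert props.sum() == pytest.approx(1.0)  # outliers clipped into end bins

    def test_heavy_tailed_class_has_more_extreme_mass(self, rng):
        n = 50_000
        normal = rng.normal(size=n)
        mix = np.concatenate(
            [rng.normal(size=int(0.7 * n)),
             rng.normal(3.0, 1.0, int(0.15 * n)),
             rng.normal(-3.0, 1.0, int(0.15 * n))]
        )
        edges = [-8, -2, 2, 8]
        sub_n = SubregionSet("intron", [GenomicInterval("chr1", 0, n)])
        p_norm = conservation_distribution({"chr1": normal}, sub_n, edges)
        sub_m = SubregionSet("pex", [GenomicInterval("chr1", 0, len(mix))])
        p_mix = conservation_distribution({"chr1": mix}, sub_m, edges)
        assert p_mix[0] > p_norm[0] and p_mix[2] > p_norm[2]

    def test_no_scored_bases_errors(self):
        scores = {"chr1": np.full(100, np.nan)}
        sub = SubregionSet("x", [GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError):
            conservation_distribution(scores, sub, [-1, 0, 1])


def exact_binomial_two_sided(k1, n1, k2, n2):
    """Doubled-tail p computed with exact rational arithmetic."""
    n = k1 + k2
    p = Fraction(n1, n1 + n2)
    pmf = [
        Fraction(math.comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(n + 1)
    ]
    lower = sum(pmf[: k1 + 1])
    upper = sum(pmf[k1:])
    return float(min(1, 2 * min(lower, upper)))


class TestRateRatioTest:
    def test_symmetric_null_is_one(self):
        assert rate_ratio_test(5, 1000, 5, 1000) == 1.0

    def test_closed_form_extreme_split(self):
        p = rate_ratio_test(10, 1000, 0, 1000)
        assert p == pytest.approx(2 * 0.5**10)

    def test_zero_counts_give_one(self):
        assert rate_ratio_test(0, 1000, 0, 2000) == 1.0

    @pytest.mark.parametrize("n1,n2", [(1000, 1000), (500, 1500), (300, 2700)])
    def test_matches_exact_rational_enumeration(self, n1, n2):
        for total in (1, 2, 5, 11, 20):
            for k1 in range(total + 1):
                got = rate_ratio_test(k1, n1, total - k1, n2)
                assert got == pytest.approx(
                    exact_binomial_two_sided(k1, n1, total - k1, n2), abs=1e-10
                )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rate_ratio_test(1, 0, 1, 10)
        with pytest.raises(ValueError):
            rate_ratio_test(-1, 10, 1, 10)
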