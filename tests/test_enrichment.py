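import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hervscan.enrichment import (
    FragmentScanResult,
    ScanConfig,
    binomial_tail,
    bonferroni_threshold,
    expected_count,
    fragment_ratio_scan,
    manhattan_table,
    normal_tail,
    poisson_tail,
    scan,
)
from hervscan.model import (
    Direction,
    GenomicInterval,
    HervElement,
    RegionClass,
    SnvRecord,
    make_background,
)
from hervscan.simulate import table2_fixture
from tests.conftest import random_snvs


def summation_tail(n_O, N, p, tail):
    """Independent oracle: direct log-space pmf summation (0 < p < 1)."""
    ks = range(n_O, N + 1) if tail == "upper" else range(0, n_O + 1)
    lp, lq = math.log(p), math.log1p(-p)
    return math.fsum(
        math.exp(math.lgamma(N + 1) - math.lgamma(k + 1) - math.lgamma(N - k + 1) + k * lp + (N - k) * lq)
        for k in ks
    )


class TestExpectedCount:
    def test_calibrated_table_values(self):
        _, background, _ = table2_fixture()
        assert round(expected_count(702, background), 2) == 54.43
        assert round(expected_count(1044, background), 2) == 80.95
        assert round(expected_count(264, background), 2) == 20.47

    def test_zero_length(self):
        _, background, _ = table2_fixture()
        assert expected_count(0, background) == 0.0

    def test_negative_length_rejected(self):
        _, background, _ = table2_fixture()
        with pytest.raises(ValueError):
            expected_count(-1, background)

    def test_expectation_sums_over_disjoint_elements(self, rng):
        background = make_background("noncoding", 1_000_000, 12_345)
        lengths = rng.integers(100, 5000, size=50)
        total = sum(expected_count(int(l), background) for l in lengths)
        assert total == pytest.approx(
            background.total_snvs_N * int(lengths.sum()) / background.total_bases_L, rel=1e-12
        )


class TestBinomialTail:
    def test_upper_at_zero_is_one(self):
        for N, p in [(1, 0.5), (100, 0.01), (10**6, 1e-6)]:
            assert binomial_tail(0, N, p, "upper") == 1.0

    def test_single_term_case(self):
        assert binomial_tail(5, 5, 0.2, "upper") == pytest.approx(0.2**5, rel=1e-12)

    def test_three_term_case(self):
        assert binomial_tail(8, 10, 0.5, "upper") == pytest.approx(56 / 1024, rel=1e-12)

    def test_n_O_above_N_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(11, 10, 0.5, "upper")
        with pytest.raises(ValueError):
            binomial_tail(-1, 10, 0.5, "lower")

    def test_matches_summation_oracle_randomized(self, rng):
        for _ in range(300):
            N = int(rng.integers(1, 501))
            p = float(rng.uniform(0.001, 0.999))
            n_O = int(rng.integers(0, N + 1))
            for tail in ("upper", "lower"):
                got = binomial_tail(n_O, N, p, tail)
                want = summation_tail(n_O, N, p, tail)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    def test_deep_tail_accuracy(self):
        # N=1000, p=1e-3, n_O=100: far tail, compare to log-space summation
        got = binomial_tail(100, 1000, 1e-3, "upper")
        want = summation_tail(100, 1000, 1e-3, "upper")
        assert got < 1e-150
        assert got == pytest.approx(want, rel=1e-8)

    def test_upper_nonincreasing_in_observed(self):
        values = [binomial_tail(k, 50, 0.3, "upper") for k in range(51)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @settings(max_examples=200, deadline=None)
    @given(
        N=st.integers(1, 400),
        p=st.floats(0.001, 0.999),
        n_O=st.integers(1, 400),
    )
    def test_tail_complement_identity(self, N, p, n_O):
        n_O = min(n_O, N)
        total = binomial_tail(n_O, N, p, "upper") + binomial_tail(n_O - 1, N, p, "lower")
        assert total == pytest.approx(1.0, abs=1e-12)


class TestPoissonTail:
    def test_upper_at_zero(self):
        assert poisson_tail(0, 3.7, "upper") == 1.0

    def test_lower_closed_form(self):
        assert poisson_tail(1, 1.0, "lower") == pytest.approx(2 / math.e, rel=1e-12)

    def test_agrees_with_binomial_at_scale(self):
        # large-N regime used by the genome-wide test
        density = 20.47 / 264
        N = 2_867_887
        L = round(N / density)
        p = 264 / L
        exact = binomial_tail(35, N, p, "upper")
        approx = poisson_tail(35, 20.47, "upper")
        assert approx == pytest.approx(exact, rel=5e-3)

    def test_agreement_window_one_percent(self, rng):
        from scipy import stats

        for _ in range(20):
            N = int(rng.integers(100_000, 2_000_000))
            p = float(rng.uniform(1e-6, 1e-3))
            lam = N * p
            lo = int(stats.binom.ppf(0.5, N, p))
            hi = int(stats.binom.ppf(0.9999, N, p))
            for n_O in {lo, (lo + hi) // 2, hi}:
                exact = binomial_tail(n_O, N, p, "upper")
                assert poisson_tail(n_O, lam, "upper") == pytest.approx(exact, rel=0.01)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_tail(1, -0.1, "upper")


class TestBonferroni:
    def test_printed_thresholds(self):
        assert f"{bonferroni_threshold(0.05, 58):.2e}" == "8.62e-04"
        assert f"{bonferroni_threshold(0.05, 3130):.2e}" == "1.60e-05"

    def test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


def _element(eid, chrom, start, length):
    return HervElement(eid, GenomicInterval(chrom, start, start + length), group="G")


def _snvs_in(element, n, stride=1):
    return [
        SnvRecord(element.interval.chrom, element.interval.start + 1 + i * stride, "C", "G")
        for i in range(n)
    ]


class TestScan:
    def test_empty_element_list(self):
        background = make_background("coding", 1000, 10)
        assert scan([], [SnvRecord("chr1", 5, "A", "C")], background) == []

    def test_saturated_element_never_significant(self):
        # one element spanning the whole region: p_F = 1, upper tail at N is 1
        element = _element("E", "chr1", 0, 1000)
        background = make_background("coding", 1000, 50)
        snvs = _snvs_in(element, 50, stride=20)
        (result,) = scan([element], snvs, background)
        assert result.p_F == 1.0
        assert result.p_upper == pytest.approx(1.0)
        assert not result.significant

    def test_direction_and_significance(self):
        elements, background, observed = table2_fixture()
        snvs = []
        for e in elements:
            snvs.extend(_snvs_in(e, observed[e.element_id]))
        results = scan(elements, snvs, background, ScanConfig(n_tests=58))
        by_id = {r.element_id: r for r in results}
        assert all(r.direction is Direction.OVER for r in results)
        assert all(r.alpha_adjusted == pytest.approx(0.05 / 58) for r in results)
        assert by_id["6114"].n_O == 35
        assert by_id["6114"].n_E == pytest.approx(20.47, abs=5e-3)
        # exact binomial verdicts at these inputs (not the printed normal-mode values)
        assert by_id["4673"].significant and by_id["4780"].significant

    def test_equal_tie_never_significant(self):
        element = _element("E", "chr1", 0, 100)
        background = make_background("coding", 1000, 50)  # n_E = 5 exactly
        (result,) = scan([element], _snvs_in(element, 5), background)
        assert result.direction is Direction.EQUAL and not result.significant

    def test_min_observed_filters_and_auto_tests(self):
        a, b = _element("A", "chr1", 0, 100), _element("B", "chr1", 1000, 100)
        background = make_background("coding", 10_000, 20)
        results = scan([a, b], _snvs_in(a, 3), background)
        assert [r.element_id for r in results] == ["A"]
        assert results[0].alpha_adjusted == 0.05  # one test performed

    def test_results_sorted_by_matched_p(self, rng):
        elements = [_element(f"E{i}", "chr1", i * 10_000, 1000) for i in range(10)]
        background = make_background("coding", 1_000_000, 5_000)
        snvs = []
        for i, e in enumerate(elements):
            snvs.extend(_snvs_in(e, int(rng.integers(1, 40))))
        results = scan(elements, snvs, background)
        ps = [r.p_matched for r in results]
        assert ps == sorted(ps)

    def test_site_collapse_vs_event_mode(self):
        element = _element("E", "chr1", 0, 100)
        background = make_background("coding", 1000, 10)
        dup = [SnvRecord("chr1", 5, "C", "G"), SnvRecord("chr1", 5, "C", "T")]
        (site_result,) = scan([element], dup, background, ScanConfig(count_mode="sites"))
        (event_result,) = scan([element], dup, background, ScanConfig(count_mode="events"))
        assert site_result.n_O == 1 and event_result.n_O == 2

    def test_normal_mode_reproduces_printed_style_pvalue(self):
        # the TNN-row inputs under the continuity-uncorrected normal tail
        density = 20.47 / 264
        N = 2_867_887
        L = round(N / density)
        p = normal_tail(35, N, 264 / L, "upper")
        assert p == pytest.approx(6.6e-4, rel=0.02)

    def test_manhattan_rows(self):
        elements, background, observed = table2_fixture()
        snvs = []
        for e in elements:
            snvs.extend(_snvs_in(e, observed[e.element_id]))
        rows = manhattan_table(scan(elements, snvs, background))
        assert len(rows) == 4
        assert all(row["neg_log10_p"] > 0 for row in rows)


class TestScanConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(alpha=0.0)
        with pytest.raises(ValueError):
            ScanConfig(n_tests=0)


class TestFragmentScan:
    def _region(self):
        return [GenomicInterval("chr1", 0, 60_000), GenomicInterval("chr2", 0, 40_000)]

    def test_zero_snvs(self):
        result = fragment_ratio_scan(self._region(), [], fragment_size=1000, n_fragments=50, seed=1)
        assert result.observed_ratio == 0.0

    def test_deterministic_for_fixed_seed(self, rng):
        snvs = random_snvs(rng, 2_000, max_pos=40_000)
        a = fragment_ratio_scan(self._region(), snvs, 1000, 200, seed=7)
        b = fragment_ratio_scan(self._region(), snvs, 1000, 200, seed=7)
        assert a.counts == b.counts and a.observed_ratio == b.observed_ratio

    def test_region_too_short_rejected(self):
        with pytest.raises(ValueError):
            fragment_ratio_scan([GenomicInterval("chr1", 0, 500)], [], fragment_size=1000)

    def test_ratio_definition(self, rng):
        snvs = random_snvs(rng, 500, max_pos=50_000)
        result = fragment_ratio_scan(self._region(), snvs, 1000, 100, seed=3)
        assert result.observed_ratio == pytest.approx(sum(result.counts) / (100 * 1000))

    def test_law_of_large_numbers(self):
        # uniform landscape at rate 0.02: mean per-base ratio concentrates
        rng = np.random.default_rng(11)
        genome = 200_000
        k = rng.binomial(genome, 0.02)
        positions = np.sort(rng.choice(genome, size=k, replace=False))
        snvs = [SnvRecord("chr1", int(p) + 1, "C", "G") for p in positions]
        result = fragment_ratio_scan(
            [GenomicInterval("chr1", 0, genome)], snvs, 1000, 1000, seed=5
        )
        mc_se = math.sqrt(0.02 * 0.98 / (1000 * 1000))
        assert abs(result.observed_ratio - 0.02) < 3 * mc_se + 3 * math.sqrt(0.02 * 0.98 / genome)
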