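"""Carrier counting, exact intervals, Hardy–Weinberg transform, projections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from carrierfreq import (
    VariantRecord,
    carrier_count,
    carrier_frequency,
    clopper_pearson,
    hwe_incidence,
    poisson_rate_ci,
    project_census,
    spectrum_matrix,
)
from carrierfreq.records import PopulationCounts
from carrierfreq.stats import binomial_ci, round_half_up


def rec(hgvs, **pop_ac_nhom):
    counts = {}
    for pop, (ac, an, nhom) in pop_ac_nhom.items():
        counts[pop] = PopulationCounts(population=pop, ac=ac, an=an, nhom=nhom, cohort_n=an // 2)
    return VariantRecord(gene="G", hgvs_c=hgvs, consequence="missense_variant", pop_counts=counts)


class TestCarrierCount:
    def test_default_policy_sums_alleles(self):
        records = [rec("c.1A>G", EAS=(3, 100, 1)), rec("c.2A>G", EAS=(2, 100, 0))]
        assert carrier_count(records, "EAS") == 5

    def test_genotype_aware_counts_each_homozygote_once(self):
        records = [rec("c.1A>G", EAS=(4, 100, 1))]
        assert carrier_count(records, "EAS", policy="genotype_aware") == 3
        assert carrier_count(records, "EAS") == 4

    def test_absent_population_contributes_zero(self):
        records = [rec("c.1A>G", EAS=(3, 100, 0))]
        assert carrier_count(records, "KOR") == 0

    def test_empty_record_list(self):
        assert carrier_count([], "EAS") == 0


class TestClopperPearson:
    def test_closed_form_at_zero_successes(self):
        low, high = clopper_pearson(0, 10, 0.95)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_boundary_at_all_successes(self):
        low, high = clopper_pearson(10, 10, 0.95)
        assert high == 1.0
        assert low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    def test_korean_interval_rounds_to_published_display(self):
        low, high = clopper_pearson(19, 1909, 0.95)
        assert round_half_up(100 * low, 1) == 0.6
        assert 1.5 <= round_half_up(100 * high, 1) <= 1.6

    @pytest.mark.parametrize("x,n", [(-1, 10), (11, 10), (0, 0)])
    def test_domain_violations_rejected(self, x, n):
        with pytest.raises(ValueError):
            clopper_pearson(x, n)

    def test_agrees_with_binomial_tail_bisection_spot_checks(self):
        # Oracle: smallest/largest p whose observed-count tail prob >= alpha/2.
        for x, n in [(0, 7), (1, 10), (5, 50), (33, 100), (19, 60), (60, 60)]:
            low, high = clopper_pearson(x, n, 0.95)
            if x > 0:
                lo, hi_b = 0.0, 1.0
                for _ in range(80):
                    mid = (lo + hi_b) / 2
                    if binom.sf(x - 1, n, mid) >= 0.025:
                        hi_b = mid
                    else:
                        lo = mid
                assert abs(low - lo) < 1e-9
            if x < n:
                lo, hi_b = 0.0, 1.0
                for _ in range(80):
                    mid = (lo + hi_b) / 2
                    if binom.cdf(x, n, mid) >= 0.025:
                        lo = mid
                    else:
                        hi_b = mid
                assert abs(high - lo) < 1e-9

    @given(n=st.integers(1, 5000), frac=st.floats(0, 1), conf=st.floats(0.5, 0.999))
    @settings(max_examples=200, derandomize=True)
    def test_interval_always_brackets_the_point_estimate(self, n, frac, conf):
        x = min(n, int(frac * (n + 1)))
        low, high = clopper_pearson(x, n, conf)
        assert 0.0 <= low <= x / n <= high <= 1.0

    def test_width_shrinks_with_sample_size_at_fixed_rate(self):
        widths = []
        for scale in (1, 10, 100):
            low, high = clopper_pearson(2 * scale, 1000 * scale, 0.95)
            widths.append(high - low)
        assert widths[0] > widths[1] > widths[2]


class TestRateInterval:
    def test_zero_count_lower_bound_is_zero(self):
        low, high = poisson_rate_ci(0, 100)
        assert low == 0.0 and high > 0

    def test_matches_chi_square_closed_form(self):
        low, high = poisson_rate_ci(33, 9197)
        # classic 95% Poisson limits for a count of 33
        assert 9197 * low == pytest.approx(22.7157, abs=1e-3)
        assert 9197 * high == pytest.approx(46.3442, abs=1e-3)

    def test_dispatcher_knows_all_methods(self):
        for method in ("clopper-pearson", "rate-poisson", "wilson", "wald"):
            low, high = binomial_ci(19, 1909, 0.95, method)
            assert 0 <= low <= 19 / 1909 <= high <= 1
        with pytest.raises(ValueError, match="unknown CI method"):
            binomial_ci(1, 10, 0.95, "magic")


class TestCarrierFrequencyAndIncidence:
    def test_east_asian_point_estimates(self):
        est = carrier_frequency(33, 9197)
        assert est.cf == 33 / 9197
        assert round_half_up(est.cf_percent, 1) == 0.4
        inc = hwe_incidence(est)
        assert inc.q == 33 / (2 * 9197)
        assert inc.reciprocal == 310688

    def test_korean_point_estimates(self):
        est = carrier_frequency(19, 1909)
        assert round_half_up(est.cf_percent, 1) == 1.0
        assert hwe_incidence(est).reciprocal == 40380

    def test_hgmd_east_asian_incidence(self):
        assert hwe_incidence(carrier_frequency(21, 9197)).reciprocal == 767209

    def test_q_is_exactly_x_over_2n(self):
        for x, n in [(1, 7), (19, 1909), (33, 9197), (5, 100)]:
            assert hwe_incidence(carrier_frequency(x, n)).q == x / (2 * n)

    def test_zero_carriers_yield_sentinel_not_infinity(self):
        est = carrier_frequency(0, 9197)
        assert est.cf == 0.0 and est.ci_low == 0.0
        inc = hwe_incidence(est)
        assert inc.no_observed_carriers
        assert inc.reciprocal is None
        assert "no observed carriers" in inc.display()

    def test_reciprocal_never_increases_with_more_carriers(self):
        previous = math.inf
        for x in range(1, 40):
            reciprocal = hwe_incidence(carrier_frequency(x, 9197)).reciprocal
            assert reciprocal <= previous
            previous = reciprocal

    def test_lower_cf_bound_maps_to_rarer_incidence(self):
        inc = hwe_incidence(carrier_frequency(19, 1909))
        assert inc.ci_reciprocal_high > inc.reciprocal > inc.ci_reciprocal_low


class TestProjection:
    def test_korean_census_projection(self):
        est = carrier_frequency(19, 1909, method="rate-poisson")
        inc = hwe_incidence(est)
        proj = project_census(inc, est, 51_800_000, 302_676)
        assert proj.newborn_carriers_per_year == 3027
        assert proj.affected_births_per_year == 7
        assert proj.total_carriers == 518_000

    def test_zero_births_zero_annual_projections(self):
        est = carrier_frequency(19, 1909)
        inc = hwe_incidence(est)
        proj = project_census(inc, est, 1_000_000, 0)
        assert proj.newborn_carriers_per_year == 0
        assert proj.affected_births_per_year == 0

    def test_negative_census_rejected(self):
        est = carrier_frequency(1, 100)
        with pytest.raises(ValueError):
            project_census(hwe_incidence(est), est, -1, 10)


class TestSpectrumMatrix:
    def test_variants_absent_from_reference_populations(self, dhcr7_records):
        result = spectrum_matrix(dhcr7_records, ["ASJ", "FIN", "AMR"])
        present = result.matrix.any(axis=1)
        assert list(result.matrix.index[present]) == ["c.907G>A"]

    def test_korean_presence_rows(self, dhcr7_records):
        result = spectrum_matrix(dhcr7_records, ["KOR"])
        assert int(result.matrix["KOR"].sum()) == 4

    def test_all_zero_row_is_all_false(self):
        record = rec("c.9A>G", EAS=(0, 100, 0), KOR=(0, 50, 0))
        result = spectrum_matrix([record], ["EAS", "KOR"])
        assert not result.matrix.loc["c.9A>G"].any()

    def test_exclusive_lists_private_variants(self, dhcr7_records):
        result = spectrum_matrix(dhcr7_records, ["EAS", "NFE"])
        assert "c.16C>T" in result.exclusive["EAS"]
        assert "c.724C>T" not in result.exclusive["EAS"]


class TestRounding:
    def test_half_up_ties(self):
        assert round_half_up(0.25008 * 10, 1) == 2.5
        assert round_half_up(2.5) == 3
        assert round_half_up(0.35, 1) == 0.4
        assert round_half_up(-2.5) == -3
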