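"""Indicator arithmetic against hand calculations and brute-force oracles."""

import datetime
import warnings
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opioid_its import (
    Cohort,
    IndicatorConfig,
    UnknownDrugError,
    build_series,
    daily_mme,
    high_dose_proportion,
    month_grid,
    multi_provider_proportion,
    naloxone_rate,
    overlap_rate_monthly,
    overlap_ratio,
    percentage,
)

D = datetime.date


class TestDailyMME:
    def test_morphine_factor_is_one(self, make_fill, catalog):
        f = make_fill(drug="morphine", mg=30.0, upd=2.0)
        assert daily_mme([f], D(2016, 3, 5), catalog) == 60.0

    def test_oxycodone_factor(self, make_fill, catalog):
        f = make_fill(drug="oxycodone", mg=10.0, upd=4.0)
        assert daily_mme([f], D(2016, 3, 5), catalog) == 60.0

    def test_concurrent_fills_add(self, make_fill, catalog):
        fills = [make_fill(rx="a", drug="morphine", mg=30.0, upd=2.0),
                 make_fill(rx="b", drug="oxycodone", mg=10.0, upd=4.0)]
        assert daily_mme(fills, D(2016, 3, 5), catalog) == 120.0

    def test_inactive_fill_ignored(self, make_fill, catalog):
        f = make_fill(start=D(2016, 3, 1), days=10)
        assert daily_mme([f], D(2016, 3, 20), catalog) == 0.0

    def test_naloxone_has_no_mme(self, make_fill, catalog):
        with pytest.raises(UnknownDrugError):
            daily_mme([make_fill(drug="NALOXONE", mg=0.4)], D(2016, 3, 5), catalog)


class TestOverlapRatio:
    def test_partial_overlap(self, make_fill):
        fills = [make_fill(rx="a", start=D(2016, 3, 1), days=10),
                 make_fill(rx="b", start=D(2016, 3, 6), days=10)]
        assert overlap_ratio(fills) == pytest.approx(5 / 15)

    def test_disjoint_fills(self, make_fill):
        fills = [make_fill(rx="a", start=D(2016, 3, 1), days=5),
                 make_fill(rx="b", start=D(2016, 3, 10), days=5)]
        assert overlap_ratio(fills) == 0.0

    def test_identical_fills(self, make_fill):
        fills = [make_fill(rx="a"), make_fill(rx="b")]
        assert overlap_ratio(fills) == 1.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 59), st.integers(1, 10)),
                    min_size=1, max_size=10))
    def test_matches_per_day_brute_force(self, spec):
        from opioid_its import PrescriptionRecord
        base = D(2016, 1, 1)
        fills = [PrescriptionRecord(f"r{i}", "p1", "d1", "h1", "oxycodone",
                                    base + datetime.timedelta(days=off), days,
                                    1.0, 10.0, "outpatient")
                 for i, (off, days) in enumerate(spec)]
        counts = Counter()
        for f in fills:
            d = f.start_date
            while d <= f.end_date:
                counts[d] += 1
                d += datetime.timedelta(days=1)
        total = sum(1 for v in counts.values() if v >= 1)
        over = sum(1 for v in counts.values() if v >= 2)
        assert overlap_ratio(fills) == pytest.approx(over / total)


class TestMonthlyProportions:
    def test_high_dose_boundary_is_inclusive(self, make_fill, catalog):
        f = make_fill(drug="morphine", mg=50.0, upd=2.0)  # exactly 100 MME/day
        pct = high_dose_proportion([f], 2016, 3, IndicatorConfig(), catalog)
        assert pct == 100.0

    def test_high_dose_monotone_in_threshold(self, make_fill, catalog):
        fills = [make_fill(rx=f"r{i}", pid=f"p{i}", drug="morphine",
                           mg=10.0 * (i + 1), upd=2.0) for i in range(5)]
        props = [high_dose_proportion(
            fills, 2016, 3, IndicatorConfig(high_dose_mme_threshold=thr), catalog)
            for thr in (120, 90, 60, 30)]
        assert props == sorted(props)

    def test_spanning_fill_counts_dose_but_not_denominator(self, make_fill, catalog):
        # started in March, still covered in April: contributes MME in April but
        # the patient is an April user only if some fill starts in April
        fills = [make_fill(start=D(2016, 3, 25), days=20, drug="morphine",
                           mg=60.0, upd=2.0)]
        assert np.isnan(high_dose_proportion(fills, 2016, 4, IndicatorConfig(),
                                             catalog))
        fills.append(make_fill(rx="r2", start=D(2016, 4, 2), days=3))
        assert high_dose_proportion(fills, 2016, 4, IndicatorConfig(),
                                    catalog) == 100.0

    def test_multi_provider_irrespective_of_institution(self, make_fill):
        fills = [make_fill(rx="a", provider="d1", inst="h1"),
                 make_fill(rx="b", provider="d2", inst="h1")]
        assert multi_provider_proportion(fills, 2016, 3, IndicatorConfig()) == 100.0

    def test_single_provider_not_counted(self, make_fill):
        fills = [make_fill(rx="a"), make_fill(rx="b")]
        assert multi_provider_proportion(fills, 2016, 3, IndicatorConfig()) == 0.0

    def test_overlap_monthly_mean_of_ratios(self, make_fill):
        fills = [make_fill(rx="a", pid="p1"), make_fill(rx="b", pid="p1"),
                 make_fill(rx="c", pid="p2", start=D(2016, 3, 20), days=5)]
        # p1 has ratio 1 (duplicate fills), p2 ratio 0 -> mean 50%
        assert overlap_rate_monthly(fills, 2016, 3) == pytest.approx(50.0)
        assert overlap_rate_monthly(fills, 2016, 3,
                                    mode="any_overlap") == pytest.approx(50.0)

    def test_naloxone_only_among_that_months_users(self, make_fill):
        opioids = [make_fill(rx="a", pid="p1")]
        naloxone = [make_fill(rx="n1", pid="p1", drug="NALOXONE", mg=0.4),
                    make_fill(rx="n2", pid="p2", drug="NALOXONE", mg=0.4)]
        assert naloxone_rate(opioids, naloxone, 2016, 3) == 100.0


class TestPercentageRounding:
    @pytest.mark.parametrize("num,den,expected", [
        (187, 24924, 0.75), (486, 24924, 1.95), (1, 800, 0.13)])
    def test_half_up_two_decimals(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            percentage(1, 0)


class TestBuildSeries:
    def _cohort(self, make_patient, make_fill, fills):
        pids = {f.patient_id for f in fills}
        patients = [make_patient(pid=p) for p in sorted(pids)]
        return Cohort(patients, [f for f in fills if f.drug_code != "NALOXONE"],
                      [f for f in fills if f.drug_code == "NALOXONE"])

    def test_sixty_row_grid(self, make_patient, make_fill):
        cohort = self._cohort(make_patient, make_fill, [make_fill()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = build_series(cohort)
        assert len(series.frame) == 60
        assert series.frame["month_index"].tolist() == list(range(1, 61))

    def test_empty_cohort_flagged_missing_with_warning(self):
        with pytest.warns(UserWarning, match="zero opioid users"):
            series = build_series(Cohort([], [], []))
        assert series.frame["high_dose_value"].isna().all()
        assert len(series.frame) == 60

    def test_invariant_to_input_permutation(self, make_patient, make_fill):
        rng = np.random.default_rng(7)
        fills = [make_fill(rx=f"r{i}", pid=f"p{i % 5}",
                           start=D(2016, 1 + i % 12, 1 + i % 25),
                           provider=f"d{i % 3}") for i in range(40)]
        cfg = IndicatorConfig(month_grid=tuple(month_grid((2016, 1), 12)))
        cohort = self._cohort(make_patient, make_fill, fills)
        a = build_series(cohort, cfg).frame
        shuffled = list(fills)
        rng.shuffle(shuffled)
        b = build_series(self._cohort(make_patient, make_fill, shuffled), cfg).frame
        assert a.equals(b)

    def test_values_match_numerator_over_denominator(self, make_patient, make_fill):
        fills = [make_fill(rx="a", pid="p1", drug="morphine", mg=60.0, upd=2.0),
                 make_fill(rx="b", pid="p2"),
                 make_fill(rx="c", pid="p2", provider="d2")]
        cfg = IndicatorConfig(month_grid=tuple(month_grid((2016, 3), 1)))
        series = build_series(self._cohort(make_patient, make_fill, fills), cfg)
        row = series.frame.iloc[0]
        assert row["n_users"] == 2
        assert row["high_dose_num"] == 1 and row["high_dose_value"] == 50.0
        assert row["multi_provider_num"] == 1 and row["multi_provider_value"] == 50.0
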