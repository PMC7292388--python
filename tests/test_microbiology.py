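"""Dilution arithmetic, selection/averaging, censoring, conflict flags."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from sanipath import (DilutionReading, EnvironmentalSample, combine_dilutions,
                      concentration_from_reading, estimate_concentrations,
                      flag_conflicts, parse_samples_csv, select_dilutions)
from sanipath.microbiology import (DilutionError, LEFT_CENSORED, OBSERVED,
                                   RIGHT_CENSORED, SampleFormatError)

RANGE = (20.0, 200.0)


def _reading(count, dilution=1e-2, amount=1.0):
    return DilutionReading(dilution_factor=dilution, amount_assayed=amount,
                           count=count)


def _sample(readings, sample_type="drain_water", unit="per_100mL"):
    return EnvironmentalSample(sample_id="s1", sample_type=sample_type,
                               neighborhood="site-a",
                               readings=tuple(readings),
                               denominator_unit=unit)


class TestSingleReading:
    @pytest.mark.parametrize("count,amount,dilution,scale,expected", [
        (45, 1.0, 1e-2, 100.0, 450_000.0),   # per 100 mL
        (12, 10.0, 1e-1, 1.0, 12.0),          # per g
        (0, 1.0, 1e-3, 100.0, 0.0),           # zero flows to censoring
    ])
    def test_hand_arithmetic(self, count, amount, dilution, scale, expected):
        r = _reading(count, dilution, amount)
        assert concentration_from_reading(r, scale) == expected

    def test_worked_example_log10(self):
        conc = concentration_from_reading(_reading(45, 1e-2, 1.0), 100.0)
        assert math.log10(conc) == pytest.approx(5.653, abs=5e-4)

    def test_zero_amount_rejected(self):
        with pytest.raises(DilutionError):
            DilutionReading(dilution_factor=1e-2, amount_assayed=0, count=5)

    def test_tntc_has_no_concentration(self):
        with pytest.raises(DilutionError):
            concentration_from_reading(_reading(None), 100.0)


class TestSelection:
    def test_single_countable_reading_wins(self):
        readings = [_reading(4, 1e-1), _reading(45, 1e-2), _reading(310, 1e-3)]
        idx = select_dilutions(readings, RANGE)
        assert [readings[i].count for i in idx] == [45]

    def test_all_zero_picks_single_nearest(self):
        readings = [_reading(0, 1.0), _reading(0, 1e-1)]
        idx = select_dilutions(readings, RANGE)
        assert len(idx) == 1

    def test_all_in_range_all_selected(self):
        readings = [_reading(180, 1e-1), _reading(30, 1e-2)]
        assert select_dilutions(readings, RANGE) == [0, 1]

    def test_all_tntc_keeps_most_dilute(self):
        readings = [DilutionReading(1e-1, 1.0, None),
                    DilutionReading(1e-3, 1.0, None)]
        assert select_dilutions(readings, RANGE) == [1]

    def test_empty_errors(self):
        with pytest.raises(DilutionError):
            select_dilutions([], RANGE)


class TestConflicts:
    def test_consistent_series_not_flagged(self):
        # implied 4.5e3 vs 5e3 per mL-equivalent
        assert flag_conflicts([_reading(45, 1e-2), _reading(5, 1e-3)]) == []

    def test_tenfold_discrepancy_flagged(self):
        # identical counts across a 10-fold dilution: implied 4.5e3 vs 4.5e4
        flags = flag_conflicts([_reading(45, 1e-2), _reading(45, 1e-3)])
        assert len(flags) == 1
        assert "10" in flags[0]

    def test_single_reading_never_conflicts(self):
        assert flag_conflicts([_reading(45)]) == []


class TestCombine:
    def test_log_scale_average_of_two_readings(self):
        # log10 5.653 and 5.477 -> mean 5.565
        s = _sample([_reading(45, 1e-2), _reading(30, 1e-2)])
        est = combine_dilutions(s, config=_cfg())
        assert est.censoring == OBSERVED
        expected = (math.log10(450_000) + math.log10(300_000)) / 2
        assert est.log10_concentration == pytest.approx(expected, abs=1e-12)
        assert est.log10_concentration == pytest.approx(5.565, abs=5e-4)

    def test_all_zero_is_left_censored_at_detection_limit(self):
        s = _sample([_reading(0, 1.0, 1.0), _reading(0, 1e-1, 1.0)])
        est = combine_dilutions(s, config=_cfg())
        assert est.censoring == LEFT_CENSORED
        assert est.limit == pytest.approx(100.0)  # 1/(1 mL x 1) x 100
        assert est.log10_concentration == pytest.approx(2.0)

    def test_tntc_everywhere_right_censored_at_range_top(self):
        s = _sample([DilutionReading(1e-3, 1.0, None)])
        est = combine_dilutions(s, config=_cfg())
        assert est.censoring == RIGHT_CENSORED
        assert est.limit == pytest.approx(2e7)  # 200/(1 mL x 1e-3) x 100

    def test_perfect_tenfold_series_is_fixed_point(self):
        # 200 and 20 across a 10-fold step imply the same concentration
        s = _sample([_reading(200, 1e-1), _reading(20, 1e-2)])
        est = combine_dilutions(s, config=_cfg())
        assert est.censoring == OBSERVED
        assert est.log10_concentration == pytest.approx(math.log10(2e5),
                                                        abs=1e-12)
        assert est.conflicts == ()

    @given(k=st.integers(min_value=2, max_value=4))
    @settings(max_examples=10, deadline=None)
    def test_scale_equivariance(self, k):
        base = [_reading(30, 1e-1), _reading(40, 1e-2)]
        scaled = [_reading(30 * k, 1e-1), _reading(40 * k, 1e-2)]
        a = combine_dilutions(_sample(base), _cfg()).log10_concentration
        b = combine_dilutions(_sample(scaled), _cfg()).log10_concentration
        assert b - a == pytest.approx(math.log10(k), abs=1e-12)

    def test_mixed_methods_rejected(self):
        with pytest.raises(DilutionError, match="mixes"):
            _sample([
                DilutionReading(1e-1, 1.0, 30, method="membrane_filtration"),
                DilutionReading(1e-2, 1.0, 5, method="mpn_tray"),
            ])


class TestCsvIngestion:
    CSV = (
        "sample_id,sample_type,neighborhood,method,dilution_factor,"
        "amount_assayed,count\n"
        "dw-1,drinking_water,site-a,membrane_filtration,1,100,35\n"
        "dw-1,drinking_water,site-a,membrane_filtration,1,10,4\n"
        "dr-1,drain_water,site-a,membrane_filtration,0.001,1,TNTC\n"
        "dr-1,drain_water,site-a,membrane_filtration,0.0001,1,85\n"
    )

    def test_rows_grouped_into_samples(self, tmp_path, config):
        path = tmp_path / "samples.csv"
        path.write_text(self.CSV)
        samples = parse_samples_csv(path, config)
        assert {s.sample_id for s in samples} == {"dw-1", "dr-1"}
        dr = next(s for s in samples if s.sample_id == "dr-1")
        assert dr.readings[0].is_tntc
        assert dr.denominator_unit == "per_100mL"

    def test_every_sample_gets_one_estimate_with_status(self, tmp_path,
                                                        config):
        path = tmp_path / "samples.csv"
        path.write_text(self.CSV)
        samples = parse_samples_csv(path, config)
        ests = estimate_concentrations(samples, config)
        assert len(ests) == len(samples)
        assert all(e.censoring in (OBSERVED, LEFT_CENSORED, RIGHT_CENSORED)
                   for e in ests)

    def test_missing_column_fatal(self, tmp_path, config):
        path = tmp_path / "samples.csv"
        path.write_text("sample_id,sample_type,count\nx,drain_water,5\n")
        with pytest.raises(SampleFormatError, match="neighborhood"):
            parse_samples_csv(path, config)

    def test_unknown_sample_type_fatal(self, tmp_path, config):
        path = tmp_path / "samples.csv"
        path.write_text(self.CSV.replace("drain_water", "lagoon_water"))
        with pytest.raises(SampleFormatError, match="lagoon_water"):
            parse_samples_csv(path, config)


def _cfg():
    from sanipath import default_config
    return default_config()
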