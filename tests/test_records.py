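"""Data model, CSV round-trips, salt reference table and the packaged dataset."""

import math

import pytest

from sorptherm import (
    IsothermSeries,
    Mode,
    SorptionRecord,
    ValidationError,
    compute_emc,
    load_sorption_csv,
    salt_water_activity,
    write_sorption_csv,
)
from sorptherm.datasets import CULTIVARS


class TestComputeEmc:
    @pytest.mark.parametrize(
        "wet,dry,expected",
        [(2.0, 1.0, 1.0), (1.0, 1.0, 0.0), (8.72, 4.36, 1.0)],
    )
    def test_values(self, wet, dry, expected):
        assert compute_emc(wet, dry) == pytest.approx(expected)

    def test_nonpositive_dry_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_emc(1.0, 0.0)

    def test_negative_moisture_rejected(self):
        with pytest.raises(ValidationError):
            compute_emc(0.9, 1.0)


class TestSaltReference:
    @pytest.mark.parametrize(
        "salt,temp,aw",
        [("KOH", 30, 0.0738), ("BaCl2.2H2O", 50, 0.8823), ("KCl", 40, 0.8232)],
    )
    def test_exact_lookup(self, salt, temp, aw):
        assert salt_water_activity(salt, temp) == pytest.approx(aw)

    def test_linear_interpolation_midpoint(self):
        # midpoint of the 30 and 40 degC tabulated values
        assert salt_water_activity("KOH", 35) == pytest.approx((0.0738 + 0.0626) / 2)

    def test_unknown_salt(self):
        with pytest.raises(KeyError):
            salt_water_activity("NaCl", 30)

    def test_temperature_out_of_range(self):
        with pytest.raises(ValueError):
            salt_water_activity("KOH", 25)

    def test_aw_decreases_with_temperature_for_every_salt(self):
        from sorptherm.records import SALT_WATER_ACTIVITY, _load_salt_table

        table = _load_salt_table()
        for salt, by_temp in table.items():
            temps = sorted(by_temp)
            vals = [by_temp[t] for t in temps]
            assert all(b <= a for a, b in zip(vals, vals[1:])), salt


class TestValidation:
    def test_aw_out_of_unit_interval(self):
        with pytest.raises(ValidationError):
            SorptionRecord("x", Mode.DESORPTION, 30, 1.2, 5.0)

    def test_negative_moisture(self):
        with pytest.raises(ValidationError):
            SorptionRecord("x", Mode.DESORPTION, 30, 0.5, -1.0)

    def test_series_requires_strictly_increasing_aw(self):
        recs = [
            SorptionRecord("x", Mode.DESORPTION, 30, a, 5.0) for a in (0.3, 0.3)
        ]
        with pytest.raises(ValidationError):
            IsothermSeries("x", Mode.DESORPTION, 30, tuple(recs))

    def test_series_rejects_foreign_record(self):
        rec = SorptionRecord("y", Mode.DESORPTION, 30, 0.5, 5.0)
        with pytest.raises(ValidationError):
            IsothermSeries("x", Mode.DESORPTION, 30, (rec,))


class TestCsvIO:
    def test_round_trip_field_for_field(self, cherry, tmp_path):
        out = tmp_path / "rt.csv"
        write_sorption_csv(cherry, out)
        again = load_sorption_csv(out)
        assert [s.key for s in again] == [s.key for s in cherry]
        for a, b in zip(again, cherry):
            assert a.records == b.records

    def test_empty_file_returns_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("sample_id,mode,temperature_c,aw,xeq_percent_db\n")
        assert load_sorption_csv(p) == []

    def test_malformed_row_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,mode,temperature_c,aw,xeq_percent_db\n"
            "a,desorption,30,0.5,10\n"
            "a,desorption,30,oops,12\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            load_sorption_csv(p)

    def test_duplicate_design_point_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "sample_id,mode,temperature_c,aw,xeq_percent_db\n"
            "a,desorption,30,0.5,10\n"
            "a,desorption,30,0.5,11\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_sorption_csv(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("sample_id,mode\n")
        with pytest.raises(ValidationError, match="missing column"):
            load_sorption_csv(p)


class TestCherryFixture:
    def test_shape(self, cherry):
        assert len(cherry) == 30
        assert sum(len(s) for s in cherry) == 180
        assert all(len(s) == 6 for s in cherry)
        assert {s.sample_id for s in cherry} == set(CULTIVARS)
        assert {s.temperature_c for s in cherry} == {30.0, 40.0, 50.0}

    @pytest.mark.parametrize(
        "key,aw,xeq",
        [
            (("Burlat", Mode.DESORPTION, 30.0), 0.0738, 14.47),
            (("Burlat", Mode.DESORPTION, 30.0), 0.898, 92.88),
            (("Napoleon", Mode.ADSORPTION, 30.0), 0.898, 71.93),
            (("Van", Mode.ADSORPTION, 40.0), 0.8910, 42.59),
            (("Coeur pigeon", Mode.DESORPTION, 50.0), 0.0572, 8.01),
            (("Cerisette", Mode.ADSORPTION, 50.0), 0.8823, 67.01),
        ],
    )
    def test_spot_cells(self, cherry_by_key, key, aw, xeq):
        series = cherry_by_key[key]
        by_aw = {r.aw: r.xeq for r in series.records}
        assert by_aw[aw] == pytest.approx(xeq)

    def test_each_series_uses_the_salt_design_points(self, cherry):
        for s in cherry:
            assert len(s) == 6
            assert all(0 < a < 1 for a in s.aw)
            assert all(math.isfinite(x) and x > 0 for x in s.xeq)
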