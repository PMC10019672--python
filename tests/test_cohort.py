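"""Record validation, CSV round-trips and design-row encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growthcustom as gc
from growthcustom.cohort import (
    DEFAULT_CONVENTION,
    PHYSIOLOGIC_COLUMNS,
    CenteringConvention,
    SchemaError,
    build_design_row,
    center_covariates,
    design_matrix,
    read_cohort,
    write_cohort,
)

HEADER = ("maternal_height,maternal_weight_prepreg,parity,race,infant_sex,"
          "ga_delivery,birthweight")
ROW = "163,64,0,NH-White,male,280,3500"


def _write(tmp_path, lines, name="cohort.csv"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadCohort:
    def test_valid_rows_all_kept(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW,
                                 "170,80,1,Hispanic,female,270,3100",
                                 "155,55,2,Asian/PI,male,285,3900"])
        result = read_cohort(path)
        assert result.n == 3
        assert result.exclusions == []
        assert result.records[1].race == "Hispanic"
        assert result.records[2].parity == 2

    def test_invariant_violation_cites_row(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW,
                                 "163,64,0,NH-White,male,280,-10",
                                 "155,55,2,Asian/PI,male,285,3900"])
        result = read_cohort(path)
        assert result.n == 2
        (idx, msg), = result.exclusions
        assert idx == 2
        assert "birthweight" in msg

    def test_missing_required_column_is_schema_error(self, tmp_path):
        path = _write(tmp_path, ["maternal_height,parity", "163,0"])
        with pytest.raises(SchemaError, match="birthweight|maternal_weight"):
            read_cohort(path)

    def test_bad_categorical_token_names_offender(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW.replace("NH-White", "Martian")])
        result = read_cohort(path)
        assert result.n == 0
        assert "Martian" in result.exclusions[0][1]

    def test_ga_window_filter_configurable(self, tmp_path):
        path = _write(tmp_path, [HEADER, ROW.replace("280", "250")])
        assert read_cohort(path).n == 0                     # outside 37-41 wk
        assert read_cohort(path, ga_range=(168, 301)).n == 1

    def test_missing_pathologic_flag_warns_not_excludes(self, tmp_path):
        path = _write(tmp_path, [HEADER + ",smoking", ROW + ","])
        result = read_cohort(path)
        assert result.n == 1
        assert not result.records[0].smoking
        assert any("smoking" in msg for _, msg in result.warnings)

    def test_synthetic_roundtrip_field_for_field(self, tmp_path):
        records = gc.generate_cohort(gc.SyntheticConfig(n=50, seed=3))
        gc.generate_morbidity(records, gc.SyntheticConfig(n=50, seed=3))
        path = tmp_path / "rt.csv"
        write_cohort(records, path)
        back = read_cohort(path).records
        assert len(back) == len(records)
        for a, b in zip(records, back):
            for f in ("maternal_height", "maternal_weight_prepreg", "parity",
                      "race", "infant_sex", "ga_delivery", "birthweight",
                      "smoking", "gestational_diabetes", "antepartum_bleeding",
                      "morbidity_sga", "morbidity_lga"):
                assert getattr(a, f) == getattr(b, f), f

    def test_reread_is_byte_identical(self, tmp_path):
        records = gc.generate_cohort(gc.SyntheticConfig(n=30, seed=5))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(records, p1)
        write_cohort(read_cohort(p1).records, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCentering:
    @pytest.mark.parametrize("weight,expected", [
        (56.699, -7.301),   # the published worked example's deviation
        (64.0, 0.0),
        (74.8, 10.8),
    ])
    def test_weight_deviation(self, weight, expected):
        rec = gc.PregnancyRecord(163, weight, 0, "NH-White", "male", 280, 3500)
        dev = center_covariates(rec)
        assert dev["weight_dev"] == pytest.approx(expected, abs=1e-9)

    def test_reference_profile_all_zero(self):
        rec = gc.PregnancyRecord(163, 64, 0, "NH-White", "male", 280, 3500)
        dev = center_covariates(rec)
        assert all(v == 0 for v in dev.values())

    def test_weight_reconstructs_to_machine_precision(self):
        conv = DEFAULT_CONVENTION
        for w in np.linspace(41.3, 129.9, 23):
            rec = gc.PregnancyRecord(163, float(w), 0, "NH-White", "male", 280, 3500)
            dev = center_covariates(rec, conv)
            assert dev["weight_dev"] + conv.weight_center == pytest.approx(w, abs=0)

    def test_nonfinite_center_rejected(self):
        with pytest.raises(ValueError):
            CenteringConvention(ga_center=float("nan"))


class TestDesignRow:
    def test_polynomials_are_exact_powers(self):
        row = build_design_row(weight_dev=-7.301)
        assert row["weight"] == -7.301
        assert row["weight2"] == pytest.approx((-7.301) ** 2)
        assert row["weight3"] == pytest.approx((-7.301) ** 3)

    def test_reference_male_profile_sparsity(self):
        row = build_design_row(sex="male")
        nonzero = row[row != 0]
        assert set(nonzero.index) == {"intercept", "sex"}
        assert row["sex"] == 1.0

    def test_parity_two_and_five_collapse(self):
        r2 = build_design_row(parity=2)
        r5 = build_design_row(parity=5)
        assert r2["parity_1"] == r5["parity_1"] == 0.0
        assert r2["parity_2plus"] == r5["parity_2plus"] == 1.0

    def test_unknown_race_rejected(self):
        with pytest.raises(ValueError, match="race"):
            build_design_row(race="Martian")

    def test_pathologic_columns_only_when_flagged(self):
        assert "smoking" not in build_design_row().index
        assert "smoking" in build_design_row(include_pathologic=True).index

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ga=st.floats(-25, 15), h=st.floats(-25, 25), w=st.floats(-25, 60),
           sex=st.sampled_from(["male", "female", "average"]),
           race=st.sampled_from(gc.cohort.RACE_LEVELS),
           parity=st.integers(0, 6))
    def test_encoding_deterministic_and_power_consistent(self, ga, h, w, sex,
                                                         race, parity):
        a = build_design_row(ga, h, w, sex, race, parity)
        b = build_design_row(ga, h, w, sex, race, parity)
        pd.testing.assert_series_equal(a, b)
        for base in ("ga", "height", "weight"):
            assert a[base + "2"] == a[base] ** 2
            assert a[base + "3"] == a[base] ** 3
        assert a["sex"] in (-1.0, 0.0, 1.0)

    def test_sex_codes_balance_in_balanced_cohort(self):
        recs = [gc.PregnancyRecord(163, 64, 0, "NH-White", s, 280, 3500)
                for s in ["male"] * 10 + ["female"] * 10]
        X = design_matrix(recs)
        assert X["sex"].sum() == 0.0

    def test_design_matrix_deterministic(self, small_cohort):
        X1 = design_matrix(small_cohort[:40])
        X2 = design_matrix(small_cohort[:40])
        pd.testing.assert_frame_equal(X1, X2)
        assert list(X1.columns[:len(PHYSIOLOGIC_COLUMNS)]) == list(PHYSIOLOGIC_COLUMNS)
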