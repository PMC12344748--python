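"""Survey IO, group aggregation and transition-dataset assembly."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coverdyn.survey import (COLUMNS, GROUPS, NL_OFFSET, SchemaError, U,
                             ValidationError, aggregate_group_abundance,
                             build_transition_dataset, read_cover_table,
                             validate_cover_table, write_cover_table)
from coverdyn.synth import (WORKED_FIXTURE_EXPECTED,
                            WORKED_FIXTURE_TOTALS_2016)


def _table(rows):
    return pd.DataFrame(rows, columns=list(COLUMNS))


def _csv(df):
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestReadCoverTable:
    def test_empty_table_gives_empty_collection(self):
        df = read_cover_table(_csv(_table([])))
        assert len(df) == 0

    def test_single_row_passthrough(self):
        df = read_cover_table(_csv(_table(
            [(2016, "A", "A1", "drought", "Bromus erectus", "grass", 12.5)])))
        assert len(df) == 1
        assert df.loc[0, "percent_cover"] == 12.5
        assert df.loc[0, "functional_group"] == "grass"

    def test_zero_cover_rejected(self):
        with pytest.raises(ValidationError, match="> 0"):
            read_cover_table(_csv(_table(
                [(2016, "A", "A1", "control", "sp", "grass", 0.0)])))

    def test_cover_above_100_rejected(self):
        with pytest.raises(ValidationError, match="<= 100"):
            validate_cover_table(_table(
                [(2016, "A", "A1", "control", "sp", "grass", 101.0)]))

    def test_missing_column_names_the_column(self):
        df = _table([(2016, "A", "A1", "control", "sp", "grass", 5.0)])
        bad = df.drop(columns=["functional_group"])
        with pytest.raises(SchemaError, match="functional_group"):
            read_cover_table(_csv(bad))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError, match="functional group"):
            validate_cover_table(_table(
                [(2016, "A", "A1", "control", "sp", "shrub", 5.0)]))

    def test_control_labels_merged(self):
        df = read_cover_table(_csv(_table([
            (2016, "A", "A1", "ambient_control", "sp1", "grass", 5.0),
            (2016, "A", "A2", "procedural_control", "sp1", "grass", 4.0),
        ])))
        assert set(df["treatment"]) == {"control"}

    def test_dialect_maps_alternative_headers(self):
        df = _table([(2016, "A", "A1", "control", "sp", "grass", 5.0)])
        df = df.rename(columns={"percent_cover": "abundance"})
        out = read_cover_table(_csv(df), dialect={"abundance":
                                                  "percent_cover"})
        assert out.loc[0, "percent_cover"] == 5.0

    def test_round_trip_identity(self, worked_fixture, tmp_path):
        path = tmp_path / "survey.csv"
        write_cover_table(worked_fixture, path)
        back = read_cover_table(path)
        pd.testing.assert_frame_equal(back, worked_fixture)


class TestAggregation:
    def test_direct_sums_and_zero_group(self):
        df = _table([
            (2016, "A", "A1", "control", "g1", "grass", 10.0),
            (2016, "A", "A1", "control", "g2", "grass", 20.0),
            (2016, "A", "A1", "control", "f1", "forb", 5.0),
        ])
        out = aggregate_group_abundance(validate_cover_table(df))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["N_g"], row["N_l"], row["N_f"]) == (30.0, 0.0, 5.0)

    def test_totals_may_exceed_100(self):
        df = _table([
            (2016, "A", "A1", "control", "g1", "grass", 60.0),
            (2016, "A", "A1", "control", "g2", "grass", 55.0),
        ])
        out = aggregate_group_abundance(validate_cover_table(df))
        assert out.iloc[0]["N_g"] == 115.0

    def test_no_cross_plot_mixing(self):
        df = _table([
            (2016, "A", "A1", "control", "g1", "grass", 10.0),
            (2016, "A", "A2", "control", "g1", "grass", 20.0),
        ])
        out = aggregate_group_abundance(validate_cover_table(df))
        assert len(out) == 2
        assert sorted(out["N_g"]) == [10.0, 20.0]

    def test_worked_fixture_year1_totals(self, worked_fixture):
        out = aggregate_group_abundance(worked_fixture)
        y16 = out[out["year"] == 2016].set_index("plot")
        for plot, exp in WORKED_FIXTURE_TOTALS_2016.items():
            for col, val in exp.items():
                assert y16.loc[plot, col] == val


class TestTransitionDataset:
    @pytest.mark.parametrize("group,treatment",
                             list(WORKED_FIXTURE_EXPECTED))
    def test_worked_fixture_counts(self, worked_fixture, group, treatment):
        ds = build_transition_dataset(worked_fixture, group, treatment)
        exp = WORKED_FIXTURE_EXPECTED[(group, treatment)]
        assert len(ds.persistence) == exp["n_persistence"]
        assert int(ds.persistence["persisted"].sum()) == exp["n_persisted"]
        assert len(ds.expansion) == exp["n_expansion"]
        assert len(ds.colonisation) == exp["n_colonisation"]

    @pytest.mark.parametrize("group,treatment",
                             list(WORKED_FIXTURE_EXPECTED))
    def test_count_conservation(self, worked_fixture, group, treatment):
        """#expansion rows == #persisted rows, always."""
        ds = build_transition_dataset(worked_fixture, group, treatment)
        assert len(ds.expansion) == int(ds.persistence["persisted"].sum())

    def test_persistence_and_expansion_values(self, worked_fixture):
        ds = build_transition_dataset(worked_fixture, "grass", "control")
        g1 = ds.expansion[(ds.expansion["species"] == "g001")
                          & (ds.expansion["year"] == 2016)].iloc[0]
        assert g1["x"] == pytest.approx(math.log(10.0))
        assert g1["y"] == pytest.approx(math.log(15.0))

    def test_extinction_gives_no_expansion_row(self, worked_fixture):
        ds = build_transition_dataset(worked_fixture, "grass", "control")
        dead = ds.persistence[(ds.persistence["species"] == "g002")
                              & (ds.persistence["year"] == 2016)]
        assert dead.iloc[0]["persisted"] == 0
        assert not ((ds.expansion["species"] == "g002")
                    & (ds.expansion["year"] == 2016)).any()

    def test_reappearance_is_fresh_colonisation(self, worked_fixture):
        ds = build_transition_dataset(worked_fixture, "grass", "control")
        col = ds.colonisation
        assert list(col["species"]) == ["g002"]
        assert col.iloc[0]["year"] == 2017  # covariates taken at t

    def test_legume_free_year_offset_is_exactly_minus_one(self,
                                                          worked_fixture):
        """A plot-year with N_l = 0 yields u_l = log(e^-1) = -1 exactly."""
        ds = build_transition_dataset(worked_fixture, "grass", "control")
        pair_2018 = ds.persistence[ds.persistence["year"] == 2018]
        assert (pair_2018["ul"] == -1.0).all()

    def test_sub_percent_cover_clamped_to_floor(self, worked_fixture):
        ds = build_transition_dataset(worked_fixture, "forb", "drought")
        f3 = ds.expansion[(ds.expansion["species"] == "f003")].iloc[0]
        assert f3["x"] == 0.0  # log(0.5) < 0 clamped to L
        assert ds.n_clamped >= 1

    def test_gap_years_form_no_pairs(self):
        df = validate_cover_table(_table([
            (2016, "A", "A1", "control", "g1", "grass", 10.0),
            (2018, "A", "A1", "control", "g1", "grass", 12.0),
        ]))
        ds = build_transition_dataset(df, "grass", "control")
        assert len(ds.persistence) == 0
        assert len(ds.colonisation) == 0

    def test_zero_grass_total_pairs_dropped(self):
        df = validate_cover_table(_table([
            (2016, "A", "A1", "control", "f1", "forb", 10.0),
            (2017, "A", "A1", "control", "f1", "forb", 12.0),
        ]))
        ds = build_transition_dataset(df, "forb", "control")
        assert len(ds.persistence) == 0
        assert ds.n_dropped_zero_total == 1

    def test_unknown_group_or_treatment_raises(self, worked_fixture):
        with pytest.raises(ValueError):
            build_transition_dataset(worked_fixture, "shrub", "control")
        with pytest.raises(ValueError):
            build_transition_dataset(worked_fixture, "grass", "flooded")

    @given(nl=st.one_of(st.just(0.0),
                        st.floats(min_value=0.5, max_value=500.0)))
    @settings(max_examples=50, deadline=None)
    def test_legume_covariate_lower_bound(self, nl):
        """log(N_l + e^-1) >= -1 with equality iff N_l = 0 (covers are
        recorded in 0.5-percent steps, so positive totals are >= 0.5)."""
        val = math.log(nl + NL_OFFSET)
        assert val >= -1.0
        if nl == 0.0:
            assert val == -1.0
        else:
            assert val > -1.0

    def test_every_occurrence_partitioned(self, worked_fixture):
        """Each species-year whose plot has a successor census yields one
        persistence row; each first appearance after a censused year yields
        one colonisation row; nothing else."""
        for (g, tr) in WORKED_FIXTURE_EXPECTED:
            ds = build_transition_dataset(worked_fixture, g, tr)
            sub = worked_fixture[worked_fixture["treatment"] == tr]
            n_pers = n_col = 0
            for (_, plot), pdf in sub.groupby(["block", "plot"]):
                census = set(pdf["year"])
                grp = pdf[pdf["functional_group"] == g]
                present = {(r["year"], r["species"])
                           for _, r in grp.iterrows()}
                for (yr, sp) in present:
                    if yr + 1 in census:
                        n_pers += 1
                    if yr - 1 in census and (yr - 1, sp) not in present:
                        n_col += 1
            assert len(ds.persistence) == n_pers
            assert len(ds.colonisation) == n_col

    def test_csv_export(self, worked_fixture, tmp_path):
        ds = build_transition_dataset(worked_fixture, "grass", "control")
        ds.to_csv(str(tmp_path / "grass_control"))
        back = pd.read_csv(tmp_path / "grass_control_persistence.csv")
        assert len(back) == len(ds.persistence)
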