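import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import patroldetect as pdt
from patroldetect.records import build_design, records_to_frame, frame_to_records


def _toy_frame(n=6):
    return pd.DataFrame(
        {
            "year": [2014, 2015, 2014, 2016, 2015, 2014][:n],
            "region": ["Arica", "Atacama", "Arica", "Atacama", "Arica", "Atacama"][:n],
            "actor": (["Small-scale fisher", "Restaurant"] * 3)[:n],
            "species": ["Anchovy", "Kelp", "Anchovy", "Kelp", "Anchovy", "Kelp"][:n],
            "violation_type": (["Access", "Quota"] * 3)[:n],
            "time_minutes": [0.0, 150.0, 300.0, 90.0, 60.0, 200.0][:n],
            "n_enforcers": [1, 2, 3, 2, 1, 4][:n],
            "outcome": [0, 1, 0, 0, 1, 0][:n],
        }
    )


class TestRecordValidation:
    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            pdt.EnforcementRecord(2014, "Arica", "a", "s", "v", -1.0, 1, 0)
        with pytest.raises(ValueError):
            pdt.EnforcementRecord(2014, "Arica", "a", "s", "v", 10.0, 0, 0)
        with pytest.raises(ValueError):
            pdt.EnforcementRecord(2014, "Arica", "a", "s", "v", 10.0, 1, 2)


class TestReadWrite:
    def test_round_trip_preserves_records(self, tmp_path, small_dataset):
        frame, _ = small_dataset
        frame = frame.head(500)
        path = tmp_path / "records.csv"
        recs = frame_to_records(frame)
        pdt.write_records(recs, path)
        back, scheme, report = pdt.read_records(path)
        assert report["invalid_rows"] == 0
        assert back == recs

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        frame = _toy_frame(4).copy()
        frame.loc[1, "n_enforcers"] = 0
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="dropped 1"):
            recs, _, report = pdt.read_records(path)
        assert len(recs) == 3
        assert report["invalid_rows"] == 1

    def test_missing_column_fatal(self, tmp_path):
        frame = _toy_frame().drop(columns=["actor"])
        path = tmp_path / "missing.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="actor"):
            pdt.read_records(path)

    def test_unknown_category_under_fixed_scheme_dropped(self, tmp_path):
        frame = _toy_frame()
        scheme = pdt.CategoryScheme.from_frame(frame.iloc[:2])
        frame.loc[3, "region"] = "Nowhere"
        path = tmp_path / "fixed.csv"
        frame.to_csv(path, index=False)
        with pytest.warns(UserWarning):
            recs, _, report = pdt.read_records(path, scheme)
        assert report["invalid_rows"] >= 1
        assert all(r.region != "Nowhere" for r in recs)

    def test_scheme_inferred_in_order_of_first_appearance(self, tmp_path):
        path = tmp_path / "t.csv"
        _toy_frame().to_csv(path, index=False)
        _, scheme, _ = pdt.read_records(path)
        assert scheme.region_levels == ["Arica", "Atacama"]
        assert scheme.reference("region") == "Arica"


class TestCollapse:
    def test_conservation_and_relabel(self):
        recs = frame_to_records(_toy_frame())
        scheme = pdt.CategoryScheme.from_frame(_toy_frame())
        out, new_scheme = pdt.collapse_categories(
            recs, scheme, "violation_type", {"Quota": "Access"}
        )
        assert len(out) == len(recs)
        assert all(r.violation_type == "Access" for r in out)
        assert new_scheme.violation_levels == ["Access"]

    def test_empty_mapping_is_identity(self):
        recs = frame_to_records(_toy_frame())
        scheme = pdt.CategoryScheme.from_frame(_toy_frame())
        out, new_scheme = pdt.collapse_categories(recs, scheme, "actor", {})
        assert out == recs
        assert new_scheme.actor_levels == scheme.actor_levels

    def test_merging_two_levels_drops_one(self):
        frame = _toy_frame()
        recs = frame_to_records(frame)
        scheme = pdt.CategoryScheme.from_frame(frame)
        out, new_scheme = pdt.collapse_categories(
            recs, scheme, "actor", {"Restaurant": "Small-scale fisher"}
        )
        assert len(new_scheme.actor_levels) == len(scheme.actor_levels) - 1
        assert len(out) == len(recs)

    def test_unknown_target_fatal_unless_declared(self):
        recs = frame_to_records(_toy_frame())
        scheme = pdt.CategoryScheme.from_frame(_toy_frame())
        with pytest.raises(ValueError, match="allow_new"):
            pdt.collapse_categories(recs, scheme, "actor", {"Restaurant": "Eatery"})
        out, new_scheme = pdt.collapse_categories(
            recs, scheme, "actor", {"Restaurant": "Eatery"}, allow_new=True
        )
        assert "Eatery" in new_scheme.actor_levels


class TestScaling:
    def test_endpoints_and_midpoint(self):
        frame = _toy_frame(3)
        scaled, info = pdt.scale_continuous(frame)
        assert list(scaled["time"]) == [0.0, 0.5, 1.0]
        assert info.time_min == 0.0 and info.time_max == 300.0

    def test_constant_column_fatal_names_column(self):
        frame = _toy_frame()
        frame["n_enforcers"] = 2
        with pytest.raises(ValueError, match="n_enforcers"):
            pdt.scale_continuous(frame)

    def test_held_out_values_clipped_with_warning(self):
        train = _toy_frame()
        _, info = pdt.scale_continuous(train)
        test = _toy_frame()
        test.loc[0, "time_minutes"] = 9999.0
        with pytest.warns(UserWarning, match="clip"):
            scaled, _ = pdt.scale_continuous(test, info)
        assert scaled["time"].max() == 1.0

    def test_stored_info_reproduces_training_design(self):
        frame = _toy_frame()
        scaled1, info = pdt.scale_continuous(frame)
        scaled2, _ = pdt.scale_continuous(frame, info)
        np.testing.assert_allclose(scaled1.to_numpy(), scaled2.to_numpy())

    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=50).filter(lambda v: len(set(v)) > 1))
    def test_scaled_values_span_unit_interval(self, times):
        frame = _toy_frame(2).iloc[np.zeros(len(times), dtype=int)].reset_index(drop=True)
        frame["time_minutes"] = times
        frame["n_enforcers"] = np.arange(1, len(times) + 1)
        scaled, _ = pdt.scale_continuous(frame)
        t = scaled["time"].to_numpy()
        assert t.min() == 0.0 and t.max() == 1.0
        assert ((t >= 0) & (t <= 1)).all()
        # affine and order-preserving
        order = np.argsort(times, kind="stable")
        assert (np.diff(t[order]) >= 0).all()


class TestCollinearityScreen:
    def test_identical_columns_flagged(self):
        x = np.arange(10.0)
        flagged = pdt.collinearity_screen(pd.DataFrame({"a": x, "b": x}))
        assert len(flagged) == 1
        assert flagged[0][2] == pytest.approx(1.0)

    def test_negation_flagged_by_absolute_value(self):
        x = np.arange(10.0)
        flagged = pdt.collinearity_screen(pd.DataFrame({"a": x, "b": -x}))
        assert len(flagged) == 1
        assert abs(flagged[0][2]) == pytest.approx(1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        assert pdt.collinearity_screen(df) == []
        # brute-force r really is near zero
        assert abs(np.corrcoef(df["a"], df["b"])[0, 1]) < 0.05

    def test_zero_variance_column_excluded_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            flagged = pdt.collinearity_screen(pd.DataFrame({"a": x, "c": np.ones(10), "b": x}))
        assert flagged == [("a", "b", pytest.approx(1.0))]


class TestDesign:
    def test_unknown_level_fatal(self, small_config):
        frame = _toy_frame()
        with pytest.raises(ValueError, match="unknown level"):
            build_design(frame, small_config.scheme)

    def test_reference_levels_carry_no_column(self, small_config, small_dataset):
        frame, _ = small_dataset
        design = build_design(frame, small_config.scheme)
        ref_names = {f"region[{small_config.scheme.reference('region')}]",
                     f"species[{small_config.scheme.reference('species')}]"}
        assert not ref_names & set(design.param_names)
        # one column per non-reference level plus the two continuous terms
        sch = small_config.scheme
        expected_det = 2 + (len(sch.region_levels) - 1) + (len(sch.actor_levels) - 1) + (
            len(sch.year_levels) - 1)
        assert len(design.det_names) == expected_det
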