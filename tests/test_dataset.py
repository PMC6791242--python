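import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipusopt as lo
from lipusopt.dataset import (
    CONTROL,
    GridFormatError,
    GroupSummary,
    ReplicateRecord,
    ResponseGrid,
    StimulationCondition,
    aggregate_replicates,
    load_acoustic_intensity,
    load_verification_groups,
    normalize_to_control,
    read_grid,
    write_grid,
    write_replicates,
)


class TestStimulationCondition:
    def test_hashable_and_orderable(self):
        a = StimulationCondition(6.0, 1.0, 9.0)
        b = StimulationCondition(6.0, 1.0, 9.0)
        assert a == b and hash(a) == hash(b)
        assert StimulationCondition(5.0, 1.0, 9.0) < a

    @pytest.mark.parametrize(
        "v,f,d",
        [(0.0, 1.0, 9.0), (6.0, 1.0, 0.0), (6.0, -0.5, 9.0), (math.nan, 1.0, 9.0)],
    )
    def test_invalid_treated_conditions_rejected(self, v, f, d):
        with pytest.raises(ValueError):
            StimulationCondition(v, f, d)

    def test_zero_frequency_encodes_control(self):
        assert CONTROL.is_control
        assert not StimulationCondition(6.0, 1.0, 9.0).is_control


class TestStudyFixture:
    def test_complete_factorial_with_stated_levels(self, study_grid):
        assert len(study_grid) == 48
        assert study_grid.is_complete_factorial
        assert study_grid.levels == (
            (5.0, 6.0, 7.0, 8.0),
            (0.6, 0.8, 1.0, 1.2),
            (3.0, 6.0, 9.0),
        )

    @pytest.mark.parametrize(
        "condition,mean,sd",
        [
            ((6.0, 1.0, 9.0), 119.57, 3.85),
            ((5.0, 1.0, 3.0), 105.17, 7.17),
            ((8.0, 1.2, 6.0), 102.77, 16.21),
        ],
    )
    def test_transcribed_cells(self, study_grid, condition, mean, sd):
        cell = study_grid[StimulationCondition(*condition)]
        assert cell.mean_viability == mean
        assert cell.sd_viability == sd
        assert cell.n_replicates == 20

    def test_control_row_stored_separately(self, study_grid):
        assert study_grid.control is not None
        assert study_grid.control.mean_viability == 100
        assert study_grid.control.condition.is_control

    def test_companion_fixtures_load(self):
        ver = load_verification_groups()
        assert list(ver["group"]) == ["control", "lipus_treated", "lipus_treated_ga_bpnn"]
        assert ver.set_index("group").loc["lipus_treated_ga_bpnn", "mean_pct"] == 124.93
        intensity = load_acoustic_intensity()
        assert len(intensity) == 16
        assert intensity["intensity_mw_cm2"].max() == 69.3


class TestCsvIO:
    def test_summary_round_trip_bit_identical(self, study_grid, tmp_path):
        path = tmp_path / "grid.csv"
        write_grid(study_grid, path)
        again = read_grid(path)
        assert again == study_grid

    def test_replicate_dialect_aggregates_with_sample_sd(self, tmp_path):
        path = tmp_path / "rep.csv"
        cond = StimulationCondition(6.0, 1.0, 9.0)
        write_replicates([ReplicateRecord(cond, 110.0), ReplicateRecord(cond, 120.0)], path)
        grid = read_grid(path, dialect="replicate")
        cell = grid[cond]
        assert cell.mean_viability == 115.0
        assert cell.sd_viability == pytest.approx(7.0711, abs=1e-4)
        assert cell.n_replicates == 2

    def test_zero_variance_replicates(self, tmp_path):
        path = tmp_path / "rep.csv"
        cond = StimulationCondition(5.0, 0.8, 3.0)
        write_replicates([ReplicateRecord(cond, 100.0)] * 3, path)
        cell = read_grid(path, dialect="replicate")[cond]
        assert (cell.mean_viability, cell.sd_viability, cell.n_replicates) == (100.0, 0.0, 3)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct\n5,1,3,100,1\n")
        with pytest.raises(GridFormatError, match="'n'"):
            read_grid(path)

    def test_extra_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct,n,extra\n5,1,3,100,1,20,x\n"
        )
        with pytest.raises(GridFormatError, match="extra"):
            read_grid(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct,n\n"
            "5,1,3,100,1,20\n5,1,6,oops,1,20\n"
        )
        with pytest.raises(GridFormatError, match="row 3"):
            read_grid(path)

    def test_duplicate_condition_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct,n\n"
            "5,1,3,100,1,20\n5,1,3,101,1,20\n"
        )
        with pytest.raises((GridFormatError, ValueError), match="duplicate"):
            read_grid(path)


class TestAggregation:
    @given(
        st.lists(st.floats(min_value=50, max_value=200), min_size=2, max_size=30),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_aggregate_matches_direct_computation(self, values):
        cond = StimulationCondition(6.0, 1.0, 9.0)
        [summary] = aggregate_replicates([ReplicateRecord(cond, v) for v in values])
        arr = np.asarray(values)
        assert summary.mean_viability == pytest.approx(arr.mean(), rel=1e-9)
        assert summary.sd_viability == pytest.approx(arr.std(ddof=1), rel=1e-9, abs=1e-9)
        assert summary.n_replicates == len(values)


class TestNormalizeToControl:
    def _records(self, control_vals, treated_vals):
        out = [ReplicateRecord(CONTROL, v) for v in control_vals]
        cond = StimulationCondition(6.0, 1.0, 9.0)
        out += [ReplicateRecord(cond, v) for v in treated_vals]
        return out

    def test_ratio_definition(self):
        normalized = normalize_to_control(self._records([0.5], [0.6]))
        assert normalized[1].viability == pytest.approx(120.0)

    def test_uneven_control_mean(self):
        normalized = normalize_to_control(self._records([0.4, 0.6], [0.55]))
        assert normalized[2].viability == pytest.approx(110.0)

    def test_all_equal_maps_to_100(self):
        normalized = normalize_to_control(self._records([0.7, 0.7], [0.7, 0.7]))
        assert all(r.viability == pytest.approx(100.0) for r in normalized)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=2.0), min_size=2, max_size=10),
        st.lists(st.floats(min_value=0.1, max_value=2.0), min_size=1, max_size=10),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_idempotent(self, control_vals, treated_vals):
        once = normalize_to_control(self._records(control_vals, treated_vals))
        twice = normalize_to_control(once)
        for a, b in zip(once, twice):
            assert b.viability == pytest.approx(a.viability, rel=1e-12)

    def test_absent_control_errors(self):
        cond = StimulationCondition(6.0, 1.0, 9.0)
        with pytest.raises(ValueError, match="control"):
            normalize_to_control([ReplicateRecord(cond, 1.0)])


class TestResponseGrid:
    def test_duplicate_conditions_rejected(self):
        s = GroupSummary(StimulationCondition(5.0, 1.0, 3.0), 100.0, 1.0, 20)
        with pytest.raises(ValueError, match="duplicate"):
            ResponseGrid([s, s])

    def test_control_mean_must_be_100(self):
        with pytest.raises(ValueError, match="100"):
            ResponseGrid([], control=GroupSummary(CONTROL, 101.0, 0.0, 20))

    def test_training_arrays_exclude_control_by_default(self, study_grid):
        X, y = study_grid.training_arrays()
        assert X.shape == (48, 3) and y.shape == (48,)
        Xc, yc = study_grid.training_arrays(include_control=True)
        assert Xc.shape == (49, 3) and yc[0] == 100.0
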