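"""Synthetic input generation and the microsimulation oracle."""

import dataclasses
from pathlib import Path

import numpy as np
import pytest

import sahcea as s
from sahcea.fixtures import (
    GompertzSpec,
    default_life_table,
    default_outcome_matrix,
    default_rebleed_schedule,
    gompertz_life_table,
    load_outcome_matrix,
    microsim_oracle,
    outcome_matrix_to_csv,
    write_fixture_files,
)
from sahcea.model_core import HealthState, run_cohort, short_term_pathway
from sahcea.parameters import LifeTable, RebleedSchedule, load_parameters


class TestGompertz:
    def test_constant_hazard_when_flat(self):
        lt = gompertz_life_table(GompertzSpec(a=0.01, b=0.0, cap=50))
        assert np.all(lt.qx[:-1] == 0.01)

    def test_closure(self):
        lt = default_life_table()
        assert lt.qx[-1] == 1.0

    def test_decade_hazard_ratio(self):
        lt = default_life_table()
        assert lt.qx_at(55) / lt.qx_at(45) == pytest.approx(np.exp(0.95), rel=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GompertzSpec(a=0.0)


class TestRebleedSchedule:
    def test_packaged_default_valid(self):
        rs = default_rebleed_schedule()
        assert rs.years[0] == 1 and len(rs.years) == 10
        assert np.all(np.diff(rs.probs) <= 0)  # front-loaded, declining

    def test_single_year_zero_tail_confines_rebleeding(self, params, immortal_life_table):
        rs = RebleedSchedule(np.array([1]), np.array([0.5]), tail="zero")
        tm = s.TransitionModel(immortal_life_table, rs)
        entry = s.EntryProfile(0.0, np.array([1.0, 0.0, 0.0, 0.0]))
        trace = run_cohort(entry, tm, params, start_age=0, stop_age=40)
        at_risk = trace.occupancy[:, HealthState.AT_RISK]
        assert at_risk[0] == pytest.approx(0.5)
        assert np.all(at_risk[:-1] == 0.5)  # nobody leaves AT_RISK afterwards

    def test_all_zero_schedule_exits_only_by_background_death(self, params, tm):
        rs = RebleedSchedule(np.array([1]), np.array([0.0]))
        tm0 = s.TransitionModel(tm.life_table, rs)
        entry = s.EntryProfile(0.0, np.array([1.0, 0.0, 0.0, 0.0]))
        trace = run_cohort(entry, tm0, params)
        occ = trace.occupancy
        assert np.all(occ[:, HealthState.FAVORABLE] == 0.0)
        assert np.all(occ[:, HealthState.UNFAVORABLE] == 0.0)


class TestTransitionFixture:
    def test_default_mode_unfavorable_death_share(self, params, tm):
        rows = tm.outcome_rows(params)
        assert rows[1, 2] == pytest.approx(0.7778)
        assert rows[0, 2] == pytest.approx(0.1067)

    def test_identity_matrix_with_no_mortality_preserves_cohort(
        self, params, immortal_life_table, no_rebleed_schedule
    ):
        tm = s.TransitionModel(
            immortal_life_table, no_rebleed_schedule, outcome_matrix=np.eye(3)
        )
        entry = s.EntryProfile(0.0, np.array([0.0, 0.6, 0.4, 0.0]))
        trace = run_cohort(entry, tm, params, start_age=0, stop_age=30)
        # alive until the forced-terminal cycle
        assert trace.occupancy[-2, HealthState.DEAD] == 0.0

    def test_matrix_csv_round_trip(self, tmp_path):
        m = np.array([[0.90, 0.05, 0.05], [0.0, 0.8845, 0.1155], [0.0, 0.0, 1.0]])
        path = outcome_matrix_to_csv(m, tmp_path / "t.csv", header="source: fixture")
        np.testing.assert_allclose(load_outcome_matrix(path), m)

    def test_bad_row_sum_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("from,to,prob\nfavorable,dead,0.5\nunfavorable,dead,1.0\ndead,dead,1.0\n")
        with pytest.raises(ValueError, match="favorable"):
            load_outcome_matrix(path)


class TestMicrosimOracle:
    def test_everyone_dead_at_entry_is_exactly_zero(self, params, tm):
        p = dataclasses.replace(
            params,
            prevalence_aneurysm=0.0,
            outcome_no_aneurysm_favorable=0.0,
            outcome_no_aneurysm_unfavorable=0.0,
        )
        res = microsim_oracle("no_repeat", p, tm, 500, seed=1)
        assert res.expected_cost == 0.0 and res.expected_qaly == 0.0

    def test_degenerate_geometric_model_within_3se(
        self, params, immortal_life_table, no_rebleed_schedule
    ):
        # no aneurysm, every survivor favorable, constant death risk:
        # QALYs follow a geometric series
        p_die = 0.2
        p = dataclasses.replace(
            params,
            prevalence_aneurysm=0.0,
            outcome_no_aneurysm_favorable=1.0,
            outcome_no_aneurysm_unfavorable=0.0,
            state_mortality=(p_die, 0.5, 0.5 - p_die),
            start_age=0,
            stop_age=60,
        )
        tm = s.TransitionModel(immortal_life_table, no_rebleed_schedule)
        res = microsim_oracle("no_repeat", p, tm, 20_000, seed=2)
        rho = (1 - p_die) / 1.035
        expected = p.utility_favorable * rho * (1 - rho**59) / (1 - rho)
        assert abs(res.expected_qaly - expected) < 3 * res.se_qaly

    def test_branch_frequencies_match_pathway(self, params, tm):
        res = microsim_oracle("repeat_cta", params, tm, 50_000, seed=3)
        profile = short_term_pathway("repeat_cta", params)
        # upfront mean cost should sit within a few pounds of the
        # deterministic expectation (branch sampling only)
        assert res.expected_cost > profile.upfront_cost * 0.9


class TestWriteFixtureFiles:
    def test_written_files_reload_and_validate(self, tmp_path):
        paths = write_fixture_files(tmp_path)
        assert set(paths) == {"defaults", "life_table", "rebleed_schedule", "transitions"}
        p = load_parameters(paths["defaults"])
        assert s.validate(p) == []
        lt = LifeTable.from_csv(paths["life_table"])
        rs = RebleedSchedule.from_csv(paths["rebleed_schedule"])
        m = load_outcome_matrix(paths["transitions"])
        np.testing.assert_allclose(m, default_outcome_matrix())
        np.testing.assert_array_equal(lt.ages, default_life_table().ages)
        np.testing.assert_allclose(rs.probs, default_rebleed_schedule().probs)

    def test_idempotent(self, tmp_path):
        first = write_fixture_files(tmp_path)
        contents = {k: Path(v).read_bytes() for k, v in first.items()}
        second = write_fixture_files(tmp_path)
        for k, v in second.items():
            assert Path(v).read_bytes() == contents[k]

    def test_packaged_data_matches_generator(self):
        data_dir = Path(s.__file__).parent / "data"
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            fresh = write_fixture_files(d)
            for name, path in fresh.items():
                packaged = data_dir / Path(path).name
                assert packaged.read_bytes() == Path(path).read_bytes(), name

    def test_fixture_files_labelled_synthetic(self, tmp_path):
        paths = write_fixture_files(tmp_path)
        for key in ("life_table", "rebleed_schedule", "transitions"):
            assert "fixture" in Path(paths[key]).read_text().splitlines()[0]
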