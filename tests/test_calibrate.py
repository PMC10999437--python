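"""Two-step field calibration: rate refinement and diapause grid search."""

import numpy as np
import pytest

import philaenus as ph
from philaenus.calibrate import (
    DiapauseGrid,
    calibrate_diapause,
    calibrate_rates,
    survey_objective,
)


@pytest.fixture(scope="module")
def small_grid():
    return DiapauseGrid(
        t_e_values=(5.5, 6.0, 6.5, 7.0, 7.5),
        dd_e_values=(100.0, 110.0, 120.0, 130.0),
    )


class TestDiapauseGrid:
    def test_default_grid_covers_stated_ranges(self):
        g = DiapauseGrid()
        assert g.t_e_values[0] == 3.0 and g.t_e_values[-1] == 10.0
        assert g.dd_e_values[0] == 30.0 and g.dd_e_values[-1] == 130.0
        assert 6.5 in g.t_e_values and 120.0 in g.dd_e_values

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            DiapauseGrid(t_e_values=(1.0, 5.0))
        with pytest.raises(ValueError):
            DiapauseGrid(dd_e_values=(10.0, 120.0))


class TestCalibrateDiapause:
    def test_recovers_generating_pair_on_small_grid(
        self, field_surveys, calibrated, age_dist, small_grid
    ):
        best, surface = calibrate_diapause(
            field_surveys, calibrated, age_dist, small_grid, grid_cells=150
        )
        assert (best.t_e, best.dd_e) == (6.5, 120.0)
        assert surface.objective.min() == pytest.approx(
            surface.loc[(surface.t_e == 6.5) & (surface.dd_e == 120.0), "objective"].iloc[0]
        )

    def test_surface_minimum_bounds_every_entry(
        self, field_surveys, calibrated, age_dist, small_grid
    ):
        best, surface = calibrate_diapause(
            field_surveys[:2], calibrated, age_dist, small_grid, grid_cells=100
        )
        best_obj = surface.loc[
            (surface.t_e == best.t_e) & (surface.dd_e == best.dd_e), "objective"
        ].iloc[0]
        assert (surface.objective >= best_obj - 1e-12).all()

    def test_deterministic_and_order_independent(
        self, field_surveys, calibrated, age_dist, small_grid
    ):
        b1, s1 = calibrate_diapause(field_surveys[:2], calibrated, age_dist, small_grid, grid_cells=100)
        b2, s2 = calibrate_diapause(
            list(reversed(field_surveys[:2])), calibrated, age_dist, small_grid, grid_cells=100
        )
        assert (b1.t_e, b1.dd_e) == (b2.t_e, b2.dd_e)
        np.testing.assert_allclose(
            s1.sort_values(["t_e", "dd_e"]).objective.to_numpy(),
            s2.sort_values(["t_e", "dd_e"]).objective.to_numpy(),
            rtol=1e-12,
        )

    def test_dd_requirement_shifts_onset_monotonically(self, calibrated, age_dist, diapause_params):
        """Larger DD requirements delay the simulated N3 onset."""
        temps = ph.generate_temperature_series(ph.MEDITERRANEAN, days=160)
        onsets = []
        for dd in (30.0, 80.0, 130.0):
            traj = ph.simulate(
                temps, calibrated, ph.DiapauseParams(6.5, dd), age_dist, horizon=160
            )
            onsets.append(traj.emergence_date(4, 1.0))
        assert onsets == sorted(onsets)

    def test_nontermination_scored_not_raised(self, calibrated, age_dist):
        """A cold series never terminating diapause contributes the all-zero
        prediction's objective for every grid pair instead of raising."""
        cold = ph.TemperatureSeries.from_daily(np.full(150, 2.0))
        import pandas as pd
        from philaenus.calibrate import FieldSurvey

        rows = []
        for d in range(64, 149, 7):
            for s, p in (("N3", 10.0), ("N4", 5.0), ("N5", 1.0)):
                rows.append((d, s, p))
        survey = FieldSurvey(
            site="cold",
            year=2017,
            data=pd.DataFrame(rows, columns=["date", "stage", "cumulative_percent"]),
            temps=cold,
        )
        best, surface = calibrate_diapause(
            [survey], calibrated, age_dist,
            DiapauseGrid(t_e_values=(6.5, 7.0), dd_e_values=(30.0, 120.0)),
            grid_cells=100,
        )
        # flat surface: every pair fails to terminate, all equally penalized
        assert surface.objective.nunique() == 1
        # tie-break: smallest dd_e, then smallest t_e
        assert (best.t_e, best.dd_e) == (6.5, 30.0)


class TestCalibrateRates:
    def test_objective_halves_from_chamber_start(self, calibrated, age_dist, diapause_params):
        """Refining the chamber preset against field data generated from the
        field preset cuts the misfit by at least half."""
        surveys = ph.generate_field_survey(
            calibrated, age_dist, diapause_params, n_sites=2, seed=3
        )
        start = ph.load_preset("parameterized")
        fitted, info = calibrate_rates(
            surveys, start, age_dist, diapause_params, grid_cells=100, maxfev_per_stage=40
        )
        assert info["final_objective"] <= 0.5 * info["initial_objective"]

    def test_truth_start_is_stable(self, calibrated, age_dist, diapause_params):
        """Noiseless surveys + truth as start: parameters barely move."""
        surveys = ph.generate_field_survey(
            calibrated, age_dist, diapause_params, n_sites=1, seed=5, noiseless=True
        )
        fitted, info = calibrate_rates(
            surveys, calibrated, age_dist, diapause_params, grid_cells=200, maxfev_per_stage=30
        )
        assert info["final_objective"] <= info["initial_objective"]
        for p_t, p_f in zip(calibrated, fitted):
            assert abs(p_f.t_inf - p_t.t_inf) <= 1.0
            assert abs(p_f.t_sup - p_t.t_sup) <= 1.0

    def test_egg_threshold_moves_down_when_truth_is_lower(self, calibrated, age_dist, diapause_params):
        """With only the egg stage misspecified (6.5 °C start vs 3.0 °C truth),
        refinement lowers the egg threshold, matching the direction of the
        published field calibration."""
        from philaenus.rates import BriereParams, StageParamSet

        surveys = ph.generate_field_survey(
            calibrated, age_dist, diapause_params, n_sites=2, seed=9, noiseless=True
        )
        start = StageParamSet(
            (BriereParams.from_max_rate(0.0373, 6.5, 32.0),) + calibrated.stages[1:]
        )
        fitted, info = calibrate_rates(
            surveys, start, age_dist, diapause_params, grid_cells=100, maxfev_per_stage=60
        )
        assert fitted[0].t_inf < 6.5

    def test_too_few_sampling_dates_rejected(self, field_surveys, calibrated, age_dist, diapause_params):
        import pandas as pd
        from philaenus.calibrate import FieldSurvey

        s = field_surveys[0]
        short = FieldSurvey(
            site=s.site,
            year=s.year,
            data=s.data[s.data.date <= 80].reset_index(drop=True),
            temps=s.temps,
        )
        with pytest.raises(ValueError, match="fewer than 5"):
            calibrate_rates([short], calibrated, age_dist, diapause_params)


def test_survey_objective_zero_on_self(field_surveys, calibrated, age_dist, diapause_params):
    """A survey generated noiselessly from a trajectory scores ~0 against it."""
    surveys = ph.generate_field_survey(
        calibrated, age_dist, diapause_params, n_sites=1, seed=2, noiseless=True
    )
    s = surveys[0]
    traj = ph.simulate(s.temps, calibrated, diapause_params, age_dist, horizon=158)
    assert survey_objective(s, traj) == pytest.approx(0.0, abs=1e-6)
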