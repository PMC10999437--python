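"""Age-transport solver: conservation, characteristics oracle, convergence."""

import numpy as np
import pytest

import philaenus as ph
from philaenus.kolmogorov import (
    AgeDistribution,
    PopulationState,
    cumulative_emergence_at,
    initialize,
    simulate,
    step,
)
from philaenus.temperature import TemperatureSeries


class TestInitialize:
    def test_discrete_mass_is_exactly_n_eggs(self, age_dist):
        state = initialize(100.0, age_dist, grid_cells=200)
        assert state.total_mass == pytest.approx(100.0, abs=1e-12)
        assert np.all(state.density[1:] == 0.0)
        assert state.adult_emerged == 0.0

    def test_flat_distribution_gives_uniform_density(self):
        state = initialize(100.0, AgeDistribution(1.0, 1.0), grid_cells=100)
        np.testing.assert_allclose(state.density[0], 100.0, rtol=1e-12)

    def test_advanced_age_mass_fraction(self, age_dist):
        """~95% of the initial egg mass sits at age >= 0.58 (advanced embryos)."""
        state = initialize(100.0, age_dist, grid_cells=200)
        edges = np.linspace(0, 1, 201)
        mask = edges[:-1] >= 0.58
        frac = state.density[0][mask].sum() / state.density[0].sum()
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            AgeDistribution(0.0, 1.0)

    def test_coarse_grid_rejected(self, age_dist):
        with pytest.raises(ValueError, match="grid_cells"):
            initialize(100.0, age_dist, grid_cells=10)


class TestStep:
    def test_frozen_below_all_thresholds(self, calibrated, age_dist):
        state = initialize(100.0, age_dist, 100)
        out = step(state, 1.0, 0.01, calibrated)
        np.testing.assert_array_equal(out.density, state.density)
        assert out.adult_emerged == 0.0
        assert out.clock == pytest.approx(0.01)

    def test_cfl_violation_reports_admissible_dt(self, calibrated, age_dist):
        state = initialize(100.0, age_dist, 200)
        with pytest.raises(ValueError, match="admissible dt"):
            step(state, 26.7, 1.0, calibrated)

    def test_point_mass_transit_time(self, calibrated):
        """A pulse at x=0 crosses the stage in 1/v(T) days (one-cell error)."""
        cells = 200
        state = initialize(100.0, AgeDistribution(1.0, 1.0), cells)
        dens = np.zeros((6, cells))
        dens[0, 0] = 100.0 * cells  # point mass at x=0
        state = PopulationState(density=dens, adult_emerged=0.0, clock=0.0)
        temp = 18.0
        v = calibrated.rates(temp)[0]
        dt = (1.0 / cells) / calibrated.max_rate
        t, hatched = 0.0, 0.0
        n_steps = 0
        while hatched < 50.0 and n_steps < 10**6:
            state = step(state, temp, dt, calibrated)
            hatched = 100.0 - state.stage_mass()[0]
            t = state.clock
            n_steps += 1
        expected = 1.0 / v
        assert t == pytest.approx(expected, abs=expected * 0.1 + 1.0 / (cells * v))

    def test_mass_conserved_per_step(self, calibrated, age_dist):
        state = initialize(100.0, age_dist, 200)
        dt = (1.0 / 200) / calibrated.max_rate
        for temp in (15.0, 22.0, 28.0, 31.0):
            state = step(state, temp, dt, calibrated)
            assert state.total_mass == pytest.approx(100.0, rel=1e-9)


class TestSimulate:
    def test_mass_conservation_over_150_days(self, calibrated, age_dist, diapause_params):
        """Total individuals (stages + adults) conserved to 1e-6 relative."""
        temps = ph.generate_temperature_series(ph.MEDITERRANEAN, days=150)
        term = ph.diapause_termination_day(temps, diapause_params)
        state = initialize(100.0, age_dist, 200)
        traj = simulate(temps, calibrated, diapause_params, age_dist, horizon=150)
        # mass never exceeds the initial count and the trajectory is consistent
        assert traj.cumulative.max() <= 100.0 * (1 + 1e-6)
        # re-run stepwise and check conservation explicitly
        dt = (1.0 / 200) / calibrated.max_rate
        means = temps.daily_means()
        for day in range(term, 151):
            T = float(means.loc[day])
            n_sub = int(np.ceil(1.0 / dt))
            for _ in range(n_sub):
                state = step(state, T, 1.0 / n_sub, calibrated)
        assert state.total_mass == pytest.approx(100.0, rel=1e-6)

    def test_all_winter_series_gives_no_emergence(self, calibrated, age_dist):
        temps = TemperatureSeries.from_daily(np.full(120, 4.0))
        with pytest.warns(UserWarning, match="diapause never terminated"):
            traj = simulate(temps, calibrated, ph.DiapauseParams(6.5, 120.0), age_dist)
        assert traj.empty
        assert np.all(traj.cumulative == 0.0)

    def test_median_hatch_matches_characteristics(self, calibrated, age_dist, const18_series):
        """At constant T the 50% hatch day equals (1 - median age)/v1."""
        traj = simulate(const18_series, calibrated, None, age_dist, horizon=250)
        v1 = calibrated.rates(18.0)[0]
        expected = (1.0 - age_dist.ppf(0.5)) / v1
        sim = traj.emergence_date(2, 50.0)
        assert sim == pytest.approx(expected, abs=1.5)

    def test_quantiles_match_beta_transform(self, calibrated, age_dist, const18_series):
        """PDE emergence quantiles equal the Beta quantile transform (N1 & N3)."""
        cells = 200
        traj = simulate(const18_series, calibrated, None, age_dist, horizon=250, grid_cells=cells)
        v = calibrated.rates(18.0)
        cell_time = (1.0 / cells) / v[0]  # one grid cell's time-equivalent
        for q in (0.25, 0.5, 0.75, 0.9):
            x0 = age_dist.ppf(1.0 - q)
            t_hatch = (1.0 - x0) / v[0]
            sim = traj.emergence_date(2, q * 100.0)
            assert sim == pytest.approx(t_hatch, abs=max(2 * cell_time, 1.5))
            t_n3 = t_hatch + 1.0 / v[1] + 1.0 / v[2]
            sim3 = traj.emergence_date(4, q * 100.0)
            assert sim3 == pytest.approx(t_n3, abs=max(2 * cell_time, 2.0))

    def test_stage_ordering_of_median_dates(self, calibrated, age_dist, field_surveys):
        traj = simulate(
            field_surveys[0].temps, calibrated, ph.default_diapause(), age_dist, horizon=158
        )
        dates = [traj.emergence_date(s, 50.0) for s in range(2, 8)]
        dates = [d for d in dates if d is not None]
        assert dates == sorted(dates)

    def test_warmer_series_emerges_earlier(self, calibrated, age_dist, diapause_params):
        import dataclasses

        warm_spec = dataclasses.replace(ph.MEDITERRANEAN, mean=18.0)
        cool = ph.generate_temperature_series(ph.MEDITERRANEAN, days=160)
        warm = ph.generate_temperature_series(warm_spec, days=160)
        t_cool = simulate(cool, calibrated, diapause_params, age_dist, horizon=160)
        t_warm = simulate(warm, calibrated, diapause_params, age_dist, horizon=160)
        for s in (2, 4, 6):
            dc, dw = t_cool.emergence_date(s, 50.0), t_warm.emergence_date(s, 50.0)
            assert dw < dc

    def test_grid_refinement_first_order(self, calibrated, age_dist, const18_series):
        """Halving the cell size shrinks the change in the 50% date."""
        dates = []
        for cells in (50, 100, 200):
            traj = simulate(const18_series, calibrated, None, age_dist, horizon=250, grid_cells=cells)
            pct = traj.percent(4)
            dates.append(float(np.interp(50.0, pct, traj.days)))
        change1 = abs(dates[1] - dates[0])
        change2 = abs(dates[2] - dates[1])
        assert change2 < change1


class TestCumulativeEmergenceAt:
    def test_before_termination_is_zero(self, calibrated, age_dist, diapause_params, med_series):
        traj = simulate(med_series, calibrated, diapause_params, age_dist, horizon=200)
        assert cumulative_emergence_at(traj, 2, [10.0, 30.0]).tolist() == [0.0, 0.0]

    def test_completion_reaches_100(self, calibrated, age_dist, const18_series):
        traj = simulate(const18_series, calibrated, None, age_dist, horizon=250)
        assert cumulative_emergence_at(traj, 7, [250.0])[0] == pytest.approx(100.0, abs=0.1)

    def test_interpolation_matches_stored_series(self, calibrated, age_dist, const18_series):
        traj = simulate(const18_series, calibrated, None, age_dist, horizon=250)
        day = 40
        direct = traj.percent(3)[day - 1]
        assert cumulative_emergence_at(traj, 3, [float(day)])[0] == pytest.approx(direct)
        mid = 0.5 * (traj.percent(3)[day - 1] + traj.percent(3)[day])
        assert cumulative_emergence_at(traj, 3, [day + 0.5])[0] == pytest.approx(mid)

    def test_stage_one_rejected(self, calibrated, age_dist, const18_series):
        traj = simulate(const18_series, calibrated, None, age_dist, horizon=100)
        with pytest.raises(ValueError, match="initial condition"):
            cumulative_emergence_at(traj, 1, [50.0])

    def test_date_past_horizon_rejected(self, calibrated, age_dist, const18_series):
        traj = simulate(const18_series, calibrated, None, age_dist, horizon=100)
        with pytest.raises(ValueError, match="horizon"):
            cumulative_emergence_at(traj, 3, [300.0])
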