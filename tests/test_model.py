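"""Tests of the daily-step internode growth simulator."""

import numpy as np
import pandas as pd
import pytest

from internode import (
    ClimateSeries,
    InternodeState,
    ModelConfig,
    PlantState,
    advance_development,
    appearance_interval,
    elongation_duration,
    elongation_step,
    final_length_light,
    normalized_response,
    simulate,
    temperature_target,
)


def make_internode(length=3.0, target=10.0, duration=4.2, active=True):
    return InternodeState(
        rank=1,
        appearance_day=2,
        length=length,
        par4d=375.0,
        t4d=20.0,
        fav=1.0,
        fil_light=target,
        target_length=target,
        elong_duration=duration,
        active=active,
    )


class TestFinalLengthLight:
    def test_intercept_at_zero_par(self, default_config):
        assert final_length_light(0.0, 0.0, default_config) == pytest.approx(13.4)

    def test_e2_mean_par4d_contribution(self, default_config):
        # at the E2 organ-level mean PAR4d of 383 umol m-2 s-1 the
        # light-determined length contribution is ~8.0 cm
        assert final_length_light(383.0, 0.0, default_config) == pytest.approx(8.038)
        assert round(final_length_light(383.0), 1) == 8.0

    def test_direct_substitution(self, default_config):
        assert final_length_light(375.0, 0.0, default_config) == pytest.approx(8.15)

    def test_floor_clamp_at_high_par(self, default_config):
        # the linear response goes negative above ~957 umol m-2 s-1
        assert final_length_light(1000.0, 0.0, default_config) == default_config.fil_floor

    def test_rfr_term_adds(self, default_config):
        assert final_length_light(375.0, 1.5, default_config) == pytest.approx(9.65)

    def test_negative_par_rejected(self, default_config):
        with pytest.raises(ValueError):
            final_length_light(-1.0, 0.0, default_config)


class TestTemperatureTarget:
    def test_reference_temperature_leaves_target_unchanged(self, default_config):
        assert temperature_target(10.0, 20.0, default_config) == pytest.approx(10.0)

    def test_scales_by_arrhenius_factor(self, default_config):
        expected = normalized_response(21.2) * 10.0
        assert temperature_target(10.0, 21.2, default_config) == pytest.approx(expected)
        assert round(temperature_target(10.0, 21.2, default_config), 1) == 11.2

    def test_insensitive_scenario_ignores_temperature(self, default_config):
        cfg = default_config.as_scenario(False)
        assert temperature_target(10.0, 25.0, cfg) == 10.0


class TestElongationStep:
    def test_half_deficit_per_day(self, default_config):
        node = make_internode(length=3.0, target=10.0)
        assert elongation_step(node, default_config) == pytest.approx(6.5)

    def test_fixed_point_at_target(self, default_config):
        node = make_internode(length=10.0, target=10.0)
        assert elongation_step(node, default_config) == pytest.approx(10.0)

    def test_geometric_approach_closed_form(self, default_config):
        node = make_internode(length=3.0, target=10.0)
        for n in range(1, 8):
            elongation_step(node, default_config)
            assert node.length == pytest.approx(10.0 - 7.0 * 0.5**n)

    def test_never_shrinks(self, default_config):
        node = make_internode(length=9.0, target=5.0)
        assert elongation_step(node, default_config) == 9.0

    def test_inactive_is_noop(self, default_config):
        node = make_internode(length=6.0, active=False)
        assert elongation_step(node, default_config) == 6.0
        assert node.length == 6.0


class TestDurations:
    def test_reference_elongation_duration(self, default_config):
        assert elongation_duration(20.0, default_config) == pytest.approx(4.2)

    def test_duration_shortens_with_temperature(self, default_config):
        d = elongation_duration(21.2, default_config)
        assert d == pytest.approx(4.2 / normalized_response(21.2))
        assert d == pytest.approx(3.76, abs=0.01)

    def test_duration_factor_product_conserved(self, default_config):
        for t in np.arange(10.0, 30.01, 0.5):
            prod = elongation_duration(t, default_config) * normalized_response(t)
            assert prod == pytest.approx(default_config.De20, rel=1e-12)

    def test_insensitive_scenario_duration_constant(self, default_config):
        cfg = default_config.as_scenario(False)
        assert elongation_duration(27.0, cfg) == 4.2

    def test_reference_appearance_interval(self, default_config):
        assert appearance_interval(20.0, default_config) == pytest.approx(1.4)

    def test_appearance_interval_at_ventilation_ceiling(self, default_config):
        # 24 degC is the upper realized greenhouse temperature
        assert round(appearance_interval(24.0, default_config), 1) == 1.0


class TestAdvanceDevelopment:
    def _plant(self, n_nodes, stage, day):
        nodes = [make_internode() for _ in range(n_nodes)]
        for i, n in enumerate(nodes):
            n.rank = i + 1
        return PlantState(stage=stage, internodes=nodes, day=day)

    def _climate(self, n=40, temperature=20.0):
        return ClimateSeries(
            day=np.arange(1, n + 1),
            par=np.full(n, 375.0),
            temperature=np.full(n, temperature),
        )

    def test_fourteen_days_at_reference_gives_ten_appearances(self, default_config):
        plant = self._plant(1, stage=1.0, day=10)
        climate = self._climate()
        created = 0
        for _ in range(14):
            created += len(advance_development(plant, 20.0, default_config, climate))
        assert created == 10  # 14 d / 1.4 d per leaf
        assert len(plant.internodes) == 11

    def test_single_threshold_crossing_single_appearance(self, default_config):
        plant = self._plant(5, stage=5.5, day=15)
        climate = self._climate(temperature=24.0)
        created = advance_development(plant, 24.0, default_config, climate)
        assert len(created) == 1
        assert created[0].rank == 6
        assert created[0].appearance_day == 15

    def test_multiple_crossings_in_one_day(self, default_config):
        # near the response optimum the daily increment exceeds 1.2 leaves;
        # a double crossing must yield two internodes, not crash
        plant = self._plant(5, stage=5.9, day=15)
        climate = self._climate(temperature=29.0)
        created = advance_development(plant, 29.0, default_config, climate)
        assert len(created) == 2
        assert [n.rank for n in created] == [6, 7]

    def test_insensitive_scenario_fixed_rate(self, default_config):
        cfg = default_config.as_scenario(False)
        plant = self._plant(1, stage=1.0, day=10)
        climate = self._climate(temperature=24.0)
        for _ in range(14):
            advance_development(plant, 24.0, cfg, climate)
        assert len(plant.internodes) == 11  # still 1/1.4 per day

    def test_internode_count_tracks_stage_floor(self, default_config):
        plant = self._plant(1, stage=1.0, day=8)
        climate = self._climate(temperature=22.5)
        for _ in range(12):
            advance_development(plant, 22.5, default_config, climate)
            assert len(plant.internodes) == int(plant.stage + 1e-9)


class TestSimulate:
    def test_constant_climate_final_length_closed_form(self, constant_series, default_config):
        # at 20 degC / PAR 375: target 8.15 cm, duration 4.2 d ->
        # 4 full first-order days then a 0.2-day fractional step:
        # L = 8.15 - (8.15-3) * 0.5**4 * (1 - 0.2*0.5)
        expected = 8.15 - 5.15 * 0.5**4 * 0.9
        res = simulate(constant_series(40), default_config, 30)
        done = res.internodes[~res.internodes["active"]]
        assert len(done) > 5
        assert np.allclose(done["final_cm"], expected)

    def test_start_conditions(self, constant_series, default_config):
        res = simulate(constant_series(10), default_config, 2)
        assert len(res.internodes) == 1
        assert res.internodes.loc[0, "final_cm"] == 3.0
        assert res.plant.stage == 1.0

    def test_sensitive_at_reference_bitwise_equals_insensitive(self, constant_series, default_config):
        s = constant_series(35, par=400.0, temperature=20.0)
        res_t = simulate(s, default_config.as_scenario(True), 30)
        res_20 = simulate(s, default_config.as_scenario(False), 30)
        pd.testing.assert_frame_equal(res_t.trajectory, res_20.trajectory, check_exact=True)
        pd.testing.assert_frame_equal(res_t.internodes, res_20.internodes, check_exact=True)

    def test_lengths_nondecreasing_and_frozen(self, default_config):
        rng = np.random.default_rng(5)
        n = 35
        s = ClimateSeries(
            day=np.arange(1, n + 1),
            par=rng.uniform(200, 700, n),
            temperature=rng.uniform(20, 24, n),
        )
        res = simulate(s, default_config, n)
        for rank, grp in res.trajectory.groupby("rank"):
            lengths = grp.sort_values("day")["length_cm"].to_numpy()
            assert (np.diff(lengths) >= -1e-12).all()
            frozen = grp.sort_values("day").loc[~grp["active"], "length_cm"].to_numpy()
            if len(frozen) > 1:
                assert (frozen == frozen[0]).all()

    def test_count_nondecreasing_and_warm_scenario_ahead(self, constant_series, default_config):
        s = constant_series(40, temperature=22.0)
        res_t = simulate(s, default_config.as_scenario(True), 35)
        res_20 = simulate(s, default_config.as_scenario(False), 35)
        merged = res_t.daily.merge(res_20.daily, on="day", suffixes=("_t", "_20"))
        assert (np.diff(res_t.daily["n_internodes"]) >= 0).all()
        assert (merged["n_internodes_t"] >= merged["n_internodes_20"]).all()

    @pytest.mark.parametrize("temperature", [20.0, 21.5, 23.0, 24.0])
    def test_empirical_appearance_interval_converges(self, constant_series, default_config, temperature):
        n = 105
        s = constant_series(n, temperature=temperature)
        res = simulate(s, default_config, n)
        days = res.internodes["appearance_day"].to_numpy()
        empirical = (days[-1] - days[0]) / (len(days) - 1)
        expected = appearance_interval(temperature, default_config)
        assert abs(empirical - expected) < 0.1  # well inside 1-day discretization

    def test_doubling_k_weakly_increases_frozen_lengths(self, default_config):
        rng = np.random.default_rng(9)
        n = 35
        s = ClimateSeries(
            day=np.arange(1, n + 1),
            par=rng.uniform(200, 700, n),
            temperature=rng.uniform(20, 24, n),
        )
        from dataclasses import replace

        res_a = simulate(s, default_config, n)
        res_b = simulate(s, replace(default_config, k_elong=1.0), n)
        a = res_a.internodes.set_index("rank")
        b = res_b.internodes.set_index("rank")
        common = a.index.intersection(b.index)
        done = common[(~a.loc[common, "active"]) & (~b.loc[common, "active"])]
        assert len(done) > 3
        assert (b.loc[done, "final_cm"] >= a.loc[done, "final_cm"] - 1e-9).all()

    def test_deterministic(self, default_config):
        rng = np.random.default_rng(2)
        n = 30
        s = ClimateSeries(
            day=np.arange(1, n + 1),
            par=rng.uniform(200, 700, n),
            temperature=rng.uniform(20, 24, n),
        )
        r1 = simulate(s, default_config, n)
        r2 = simulate(s, default_config, n)
        pd.testing.assert_frame_equal(r1.trajectory, r2.trajectory, check_exact=True)
        pd.testing.assert_frame_equal(r1.internodes, r2.internodes, check_exact=True)

    def test_short_climate_rejected_before_computation(self, constant_series, default_config):
        with pytest.raises(ValueError, match="steps"):
            simulate(constant_series(10), default_config, 29)

    def test_floor_duration_mode(self, constant_series, default_config):
        from dataclasses import replace

        cfg = replace(default_config, fractional_final_step=False)
        res = simulate(constant_series(40), cfg, 30)
        done = res.internodes[~res.internodes["active"]]
        expected = 8.15 - 5.15 * 0.5**4  # 4 whole days only
        assert np.allclose(done["final_cm"], expected)

    def test_daily_mean_final_uses_min_rank(self, constant_series, default_config):
        res = simulate(constant_series(40), default_config, 30)
        last = res.daily.iloc[-1]
        done = res.internodes[
            (~res.internodes["active"])
            & (res.internodes["rank"] >= default_config.analysis_min_rank)
        ]
        assert last["mean_final_cm"] == pytest.approx(done["final_cm"].mean())
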