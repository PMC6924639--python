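"""Life-table engine: closed forms, independent recomputations, and a
per-individual Monte-Carlo oracle."""

import numpy as np
import pandas as pd
import pytest

from polyscreen import (RiskModel, ScreeningEffects, Strategy, build_schedule,
                        run_cohort)
from polyscreen.lifetable import (RateTable, overdiagnosis_proportion,
                                  ten_year_absolute_risk)

from conftest import make_rates


class TestRateTable:
    def test_csv_round_trip(self, synth_rates, tmp_path):
        path = tmp_path / "rates.csv"
        synth_rates.to_csv(path)
        again = RateTable.from_csv(path)
        pd.testing.assert_frame_equal(synth_rates.frame, again.frame)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            RateTable(pd.DataFrame({"age": [50], "pc_incidence": [0.01]}))

    def test_non_contiguous_ages_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            make_rates([50, 52, 53], 0.01, 0.001, 0.01)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            make_rates([50, 51], [0.01, 1.0], 0.001, 0.01)

    def test_weight_validation(self, synth_rates):
        synth_rates.validate_weights(4_480_000)
        with pytest.raises(ValueError, match="weights"):
            synth_rates.validate_weights(4_800_000)

    def test_lookup_out_of_range(self, toy_rates):
        with pytest.raises(ValueError, match="outside"):
            toy_rates.pc_incidence(50)


class TestTenYearAbsoluteRisk:
    def test_closed_form_no_competing_risk(self):
        # constant hazard 0.003, no mortality: 1 - 0.997^10
        rates = make_rates(range(50, 70), 0.003, 0.0, 0.0)
        assert ten_year_absolute_risk(rates, 55) == \
            pytest.approx(1 - 0.997 ** 10, rel=1e-12)

    def test_window_range_error(self, toy_rates):
        with pytest.raises(ValueError, match="exceeds"):
            ten_year_absolute_risk(toy_rates, 85)

    def test_daily_step_brute_force_oracle(self, synth_rates):
        # continuous-hazard cohort integrated in daily steps; the annual
        # competing-event convention carries a small upward discretisation
        # bias that grows with the mortality level (~1e-4 at 55)
        def oracle(age, steps=365):
            surv, risk = 1.0, 0.0
            for t in range(10):
                a = age + t
                hi = -np.log(1 - synth_rates.pc_incidence(a)) / steps
                hm = -np.log(1 - synth_rates.pc_mortality(a)) / steps
                ho = -np.log(1 - synth_rates.other_mortality(a)) / steps
                for _ in range(steps):
                    risk += surv * hi
                    surv *= (1 - hi) * (1 - hm) * (1 - ho)
            return risk

        for age, tol in ((55, 1.5e-4), (69, 1.1e-3)):
            annual = ten_year_absolute_risk(synth_rates, age)
            brute = oracle(age)
            assert annual == pytest.approx(brute, abs=tol)
            assert abs(annual - brute) / brute < 0.015

    def test_increasing_in_incidence(self, synth_rates):
        bumped = synth_rates.frame.copy()
        bumped["pc_incidence"] *= 1.1
        assert ten_year_absolute_risk(RateTable(bumped), 60) > \
            ten_year_absolute_risk(synth_rates, 60)


class TestOverdiagnosisProportion:
    @pytest.mark.parametrize("age, expected", [
        (55, 0.15),    # -0.62 + 55 * 0.014
        (69, 0.346),   # -0.62 + 69 * 0.014
        (44, 0.0),     # clamped from -0.004
    ])
    def test_age_linear_with_clamp(self, effects, age, expected):
        assert overdiagnosis_proportion(effects, age) == pytest.approx(expected, abs=1e-12)

    def test_presampled_override(self, effects):
        effects.od_by_age = {60: 0.123}
        assert overdiagnosis_proportion(effects, 60) == 0.123


def no_screening_outcome(rates, effects, entry):
    model = RiskModel()
    sched = build_schedule(Strategy(kind="none"), rates, model, entry_age=entry)
    return run_cohort(rates, sched, effects, entry)


class TestRunCohort:
    def test_zero_rates_full_life_years(self, effects):
        rates = make_rates(range(55, 91), 0.0, 0.0, 0.0)
        out = no_screening_outcome(rates, effects, 55)
        assert out.cases == 0
        assert out.pc_deaths == 0
        assert out.life_years == pytest.approx(90 - 55, rel=1e-12)

    def test_no_screening_matches_independent_life_table(self, effects):
        # independent spreadsheet-style recomputation on a 3-age toy table
        rates = make_rates([87, 88, 89], [0.03, 0.035, 0.04],
                           [0.01, 0.012, 0.014], [0.08, 0.09, 0.10])
        out = no_screening_outcome(rates, effects, 87)

        healthy, diagnosed = 1.0, 0.0
        cases = pcd = ly = 0.0
        for a in (87, 88, 89):
            ly += healthy + diagnosed
            new = healthy * rates.pc_incidence(a) * 0.9  # opportunistic adjustment
            cases += new
            healthy -= new
            diagnosed += new
            q = rates.pc_mortality(a)  # population rate, all alive exposed
            pcd += (healthy + diagnosed) * q
            healthy *= 1 - q
            diagnosed *= 1 - q
            m = rates.other_mortality(a)
            healthy *= 1 - m
            diagnosed *= 1 - m
        assert out.life_years == pytest.approx(ly, rel=1e-9)
        assert out.cases == pytest.approx(cases, rel=1e-9)
        assert out.pc_deaths == pytest.approx(pcd, rel=1e-9)

    def test_mortality_benefit_proportional_in_single_cycle(self, toy_rates):
        # one cycle, everyone screened, incidence effects disabled:
        # PC deaths scale exactly by rr_mortality
        model = RiskModel()
        strat = Strategy(kind="age_based", start_age=85, stop_age=89)
        sched = build_schedule(strat, toy_rates, model, entry_age=89)
        base = dict(rr_incidence=1.0, overdiagnosis_intercept=0.0,
                    overdiagnosis_slope=0.0, opportunistic_fraction=0.0)
        screened = run_cohort(toy_rates, sched,
                              ScreeningEffects(rr_mortality=0.79, **base), 89)
        unscreened = run_cohort(toy_rates, sched,
                                ScreeningEffects(rr_mortality=1.0, **base), 89)
        assert screened.pc_deaths == pytest.approx(0.79 * unscreened.pc_deaths, rel=1e-12)

    def test_population_conservation_each_cycle(self, synth_rates, effects, risk_model):
        strat = Strategy(kind="precision", threshold=0.04)
        sched = build_schedule(strat, synth_rates, risk_model, entry_age=55)
        out = run_cohort(synth_rates, sched, effects, 55)
        alive = out.traj["alive_start"]
        deaths = out.traj["pc_deaths"] + out.traj["other_deaths"]
        recomputed = 1.0 - np.concatenate([[0.0], np.cumsum(deaths)[:-1]])
        assert np.allclose(alive, recomputed, atol=1e-9)

    def test_neutral_effects_make_scenarios_identical(self, synth_rates, neutral_effects,
                                                      risk_model):
        outs = {}
        for strat in (Strategy(kind="none"), Strategy(kind="age_based"),
                      Strategy(kind="precision", threshold=0.05)):
            sched = build_schedule(strat, synth_rates, risk_model, entry_age=55)
            outs[strat.kind] = run_cohort(synth_rates, sched, neutral_effects, 55)
        for k in ("age_based", "precision"):
            assert outs[k].cases == pytest.approx(outs["none"].cases, rel=1e-9)
            assert outs[k].pc_deaths == pytest.approx(outs["none"].pc_deaths, rel=1e-9)

    def test_pc_deaths_monotone_in_mortality_rr(self, synth_rates, risk_model):
        strat = Strategy(kind="age_based")
        sched = build_schedule(strat, synth_rates, risk_model, entry_age=55)
        deaths = [run_cohort(synth_rates, sched, ScreeningEffects(rr_mortality=rr), 55).pc_deaths
                  for rr in (0.6, 0.79, 1.0, 1.2)]
        assert np.all(np.diff(deaths) > 0)

    def test_life_years_fall_when_mortality_rises(self, effects):
        rng = np.random.default_rng(7)
        base = make_rates(range(55, 91), 0.004, 0.002, 0.02)
        out0 = no_screening_outcome(base, effects, 55)
        for _ in range(5):
            col = rng.choice(["pc_mortality", "other_mortality"])
            bumped = base.frame.copy()
            bumped[col] *= 1.0 + rng.uniform(0.05, 0.5)
            out1 = no_screening_outcome(RateTable(bumped), effects, 55)
            assert out1.life_years < out0.life_years

    def test_overdiagnosed_bounded_by_cases(self, synth_rates, effects, risk_model):
        strat = Strategy(kind="age_based")
        sched = build_schedule(strat, synth_rates, risk_model, entry_age=55)
        out = run_cohort(synth_rates, sched, effects, 55)
        assert 0 < out.overdiagnosed < out.cases
        for k, v in out.traj.items():
            assert np.all(v >= -1e-12), k

    def test_matches_individual_monte_carlo(self, toy_rates, effects, risk_model):
        # 1e5 simulated men under age-based screening on the toy table
        strat = Strategy(kind="age_based", start_age=85, stop_age=89)
        sched = build_schedule(strat, toy_rates, risk_model, entry_age=85)
        out = run_cohort(toy_rates, sched, effects, 85)

        rng = np.random.default_rng(12345)
        n = 100_000
        healthy = np.ones(n, bool)
        alive = np.ones(n, bool)
        overdx = np.zeros(n, bool)
        cases = pcd = 0
        for a in range(85, 90):
            p_inc = toy_rates.pc_incidence(a) * 0.9 * 1.23
            new = alive & healthy & (rng.random(n) < p_inc)
            cases += new.sum()
            overdx |= new & (rng.random(n) < np.clip(-0.62 + 0.014 * a, 0, 1))
            healthy &= ~new
            q = toy_rates.pc_mortality(a) * 0.79
            die = alive & ~overdx & (rng.random(n) < q)
            pcd += die.sum()
            alive &= ~die
            alive &= ~(alive & (rng.random(n) < toy_rates.other_mortality(a)))
        se_cases = np.sqrt(cases) / n
        se_pcd = np.sqrt(pcd) / n
        assert abs(out.cases - cases / n) < 3 * se_cases
        assert abs(out.pc_deaths - pcd / n) < 3 * se_pcd

    def test_schedule_misalignment_rejected(self, toy_rates, effects, risk_model):
        sched = build_schedule(Strategy(kind="none"), toy_rates, risk_model, entry_age=87)
        with pytest.raises(ValueError, match="cover"):
            run_cohort(toy_rates, sched, effects, 85)
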