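"""Virtual population generation and batch simulation."""

import numpy as np
import pandas as pd
import pytest

import pbpkit as pk
from pbpkit.population import (
    SUMMARY_PARAMETERS,
    age_clearance_factor,
    weight_for_age_sex,
)

CFG = pk.SimulationConfig(t_end_hr=24.0, grid_step_hr=0.25)
DOSE = pk.DoseEvent(0.1)


class TestGeneratePopulation:
    def test_mouse_weights_within_stated_range(self):
        spec = pk.PopulationSpec(species="mouse", n=100, seed=3)
        population = pk.generate_population(spec)
        weights = np.array([ind.body_weight_kg for ind in population])
        assert len(population) == 100
        assert np.all((weights >= 0.012) & (weights <= 0.030))

    def test_same_seed_reproduces_population(self):
        spec = pk.PopulationSpec(species="human", n=25, seed=42)
        a = pk.generate_population(spec)
        b = pk.generate_population(spec)
        assert [x.body_weight_kg for x in a] == [y.body_weight_kg for y in b]
        assert [x.age_yr for x in a] == [y.age_yr for y in b]
        assert [x.sex for x in a] == [y.sex for y in b]

    def test_collapsed_range_returns_reference_physiology(self, mouse_physiology):
        spec = pk.PopulationSpec(
            species="mouse", n=1, weight_range_kg=(0.0275 - 1e-12, 0.0275 + 1e-12), seed=0
        )
        ind = pk.generate_population(spec)[0]
        assert ind.physiology.organs["liver"].volume_ml == pytest.approx(
            mouse_physiology.organs["liver"].volume_ml, rel=1e-9
        )

    def test_human_covariates(self):
        spec = pk.PopulationSpec(species="human", n=30, seed=8)
        population = pk.generate_population(spec)
        ages = np.array([ind.age_yr for ind in population])
        sexes = [ind.sex for ind in population]
        assert np.all((ages >= 20.0) & (ages <= 80.0))
        assert sexes.count("female") == 15  # exactly equal split
        for ind in population:
            assert ind.body_weight_kg == pytest.approx(
                weight_for_age_sex(ind.age_yr, ind.sex)
            )
            assert ind.clearance_scale == pytest.approx(age_clearance_factor(ind.age_yr))

    def test_age_clearance_factor_shape(self):
        assert age_clearance_factor(25.0) == 1.0
        assert age_clearance_factor(45.0) == pytest.approx(0.95)
        assert age_clearance_factor(120.0) == 0.70  # floor

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            pk.PopulationSpec(species="mouse", n=0)
        with pytest.raises(ValueError):
            pk.PopulationSpec(species="mouse", n=5, weight_range_kg=(0.03, 0.01))


class TestSimulatePopulation:
    def test_identical_individuals_have_zero_spread(self, mouse_physiology, at_rvd1, mouse_clearance):
        ind = pk.Individual(
            individual_id="m0", physiology=mouse_physiology, body_weight_kg=0.0275
        )
        clones = [
            pk.Individual(individual_id=f"m{i}", physiology=mouse_physiology, body_weight_kg=0.0275)
            for i in range(3)
        ]
        res = pk.simulate_population(clones, at_rvd1, mouse_clearance, DOSE, CFG)
        assert np.allclose(res.summary.parameters["sd"], 0.0)

    def test_summary_mean_is_arithmetic_mean_of_individuals(self, at_rvd1, mouse_clearance):
        population = pk.generate_population(pk.PopulationSpec(species="mouse", n=6, seed=2))
        res = pk.simulate_population(population, at_rvd1, mouse_clearance, DOSE, CFG)
        assert res.summary.parameters.loc["auc_0_inf_ng_hr_ml", "mean"] == pytest.approx(
            res.nca["auc_0_inf_ng_hr_ml"].mean(), rel=1e-12
        )

    def test_summary_matches_brute_force_recomputation(self, at_rvd1, mouse_clearance):
        population = pk.generate_population(pk.PopulationSpec(species="mouse", n=5, seed=4))
        res = pk.simulate_population(population, at_rvd1, mouse_clearance, DOSE, CFG)
        for param in SUMMARY_PARAMETERS:
            vals = res.nca[param].to_numpy()
            row = res.summary.parameters.loc[param]
            assert row["mean"] == pytest.approx(vals.mean(), rel=1e-12)
            assert row["sd"] == pytest.approx(vals.std(ddof=1), rel=1e-9)
        # concentration bands against a direct groupby
        sub = res.profiles[res.profiles.compartment == "plasma"]
        direct = sub.groupby("time_hr")["conc_ng_per_ml"].median()
        bands = res.summary.concentration_bands
        got = bands[bands.compartment == "plasma"].set_index("time_hr")["p50"]
        assert np.allclose(got.to_numpy(), direct.to_numpy())

    def test_mouse_variability_much_smaller_than_human(self, at_rvd1):
        mouse_cl = pk.ClearanceSpec(mode="calibrated_total", total_plasma_clearance_ml_min_kg=4.58)
        human_cl = pk.ClearanceSpec(mode="calibrated_total", total_plasma_clearance_ml_min_kg=14.02)
        mice = pk.generate_population(pk.PopulationSpec(species="mouse", n=12, seed=5))
        humans = pk.generate_population(pk.PopulationSpec(species="human", n=12, seed=6))
        res_m = pk.simulate_population(mice, at_rvd1, mouse_cl, DOSE, CFG)
        res_h = pk.simulate_population(humans, at_rvd1, human_cl, DOSE, CFG)
        cv = lambda s: s.std() / s.mean()
        cv_mouse = cv(res_m.nca["auc_0_inf_ng_hr_ml"])
        cv_human = cv(res_h.nca["auc_0_inf_ng_hr_ml"])
        # mice vary in weight only (per-kg dosing cancels it); humans carry
        # age- and sex-driven variability on top
        assert cv_mouse < 0.5 * cv_human

    def test_expected_compartments_reported(self, at_rvd1, mouse_clearance):
        population = pk.generate_population(pk.PopulationSpec(species="mouse", n=2, seed=1))
        res = pk.simulate_population(population, at_rvd1, mouse_clearance, DOSE, CFG)
        present = set(res.profiles.compartment.unique())
        assert {"plasma", "saliva", "brain", "heart", "lung", "liver", "kidney", "spleen"} <= present

    def test_empty_population_rejected(self, at_rvd1, mouse_clearance):
        with pytest.raises(ValueError):
            pk.simulate_population([], at_rvd1, mouse_clearance, DOSE, CFG)

    def test_failing_individual_is_isolated(self, mouse_physiology, at_rvd1):
        # clearance feasible for the reference but not for a very small mouse
        tight = pk.ClearanceSpec(mode="calibrated_total", total_plasma_clearance_ml_min_kg=50.0)
        ok = pk.Individual("ok", mouse_physiology, 0.0275)
        tiny = pk.Individual(
            "tiny", pk.scale_physiology(mouse_physiology, 0.004), 0.004, clearance_scale=4.0
        )
        res = pk.simulate_population([ok, tiny], at_rvd1, tight, DOSE, CFG)
        assert res.summary.n_failures == 1
        assert "tiny" in res.failures[0]
        assert res.summary.n_individuals == 1
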