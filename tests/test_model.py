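"""PBPK model assembly, dosing, integration and conservation laws."""

import numpy as np
import pytest

import pbpkit as pk
from pbpkit.model import ModelConfigurationError, UnsupportedRouteError
from pbpkit.synth import reduced_physiology, water_compound


class TestBuildModel:
    def test_every_organ_gets_partition_coefficient(self, mouse_model):
        assert set(mouse_model.k_organ) == set(mouse_model.physiology.organs)
        assert all(v > 0 for v in mouse_model.k_organ.values())

    def test_all_water_organs_have_unit_partition(self):
        phys = reduced_physiology({"a": (5.0, 1.0), "b": (3.0, 2.0)})
        model = pk.build_model(phys, water_compound(), None)
        assert all(v == pytest.approx(1.0) for v in model.k_organ.values())

    def test_mouse_topology_is_fifteen_organs_plus_pools_and_saliva(self, mouse_model):
        # 15 organs + venous + arterial + saliva + eliminated-mass bookkeeping
        assert len(mouse_model.physiology.organs) == 15
        assert mouse_model.state_names[:2] == ("venous", "arterial")
        assert "saliva" in mouse_model.state_names
        assert mouse_model.state_names[-1] == "eliminated"

    def test_calibrated_clearance_is_exact(self, mouse_model, mouse_physiology):
        target = 4.58 * 60.0 * mouse_physiology.body_weight_kg
        assert mouse_model.total_plasma_clearance_ml_hr == pytest.approx(target, rel=1e-12)

    def test_zero_partition_organ_rejected(self):
        phys = reduced_physiology(
            {"a": (5.0, 1.0)}, compositions={"a": (0.0, 0.0, 0.0)}
        )
        with pytest.raises(ModelConfigurationError, match="'a'"):
            pk.build_model(phys, water_compound(), None)

    def test_infeasible_calibrated_clearance_rejected(self, mouse_physiology, at_rvd1):
        huge = pk.ClearanceSpec(mode="calibrated_total", total_plasma_clearance_ml_min_kg=500.0)
        with pytest.raises(ModelConfigurationError, match="exceeds"):
            pk.build_model(mouse_physiology, at_rvd1, huge)

    def test_enzymatic_mode_requires_expressing_organ(self, at_rvd1):
        phys = reduced_physiology({"a": (5.0, 1.0)})
        enz = pk.ClearanceSpec(mode="enzymatic", vmax_ng_min=1.0, km_ng_ml=10.0)
        with pytest.raises(ModelConfigurationError, match="eor_abundance"):
            pk.build_model(phys, at_rvd1, enz, eliminating_organs=("a",))


class TestApplyDose:
    def test_mouse_dose_in_venous_pool(self, mouse_model):
        y0 = pk.apply_dose(mouse_model, pk.DoseEvent(0.1))
        assert y0[0] == pytest.approx(2750.0)  # 100,000 ng/kg x 0.0275 kg
        assert np.all(y0[1:] == 0.0)

    def test_human_dose(self, human_physiology, at_rvd1):
        model = pk.build_model(
            human_physiology, at_rvd1,
            pk.ClearanceSpec(mode="calibrated_total", total_plasma_clearance_ml_min_kg=14.02),
        )
        y0 = pk.apply_dose(model, pk.DoseEvent(0.1))
        assert y0[0] == pytest.approx(8.035e6)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            pk.DoseEvent(0.0)

    def test_non_iv_route_rejected(self):
        with pytest.raises(UnsupportedRouteError):
            pk.DoseEvent(0.1, route="oral")


class TestConservationAndLinearity:
    def test_zero_clearance_conserves_dose_everywhere(self, mouse_physiology, at_rvd1):
        model = pk.build_model(mouse_physiology, at_rvd1, None)
        result = pk.simulate(model, pk.DoseEvent(0.1), pk.SimulationConfig())
        totals = result.amounts_ng.sum(axis=0)
        assert np.max(np.abs(totals - result.dose_ng)) / result.dose_ng < 1e-6
        assert result.eliminated_ng[-1] == pytest.approx(0.0, abs=1e-9)

    def test_nonzero_clearance_mass_balance(self, mouse_model):
        result = pk.simulate(mouse_model, pk.DoseEvent(0.1), pk.SimulationConfig())
        assert result.mass_balance_rel_error() < 1e-6
        assert result.eliminated_ng[-1] > 0

    def test_dose_linearity(self, mouse_model):
        cfg = pk.SimulationConfig(t_end_hr=12.0, grid_step_hr=0.25)
        low = pk.simulate(mouse_model, pk.DoseEvent(0.1), cfg)
        high = pk.simulate(mouse_model, pk.DoseEvent(0.2), cfg)
        for name in ("plasma", "liver", "saliva"):
            c1 = low[name].concentrations_ng_ml[1:]
            c2 = high[name].concentrations_ng_ml[1:]
            assert np.allclose(c2, 2.0 * c1, rtol=1e-6)

    def test_states_nonnegative(self, mouse_model):
        result = pk.simulate(mouse_model, pk.DoseEvent(0.1), pk.SimulationConfig())
        assert result.amounts_ng.min() >= 0.0


class TestOneCompartmentReduction:
    def test_matches_closed_form_within_a_tenth_percent(self, fast_one_compartment, fine_short_grid):
        model, ke, cl = fast_one_compartment
        cfg = pk.SimulationConfig(t_end_hr=10.0, output_grid_hr=fine_short_grid)
        result = pk.simulate(model, pk.DoseEvent(0.1), cfg)
        t = result["plasma"].times_hr
        c = result["plasma"].concentrations_ng_ml
        closed = 0.1e6 / 1000.0 * np.exp(-ke * t)  # Dose/V * exp(-ke t), V = 1000 ml
        mask = t >= 0.1  # after the sub-second venous mixing transient
        assert np.max(np.abs(c[mask] - closed[mask]) / closed[mask]) < 1e-3

    def test_nca_recovers_volume_and_clearance(self, fast_one_compartment, fine_short_grid):
        model, ke, cl = fast_one_compartment
        cfg = pk.SimulationConfig(t_end_hr=10.0, output_grid_hr=fine_short_grid)
        result = pk.simulate(model, pk.DoseEvent(0.1), cfg)
        summary = pk.pk_summary(result["plasma"], 0.1)
        assert summary.cl_ml_min_kg == pytest.approx(cl, rel=5e-3)
        assert summary.vd_l_kg == pytest.approx(1.0, rel=5e-3)


class TestDistributionBehaviour:
    def test_terminal_tissue_plasma_ratio_approaches_k_organ(self):
        # closed system: at equilibrium C_tissue/C_plasma = k_organ exactly
        phys = reduced_physiology(
            {"fatty": (2.0, 5.0), "lean": (10.0, 20.0)},
            compositions={"fatty": (0.2, 0.4, 0.1), "lean": (0.9, 0.02, 0.05)},
        )
        comp = water_compound(fu_plasma=0.5)
        model = pk.build_model(phys, comp, None)
        grid = np.linspace(0.0, 50.0, 200)
        result = pk.simulate(
            model, pk.DoseEvent(0.1), pk.SimulationConfig(t_end_hr=50.0, output_grid_hr=grid)
        )
        c_plasma = result["plasma"].concentrations_ng_ml[-1]
        for organ in ("fatty", "lean"):
            ratio = result[organ].concentrations_ng_ml[-1] / c_plasma
            assert ratio == pytest.approx(model.k_organ[organ], rel=1e-4)

    def test_no_accumulation_without_lipid_or_protein(self):
        # all k_organ = f_water <= 1: tissue never exceeds plasma Cmax
        phys = reduced_physiology(
            {"a": (2.0, 5.0), "b": (4.0, 3.0), "c": (1.0, 1.0)},
            compositions={"a": (0.8, 0.0, 0.0), "b": (1.0, 0.0, 0.0), "c": (0.6, 0.0, 0.0)},
        )
        model = pk.build_model(phys, water_compound(), None)
        result = pk.simulate(model, pk.DoseEvent(0.1), pk.SimulationConfig(t_end_hr=20.0, grid_step_hr=0.05))
        plasma_cmax = result["plasma"].concentrations_ng_ml[1:].max()
        for organ in ("a", "b", "c"):
            assert result[organ].concentrations_ng_ml.max() <= plasma_cmax * (1 + 1e-9)

    def test_saliva_tracks_salivary_gland_plasma(self, mouse_model):
        result = pk.simulate(mouse_model, pk.DoseEvent(0.1), pk.SimulationConfig())
        t = result.times_hr
        mask = t >= 1.0  # past the equilibration lag (k_sal = 10/hr)
        fu = mouse_model.compound.fu_plasma
        gland_plasma = (
            result["salivary_gland"].concentrations_ng_ml[mask]
            / mouse_model.k_organ["salivary_gland"]
        )
        saliva = result["saliva"].concentrations_ng_ml[mask]
        assert np.allclose(saliva, fu * gland_plasma, rtol=0.05)


class TestGridAndConfig:
    def test_default_grid_is_three_minute_steps(self):
        grid = pk.SimulationConfig().grid()
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(24.0)
        assert np.allclose(np.diff(grid), 0.05)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            pk.SimulationConfig(output_grid_hr=np.array([0.0, 1.0, 1.0]))

    def test_time_window_validation(self):
        with pytest.raises(ValueError):
            pk.SimulationConfig(t_start_hr=5.0, t_end_hr=5.0)

    def test_dose_outside_window_rejected(self, mouse_model):
        with pytest.raises(ValueError):
            pk.simulate(mouse_model, pk.DoseEvent(0.1, time_hr=30.0), pk.SimulationConfig())

    def test_quadrature_grid_strictly_increasing(self):
        grid = pk.quadrature_grid(2000.0)
        assert np.all(np.diff(grid) > 0)
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(2000.0)
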