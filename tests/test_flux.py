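"""Term-wise flux decomposition: values, linearity, composition."""

import dataclasses

import numpy as np
import pytest

from memflux import (ConfigError, DrivingForces, compare_membranes,
                     convection_flux, diffusion_flux, electromigration_flux,
                     get_toxin, ph_flux, sweep, total_flux,
                     ultrafiltration_flux)

DEFF = 5.73e-11      # m^2/s
CM = 1.199e-4        # mol/m^3


class TestDiffusionTerm:
    def test_zero_gradient(self):
        assert diffusion_flux(DEFF, 1, 0.58073, 0.0, 1e-6) == 0.0

    def test_reference_value(self):
        assert diffusion_flux(DEFF, 1, 0.58073, CM, 1e-6) == pytest.approx(
            -3.990e-9, rel=1e-3)

    def test_sign_flips_with_gradient(self):
        assert diffusion_flux(DEFF, 1, 0.5, -CM, 1e-6) == \
            -diffusion_flux(DEFF, 1, 0.5, CM, 1e-6)

    def test_no_double_hindrance_mode(self):
        literal = diffusion_flux(DEFF, 1, 0.58073, CM, 1e-6)
        single = diffusion_flux(DEFF, 1, 0.58073, CM, 1e-6,
                                double_hindrance=False)
        assert literal == pytest.approx(0.58073 * single, rel=1e-12)


class TestElectromigrationTerm:
    def test_zero_potential(self):
        assert electromigration_flux(DEFF, 1, CM, 1, 310.15, 0.0, 1e-6) == 0.0

    def test_reference_magnitude(self):
        j = electromigration_flux(DEFF, 1, CM, 1, 310.15, 0.01, 1e-6)
        assert abs(j) == pytest.approx(2.571e-9, rel=1e-3)

    def test_thickness_ratio_of_25(self):
        thin = electromigration_flux(DEFF, 1, CM, None, 310.15, 0.01, 1e-6)
        thick = electromigration_flux(DEFF, 1, CM, None, 310.15, 0.01, 25e-6)
        assert thin / thick == pytest.approx(25.0, rel=1e-14)

    def test_linear_in_potential_and_valence(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            dv, z, k = rng.uniform(0.001, 0.1), rng.uniform(-3, 3), rng.uniform(0.1, 5)
            base = electromigration_flux(DEFF, 1, CM, z, 310.15, dv, 1e-6)
            assert electromigration_flux(DEFF, 1, CM, z, 310.15, k * dv, 1e-6) \
                == pytest.approx(k * base, rel=1e-12)
            assert electromigration_flux(DEFF, 1, CM, k * z, 310.15, dv, 1e-6) \
                == pytest.approx(k * base, rel=1e-12)

    def test_per_valence_when_charge_unknown(self):
        per_z = electromigration_flux(DEFF, 1, CM, None, 310.15, 0.01, 1e-6)
        z1 = electromigration_flux(DEFF, 1, CM, 1.0, 310.15, 0.01, 1e-6)
        assert per_z == pytest.approx(-z1, rel=1e-14)
        assert per_z > 0


class TestPHTerm:
    def test_zero_concentration(self):
        assert ph_flux(DEFF, 1, 0.0, 1e-6, 7.4, 7.4) == 0.0

    def test_reference_value_at_physiological_ph(self):
        # bracket at pH 7.4 on both sides is -38.088
        assert ph_flux(DEFF, 1, CM, 1e-6, 7.4, 7.4) == pytest.approx(
            2.617e-7, rel=1e-3)

    def test_linear_in_concentration(self):
        base = ph_flux(DEFF, 1, CM, 1e-6, 7.4, 7.2)
        assert ph_flux(DEFF, 1, 3 * CM, 1e-6, 7.4, 7.2) == pytest.approx(
            3 * base, rel=1e-12)


class TestConvectionAndUltrafiltration:
    def test_convection(self):
        assert convection_flux(1, 1, CM, 0.0) == 0.0
        assert convection_flux(1, 1, CM, 1e-8) == pytest.approx(
            1.199e-12, rel=1e-3)
        assert convection_flux(2, 3, CM, 1e-8) == pytest.approx(
            6 * convection_flux(1, 1, CM, 1e-8), rel=1e-12)

    def test_ultrafiltration(self):
        assert ultrafiltration_flux(1, 1e-11, 1, 5000, -5000) == 0.0
        assert ultrafiltration_flux(1, 1e-11, 1, 5000, 0) == pytest.approx(5e-8)
        a = ultrafiltration_flux(1, 1e-11, 1, 3000, 0)
        b = ultrafiltration_flux(1, 1e-11, 1, 0, 2000)
        assert ultrafiltration_flux(1, 1e-11, 1, 3000, 2000) == pytest.approx(
            a + b, rel=1e-12)


class TestTotalFlux:
    def test_all_forces_zero(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        b = total_flux(toxin, nanofab, DrivingForces())
        assert b.j_total == 0.0
        assert all(v == 0.0 for v in b.terms.values())

    def test_total_is_exact_sum_of_terms(self, catalog, nanofab):
        toxin = get_toxin("Endothelin", catalog)
        forces = DrivingForces(delta_c=1e-8, delta_V=0.02,
                               pH_blood=7.4, pH_dialysate=7.33)
        b = total_flux(toxin, nanofab, forces)
        assert b.j_total == sum(b.terms.values())

    def test_single_driving_force_isolates_one_term(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        b = total_flux(toxin, nanofab, DrivingForces(delta_V=0.01))
        assert b.j_total == b.j_electromigration
        assert b.j_diffusion == b.j_ph == b.j_convection == 0.0
        assert b.per_valence  # z unset in the builtin panel

    def test_linear_in_concentration(self, catalog, nanofab):
        toxin = get_toxin("Interleukin-6", catalog)
        forces = DrivingForces(delta_V=0.01, pH_blood=7.4, pH_dialysate=7.4)
        b1 = total_flux(toxin, nanofab, forces, c_m=1e-7)
        b3 = total_flux(toxin, nanofab, forces, c_m=3e-7)
        for term in ("j_electromigration", "j_ph", "j_convection"):
            assert getattr(b3, term) == pytest.approx(
                3 * getattr(b1, term), rel=1e-12)

    def test_missing_concentration_is_config_error(self, catalog, nanofab):
        toxin = get_toxin("Retinol-binding protein", catalog)  # no c_normal
        with pytest.raises(ConfigError, match="c_m"):
            total_flux(toxin, nanofab, DrivingForces(delta_V=0.01))

    def test_missing_hydraulic_permeability_is_config_error(
            self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        with pytest.raises(ConfigError, match="L_p"):
            total_flux(toxin, nanofab, DrivingForces(delta_P=5000.0))

    def test_ultrafiltration_with_configured_membrane(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        mem = dataclasses.replace(nanofab, L_p=1e-11, Omega=1.0)
        b = total_flux(toxin, mem, DrivingForces(delta_P=5000.0))
        assert b.j_ultrafiltration == pytest.approx(5e-8)
        assert b.j_total == b.j_ultrafiltration

    def test_provenance_recorded(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        b = total_flux(toxin, nanofab, DrivingForces(delta_V=0.01))
        assert b.inputs["toxin"] == "Cystatin C"
        assert b.inputs["sign_convention"] == "positive = blood to dialysate"
        assert b.F == 96485.0 and b.R == 8.314


class TestSweep:
    def test_potential_sweep_is_proportional(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        grid = [v * 1e-3 for v in range(10, 90, 10)]
        tab = sweep(toxin, nanofab, DrivingForces(), "delta_V", grid)
        assert len(tab.breakdowns) == 8
        j10 = tab.breakdowns[0].j_electromigration
        for v, b in zip(grid, tab.breakdowns):
            assert b.j_electromigration == pytest.approx(
                j10 * v / grid[0], rel=1e-12)

    def test_thickness_sweep_electromigration_ratio(self, catalog, nanofab):
        toxin = get_toxin("Endothelin", catalog)
        tab = sweep(toxin, nanofab, DrivingForces(delta_V=0.01),
                    "x", [25e-6, 1e-6])
        thick, thin = tab.breakdowns
        assert thin.j_electromigration / thick.j_electromigration == \
            pytest.approx(25.0, rel=1e-12)

    def test_singleton_grid_equals_total_flux(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        forces = DrivingForces(delta_V=0.05)
        tab = sweep(toxin, nanofab, forces, "delta_V", [0.05])
        direct = total_flux(toxin, nanofab, forces)
        assert tab.breakdowns[0].j_total == direct.j_total

    def test_ph_sweep_frame_shape(self, catalog, nanofab):
        toxin = get_toxin("Interleukin-6", catalog)
        tab = sweep(toxin, nanofab, DrivingForces(), "pH",
                    [7.0, 7.2, 7.4])
        frame = tab.to_frame()
        assert list(frame["pH"]) == [7.0, 7.2, 7.4]
        assert (frame["J_pH"] != 0).all()

    def test_invalid_grid(self, catalog, nanofab):
        toxin = get_toxin("Cystatin C", catalog)
        with pytest.raises(ConfigError):
            sweep(toxin, nanofab, DrivingForces(), "delta_V", [])
        with pytest.raises(ConfigError):
            sweep(toxin, nanofab, DrivingForces(), "voltage", [1.0])


class TestCompareMembranes:
    def test_reproduces_published_nanopore_column(
            self, catalog, highflux, nanofab, highflux_deff,
            nanofab_deff_published):
        table = compare_membranes(catalog, highflux, nanofab,
                                  d_eff_a=highflux_deff)
        assert len(table) == 3
        for _, row in table.iterrows():
            assert row["d_eff_b_cm2_s"] == pytest.approx(
                nanofab_deff_published[row["toxin"]], rel=0.035)

    def test_identical_membranes_give_unit_ratio(self, catalog, nanofab,
                                                 highflux_deff):
        # hindrance cancels, so the measured values act as plain D0 carriers
        table = compare_membranes(catalog, nanofab, nanofab,
                                  d_eff_a=highflux_deff)
        assert np.allclose(table["ratio_b_over_a"], 1.0)

    def test_endothelin_enhancement_three_orders_of_magnitude(
            self, catalog, highflux, nanofab, highflux_deff):
        table = compare_membranes(catalog, highflux, nanofab,
                                  d_eff_a=highflux_deff)
        ratio = float(table.set_index("toxin")
                      .loc["Endothelin", "ratio_b_over_a"])
        assert ratio == pytest.approx(9.2e2, rel=0.05)

    def test_predicted_route_covers_whole_panel(self, catalog, highflux,
                                                nanofab):
        table = compare_membranes(catalog, highflux, nanofab)
        assert len(table) == 7
        assert (table["d_eff_b_cm2_s"] > table["d_eff_a_cm2_s"]).all()
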