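"""Geometric cross sections, mean free paths, attenuation, and the grid fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ionslab.cross_sections import (DEFAULT_B_GRID, DEFAULT_R0_GRID,
                                    CrossSectionRecord, GeometricParams,
                                    GeometricProvider, MeasuredProvider,
                                    MfpOverrideProvider, attenuation_table,
                                    chi2_fit, filter_records_by_target,
                                    interaction_fraction, mean_free_path,
                                    read_records_csv, sigma_cc,
                                    survival_fraction, write_records_csv)
from ionslab.physics import IonState
from ionslab.synthetic import make_xsec_dataset

NOMINAL = GeometricParams()

#: printed attenuation of high-energy ions in aluminum (rows: ion, cols:
#: depth 5/10/20/40 g cm^-2), r0 = 1.26 fm, b = 0.2
TABLE1 = {
    (6, 12): [0.128, 0.240, 0.423, 0.667],
    (8, 16): [0.141, 0.261, 0.455, 0.702],
    (12, 24): [0.160, 0.295, 0.503, 0.753],
    (14, 28): [0.169, 0.309, 0.522, 0.772],
    (26, 56): [0.213, 0.381, 0.617, 0.853],
}


class TestSigma:
    def test_iron_on_aluminum(self):
        assert sigma_cc(56, 27, NOMINAL) == pytest.approx(2154, abs=1)

    def test_carbon_on_aluminum(self):
        assert sigma_cc(12, 27, NOMINAL) == pytest.approx(1232, abs=1)

    @given(st.integers(min_value=2, max_value=240),
           st.integers(min_value=2, max_value=240))
    @settings(max_examples=50)
    def test_projectile_target_symmetry(self, a, b):
        # symmetric up to float summation order
        assert sigma_cc(a, b, NOMINAL) == pytest.approx(
            sigma_cc(b, a, NOMINAL), rel=1e-14)

    def test_tiny_system_with_large_transparency_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            sigma_cc(1, 1, GeometricParams(1.26, 1.2))

    def test_out_of_band_energy_warns(self):
        with pytest.warns(UserWarning, match="outside the validated"):
            sigma_cc(12, 27, NOMINAL, energy=50.0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GeometricParams(r0=0.5)
        with pytest.raises(ValueError):
            GeometricParams(transparency=1.3)
        # the large measured 4He transparency must be representable
        GeometricParams(1.36, 1.10)


class TestMeanFreePath:
    def test_iron_in_aluminum(self, aluminum):
        lam = mean_free_path(IonState(26, 56, 1000), aluminum)
        assert lam == pytest.approx(27 / (6.02214076e23 * 2153.5e-27),
                                    rel=1e-3)
        assert lam == pytest.approx(20.8, abs=0.1)

    def test_compound_rule_equals_elementwise_sum(self, polyethylene):
        lam = mean_free_path(IonState(6, 12, 400), polyethylene)
        s_c = sigma_cc(12, 12, NOMINAL) * 1e-27
        s_h = sigma_cc(12, 1, NOMINAL) * 1e-27
        expected = 14.0 / (6.02214076e23 * (s_c + 2 * s_h))
        assert lam == pytest.approx(expected, rel=1e-12)

    def test_geometric_model_overestimates_hydrogen_target(self,
                                                           polyethylene):
        # the model gives ~18-19 g/cm2 for carbon in CH2; the measured
        # value (23 cm x 0.97) is distinctly longer
        lam = mean_free_path(IonState(6, 12, 400), polyethylene)
        assert 18.0 <= lam <= 19.0
        assert lam < 23.0 * 0.97

    def test_measured_provider_precedence_and_error(self, aluminum):
        rec = CrossSectionRecord(26, 56, "Al", 27, 600, 2000.0, 100.0)
        prov = MeasuredProvider([rec])
        lam = mean_free_path(IonState(26, 56, 600), aluminum, prov)
        assert lam == pytest.approx(27 / (6.02214076e23 * 2000e-27), rel=1e-9)
        with pytest.raises(KeyError, match="Z=13"):
            mean_free_path(IonState(6, 12, 600), aluminum, prov)

    def test_mfp_override_provider(self, polyethylene):
        prov = MfpOverrideProvider({(6, 12): 22.3})
        assert mean_free_path(IonState(6, 12, 400), polyethylene,
                              prov) == 22.3
        # non-overridden species falls back to the geometric model
        lam_o = mean_free_path(IonState(8, 16, 600), polyethylene, prov)
        assert lam_o == pytest.approx(
            mean_free_path(IonState(8, 16, 600), polyethylene), rel=1e-12)


class TestSurvival:
    def test_zero_depth(self):
        assert survival_fraction(0.0, 23.0) == 1.0

    def test_printed_worked_numbers(self):
        # 16O over 37 cm with a 17 cm mfp; 4He over 16 g/cm2 with 66 g/cm2
        assert survival_fraction(37, 17) == pytest.approx(0.11, abs=0.005)
        assert survival_fraction(16, 66) == pytest.approx(0.78, abs=0.005)
        assert interaction_fraction(12, 23) == pytest.approx(0.40, abs=0.01)

    @given(st.floats(min_value=0, max_value=50),
           st.floats(min_value=0, max_value=50))
    @settings(max_examples=50)
    def test_multiplicative_over_stacked_slabs(self, x1, x2):
        lam = 17.0
        assert survival_fraction(x1 + x2, lam) == pytest.approx(
            survival_fraction(x1, lam) * survival_fraction(x2, lam),
            rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            survival_fraction(-1.0, 23.0)
        with pytest.raises(ValueError):
            survival_fraction(1.0, 0.0)


class TestAttenuationTable:
    def test_reproduces_printed_table(self, aluminum):
        ions = [IonState(z, a, 1000) for z, a in TABLE1]
        df = attenuation_table(ions, [5, 10, 20, 40], aluminum, NOMINAL)
        for (z, a), expected in TABLE1.items():
            got = df.loc[f"Z{z}A{a}"].to_numpy()
            assert np.max(np.abs(got - expected)) <= 0.001

    def test_monotone_in_depth_and_mass(self, aluminum):
        ions = [IonState(z, a, 1000) for z, a in TABLE1]
        df = attenuation_table(ions, [5, 10, 20, 40], aluminum, NOMINAL)
        assert (df.diff(axis=1).iloc[:, 1:] > 0).all().all()
        assert (df.diff(axis=0).iloc[1:] > 0).all().all()

    def test_zero_depth_zero_attenuation(self, aluminum):
        df = attenuation_table([IonState(6, 12, 1000)], [0.0, 5.0], aluminum)
        assert df.iloc[0, 0] == 0.0


class TestChi2Fit:
    def test_noiseless_truth_recovered_exactly(self):
        records = make_xsec_dataset(noise_fraction=0.0, seed=0)
        surf = chi2_fit(records)
        assert surf.best_fit == GeometricParams(1.26, 0.2)
        assert surf.chi2_min == pytest.approx(0.0, abs=1e-20)

    def test_best_fit_attains_grid_minimum(self):
        surf = chi2_fit(make_xsec_dataset(noise_fraction=0.1, seed=5))
        assert surf.chi2_min == surf.chi2.min()
        i = list(surf.r0_grid).index(surf.best_fit.r0)
        j = list(surf.b_grid).index(surf.best_fit.transparency)
        assert surf.chi2[i, j] == surf.chi2_min

    def test_correlation_ridge_is_shallow(self):
        # moving r0 up with a compensating transparency barely raises chi2
        surf = chi2_fit(make_xsec_dataset(noise_fraction=0.1, seed=3))
        i = int(np.argmin(np.abs(surf.r0_grid - 1.30)))
        ridge_chi2 = surf.chi2[i].min()
        assert surf.chi2_min > 0
        assert ridge_chi2 < 2.0 * surf.chi2_min

    def test_light_target_subset_pulls_parameters_down(self):
        # fits restricted to H/C/Al targets prefer smaller r0 and b than
        # heavy-target fits when the data carry a hydrogen-target excess,
        # mirroring the behaviour seen in measured datasets; here we check
        # the machinery: filtering works and the subset fit is valid
        records = make_xsec_dataset(noise_fraction=0.05, seed=9)
        light = filter_records_by_target(records, ["H", "C", "Al"])
        heavy = filter_records_by_target(records, ["Cu", "Sn"])
        assert {r.target_symbol for r in light} == {"H", "C", "Al"}
        s_light = chi2_fit(light)
        s_heavy = chi2_fit(heavy)
        assert s_light.chi2_min >= 0 and s_heavy.chi2_min >= 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            chi2_fit([])
        rec = CrossSectionRecord(6, 12, "Al", 27, 600, 1000.0, 50.0)
        with pytest.raises(ValueError):
            chi2_fit([rec, rec], r0_grid=[], b_grid=DEFAULT_B_GRID)

    def test_surface_export(self, tmp_path):
        surf = chi2_fit(make_xsec_dataset(noise_fraction=0.1, seed=2))
        surf.to_csv(tmp_path / "surf.csv")
        surf.best_fit_json(tmp_path / "best.json")
        import json
        best = json.loads((tmp_path / "best.json").read_text())
        assert best["r0_fm"] == surf.best_fit.r0


def test_records_csv_round_trip(tmp_path):
    records = make_xsec_dataset(noise_fraction=0.1, seed=4)[:5]
    path = tmp_path / "recs.csv"
    write_records_csv(records, path)
    back = read_records_csv(path)
    assert len(back) == len(records)
    for b, r in zip(back, records):
        assert (b.z_proj, b.a_proj, b.target_symbol) == \
            (r.z_proj, r.a_proj, r.target_symbol)
        assert b.sigma_cc == pytest.approx(r.sigma_cc, rel=1e-12)
        assert b.sigma_err == pytest.approx(r.sigma_err, rel=1e-12)
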