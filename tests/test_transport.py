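"""Monte Carlo slab transport: survival, Bragg curves, peak analysis."""

import numpy as np
import pandas as pd
import pytest

from ionslab.cross_sections import (GeometricProvider, MfpOverrideProvider,
                                    mean_free_path)
from ionslab.fragmentation import BranchingTable, default_branching_table
from ionslab.physics import IonState, csda_range, range_table
from ionslab.transport import (BraggCurve, TransportConfig, bragg_curve,
                               composition_at_depth, peak_analysis,
                               score_bragg, transport_slab)

C200 = IonState(6, 12, 200.0)


def small_config(**kw):
    defaults = dict(step=0.05, rng_seed=31, n_primaries=400)
    defaults.update(kw)
    return TransportConfig(**defaults)


class TestDeterministicSlowing:
    def test_fragmentation_off_all_stop_at_csda_range(self, polyethylene):
        cfg = small_config(fragmentation_enabled=False, straggling=False)
        r = csda_range(C200, polyethylene)
        res = transport_slab(C200, polyethylene, 12.0, cfg)
        surv = res.primary_survival([r - 0.2, r + 0.2])
        assert surv[0] == 1.0
        assert surv[1] == 0.0
        stops = np.array([p.stop_depth for p in res.primaries])
        assert stops == pytest.approx(r, rel=1e-3)

    def test_seed_determinism_bit_identical(self, polyethylene):
        cfg = small_config(n_primaries=200)
        r1 = transport_slab(C200, polyethylene, 10.0, cfg)
        r2 = transport_slab(C200, polyethylene, 10.0, cfg)
        e1 = [(p.particle_id, p.end_depth, p.fate) for p in r1.records]
        e2 = [(p.particle_id, p.end_depth, p.fate) for p in r2.records]
        assert e1 == e2

    def test_different_seed_differs(self, polyethylene):
        r1 = transport_slab(C200, polyethylene, 10.0,
                            small_config(rng_seed=1, n_primaries=200))
        r2 = transport_slab(C200, polyethylene, 10.0,
                            small_config(rng_seed=2, n_primaries=200))
        assert [p.end_depth for p in r1.records] != \
            [p.end_depth for p in r2.records]


class TestSurvivalOracle:
    def test_charge_changing_survival_matches_exponential(self,
                                                          polyethylene):
        # closed-form e^(-x/lambda) vs Monte Carlo at 3-sigma binomial
        cfg = small_config(n_primaries=3000, rng_seed=8)
        lam = mean_free_path(IonState(6, 12, 400), polyethylene)
        res = transport_slab(IonState(6, 12, 400), polyethylene, 20.0, cfg)
        for x in (5.0, 10.0, 18.0):
            expected = np.exp(-x / lam)
            got = res.charge_changing_survival([x])[0]
            sd = np.sqrt(expected * (1 - expected) / cfg.n_primaries)
            assert abs(got - expected) < 3 * sd + 1e-9

    def test_printed_worked_survivals(self, polyethylene):
        # measured mean free paths as inputs: 50% of 293 MeV/nuc carbon
        # fragmented at its Bragg peak (16 cm linear)
        prov = MfpOverrideProvider({(6, 12): 23.0 * 0.97})
        cfg = small_config(n_primaries=4000, rng_seed=12)
        res = transport_slab(IonState(6, 12, 293), polyethylene, 15.6, cfg,
                             sigma_provider=prov)
        surv = res.charge_changing_survival([15.52])[0]
        assert surv == pytest.approx(0.50, abs=0.025)

    def test_let_budget_every_event(self, polyethylene):
        cfg = small_config(n_primaries=1500, rng_seed=4)
        res = transport_slab(C200, polyethylene, 10.0, cfg)
        assert len(res.let_budget) > 100
        assert all(f < p for p, f in res.let_budget)

    def test_bernoulli_sampling_and_step_warning(self, polyethylene):
        cfg = small_config(n_primaries=300, rng_seed=3,
                           interaction_sampling="bernoulli", step=0.05)
        res = transport_slab(C200, polyethylene, 10.0, cfg)
        assert any(p.fate == "fragmented" for p in res.primaries)
        big = small_config(interaction_sampling="bernoulli", step=5.0,
                           n_primaries=50)
        with pytest.warns(UserWarning, match="lambda/10"):
            transport_slab(C200, polyethylene, 10.0, big)


class TestBraggCurve:
    @pytest.fixture(scope="class")
    @staticmethod
    def carbon_curve():
        cfg = TransportConfig(step=0.05, rng_seed=17, n_primaries=3000)
        from ionslab.materials import POLYETHYLENE
        return bragg_curve(C200, POLYETHYLENE, 12.0, cfg)

    def test_entrance_ratio_is_one(self, carbon_curve):
        assert carbon_curve.ionization_ratio[0] == pytest.approx(1.0,
                                                                 abs=0.02)

    def test_peak_near_csda_range(self, carbon_curve, polyethylene):
        pk = peak_analysis(carbon_curve)
        r = csda_range(C200, polyethylene)
        assert pk.peak_depth == pytest.approx(r, rel=0.03)
        assert pk.peak_ratio > 3.0
        assert not pk.no_peak

    def test_distal_tail_present_iff_fragmentation(self, polyethylene):
        pk_frag = peak_analysis(
            bragg_curve(C200, polyethylene, 12.0,
                        small_config(n_primaries=800)))
        assert pk_frag.distal_integral > 0
        cfg_off = small_config(fragmentation_enabled=False,
                               straggling=False, n_primaries=200)
        curve = bragg_curve(C200, polyethylene, 12.0, cfg_off)
        r = csda_range(C200, polyethylene)
        beyond = curve.depth_grid > r
        assert np.all(curve.ionization_ratio[beyond] == 0.0)

    def test_step_halving_moves_peak_less_than_one_percent(self,
                                                           polyethylene):
        pks = []
        for step in (0.05, 0.025):
            cfg = TransportConfig(step=step, rng_seed=21, n_primaries=1500)
            pks.append(peak_analysis(
                bragg_curve(C200, polyethylene, 10.0, cfg)).peak_depth)
        assert abs(pks[0] - pks[1]) / pks[0] < 0.01

    def test_composition_entrance_is_pure_beam(self, carbon_curve):
        comp = composition_at_depth(carbon_curve, 0.0)
        assert comp == {6: 1.0}

    def test_composition_fractions_sum_to_one(self, carbon_curve):
        pk = peak_analysis(carbon_curve)
        comp = composition_at_depth(carbon_curve, pk.peak_depth)
        assert sum(comp.values()) == pytest.approx(1.0, rel=1e-9)
        # survivors plus a H/He-dominated fragment complement
        assert comp[6] > 0.1
        light = comp.get(1, 0) + comp.get(2, 0)
        heavy_frag = sum(v for z, v in comp.items() if z in (3, 4, 5))
        assert light > heavy_frag

    def test_far_distal_only_hydrogen_and_helium(self, polyethylene):
        # beyond the reach of B/Be/Li (longest: Li at ~2.3x the carbon
        # range from the entrance) only Z=1,2 can appear
        cfg = small_config(n_primaries=600, rng_seed=6, step=0.1)
        curve = bragg_curve(C200, polyethylene, 25.0, cfg)
        r_li = 7 / 9 * 36 / 12 * csda_range(C200, polyethylene)
        # 20% headroom for Goldhaber longitudinal kicks and straggling
        sel = curve.depth_grid > 1.2 * r_li
        present = {z for z in curve.composition.columns
                   if curve.composition.loc[sel, z].sum() > 0}
        assert present <= {1, 2}

    def test_csv_round_trip(self, carbon_curve, tmp_path):
        path = tmp_path / "curve.csv"
        carbon_curve.to_csv(path)
        back = BraggCurve.from_csv(path)
        assert back.depth_grid == pytest.approx(carbon_curve.depth_grid)
        assert back.ionization_ratio == pytest.approx(
            carbon_curve.ionization_ratio, rel=1e-5)


class TestPeakAnalysis:
    def test_triangular_curve_exact_apex(self):
        grid = np.linspace(0, 10, 101)
        ratio = np.where(grid <= 6, 1 + grid, 7 - (grid - 6))
        comp = pd.DataFrame({6: np.ones_like(grid)}, index=grid)
        curve = BraggCurve(grid, ratio, comp, 1)
        pk = peak_analysis(curve)
        assert pk.peak_depth == 6.0
        assert pk.peak_ratio == 7.0

    def test_monotone_decreasing_flagged(self):
        grid = np.linspace(0, 10, 50)
        ratio = 1.0 / (1.0 + grid)
        comp = pd.DataFrame({1: np.ones_like(grid)}, index=grid)
        pk = peak_analysis(BraggCurve(grid, ratio, comp, 1))
        assert pk.no_peak
        assert pk.peak_depth == 0.0

    def test_all_zero_curve_rejected(self):
        grid = np.linspace(0, 1, 5)
        comp = pd.DataFrame({1: np.zeros(5)}, index=grid)
        with pytest.raises(ValueError):
            peak_analysis(BraggCurve(grid, np.zeros(5), comp, 1))

    def test_fixture_peak_recovered_within_one_grid_step(self):
        from ionslab.synthetic import make_bragg_fixture
        curve, truth = make_bragg_fixture(peak_depth=8.13, peak_ratio=6.5,
                                          noise_fraction=0.01, seed=2)
        pk = peak_analysis(curve)
        assert abs(pk.peak_depth - truth["peak_depth"]) <= \
            truth["step"] + 1e-9


class TestConfigValidation:
    def test_bad_step(self):
        with pytest.raises(ValueError):
            TransportConfig(step=0.0)

    def test_bad_sampling(self):
        with pytest.raises(ValueError):
            TransportConfig(interaction_sampling="metropolis")

    def test_low_energy_beam_rejected(self, polyethylene):
        with pytest.raises(ValueError):
            transport_slab(IonState(6, 12, 0.5), polyethylene, 1.0,
                           small_config())
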