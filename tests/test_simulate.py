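"""Monte Carlo trough simulation, PTA/exceedance, dose recommendation."""

import numpy as np
import pytest

import siropk as sp
from siropk.errors import ConfigError, NoFeasibleDoseError
from siropk.simulate import _arm_troughs_by_dose


class TestSimulateTroughs:
    def test_no_variability_gives_constant_troughs(self, final_model):
        frozen = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        t = sp.simulate_troughs(frozen, 20.0, 0.06, n=50, seed=0)
        assert np.allclose(t, t[0])
        assert t[0] == pytest.approx(9.529, abs=5e-3)

    def test_median_converges_to_typical_trough(self, final_model):
        """Median of exp(eta) is 1, so the sample median approaches the
        typical steady-state trough."""
        t = sp.simulate_troughs(final_model, 20.0, 0.06, n=10_000, seed=123)
        assert np.median(t) == pytest.approx(9.53, abs=0.5)

    def test_same_seed_reproduces_vector(self, final_model):
        a = sp.simulate_troughs(final_model, 30.0, 0.05, n=500, seed=9)
        b = sp.simulate_troughs(final_model, 30.0, 0.05, n=500, seed=9)
        assert np.array_equal(a, b)

    def test_residual_noise_keeps_troughs_nonnegative(self, final_model):
        t = sp.simulate_troughs(final_model, 10.0, 0.01, n=2000, seed=2, include_residual=True)
        assert (t >= 0).all()
        assert t.std() > sp.simulate_troughs(final_model, 10.0, 0.01, n=2000, seed=2).std()

    def test_invalid_arguments_rejected(self, final_model):
        with pytest.raises(ConfigError):
            sp.simulate_troughs(final_model, -5.0, 0.06)
        with pytest.raises(ConfigError):
            sp.simulate_troughs(final_model, 20.0, 0.0)


class TestPtaAndExceedance:
    def test_pta_inclusive_window(self):
        assert sp.pta([4, 5, 10, 15, 16], (5, 15)) == pytest.approx(0.6)
        assert sp.pta([6, 7, 8], (5, 15)) == 1.0
        assert sp.pta([6, 7, 8], (0, np.inf)) == 1.0

    def test_p_exceed_strict(self):
        assert sp.p_exceed([4, 5, 10, 15, 16]) == pytest.approx(0.2)
        assert sp.p_exceed([4, 15]) == 0.0

    def test_partition_identity(self, final_model):
        t = sp.simulate_troughs(final_model, 20.0, 0.08, n=1000, seed=6)
        below = float(np.mean(t < 5.0))
        assert below + sp.pta(t, (5, 15)) + sp.p_exceed(t, 15.0) == pytest.approx(1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ConfigError):
            sp.pta([])
        with pytest.raises(ConfigError):
            sp.p_exceed([])


class TestRecommendDose:
    def test_degenerate_model_ties_break_low(self, final_model):
        """Without variability the typical 20 kg trough is 1.59k ng/ml at dose
        0.01k, inside [5, 15] exactly for 0.04-0.09: PTA ties at 1 and the
        lowest tied dose wins."""
        frozen = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        cfg = sp.SimulationConfig(n=10, seed=0)
        assert sp.recommend_dose(frozen, 20.0, config=cfg) == 0.04

    def test_no_feasible_dose_signalled(self, final_model):
        cfg = sp.SimulationConfig(n=50, seed=0, window=(4000.0, 5000.0))
        with pytest.raises(NoFeasibleDoseError):
            sp.recommend_dose(final_model, 10.0, config=cfg)

    def test_p_exceed_monotone_in_dose_with_crn(self, final_model):
        """Common random draws make troughs linear in dose, so exceedance
        probabilities are exactly non-decreasing along the dose grid."""
        cfg = sp.SimulationConfig(n=1000, seed=17)
        for weight in (10.0, 30.0, 60.0):
            by_dose = _arm_troughs_by_dose(final_model, weight, 0, cfg)
            pe = [sp.p_exceed(by_dose[d]) for d in sorted(by_dose)]
            assert all(a <= b for a, b in zip(pe, pe[1:]))


class TestGridAndBands:
    def test_grid_has_all_arms(self, final_model):
        grid = sp.simulate_grid(final_model, sp.SimulationConfig(n=50, seed=3))
        assert len(grid) == 6 * 10 * 2
        assert set(grid["pos"]) == {0, 1}
        assert grid["pta"].between(0, 1).all()
        assert ((grid["pta"] + grid["p_exceed"]) <= 1 + 1e-12).all()

    def test_bands_tile_weight_range_without_gaps(self, final_model):
        bands = sp.weight_band_table(final_model, sp.SimulationConfig(n=200, seed=4))
        assert bands[0].weight_low == 10.0
        assert bands[-1].weight_high == 60.0
        for a, b in zip(bands, bands[1:]):
            assert a.weight_high == b.weight_low
        doses = {b.dose_per_kg for b in bands}
        assert doses <= set(sp.SimulationConfig().doses)

    def test_recommended_dose_per_kg_non_increasing_in_weight(self, final_model):
        """Allometry makes troughs per mg/kg rise with weight, so the
        recommended dose per kg cannot increase with weight (checked on the
        deterministic typical-value model to avoid Monte Carlo ties)."""
        frozen = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        cfg = sp.SimulationConfig(n=10, seed=0)
        recs = [sp.recommend_dose(frozen, w, config=cfg) for w in range(10, 61, 5)]
        assert all(a >= b for a, b in zip(recs, recs[1:]))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            sp.SimulationConfig(window=(15.0, 5.0))
        with pytest.raises(ConfigError):
            sp.SimulationConfig(n=0)
        with pytest.raises(ConfigError):
            sp.SimulationConfig(doses=(0.0, 0.1))
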