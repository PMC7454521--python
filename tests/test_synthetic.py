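"""Generator contracts: exactness at zero noise, seeding, noise calibration."""

import numpy as np
import pandas as pd
import pytest

from allokit import (
    GroundTruth,
    InvalidInputError,
    simulate_abundance,
    simulate_competition,
    simulate_cycle_scenario,
    simulate_kinetics,
    simulate_melt,
    species_fractions,
)
from allokit.constants import rt
from allokit.fitness import LN2
from allokit.synthetic import DEFAULT_WAVELENGTHS


class TestSimulateMelt:
    def test_zero_noise_equals_model_prediction(self, wt_truth):
        """Noiseless melts are exact fixed points of the forward model."""
        ds = simulate_melt(wt_truth, noise_sd=0.0)
        for wl, sub in ds.data.groupby("wavelength_nm"):
            expected = wt_truth.melt_signal(sub["urea_M"].to_numpy(), wl)
            np.testing.assert_allclose(sub["signal"].to_numpy(), expected, rtol=0, atol=1e-12)

    def test_fully_native_limit_hits_native_baseline(self):
        truth = GroundTruth(dG_NI=10.0, dG_IU=10.0)
        ds = simulate_melt(truth, urea_grid=[0.0] + list(range(1, 10)), noise_sd=0.0)
        row = ds.data[(ds.data["urea_M"] == 0.0) & (ds.data["wavelength_nm"] == 218.0)]
        a_n = truth.baselines_for([218.0])[218.0]["N"][0]
        assert abs(row["signal"].iloc[0] - a_n) < 1e-6

    def test_equal_boltzmann_weights_give_mean_of_baselines(self):
        """With both dG(urea)=0 at 5 M, all three species weigh 1/3."""
        truth = GroundTruth(dG_NI=5.0, m_NI=1.0, dG_IU=5.0, m_IU=1.0)
        ds = simulate_melt(truth, urea_grid=np.arange(0, 9.1, 0.5), noise_sd=0.0)
        wl = 224.0
        b = truth.baselines_for([wl])[wl]
        mean_bl = np.mean([b[sp][0] + b[sp][1] * 5.0 for sp in ("N", "I", "U")])
        row = ds.data[(ds.data["urea_M"] == 5.0) & (ds.data["wavelength_nm"] == wl)]
        assert abs(row["signal"].iloc[0] - mean_bl) < 1e-10

    def test_empty_grid_rejected(self, wt_truth):
        with pytest.raises(InvalidInputError):
            simulate_melt(wt_truth, urea_grid=[])
        with pytest.raises(InvalidInputError):
            simulate_melt(wt_truth, wavelengths=[])

    def test_noise_sd_matches_request(self, wt_truth):
        """Empirical residual SD within 15% of the requested level (n>=1000)."""
        ds = simulate_melt(
            wt_truth,
            urea_grid=np.linspace(0, 9, 250),
            wavelengths=DEFAULT_WAVELENGTHS,
            noise_sd=0.5,
            seed=11,
        )
        resid = []
        for wl, sub in ds.data.groupby("wavelength_nm"):
            resid.append(
                sub["signal"].to_numpy() - wt_truth.melt_signal(sub["urea_M"].to_numpy(), wl)
            )
        resid = np.concatenate(resid)
        assert len(resid) >= 1000
        assert abs(resid.std() - 0.5) / 0.5 < 0.15


class TestSimulateKinetics:
    def test_half_saturation_and_origin(self, wt_truth):
        ds = simulate_kinetics(
            wt_truth, substrate_grid=[0.0, wt_truth.Km], noise_cv=0.0, replicates=1
        )
        vmax = wt_truth.kcat * wt_truth.E0
        v = ds.data.set_index("substrate_uM")["v0"]
        assert v[0.0] == 0.0
        assert abs(v[wt_truth.Km] - vmax / 2) < 1e-12

    def test_velocity_matches_direct_formula_at_saturating_substrate(self):
        """WT enzyme (kcat 9.5/s, Km 359 uM) at 1500 uM CdRP."""
        truth = GroundTruth(kcat=9.5, Km=359.0, E0=1.0)
        ds = simulate_kinetics(truth, substrate_grid=[1500.0], noise_cv=0.0, replicates=1)
        expected = 9.5 * 1.0 * 1500.0 / (1500.0 + 359.0)
        assert abs(ds.data["v0"].iloc[0] - expected) < 1e-12

    def test_negative_substrate_rejected(self, wt_truth):
        with pytest.raises(InvalidInputError):
            simulate_kinetics(wt_truth, substrate_grid=[-1.0])


class TestSimulateCompetition:
    def test_equal_rates_give_flat_trajectory(self):
        ds = simulate_competition(k_WT=0.154, k_MT=0.154, noise_sd=0.0, seed=0)
        mt = ds.data[ds.data["variant_id"] == "MT"]
        assert np.allclose(mt["log2_ratio"], 0.0)

    def test_ln2_rate_gap_gives_unit_log2_slope(self):
        """k_MT - k_WT = ln2 per hr corresponds to 1 log2 unit per hr."""
        ds = simulate_competition(k_WT=0.2, k_MT=0.2 + LN2, noise_sd=0.0, seed=0)
        mt = ds.data[(ds.data["variant_id"] == "MT") & (ds.data["replicate"] == 1)]
        slope = np.polyfit(mt["time_hr"], mt["log2_ratio"], 1)[0]
        assert abs(slope - 1.0) < 1e-12

    def test_vector_control_included_and_too_few_timepoints_rejected(self):
        ds = simulate_competition(k_WT=0.15, k_MT=0.15, noise_sd=0.0)
        assert ds.data["is_vector_control"].any()
        with pytest.raises(InvalidInputError):
            simulate_competition(k_WT=0.15, k_MT=0.15, timepoints=[0.0])


class TestCycleScenario:
    def test_zero_effects_give_identical_variants(self, wt_truth):
        bundle = simulate_cycle_scenario(wt_truth, {}, {}, {})
        for vid in ("M1", "M2", "DM"):
            assert bundle[vid].dG_NI == bundle["WT"].dG_NI
            assert bundle[vid].kcat == bundle["WT"].kcat

    def test_additive_scenario_sums_exactly(self, wt_truth):
        bundle = simulate_cycle_scenario(
            wt_truth, {"dG_NI": 0.6}, {"dG_NI": 0.3}, {"dG_NI": 0.0}
        )
        ddg = {v: wt_truth.dG_NI - bundle[v].dG_NI for v in ("M1", "M2", "DM")}
        assert abs(ddg["DM"] - (ddg["M1"] + ddg["M2"])) < 1e-12

    def test_injected_delta_appears_in_double_mutant(self, wt_truth):
        bundle = simulate_cycle_scenario(
            wt_truth, {"dG_NI": 0.6}, {"dG_NI": 0.3}, {"dG_NI": 0.8}
        )
        ddg = {v: wt_truth.dG_NI - bundle[v].dG_NI for v in ("M1", "M2", "DM")}
        assert abs(ddg["DM"] - (ddg["M1"] + ddg["M2"]) - 0.8) < 1e-12

    def test_dGcat_effect_scales_kcat_through_barrier(self, wt_truth):
        bundle = simulate_cycle_scenario(wt_truth, {"dGcat": 0.5}, {}, {})
        expected = wt_truth.kcat * np.exp(-0.5 / rt())
        assert abs(bundle["M1"].kcat - expected) < 1e-12

    def test_unknown_property_rejected(self, wt_truth):
        with pytest.raises(InvalidInputError):
            simulate_cycle_scenario(wt_truth, {"dG_XX": 1.0}, {}, {})


class TestDeterminism:
    def test_same_seed_reproduces_all_generators(self, wt_truth):
        for make in (
            lambda s: simulate_melt(wt_truth, noise_sd=0.2, seed=s).data,
            lambda s: simulate_kinetics(wt_truth, noise_cv=0.05, seed=s).data,
            lambda s: simulate_competition(0.15, 0.17, noise_sd=0.02, seed=s).data,
            lambda s: simulate_abundance({"M1": 1.5}, seed=s),
        ):
            a, b, c = make(7), make(7), make(8)
            pd.testing.assert_frame_equal(a, b)
            assert not a.equals(c)
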