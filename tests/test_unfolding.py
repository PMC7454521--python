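"""Three-state linear-extrapolation model: populations, global fit, ddG."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit import (
    GroundTruth,
    InvalidInputError,
    MeltDataset,
    fit_three_state,
    fraction_unfolded_apparent,
    predict_signal,
    simulate_melt,
    species_fractions,
    stability_perturbation,
)
from allokit.constants import rt
from allokit.synthetic import DEFAULT_UREA_GRID


def hand_partition_fractions(dG_NI, m_NI, dG_IU, m_IU, urea, RT):
    """Independent oracle: direct Boltzmann-weight normalization."""
    K_NI = np.exp(-(dG_NI - m_NI * urea) / RT)
    K_IU = np.exp(-(dG_IU - m_IU * urea) / RT)
    Z = 1.0 + K_NI + K_NI * K_IU
    return 1.0 / Z, K_NI / Z, K_NI * K_IU / Z


class TestSpeciesFractions:
    def test_strongly_native_limit(self):
        fN, fI, fU = species_fractions(10.0, 1.5, 10.0, 1.0, 0.0, 0.6024)
        assert fN > 0.999

    def test_equal_weights_when_both_dG_vanish(self):
        fN, fI, fU = species_fractions(5.0, 1.0, 5.0, 1.0, 5.0)
        np.testing.assert_allclose([fN, fI, fU], [1 / 3] * 3, atol=1e-12)

    def test_matches_hand_coded_partition_function(self):
        RT = rt()
        got = species_fractions(5.0, 1.2, 4.0, 0.8, 3.0, RT)
        want = hand_partition_fractions(5.0, 1.2, 4.0, 0.8, 3.0, RT)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        dG1=st.floats(-12, 20),
        m1=st.floats(0.1, 5),
        dG2=st.floats(-12, 20),
        m2=st.floats(0.1, 5),
        urea=st.floats(0, 10),
    )
    def test_fractions_normalized_and_bounded(self, dG1, m1, dG2, m2, urea):
        """Populations sum to 1 at machine precision for any parameters."""
        fN, fI, fU = species_fractions(dG1, m1, dG2, m2, urea)
        assert abs(fN + fI + fU - 1.0) < 1e-12
        assert 0.0 <= fN <= 1.0 and 0.0 <= fI <= 1.0 and 0.0 <= fU <= 1.0

    def test_native_fraction_monotone_nonincreasing_in_urea(self):
        u = np.linspace(0, 9, 50)
        fN, _, _ = species_fractions(5.5, 1.8, 5.0, 1.0, u)
        assert np.all(np.diff(fN) <= 1e-12)


class TestFitAndPredict:
    def test_noiseless_recovery_is_exact(self, wt_truth):
        ds = simulate_melt(wt_truth, noise_sd=0.0)
        fit = fit_three_state(ds, bootstrap=0, seed=1)
        np.testing.assert_allclose(
            fit.params,
            [wt_truth.dG_NI, wt_truth.m_NI, wt_truth.dG_IU, wt_truth.m_IU],
            atol=1e-4,
        )
        assert fit.rms < 1e-8

    def test_predict_signal_limits_and_mixture(self, wt_truth):
        ds = simulate_melt(wt_truth, noise_sd=0.0)
        fit = fit_three_state(ds, bootstrap=0, seed=1)
        wl = 218.0
        b = wt_truth.baselines_for([wl])[wl]
        # native limit: 0 M on a stable protein is essentially pure N
        assert abs(predict_signal(fit, 0.0, wl) - b["N"][0]) < 5e-3
        # unfolded limit at 9 M
        y9 = b["U"][0] + b["U"][1] * 9.0
        assert abs(predict_signal(fit, 9.0, wl) - y9) < 5e-2
        with pytest.raises(InvalidInputError):
            predict_signal(fit, 3.0, 999.0)

    def test_equal_thirds_prediction_is_mean_of_baselines(self):
        truth = GroundTruth(dG_NI=5.0, m_NI=1.0, dG_IU=5.0, m_IU=1.0)
        ds = simulate_melt(truth, noise_sd=0.0)
        fit = fit_three_state(ds, bootstrap=0, seed=1)
        wl = 224.0
        b = truth.baselines_for([wl])[wl]
        mean_bl = np.mean([b[sp][0] + b[sp][1] * 5.0 for sp in ("N", "I", "U")])
        assert abs(predict_signal(fit, 5.0, wl) - mean_bl) < 1e-4

    def test_fit_invariant_to_row_order_and_affine_signal_rescale(self, wt_truth, melt_noise_sd):
        ds = simulate_melt(wt_truth, noise_sd=melt_noise_sd, seed=3)
        fit = fit_three_state(ds, bootstrap=0, seed=5)

        shuffled = MeltDataset(
            ds.variant_id,
            ds.data.sample(frac=1.0, random_state=0).reset_index(drop=True),
            ds.temperature,
        )
        fit_shuf = fit_three_state(shuffled, bootstrap=0, seed=5)
        np.testing.assert_allclose(fit_shuf.params, fit.params, atol=1e-6)

        rescaled = MeltDataset(
            ds.variant_id,
            ds.data.assign(signal=2.5 * ds.data["signal"] + 7.0),
            ds.temperature,
        )
        fit_resc = fit_three_state(rescaled, bootstrap=0, seed=5)
        np.testing.assert_allclose(fit_resc.params, fit.params, atol=1e-5)

    def test_two_state_limit_matches_two_state_fit(self):
        """When N is never populated the visible I<=>U transition must be
        recovered with the same dG/m a dedicated two-state fit finds."""
        from scipy.optimize import least_squares

        truth = GroundTruth(dG_NI=-8.0, m_NI=0.5, dG_IU=5.0, m_IU=1.0)
        ds = simulate_melt(truth, noise_sd=0.0)
        fit = fit_three_state(ds, bootstrap=0, seed=2)

        # independent two-state oracle on the same data
        def resid(theta):
            dG, m = theta
            out = []
            for wl, sub in ds.data.groupby("wavelength_nm"):
                u = sub["urea_M"].to_numpy()
                y = sub["signal"].to_numpy()
                K = np.exp(-(dG - m * u) / rt())
                fI = 1.0 / (1.0 + K)
                X = np.column_stack([fI, fI * u, 1 - fI, (1 - fI) * u])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                out.append(y - X @ beta)
            return np.concatenate(out)

        sol = least_squares(resid, [4.0, 1.2], bounds=([0, 0.05], [20, 5]))
        assert abs(fit.dG_IU - sol.x[0]) < 0.1
        assert abs(fit.m_IU - sol.x[1]) < 0.05

    def test_insufficient_urea_coverage_rejected(self, wt_truth):
        ds = simulate_melt(wt_truth, urea_grid=[0, 1, 2, 3, 4], noise_sd=0.0)
        with pytest.raises(InvalidInputError):
            fit_three_state(ds, bootstrap=0)

    def test_grid_search_oracle_equivalence(self):
        """On a small noiseless melt the fit must reach the SSE of an
        exhaustive 0.05-resolution grid search over all four parameters."""
        truth = GroundTruth(dG_NI=5.5, m_NI=1.8, dG_IU=5.0, m_IU=1.0)
        u = np.linspace(0, 9, 12)
        ds = simulate_melt(truth, urea_grid=u, wavelengths=[222.0], noise_sd=0.0)
        fit = fit_three_state(ds, bootstrap=0, seed=0)

        sub = ds.data.sort_values("urea_M")
        uu = sub["urea_M"].to_numpy()
        y = sub["signal"].to_numpy()

        def sse_at(theta):
            fN, fI, fU = species_fractions(*theta, uu)
            X = np.column_stack([fN, fN * uu, fI, fU, fU * uu])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        step = 0.05
        grid_best = np.inf
        for g1 in np.arange(truth.dG_NI - 0.25, truth.dG_NI + 0.251, step):
            for m1 in np.arange(truth.m_NI - 0.25, truth.m_NI + 0.251, step):
                for g2 in np.arange(truth.dG_IU - 0.25, truth.dG_IU + 0.251, step):
                    for m2 in np.arange(truth.m_IU - 0.25, truth.m_IU + 0.251, step):
                        grid_best = min(grid_best, sse_at((g1, m1, g2, m2)))
        fit_sse = sse_at(fit.params)
        assert fit_sse <= grid_best + 1e-9


class TestApparentFractionAndPerturbation:
    def test_endpoints_and_midpoint_of_apparent_fraction(self):
        """A point on the native baseline maps to 0, on the unfolded
        baseline to 1, and an equal-thirds point with the I baseline midway
        between N and U maps to 0.5."""
        wl = 222.0
        baselines = {wl: {"N": (-12.0, 0.0), "I": (-7.0, 0.0), "U": (-2.0, 0.0)}}
        truth = GroundTruth(dG_NI=5.0, m_NI=1.0, dG_IU=5.0, m_IU=1.0, baselines=baselines)
        ds = simulate_melt(truth, urea_grid=np.arange(0, 10.5, 0.5), wavelengths=[wl], noise_sd=0.0)
        fit = fit_three_state(ds, bootstrap=0, seed=0)
        curve = fraction_unfolded_apparent(ds, fit, wl).set_index("urea_M")["F_app"]
        assert abs(curve[0.0]) < 1e-3          # native end
        assert abs(curve[10.0] - 1.0) < 1e-3   # unfolded end
        assert abs(curve[5.0] - 0.5) < 1e-3    # equal thirds, I midway

    def test_degenerate_baselines_rejected(self):
        wl = 222.0
        baselines = {wl: {"N": (-5.0, 0.0), "I": (-5.0, 0.0), "U": (-5.0, 0.0)}}
        truth = GroundTruth(baselines=baselines)
        ds = simulate_melt(truth, wavelengths=[wl], noise_sd=0.0)
        with pytest.raises((InvalidInputError, Exception)):
            fit = fit_three_state(ds, bootstrap=0, seed=0)
            fraction_unfolded_apparent(ds, fit, wl)

    def test_stability_perturbation_sign_and_quadrature(self, wt_truth):
        ds_wt = simulate_melt(wt_truth, noise_sd=0.0)
        fit_wt = fit_three_state(ds_wt, bootstrap=0, seed=1)
        p0 = stability_perturbation(fit_wt, fit_wt)
        assert p0.ddG_NI == 0.0 and p0.ddG_IU == 0.0

        import dataclasses

        mut = dataclasses.replace(fit_wt, variant_id="mut", dG_NI=fit_wt.dG_NI - 1.5)
        p = stability_perturbation(fit_wt, mut)
        assert abs(p.ddG_NI - 1.5) < 1e-12  # destabilized => positive

    def test_end_to_end_destabilized_mutant_recovery(self, wt_truth, melt_noise_sd):
        """Noisy WT and destabilized-mutant melts: the recovered ddG_NI
        must land within +/-2 SE of the injected difference."""
        import dataclasses

        mut_truth = dataclasses.replace(wt_truth, variant_id="mut", dG_NI=wt_truth.dG_NI - 1.5)
        fit_wt = fit_three_state(
            simulate_melt(wt_truth, noise_sd=melt_noise_sd, seed=21), bootstrap=100, seed=1
        )
        fit_mut = fit_three_state(
            simulate_melt(mut_truth, noise_sd=melt_noise_sd, seed=22), bootstrap=100, seed=2
        )
        p = stability_perturbation(fit_wt, fit_mut)
        assert abs(p.ddG_NI - 1.5) <= 2.0 * p.ddG_NI_se + 0.3
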