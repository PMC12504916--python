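import math

import numpy as np
import pytest

from p31quant.amares_fit import (
    PeakPrior,
    _quarter_sine_weights,
    correct_ratio,
    default_priors,
    fit_spectrum,
    refit_broad_pde,
    saturation_factor,
)
from p31quant.core import AcquisitionParams, FID
from p31quant.spectra_sim import GroundTruth, synthesize_fid


class TestQuarterSineWeights:
    def test_first_point_attenuated_not_zero(self):
        w = _quarter_sine_weights(100, 12)
        assert 0 < w[0] < w[1] < w[11]
        assert w[11] == pytest.approx(1.0)
        assert np.all(w[12:] == 1.0)

    def test_zero_length_is_flat(self):
        assert np.all(_quarter_sine_weights(64, 0) == 1.0)

    def test_matches_quarter_sine_formula(self):
        L = 12
        w = _quarter_sine_weights(40, L)
        expected = np.sin(np.pi * (np.arange(L) + 1) / (2 * L))
        np.testing.assert_allclose(w[:L], expected)


class TestFitSpectrum:
    def test_single_lorentzian_exact_recovery(self, acq):
        truth = GroundTruth(amplitudes={"PCr": 0.8}, dampings={"PCr": 9.0})
        fid = synthesize_fid(truth, acq)
        fit = fit_spectrum(fid, priors=[PeakPrior("PCr", 0.0, 0.2, (2.0, 40.0))])
        assert fit.converged
        assert fit.peaks["PCr"].amplitude == pytest.approx(0.8, rel=1e-6)
        assert fit.peaks["PCr"].shift == pytest.approx(0.0, abs=1e-6)
        assert fit.peaks["PCr"].linewidth == pytest.approx(9.0, rel=1e-6)

    def test_seven_peak_noiseless_round_trip(self, control_truth, control_fid):
        fit = fit_spectrum(control_fid)
        shifts = control_truth.resolved_shifts()
        for name, peak in fit.peaks.items():
            assert peak.amplitude == pytest.approx(control_truth.amplitudes[name], rel=1e-4)
            assert peak.shift == pytest.approx(shifts[name], abs=1e-4)

    def test_grid_search_oracle_two_peaks(self, acq):
        """Exhaustive (shift, linewidth) grid + linear amplitude solve agrees
        with the nonlinear fit on a noiseless two-peak signal."""
        truth = GroundTruth(
            amplitudes={"PCr": 1.0, "Pi_a": 0.25},
            shifts={"PCr": 0.012, "Pi_a": float("nan")},
            dampings={"PCr": 9.3, "Pi_a": 14.1},
            true_ph_a=7.03,
        )
        fid = synthesize_fid(truth, acq)
        priors = [
            PeakPrior("PCr", 0.0, 0.1, (5.0, 20.0)),
            PeakPrior("Pi_a", 4.87, 0.1, (8.0, 25.0)),
        ]
        t = acq.time_axis()

        def basis(shift, lw):
            return np.exp((2j * np.pi * shift * acq.reference_frequency - np.pi * lw) * t)

        best = None
        pi_shift_true = truth.resolved_shifts()["Pi_a"]
        for s1 in np.arange(0.012 - 2e-3, 0.012 + 2e-3, 1e-3):
            for s2 in np.arange(pi_shift_true - 2e-3, pi_shift_true + 2e-3, 1e-3):
                for w1 in np.arange(9.3 - 0.02, 9.3 + 0.02, 1e-2):
                    for w2 in np.arange(14.1 - 0.02, 14.1 + 0.02, 1e-2):
                        design = np.vstack([basis(s1, w1), basis(s2, w2)]).T
                        amps, res, *_ = np.linalg.lstsq(design, fid.samples, rcond=None)
                        rnorm = np.linalg.norm(fid.samples - design @ amps)
                        if best is None or rnorm < best[0]:
                            best = (rnorm, s1, s2, np.abs(amps))
        fit = fit_spectrum(fid, priors=priors, weighting_length=0, fixed_phase0=0.0)
        _, s1, s2, amps = best
        assert fit.peaks["PCr"].shift == pytest.approx(s1, abs=1e-3)
        assert fit.peaks["Pi_a"].shift == pytest.approx(s2, abs=1e-3)
        assert fit.peaks["PCr"].amplitude == pytest.approx(amps[0], rel=1e-2)
        assert fit.peaks["Pi_a"].amplitude == pytest.approx(amps[1], rel=1e-2)

    def test_amplitude_bias_within_two_se_at_snr30(self, control_truth, acq, ortho_peak_height):
        """Seeded Monte-Carlo: amplitude estimates at SNR 30 are unbiased
        within two standard errors for every resonance."""
        n_rep = 100
        estimates = {name: [] for name in control_truth.amplitudes}
        for r in range(n_rep):
            truth = GroundTruth(
                amplitudes=dict(control_truth.amplitudes),
                true_ph_a=control_truth.true_ph_a,
                true_ph_b=control_truth.true_ph_b,
                true_mg=control_truth.true_mg,
                noise_sd=ortho_peak_height / 30.0,
                seed=7000 + r,
            )
            fit = fit_spectrum(synthesize_fid(truth, acq))
            for name in estimates:
                estimates[name].append(fit.amplitude(name))
        for name, values in estimates.items():
            values = np.array(values)
            se = values.std(ddof=1) / math.sqrt(n_rep)
            bias = values.mean() - control_truth.amplitudes[name]
            assert abs(bias) <= 2.0 * se, f"{name}: bias {bias:.2e} exceeds 2 SE {2*se:.2e}"

    def test_rmse_non_increasing_in_snr(self, control_truth, acq, ortho_peak_height):
        rmses = []
        for snr in (10.0, 20.0, 40.0):
            errs = []
            for r in range(25):
                truth = GroundTruth(
                    amplitudes=dict(control_truth.amplitudes),
                    true_ph_a=control_truth.true_ph_a,
                    true_ph_b=control_truth.true_ph_b,
                    true_mg=control_truth.true_mg,
                    noise_sd=ortho_peak_height / snr,
                    seed=8100 + r,
                )
                fit = fit_spectrum(synthesize_fid(truth, acq))
                errs.append(fit.amplitude("PCr") - control_truth.amplitudes["PCr"])
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_duplicate_names_rejected(self, control_fid):
        priors = [PeakPrior("PCr", 0.0), PeakPrior("PCr", 1.0)]
        with pytest.raises(ValueError, match="duplicate"):
            fit_spectrum(control_fid, priors=priors)


@pytest.fixture(scope="module")
def broad_pde_fid(acq):
    # PDE several times broader than the shared-width model allows
    truth = GroundTruth(
        amplitudes={"PCr": 1.0, "gATP": 0.3, "aATP": 0.3, "bATP": 0.3, "PDE": 0.25, "Pi_a": 0.1, "Pi_b": 0.02},
        dampings={"PCr": 10.0, "gATP": 25.0, "aATP": 25.0, "bATP": 30.0, "PDE": 150.0, "Pi_a": 15.0, "Pi_b": 15.0},
    )
    return synthesize_fid(truth, acq)


class TestRefitBroadPde:
    def test_default_fit_flags_broad_pde(self, broad_pde_fid):
        fit = fit_spectrum(broad_pde_fid)
        assert any(f.startswith("PDE:") for f in fit.flags) or not fit.converged

    def test_refit_recovers_broad_linewidth(self, broad_pde_fid):
        refit = refit_broad_pde(broad_pde_fid, fixed_phase0=0.0, fixed_phase1=0.0)
        assert refit.converged
        assert refit.peaks["PDE"].linewidth == pytest.approx(150.0, rel=0.05)
        assert refit.weighting_length == 16

    def test_phases_equal_clamped_values(self, broad_pde_fid):
        refit = refit_broad_pde(broad_pde_fid, fixed_phase0=7.5, fixed_phase1=-1.25)
        assert refit.phase0 == 7.5
        assert refit.phase1 == -1.25


class TestSaturation:
    def test_fully_relaxed_no_correction(self):
        assert saturation_factor(t1=0.1, tr=100.0, flip_deg=90.0) == pytest.approx(1.0, abs=1e-9)

    def test_infinite_t1_fully_saturated(self):
        assert saturation_factor(t1=1e9, tr=2.0, flip_deg=90.0) == pytest.approx(0.0, abs=1e-6)

    def test_frozen_reference_value(self):
        # f = sin(45) (1 - e^{-1/2}) / (1 - e^{-1/2} cos(45)), evaluated once
        assert saturation_factor(t1=4.0, tr=2.0, flip_deg=45.0) == pytest.approx(0.4871582, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            saturation_factor(t1=-1.0, tr=2.0, flip_deg=45.0)
        with pytest.raises(ValueError):
            saturation_factor(t1=1.0, tr=2.0, flip_deg=95.0)


class TestCorrectRatio:
    def test_equal_t1_leaves_ratio(self, acq):
        assert correct_ratio(0.37, 1.0, 3.0, 3.0, acq) == pytest.approx(0.37)

    def test_scale_invariance(self, acq):
        a = correct_ratio(0.2, 0.5, 5.0, 0.8, acq)
        b = correct_ratio(2.0, 5.0, 5.0, 0.8, acq)
        assert a == pytest.approx(b, rel=1e-12)

    def test_round_trip_recovers_concentration_ratio(self, acq):
        t1_num, t1_den, true_ratio = 5.0, 0.8, 0.45
        f_num = saturation_factor(t1_num, acq.tr, acq.flip_angle)
        f_den = saturation_factor(t1_den, acq.tr, acq.flip_angle)
        measured_num = true_ratio * f_num
        measured_den = 1.0 * f_den
        assert correct_ratio(measured_num, measured_den, t1_num, t1_den, acq) == pytest.approx(
            true_ratio, rel=1e-6
        )

    def test_zero_denominator_rejected(self, acq):
        with pytest.raises(ZeroDivisionError):
            correct_ratio(1.0, 0.0, 1.0, 1.0, acq)
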