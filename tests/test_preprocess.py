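import numpy as np
import pytest

from p31quant import preprocess
from p31quant.core import (
    AcquisitionParams,
    ExclusionReason,
    FID,
    QCReport,
    fid_from_spectrum,
    spectrum_from_fid,
)
from p31quant.amares_fit import PeakPrior, fit_spectrum
from p31quant.spectra_sim import GroundTruth, synthesize_csi, synthesize_fid


@pytest.fixture(scope="module")
def small_acq():
    return AcquisitionParams(n_points=256)


class TestHannFilter:
    def test_centre_sample_preserved(self, small_acq):
        phantom = np.full((8, 10), GroundTruth(amplitudes={"PCr": 1.0}), dtype=object)
        grid = synthesize_csi(phantom, small_acq)
        filtered = preprocess.hann_filter(grid)
        np.testing.assert_allclose(filtered.kspace[0, 0], grid.kspace[0, 0], rtol=1e-14)

    def test_double_filtering_rejected(self, small_acq):
        phantom = np.full((4, 4), None, dtype=object)
        phantom[1, 1] = GroundTruth(amplitudes={"PCr": 1.0})
        grid = preprocess.hann_filter(synthesize_csi(phantom, small_acq))
        with pytest.raises(ValueError, match="already"):
            preprocess.hann_filter(grid)

    def test_uniform_phantom_shape_preserved(self, small_acq):
        """A flat phantom concentrates all energy at k = 0, so the filter's
        only effect is through the (unit) centre weight."""
        phantom = np.full((8, 10), GroundTruth(amplitudes={"PCr": 1.0}), dtype=object)
        grid = synthesize_csi(phantom, small_acq)
        voxels_before = preprocess.reconstruct_voxels(grid)
        voxels_after = preprocess.reconstruct_voxels(preprocess.hann_filter(grid))
        np.testing.assert_allclose(
            voxels_after[4, 5].samples, voxels_before[4, 5].samples, atol=1e-10
        )

    def test_impulse_spreads_as_window_transform(self, small_acq):
        """Point source -> spatial profile equal to the inverse DFT of the
        Hann weights (the filter's point-spread function)."""
        phantom = np.full((8, 10), None, dtype=object)
        phantom[0, 0] = GroundTruth(amplitudes={"PCr": 1.0})
        grid = synthesize_csi(phantom, small_acq)
        filtered = preprocess.hann_filter(grid)
        voxels = preprocess.reconstruct_voxels(filtered)
        profile = np.array([[voxels[i, j].samples[0] for j in range(10)] for i in range(8)])
        wx = preprocess._hann_weights(8)
        wy = preprocess._hann_weights(10)
        psf = np.fft.ifft(wx)[:, None] * np.fft.ifft(wy)[None, :]
        source = synthesize_fid(phantom[0, 0], small_acq).samples[0]
        np.testing.assert_allclose(profile, psf * source, atol=1e-10)


class TestReconstructVoxels:
    def test_zero_shift_exact_recovery(self, small_acq):
        truth = GroundTruth(amplitudes={"PCr": 1.0, "Pi_a": 0.3})
        phantom = np.full((8, 10), None, dtype=object)
        phantom[2, 7] = truth
        voxels = preprocess.reconstruct_voxels(synthesize_csi(phantom, small_acq))
        np.testing.assert_allclose(
            voxels[2, 7].samples, synthesize_fid(truth, small_acq).samples, atol=1e-9
        )

    def test_half_voxel_shift_mixes_neighbours_equally(self, small_acq):
        truth = GroundTruth(amplitudes={"PCr": 1.0})
        fid = synthesize_fid(truth, small_acq).samples
        phantom = np.full((8, 1), None, dtype=object)
        phantom[3, 0] = truth
        phantom[4, 0] = truth
        grid = synthesize_csi(phantom, small_acq)
        voxels = preprocess.reconstruct_voxels(grid, shift=(0.5, 0.0))
        # sampled midway between two identical sources: the two sinc
        # interpolants add symmetrically, so the real part matches the
        # source profile interpolated at the midpoint
        mid = voxels[3, 0].samples
        ratio = np.abs(mid[0]) / np.abs(fid[0])
        assert 0.9 < ratio < 1.35  # constructive mixture, not a null

    def test_out_of_range_shift_rejected(self, small_acq):
        phantom = np.full((4, 4), None, dtype=object)
        phantom[0, 0] = GroundTruth(amplitudes={"PCr": 1.0})
        grid = synthesize_csi(phantom, small_acq)
        with pytest.raises(ValueError, match="0.5"):
            preprocess.reconstruct_voxels(grid, shift=(0.6, 0.0))


class TestEstimateSnr:
    def test_constructed_snr_recovered(self, acq):
        # scale the peak so its (orthonormal) spectral height is 50, inject
        # unit-SD noise in the tail window: the estimate should read ~50
        unit = synthesize_fid(GroundTruth(amplitudes={"PCr": 1.0}), acq)
        unit_height = np.abs(np.fft.fft(unit.samples, norm="ortho")).max()
        clean = unit.samples * (50.0 / unit_height)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, (2, acq.n_points))
        noisy = FID(clean + noise[0] + 1j * noise[1], acq)
        assert preprocess.estimate_snr(noisy) == pytest.approx(50.0, rel=0.10)

    def test_snr_linear_in_amplitude(self, acq):
        unit = synthesize_fid(GroundTruth(amplitudes={"PCr": 1.0}), acq)
        unit_height = np.abs(np.fft.fft(unit.samples, norm="ortho")).max()
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, (2, acq.n_points))
        out = []
        for target in (40.0, 80.0):
            noisy = FID(unit.samples * (target / unit_height) + noise[0] + 1j * noise[1], acq)
            out.append(preprocess.estimate_snr(noisy))
        assert out[1] / out[0] == pytest.approx(2.0, rel=0.05)

    def test_zero_noise_flags_infinite(self, acq):
        samples = np.zeros(acq.n_points, dtype=complex)
        samples[:100] = np.exp(-np.arange(100) / 10.0)  # fully decayed tail
        assert preprocess.estimate_snr(FID(samples, acq)) == np.inf


class TestAutophase:
    def test_pure_absorption_recovers_zero(self, acq):
        spec = spectrum_from_fid(synthesize_fid(GroundTruth(), acq))
        _, p0, p1 = preprocess.autophase(spec)
        assert abs(p0) < 1.0
        assert abs(p1) < 1.0

    @pytest.mark.parametrize("true0,true1,tol", [(30.0, 0.0, 1.0), (20.0, 10.0, 2.0), (-45.0, -5.0, 2.0)])
    def test_known_dephasing_inverted(self, acq, true0, true1, tol):
        truth = GroundTruth(phase0=true0, phase1=true1)
        spec = spectrum_from_fid(synthesize_fid(truth, acq))
        phased, p0, p1 = preprocess.autophase(spec)
        assert p0 == pytest.approx(-true0, abs=tol)
        assert p1 == pytest.approx(-true1, abs=tol)
        # corrected real part is absorptive: no significant negative lobes
        assert phased.values.real.min() > -0.02 * phased.values.real.max()


class TestApodizeZerofill:
    def test_zero_input(self, acq):
        fid = FID(np.zeros(acq.n_points, dtype=complex), acq)
        out = preprocess.apodize_zerofill(fid)
        assert len(out) == 2 * acq.n_points
        assert np.all(out.samples == 0)

    def test_linewidth_grows_by_filter_width(self, acq):
        truth = GroundTruth(amplitudes={"PCr": 1.0}, dampings={"PCr": 12.0})
        apodized = preprocess.apodize_zerofill(synthesize_fid(truth, acq), lb=20.0, zerofill_factor=1)
        fit = fit_spectrum(apodized, priors=[PeakPrior("PCr", 0.0, 0.2, (2.0, 60.0))])
        assert fit.peaks["PCr"].linewidth == pytest.approx(32.0, abs=0.05)
        assert fit.peaks["PCr"].amplitude == pytest.approx(1.0, rel=1e-4)

    def test_grid_spacing_halves(self, acq):
        fid = synthesize_fid(GroundTruth(), acq)
        out = preprocess.apodize_zerofill(fid)
        spec = spectrum_from_fid(out)
        raw = spectrum_from_fid(fid)
        assert len(spec.values) == 2 * len(raw.values)
        assert (spec.ppm_axis[1] - spec.ppm_axis[0]) == pytest.approx(
            0.5 * (raw.ppm_axis[1] - raw.ppm_axis[0])
        )


class TestReferenceToPcr:
    def test_offset_pcr_recentred(self, acq):
        truth = GroundTruth(amplitudes={"PCr": 1.0}, shifts={"PCr": 0.4})
        spec = spectrum_from_fid(preprocess.apodize_zerofill(synthesize_fid(truth, acq)))
        referenced, offset = preprocess.reference_to_pcr(spec)
        assert offset == pytest.approx(0.4, abs=0.01)
        peak = referenced.ppm_axis[np.argmax(referenced.magnitude())]
        assert abs(peak) <= referenced.ppm_axis[1] - referenced.ppm_axis[0]

    def test_already_referenced_is_identity(self, acq):
        spec = spectrum_from_fid(preprocess.apodize_zerofill(synthesize_fid(GroundTruth(), acq)))
        _, offset = preprocess.reference_to_pcr(spec)
        assert abs(offset) < 0.01

    def test_no_pcr_flags_artefact(self, acq):
        truth = GroundTruth(amplitudes={"bATP": 1.0}, true_mg=0.72)
        spec = spectrum_from_fid(synthesize_fid(truth, acq))
        with pytest.raises(preprocess.PeakNotFoundError):
            preprocess.reference_to_pcr(spec)


class TestAlignAndAverage:
    def test_identical_spectra_average_to_input(self, acq):
        spec = spectrum_from_fid(synthesize_fid(GroundTruth(), acq))
        avg, reports = preprocess.align_and_average([spec.copy(), spec.copy(), spec.copy()])
        np.testing.assert_allclose(avg.values, spec.values, atol=1e-8)
        assert not any(r.excluded for r in reports)

    def test_offset_pair_realigned(self, acq):
        base = GroundTruth(amplitudes={"PCr": 1.0, "gATP": 0.3})
        shifted = GroundTruth(amplitudes={"PCr": 1.0, "gATP": 0.3}, shifts={"PCr": 0.2, "gATP": -2.3, "aATP": -7.52, "bATP": float("nan"), "PDE": 3.2, "Pi_a": float("nan"), "Pi_b": float("nan")})
        s1 = spectrum_from_fid(synthesize_fid(base, acq))
        s2 = spectrum_from_fid(synthesize_fid(shifted, acq))
        avg, _ = preprocess.align_and_average([s1, s2], snrs=[2.0, 1.0])
        step = s1.ppm_axis[1] - s1.ppm_axis[0]
        peak_avg = avg.ppm_axis[np.argmax(np.abs(avg.values))]
        peak_ref = s1.ppm_axis[np.argmax(np.abs(s1.values))]
        assert abs(peak_avg - peak_ref) <= step
        # constructive averaging: aligned mean is nearly as tall as the reference
        assert np.abs(avg.values).max() >= 0.95 * np.abs(s1.values).max()

    def test_averaging_improves_snr(self, acq):
        rng = np.random.default_rng(8)
        n_rep = 9
        truth = GroundTruth(amplitudes={"PCr": 1.0})
        clean = synthesize_fid(truth, acq)
        height = np.abs(np.fft.fft(clean.samples, norm="ortho")).max()
        sd = height / 20.0
        fids, snrs = [], []
        for _ in range(n_rep):
            noise = rng.normal(0, sd, (2, acq.n_points))
            fid = FID(clean.samples + noise[0] + 1j * noise[1], acq)
            fids.append(fid)
            snrs.append(preprocess.estimate_snr(fid))
        specs = [spectrum_from_fid(f) for f in fids]
        avg, _ = preprocess.align_and_average(specs, snrs=snrs)
        avg_snr = preprocess.estimate_snr(fid_from_spectrum(avg))
        assert avg_snr == pytest.approx(20.0 * np.sqrt(n_rep), rel=0.20)

    def test_reference_choice_deterministic_and_order_invariant(self, acq):
        rng = np.random.default_rng(3)
        clean = synthesize_fid(GroundTruth(), acq)
        specs = []
        for _ in range(3):
            noise = rng.normal(0, 0.5, (2, acq.n_points))
            specs.append(spectrum_from_fid(FID(clean.samples + noise[0] + 1j * noise[1], acq)))
        snrs = [12.0, 30.0, 11.0]
        avg1, _ = preprocess.align_and_average(list(specs), snrs=list(snrs))
        order = [1, 2, 0]
        avg2, _ = preprocess.align_and_average([specs[i] for i in order], snrs=[snrs[i] for i in order])
        np.testing.assert_allclose(avg1.values, avg2.values, atol=1e-9)

    def test_single_spectrum_rejected(self, acq):
        spec = spectrum_from_fid(synthesize_fid(GroundTruth(), acq))
        with pytest.raises(ValueError):
            preprocess.align_and_average([spec])


class TestQcFilter:
    @staticmethod
    def _items(snrs, flags=None):
        flags = flags or {}
        items = []
        for i, s in enumerate(snrs):
            report = QCReport(snr=s)
            if i in flags:
                report.exclude(flags[i])
            items.append((None, report))
        return items

    def test_all_good_all_retained(self):
        retained, summary = preprocess.qc_filter(self._items([15, 20, 10]))
        assert len(retained) == 3
        assert summary["low_snr"] == 0

    def test_batch_with_low_snr_members(self):
        snrs = [12, 8, 15, 9.9, 30, 5, 10, 9, 3, 2, 14, 13, 16, 18, 25, 22, 19, 17, 21, 23]
        retained, summary = preprocess.qc_filter(self._items(snrs))
        assert summary["low_snr"] == 6
        assert len(retained) == 14

    def test_exactly_threshold_retained(self):
        retained, summary = preprocess.qc_filter(self._items([10.0]))
        assert len(retained) == 1
        assert summary["low_snr"] == 0

    def test_artefact_flags_respected(self):
        items = self._items([20, 25], flags={1: ExclusionReason.ARTEFACT})
        retained, summary = preprocess.qc_filter(items)
        assert len(retained) == 1
        assert summary["artefact"] == 1

    def test_idempotent(self):
        items = self._items([12, 8, 15])
        retained, _ = preprocess.qc_filter(items)
        retained2, summary2 = preprocess.qc_filter(retained)
        assert retained2 == retained
        assert all(v == 0 for v in summary2.values())
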