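import numpy as np
import pytest

from p31quant.constants import default_equilibrium_constants, default_t1_table
from p31quant.core import AcquisitionParams
from p31quant.spectra_sim import (
    DEFAULT_AMPLITUDES,
    GroundTruth,
    saturation_factor,
    synthesize_fid,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def constants():
    return default_equilibrium_constants()


@pytest.fixture(scope="session")
def t1s():
    return default_t1_table()


@pytest.fixture(scope="session")
def control_truth(acq, t1s):
    """Ground truth at the control-group medians, with saturation-weighted
    amplitudes so the downstream T1 correction is exercised."""
    sat = {k: saturation_factor(t1s[k], acq.tr, acq.flip_angle) for k in DEFAULT_AMPLITUDES}
    amps0 = dict(DEFAULT_AMPLITUDES)
    amps0["PDE"] = 0.37 * amps0["gATP"]
    amps = {k: v * sat[k] for k, v in amps0.items()}
    w_b = DEFAULT_AMPLITUDES["Pi_b"] / (DEFAULT_AMPLITUDES["Pi_a"] + DEFAULT_AMPLITUDES["Pi_b"])
    ph_a = 7.05 - w_b * 0.30
    return GroundTruth(amplitudes=amps, true_ph_a=ph_a, true_ph_b=ph_a + 0.30, true_mg=0.72)


@pytest.fixture(scope="session")
def control_fid(control_truth, acq):
    return synthesize_fid(control_truth, acq)


@pytest.fixture(scope="session")
def ortho_peak_height(control_fid):
    """Orthonormal-FFT peak height of the noiseless control spectrum: the
    scale that converts an SNR target into a time-domain noise SD."""
    return float(np.abs(np.fft.fft(control_fid.samples, norm="ortho")).max())
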