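"""Per-fit diagnostic plots: data, model and residual in the frequency domain."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .amares_fit import FitResult
from .core import FID, spectrum_from_fid


def plot_fit(fid: FID, fit: FitResult, path: str | Path, title: str = "") -> None:
    """Write a spectrum/model/residual plot for one fitted FID.

    The model FID is rebuilt from the fitted parameters, transformed with
    the same settings as the data, and shown on the ppm axis (downfield
    left, spectroscopy convention).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = fid.acq.time_axis(len(fid))
    model = np.zeros(len(t), dtype=complex)
    for peak in fit.peaks.values():
        phi = np.deg2rad(peak.phase)
        f_hz = fid.acq.ppm_to_hz(peak.shift)
        model += peak.amplitude * np.exp(1j * (2 * np.pi * f_hz * t + phi)) * np.exp(-np.pi * peak.linewidth * t)
    spec_data = spectrum_from_fid(fid)
    spec_model = spectrum_from_fid(FID(samples=model, acq=fid.acq))

    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True, height_ratios=[3, 1])
    axes[0].plot(spec_data.ppm_axis, spec_data.values.real, lw=0.7, label="data")
    axes[0].plot(spec_model.ppm_axis, spec_model.values.real, lw=0.9, label="model")
    axes[0].legend(frameon=False)
    axes[0].set_ylabel("real intensity (a.u.)")
    axes[0].set_title(title or fid.provenance)
    axes[1].plot(spec_data.ppm_axis, (spec_data.values - spec_model.values).real, lw=0.6, color="gray")
    axes[1].set_ylabel("residual")
    axes[1].set_xlabel("chemical shift (ppm)")
    axes[1].invert_xaxis()  # shared axis: downfield on the left
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
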