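"""Core containers and Fourier helpers shared across the pipeline.

Conventions
-----------
* The ppm axis is downfield-positive with the carrier at 0 ppm; after
  referencing, phosphocreatine (PCr) sits at 0 ppm.  1 ppm corresponds to
  ``reference_frequency`` Hz (the reference frequency is given in MHz).
* Spectra are stored fftshifted, i.e. ``values[i]`` corresponds to the
  strictly increasing ``ppm_axis[i]``.
* On the forward FID -> spectrum transform the first time-domain point is
  halved, the standard trapezoid correction that removes the constant
  baseline offset a discrete Fourier transform of a truncated decay would
  otherwise produce.  ``fid_from_spectrum`` undoes it, so the pair is an
  exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Any

import numpy as np

__all__ = [
    "AcquisitionParams",
    "FID",
    "Spectrum",
    "CSIGrid",
    "QCReport",
    "ExclusionReason",
    "spectrum_from_fid",
    "fid_from_spectrum",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-acquire CSI acquisition settings.

    Parameters
    ----------
    dwell_time : float
        Seconds per complex point (1 / bandwidth).
    n_points : int
        Number of complex points per FID.
    reference_frequency : float
        31P carrier frequency in MHz (ppm <-> Hz conversion factor).
    tr : float
        Repetition time in seconds.
    flip_angle : float
        Excitation flip angle in degrees (0, 90].
    """

    dwell_time: float = 1.0 / 4000.0
    n_points: int = 2048
    reference_frequency: float = 120.6
    tr: float = 2.0
    flip_angle: float = 45.0

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.n_points <= 0:
            raise ValueError("n_points must be > 0")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip_angle must be in (0, 90] degrees")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")

    @property
    def bandwidth(self) -> float:
        """Spectral width in Hz; bandwidth * dwell_time = 1 by construction."""
        return 1.0 / self.dwell_time

    def time_axis(self, n: int | None = None) -> np.ndarray:
        return np.arange(self.n_points if n is None else n) * self.dwell_time

    def ppm_axis(self, n: int | None = None) -> np.ndarray:
        """Strictly increasing ppm axis of the fftshifted spectrum."""
        n = self.n_points if n is None else n
        hz = np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell_time))
        return hz / self.reference_frequency

    def ppm_to_hz(self, ppm: float) -> float:
        return ppm * self.reference_frequency


@dataclass
class FID:
    """A free induction decay: the complex time-domain unit of processing."""

    samples: np.ndarray
    acq: AcquisitionParams
    provenance: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise ValueError("FID samples must be one-dimensional")

    def __len__(self) -> int:
        return len(self.samples)

    def copy_with(self, samples: np.ndarray, **kw: Any) -> "FID":
        return FID(samples=samples, acq=self.acq, provenance=kw.get("provenance", self.provenance))


@dataclass
class Spectrum:
    """Frequency-domain spectrum on a strictly increasing ppm axis."""

    values: np.ndarray
    ppm_axis: np.ndarray
    acq: AcquisitionParams
    phase0: float = 0.0    # accumulated zero-order correction, degrees
    phase1: float = 0.0    # accumulated first-order correction, degrees/ppm
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.values.shape != self.ppm_axis.shape:
            raise ValueError("values and ppm_axis must have matching shape")
        if len(self.ppm_axis) > 1 and not np.all(np.diff(self.ppm_axis) > 0):
            raise ValueError("ppm_axis must be strictly increasing")

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def copy(self) -> "Spectrum":
        return Spectrum(
            values=self.values.copy(),
            ppm_axis=self.ppm_axis.copy(),
            acq=self.acq,
            phase0=self.phase0,
            phase1=self.phase1,
            provenance=self.provenance,
        )


@dataclass
class CSIGrid:
    """2D chemical-shift-imaging k-space: a grid of FIDs plus voxel geometry.

    ``kspace`` has shape (nx, ny, n_points) and is stored in unshifted DFT
    order (k = 0 at index [0, 0]).
    """

    kspace: np.ndarray
    acq: AcquisitionParams
    field_of_view: tuple[float, float] = (160.0, 200.0)  # mm
    filtered: bool = False

    def __post_init__(self) -> None:
        self.kspace = np.asarray(self.kspace, dtype=complex)
        if self.kspace.ndim != 3:
            raise ValueError("kspace must have shape (nx, ny, n_points)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.kspace.shape[:2]


class ExclusionReason(str, Enum):
    NONE = "none"
    LOW_SNR = "low_snr"
    ARTEFACT = "artefact"
    ALIGNMENT_FAILURE = "alignment_failure"


@dataclass
class QCReport:
    """Quality-control record accompanying each spectrum through the pipeline."""

    snr: float = np.nan
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    notes: str = ""

    def exclude(self, reason: ExclusionReason, note: str = "") -> None:
        self.excluded = True
        self.exclusion_reason = reason
        if note:
            self.notes = (self.notes + "; " + note).lstrip("; ")


def spectrum_from_fid(fid: FID, first_point_half: bool = True) -> Spectrum:
    """Fourier transform an FID to an fftshifted spectrum on a ppm axis."""
    samples = fid.samples.astype(complex).copy()
    if first_point_half and len(samples):
        samples[0] *= 0.5
    values = np.fft.fftshift(np.fft.fft(samples))
    return Spectrum(
        values=values,
        ppm_axis=fid.acq.ppm_axis(len(samples)),
        acq=fid.acq,
        provenance=fid.provenance,
    )


def fid_from_spectrum(spec: Spectrum, first_point_half: bool = True) -> FID:
    """Exact inverse of :func:`spectrum_from_fid` (phase corrections baked in)."""
    samples = np.fft.ifft(np.fft.ifftshift(spec.values))
    if first_point_half and len(samples):
        samples[0] *= 2.0
    return FID(samples=samples, acq=spec.acq, provenance=spec.provenance)
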