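"""Synthetic 31P-MRS signal generation with known ground truth.

Simulates the resting-muscle 31P spectrum at 7 T as a sum of Lorentzian-damped
complex exponentials: PCr (the 0-ppm reference), the three ATP moieties, the
phosphodiester band (PDE) and two inorganic-phosphate components (Pi_a, Pi_b).
Two physical couplings make the spectrum a biomarker carrier:

* the Pi chemical shift moves downfield with pH (Henderson-Hasselbalch
  titration between the H2PO4- and HPO4^2- limiting shifts at 3.27 and
  5.69 ppm from PCr, pK 6.75);
* the beta-ATP resonance moves with Mg2+ binding, so the alpha-beta shift
  difference encodes free intracellular [Mg2+] through a five-species
  equilibrium model.

The generator also produces 2D-CSI k-space data (spatial DFT of a voxel
phantom) and three-group cohorts (CTRL / BMD_pre / BMD_prog) whose
ground-truth biomarker distributions default to the published group medians,
so the full pipeline can be exercised end to end without any acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import EquilibriumConstants, T1Table, default_equilibrium_constants, default_t1_table
from .core import FID, AcquisitionParams, CSIGrid

__all__ = [
    "PH_PK",
    "PH_SHIFT_ACID",
    "PH_SHIFT_BASE",
    "GroundTruth",
    "CohortSpec",
    "CohortMember",
    "shift_from_ph",
    "shift_from_mg",
    "synthesize_fid",
    "synthesize_csi",
    "make_cohort",
    "saturation_factor",
]

# Henderson-Hasselbalch calibration of the Pi shift (ppm from PCr)
PH_PK = 6.75
PH_SHIFT_ACID = 3.27   # H2PO4- limiting shift
PH_SHIFT_BASE = 5.69   # HPO4^2- limiting shift

# Default resonance set: shift (ppm from PCr), Lorentzian FWHM (Hz),
# relative equilibrium amplitude (fraction of PCr).  Pi and beta-ATP shifts
# are derived from ground-truth pH and [Mg2+] at synthesis time.
DEFAULT_SHIFTS: dict[str, float] = {
    "PCr": 0.0,
    "gATP": -2.50,
    "aATP": -7.52,
    "bATP": float("nan"),   # from [Mg2+]
    "PDE": 3.20,
    "Pi_a": float("nan"),   # from pH_a
    "Pi_b": float("nan"),   # from pH_b
}
DEFAULT_DAMPINGS: dict[str, float] = {
    "PCr": 10.0,
    "gATP": 25.0,
    "aATP": 25.0,
    "bATP": 30.0,
    "PDE": 35.0,
    "Pi_a": 15.0,
    "Pi_b": 15.0,
}
DEFAULT_AMPLITUDES: dict[str, float] = {
    "PCr": 1.0,
    "gATP": 0.30,
    "aATP": 0.30,
    "bATP": 0.30,
    "PDE": 0.111,   # overridden by true_pde_gatp in cohorts
    "Pi_a": 0.10,
    "Pi_b": 0.02,   # 20% of Pi_a: a generator choice, not a literature claim
}

# Pi_b is modelled one fixed pH step alkaline of Pi_a (generator choice).
PI_B_PH_OFFSET = 0.30


def shift_from_ph(ph: float) -> float:
    """Pi chemical shift (ppm from PCr) implied by pH; inverse of the
    modified Henderson-Hasselbalch relation.

    ``sigma1 = (3.27 + 5.69 r) / (1 + r)`` with ``r = 10**(ph - 6.75)``;
    the result lies strictly inside (3.27, 5.69) for any finite pH.
    """
    ph = float(ph)
    if not math.isfinite(ph):
        raise ValueError("ph must be finite")
    r = 10.0 ** (ph - PH_PK)
    return (PH_SHIFT_ACID + PH_SHIFT_BASE * r) / (1.0 + r)


def _species_populations(
    mg_mm: float, ph: float, constants: EquilibriumConstants
) -> np.ndarray:
    """Unnormalised populations of (ATP, HATP, MgATP, MgHATP, Mg2ATP)."""
    h = 10.0 ** (-ph)
    m = mg_mm * 1e-3  # mM -> M; formation constants are on the M^-1 scale
    return np.array(
        [
            1.0,
            constants.k_h * h,
            constants.k_mg * m,
            constants.k_h * constants.k_mgh * h * m,
            constants.k_mg2 * constants.k_mg * m * m,
        ]
    )


def shift_from_mg(
    mg: float, ph: float, constants: EquilibriumConstants | None = None
) -> float:
    """Observed alpha-beta ATP shift difference (ppm) at free [Mg2+] ``mg`` (mM).

    Species-population-weighted mean of the five limiting shifts; strictly
    decreasing in ``mg`` (Mg-bound species resonate closer together).
    """
    if mg < 0:
        raise ValueError("mg must be >= 0")
    c = constants if constants is not None else default_equilibrium_constants()
    pops = _species_populations(mg, ph, c)
    deltas = np.array([c.d_atp, c.d_hatp, c.d_mgatp, c.d_mghatp, c.d_mg2atp])
    if c.flip_sign:
        deltas = -deltas
    return float(np.dot(deltas, pops) / pops.sum())


def saturation_factor(t1: float, tr: float, flip_deg: float) -> float:
    """Steady-state partial-saturation factor ``sin(a)(1-E)/(1-E cos(a))``.

    ``E = exp(-tr/t1)``.  Fully relaxed acquisition gives 1; measured
    amplitude = equilibrium amplitude * factor.  Re-exported by the fitting
    module where the inverse correction is applied.
    """
    if t1 <= 0 or tr <= 0:
        raise ValueError("t1 and tr must be > 0")
    if not 0 < flip_deg <= 90:
        raise ValueError("flip angle must be in (0, 90] degrees")
    theta = math.radians(flip_deg)
    e = math.exp(-tr / t1)
    return math.sin(theta) * (1.0 - e) / (1.0 - e * math.cos(theta))


@dataclass
class GroundTruth:
    """Complete description of one synthetic spectrum.

    ``amplitudes`` are the *observed* (saturation-weighted) complex-exponential
    amplitudes actually synthesised; ``shifts`` entries for Pi_a/Pi_b/bATP may
    be NaN, in which case they are derived from ``true_ph_a``/``true_ph_b``/
    ``true_mg`` at synthesis time.  ``phase0`` is a global zero-order phase
    (degrees); ``phase1`` a continuous linear phase ramp across the spectrum
    (degrees/ppm, pivot at the carrier), as produced by a receiver dead-time
    delay.
    """

    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    shifts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SHIFTS))
    dampings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DAMPINGS))
    phase0: float = 0.0
    phase1: float = 0.0
    true_ph_a: float = 7.00
    true_ph_b: float = 7.30
    true_mg: float = 0.72
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be >= 0")
        if self.true_mg < 0:
            raise ValueError("true_mg must be >= 0")
        for ph in (self.true_ph_a, self.true_ph_b):
            s = shift_from_ph(ph)
            if not PH_SHIFT_ACID < s < PH_SHIFT_BASE:
                raise ValueError("pH implies Pi shift outside (3.27, 5.69) ppm")

    @property
    def true_ph_wt(self) -> float:
        """Amplitude-weighted pH implied by the two Pi components."""
        a, b = self.amplitudes.get("Pi_a", 0.0), self.amplitudes.get("Pi_b", 0.0)
        if a + b == 0:
            return self.true_ph_a
        return (self.true_ph_a * a + self.true_ph_b * b) / (a + b)

    def resolved_shifts(self, constants: EquilibriumConstants | None = None) -> dict[str, float]:
        """Shift table with pH- and Mg-dependent entries filled in."""
        shifts = dict(self.shifts)
        if "Pi_a" in self.amplitudes and not math.isfinite(shifts.get("Pi_a", float("nan"))):
            shifts["Pi_a"] = shift_from_ph(self.true_ph_a)
        if "Pi_b" in self.amplitudes and not math.isfinite(shifts.get("Pi_b", float("nan"))):
            shifts["Pi_b"] = shift_from_ph(self.true_ph_b)
        if "bATP" in self.amplitudes and not math.isfinite(shifts.get("bATP", float("nan"))):
            dab = shift_from_mg(self.true_mg, self.true_ph_wt, constants)
            shifts["bATP"] = shifts["aATP"] - dab
        return shifts


def synthesize_fid(
    truth: GroundTruth,
    acq: AcquisitionParams | None = None,
    constants: EquilibriumConstants | None = None,
    provenance: str = "",
) -> FID:
    """Render a GroundTruth as a noisy Lorentzian-damped FID.

    ``fid(t) = sum_k A_k exp(i(2 pi f_k t + phi0)) exp(-pi lw_k t) + noise``
    with a global zero-order phase, a continuous first-order phase ramp
    applied across the spectrum (``phase1`` deg/ppm), and circularly-
    symmetric complex Gaussian noise of SD ``noise_sd`` per channel.
    Bit-reproducible for a given seed.
    """
    acq = acq or AcquisitionParams()
    shifts = truth.resolved_shifts(constants)
    t = acq.time_axis()
    fid = np.zeros(acq.n_points, dtype=complex)
    half_bw = acq.bandwidth / 2.0
    phi0 = math.radians(truth.phase0)
    for name, amp in truth.amplitudes.items():
        if amp == 0:
            continue
        shift = shifts[name]
        f_hz = acq.ppm_to_hz(shift)
        if abs(f_hz) >= half_bw:
            raise ValueError(
                f"resonance {name} at {shift:.2f} ppm ({f_hz:.0f} Hz) falls outside "
                f"the acquisition bandwidth (+/-{half_bw:.0f} Hz)"
            )
        lw = truth.dampings[name]
        fid += amp * np.exp(1j * (2 * np.pi * f_hz * t + phi0)) * np.exp(-np.pi * lw * t)
    if truth.phase1 != 0.0:
        ramp = np.exp(1j * np.deg2rad(truth.phase1) * acq.ppm_axis())
        fid = np.fft.ifft(np.fft.ifftshift(np.fft.fftshift(np.fft.fft(fid)) * ramp))
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        noise = rng.normal(0.0, truth.noise_sd, size=(2, acq.n_points))
        fid = fid + noise[0] + 1j * noise[1]
    return FID(samples=fid, acq=acq, provenance=provenance)


def synthesize_csi(
    phantom: np.ndarray | list,
    acq: AcquisitionParams | None = None,
    constants: EquilibriumConstants | None = None,
    field_of_view: tuple[float, float] = (160.0, 200.0),
) -> CSIGrid:
    """Forward-encode a voxel phantom of GroundTruth objects into CSI k-space.

    ``phantom`` is an (nx, ny) object array; ``None`` entries are empty
    voxels.  k-space is the unnormalised 2D spatial DFT of the voxel FIDs,
    so an inverse DFT recovers the voxel signals exactly when no filter is
    applied.
    """
    acq = acq or AcquisitionParams()
    phantom = np.asarray(phantom, dtype=object)
    if phantom.ndim != 2:
        raise ValueError("phantom must be a 2D voxel map")
    nx, ny = phantom.shape
    voxels = np.zeros((nx, ny, acq.n_points), dtype=complex)
    for ix in range(nx):
        for iy in range(ny):
            truth = phantom[ix, iy]
            if truth is None:
                continue
            voxels[ix, iy] = synthesize_fid(truth, acq, constants).samples
    kspace = np.fft.fft2(voxels, axes=(0, 1))
    return CSIGrid(kspace=kspace, acq=acq, field_of_view=field_of_view, filtered=False)


MUSCLES = ("TA", "TP", "PER", "SOL", "GCL", "GCM")

# Published baseline group medians and IQRs (CTRL / BMD_pre / BMD_prog):
# [Mg2+] (mM), weighted pH, T1-corrected PDE/gATP.
GROUP_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "CTRL": {"mg": (0.72, 0.10), "ph": (7.05, 0.04), "pde_ratio": (0.37, 0.18)},
    "BMD_pre": {"mg": (0.63, 0.16), "ph": (7.08, 0.05), "pde_ratio": (0.45, 0.33)},
    "BMD_prog": {"mg": (0.62, 0.13), "ph": (7.07, 0.05), "pde_ratio": (0.46, 0.23)},
}


@dataclass
class CohortSpec:
    """Sampling plan for one synthetic group.

    Medians/IQRs default to the published baseline values for the group;
    ground-truth biomarkers are drawn from normal distributions with
    ``sd = IQR / 1.349`` (the normal IQR-to-SD factor), truncated to
    physiological ranges.
    """

    group: str = "CTRL"
    n_participants: int = 10
    muscles: tuple[str, ...] = MUSCLES
    mg_median: float | None = None
    mg_iqr: float | None = None
    ph_median: float | None = None
    ph_iqr: float | None = None
    pde_median: float | None = None
    pde_iqr: float | None = None
    snr_target: float = 30.0

    def __post_init__(self) -> None:
        if self.group not in GROUP_DEFAULTS:
            raise ValueError(f"unknown group {self.group!r}; use one of {sorted(GROUP_DEFAULTS)}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.muscles:
            raise ValueError("muscle list must be non-empty")
        defaults = GROUP_DEFAULTS[self.group]
        if self.mg_median is None:
            self.mg_median = defaults["mg"][0]
        if self.mg_iqr is None:
            self.mg_iqr = defaults["mg"][1]
        if self.ph_median is None:
            self.ph_median = defaults["ph"][0]
        if self.ph_iqr is None:
            self.ph_iqr = defaults["ph"][1]
        if self.pde_median is None:
            self.pde_median = defaults["pde_ratio"][0]
        if self.pde_iqr is None:
            self.pde_iqr = defaults["pde_ratio"][1]

    def sd(self, which: str) -> float:
        iqr = {"mg": self.mg_iqr, "ph": self.ph_iqr, "pde_ratio": self.pde_iqr}[which]
        return iqr / 1.349


@dataclass
class CohortMember:
    participant: str
    muscle: str
    group: str
    fid: FID
    truth: GroundTruth


def _truncated_normal(rng: np.random.Generator, median: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(median, lo, hi))
    for _ in range(100):
        x = rng.normal(median, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(median, lo, hi))


def make_cohort(
    spec: CohortSpec,
    seed: int,
    acq: AcquisitionParams | None = None,
    constants: EquilibriumConstants | None = None,
    t1s: T1Table | None = None,
    max_spectra: int | None = None,
) -> tuple[list[CohortMember], pd.DataFrame]:
    """Draw a cohort of (participant, muscle) spectra with known ground truth.

    Per muscle, true [Mg2+], weighted pH and T1-corrected PDE/gATP are drawn
    from the group distributions; the acid Pi component pH is set so that the
    amplitude-weighted pH of the two Pi peaks equals the drawn value, and the
    synthesised amplitudes carry the steady-state saturation weighting that
    the downstream T1 correction removes.  Returns the members and a
    ground-truth manifest (one row per spectrum).
    """
    acq = acq or AcquisitionParams()
    constants = constants or default_equilibrium_constants()
    t1s = t1s or default_t1_table()
    rng = np.random.default_rng(seed)

    amp_a = DEFAULT_AMPLITUDES["Pi_a"]
    amp_b = DEFAULT_AMPLITUDES["Pi_b"]
    w_b = amp_b / (amp_a + amp_b)
    sat = {name: saturation_factor(t1s[name], acq.tr, acq.flip_angle) for name in DEFAULT_AMPLITUDES}

    members: list[CohortMember] = []
    rows = []
    for i in range(spec.n_participants):
        pid = f"{spec.group}{i + 1:03d}"
        for muscle in spec.muscles:
            if max_spectra is not None and len(members) >= max_spectra:
                break
            mg = _truncated_normal(rng, spec.mg_median, spec.sd("mg"), 0.10, 3.0)
            ph_wt = _truncated_normal(rng, spec.ph_median, spec.sd("ph"), 6.60, 7.40)
            pde = _truncated_normal(rng, spec.pde_median, spec.sd("pde_ratio"), 0.05, 2.0)
            ph_a = ph_wt - w_b * PI_B_PH_OFFSET
            ph_b = ph_a + PI_B_PH_OFFSET

            amps0 = dict(DEFAULT_AMPLITUDES)
            amps0["PDE"] = pde * amps0["gATP"]       # equilibrium (T1-corrected) ratio
            amps = {k: v * sat[k] for k, v in amps0.items()}
            # one multiplicative width factor per spectrum: shim-driven B0
            # inhomogeneity broadens all resonances together
            shim = float(np.exp(rng.normal(0.0, 0.08)))
            dampings = {k: v * shim for k, v in DEFAULT_DAMPINGS.items()}
            phase0 = float(rng.uniform(-30, 30))
            phase1 = float(rng.uniform(-2, 2))
            member_seed = int(rng.integers(0, 2**31 - 1))

            truth = GroundTruth(
                amplitudes=amps,
                shifts=dict(DEFAULT_SHIFTS),
                dampings=dampings,
                phase0=phase0,
                phase1=phase1,
                true_ph_a=ph_a,
                true_ph_b=ph_b,
                true_mg=mg,
                noise_sd=0.0,
                seed=member_seed,
            )
            if spec.snr_target and spec.snr_target > 0:
                clean = synthesize_fid(truth, acq, constants)
                peak = float(np.abs(np.fft.fft(clean.samples, norm="ortho")).max())
                truth.noise_sd = peak / spec.snr_target
            fid = synthesize_fid(truth, acq, constants, provenance=f"{pid}/{muscle}")
            members.append(CohortMember(pid, muscle, spec.group, fid, truth))
            rows.append(
                {
                    "participant": pid,
                    "muscle": muscle,
                    "group": spec.group,
                    "true_mg": mg,
                    "true_ph_a": ph_a,
                    "true_ph_b": ph_b,
                    "true_ph_wt": truth.true_ph_wt,
                    "true_pde_gatp": pde,
                    "phase0": phase0,
                    "phase1": phase1,
                    "noise_sd": truth.noise_sd,
                    "seed": member_seed,
                }
            )
    return members, pd.DataFrame(rows)
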