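"""Biomarkers from fitted 31P spectra.

* Intracellular pH per Pi component from the Pi-to-PCr shift difference
  sigma1 via the modified Henderson-Hasselbalch relation
  ``pH = 6.75 + log10((3.27 - sigma1) / (sigma1 - 5.69))`` (valid on the
  open interval 3.27 < sigma1 < 5.69 ppm).
* Weighted pH: the amplitude-weighted mean of the pH values of the two
  fitted Pi components.
* Free intracellular [Mg2+]: root of the five-species equilibrium model of
  the alpha-beta ATP shift difference, solved either by Newton iteration on
  the rational form (reference path, with bisection fallback) or by the
  closed-form quadratic obtained after clearing the denominator (fast path).
  The forward model is strictly monotone in [Mg2+], so the admissible root
  is unique.
* PDE/gamma-ATP, T1-saturation corrected: a membrane-turnover marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, newton

from .amares_fit import FitResult, correct_ratio
from .constants import EquilibriumConstants, T1Table
from .core import AcquisitionParams, QCReport
from .spectra_sim import PH_PK, PH_SHIFT_ACID, PH_SHIFT_BASE, shift_from_mg

__all__ = [
    "MetaboliteMetrics",
    "ShiftOutOfRangeError",
    "UnattainableShiftError",
    "ExcludedSpectrumError",
    "ph_from_shift",
    "weighted_ph",
    "mg_from_shift",
    "pde_gatp_ratio",
    "compute_metrics",
]


class ShiftOutOfRangeError(ValueError):
    """Pi shift outside the open Henderson-Hasselbalch interval."""


class UnattainableShiftError(ValueError):
    """alpha-beta shift outside the range the equilibrium model can produce."""


class ExcludedSpectrumError(RuntimeError):
    """Metrics requested for a QC-excluded spectrum."""


def ph_from_shift(sigma1: float) -> float:
    """Intracellular pH from the Pi-to-PCr shift difference (ppm).

    Strictly increasing on the open interval (3.27, 5.69); the calibration
    endpoints are singular and rejected.
    """
    sigma1 = float(sigma1)
    if not PH_SHIFT_ACID < sigma1 < PH_SHIFT_BASE:
        raise ShiftOutOfRangeError(
            f"sigma1 = {sigma1:.4g} ppm outside the valid open interval "
            f"({PH_SHIFT_ACID}, {PH_SHIFT_BASE}) ppm"
        )
    return PH_PK + math.log10((PH_SHIFT_ACID - sigma1) / (sigma1 - PH_SHIFT_BASE))


def weighted_ph(ph_a: float, ph_b: float, amp_a: float, amp_b: float) -> float:
    """Amplitude-weighted mean pH of the two Pi components."""
    if amp_a < 0 or amp_b < 0:
        raise ValueError("Pi amplitudes must be >= 0")
    total = amp_a + amp_b
    if total == 0:
        raise ValueError("both Pi amplitudes are zero")
    return (ph_a * amp_a + ph_b * amp_b) / total


def _quadratic_mg(delta: float, ph: float, c: EquilibriumConstants) -> float:
    """Closed-form root of the cleared-denominator quadratic, in mM."""
    h = 10.0 ** (-ph)
    dA, dH, dM, dMH, dM2 = c.d_atp, c.d_hatp, c.d_mgatp, c.d_mghatp, c.d_mg2atp
    d = delta
    if c.flip_sign:
        dA, dH, dM, dMH, dM2 = -dA, -dH, -dM, -dMH, -dM2
        d = -delta
    # denominator D(m) = c0 + c1 m + c2 m^2 ; numerator N(m) = n0 + n1 m + n2 m^2
    c0 = 1.0 + c.k_h * h
    c1 = c.k_mg + c.k_h * c.k_mgh * h
    c2 = c.k_mg2 * c.k_mg
    n0 = dA + dH * c.k_h * h
    n1 = dM * c.k_mg + dMH * c.k_h * c.k_mgh * h
    n2 = dM2 * c.k_mg2 * c.k_mg
    a = d * c2 - n2
    b = d * c1 - n1
    cc = d * c0 - n0
    roots = np.roots([a, b, cc]) if a != 0 else np.array([-cc / b])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-12 and r.real >= -1e-15]
    if not real:
        raise UnattainableShiftError(f"no admissible [Mg2+] root for delta = {delta:.4g} ppm")
    # monotonicity guarantees a unique admissible root; pick the one whose
    # forward-model residual is smallest in case of numerical near-ties
    best = min(real, key=lambda m: abs(shift_from_mg(max(m, 0.0) * 1e3, ph, c) - delta))
    return max(best, 0.0) * 1e3


def mg_from_shift(
    delta_obs: float,
    ph_wt: float,
    constants: EquilibriumConstants,
    guess: float = 0.5,
    method: str = "newton",
) -> float:
    """Free intracellular [Mg2+] (mM) from the observed alpha-beta ATP shift.

    ``delta_obs`` must lie strictly inside the attainable range of the
    forward model at this pH (between the infinite-Mg and zero-Mg limits).
    ``method`` selects Newton iteration on the rational form (default;
    bisection fallback on [1e-6, 10] mM) or the cleared-denominator
    quadratic ("quadratic").  Both agree to better than 1e-8 mM.
    """
    if constants is None:
        raise ValueError("an explicit EquilibriumConstants set is required")
    lo_lim = shift_from_mg(1e7, ph_wt, constants)   # infinite-Mg limit (numerically)
    hi_lim = shift_from_mg(0.0, ph_wt, constants)
    lo, hi = sorted((lo_lim, hi_lim))
    if not lo < delta_obs < hi:
        raise UnattainableShiftError(
            f"delta_obs = {delta_obs:.4g} ppm outside the attainable range "
            f"({lo:.4g}, {hi:.4g}) ppm at pH {ph_wt:.2f}; check the fit and the "
            "shift-difference sign convention"
        )
    if method == "quadratic":
        return _quadratic_mg(delta_obs, ph_wt, constants)
    if method != "newton":
        raise ValueError("method must be 'newton' or 'quadratic'")

    def f(mg_mm: float) -> float:
        return shift_from_mg(max(mg_mm, 0.0), ph_wt, constants) - delta_obs

    try:
        root = newton(f, x0=max(guess, 1e-4), tol=1e-12, maxiter=80)
        if root < 0 or abs(f(root)) > 1e-10:
            raise RuntimeError("newton result rejected")
    except (RuntimeError, OverflowError):
        root = brentq(f, 0.0, 1e4, xtol=1e-13)
    if abs(f(root)) > 1e-10:
        raise RuntimeError("[Mg2+] root-finding did not converge")
    return float(root)


def pde_gatp_ratio(fit: FitResult, t1s: T1Table, acq: AcquisitionParams) -> float:
    """T1-corrected PDE / gamma-ATP amplitude ratio from a converged fit."""
    if not fit.converged:
        raise ValueError("fit did not converge; ratio not defined")
    amp_g = fit.amplitude("gATP")
    if amp_g == 0:
        raise ZeroDivisionError("gamma-ATP amplitude is zero")
    return correct_ratio(fit.amplitude("PDE"), amp_g, t1s["PDE"], t1s["gATP"], acq)


@dataclass
class MetaboliteMetrics:
    """Per-muscle biomarker record: the analysis-ready row."""

    ph_a: float = math.nan
    ph_b: float = math.nan
    ph_wt: float = math.nan
    mg: float = math.nan
    pde_gatp: float = math.nan
    snr: float = math.nan
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def compute_metrics(
    fit: FitResult,
    constants: EquilibriumConstants,
    t1s: T1Table,
    acq: AcquisitionParams,
    qc: QCReport | None = None,
) -> MetaboliteMetrics:
    """Assemble all biomarkers from one fitted spectrum.

    Shift differences are taken between fitted centres (Pi - PCr for sigma1,
    alpha - beta ATP for the Mg-sensitive difference), so any residual
    referencing offset cancels.  Borderline fits produce NaN fields plus a
    flag rather than an exception; a QC-excluded input is refused outright.
    """
    if qc is not None and qc.excluded:
        raise ExcludedSpectrumError(f"spectrum excluded ({qc.exclusion_reason.value}): {qc.notes}")
    out = MetaboliteMetrics(snr=qc.snr if qc is not None else math.nan)
    if not fit.converged:
        out.flags.append("fit_not_converged")
        return out

    pcr = fit.shift("PCr")
    try:
        out.ph_a = ph_from_shift(fit.shift("Pi_a") - pcr)
        out.ph_b = ph_from_shift(fit.shift("Pi_b") - pcr)
        out.ph_wt = weighted_ph(out.ph_a, out.ph_b, fit.amplitude("Pi_a"), fit.amplitude("Pi_b"))
    except (ShiftOutOfRangeError, ValueError) as err:
        out.flags.append(f"ph:{err}")

    if math.isfinite(out.ph_wt):
        delta_obs = fit.shift("aATP") - fit.shift("bATP")
        try:
            out.mg = mg_from_shift(delta_obs, out.ph_wt, constants)
        except (UnattainableShiftError, RuntimeError) as err:
            out.flags.append(f"mg:{err}")
    else:
        out.flags.append("mg:weighted pH unavailable")

    try:
        out.pde_gatp = pde_gatp_ratio(fit, t1s, acq)
    except (ValueError, ZeroDivisionError) as err:
        out.flags.append(f"pde_gatp:{err}")
    return out
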