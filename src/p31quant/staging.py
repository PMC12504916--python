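"""Dixon fat-fraction computation and muscle disease staging.

Muscles in Becker muscular dystrophy are grouped by where their baseline fat
fraction sits on the fat-replacement trajectory: 'preserved' (BMD_pre, fat
fraction <= lower threshold), 'progressing' (BMD_prog, strictly between the
thresholds) and 'end-stage' (BMD_end, >= upper threshold; excluded from
biomarker analyses).  The operating thresholds (13.5%, 81.5%) are the two
roots of the lower uncertainty bound of a sigmoid fitted to 24-month
fat-fraction change versus baseline fat fraction: where that lower bound is
positive, fat replacement is credibly progressing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

__all__ = [
    "DEFAULT_THRESHOLDS",
    "MuscleRecord",
    "SigmoidFit",
    "ThresholdDerivationError",
    "fat_fraction",
    "muscle_mean_ff",
    "derive_thresholds",
    "categorize",
]

DEFAULT_THRESHOLDS: tuple[float, float] = (13.5, 81.5)

MUSCLES = ("TA", "TP", "PER", "SOL", "GCL", "GCM")
CATEGORIES = ("CTRL", "BMD_pre", "BMD_prog", "BMD_end")


class ThresholdDerivationError(RuntimeError):
    """The lower bound of the sigmoid fit does not cross zero twice."""


@dataclass
class MuscleRecord:
    participant_id: str
    group: str                      # CTRL or BMD
    muscle: str
    ff_baseline: float              # %
    ff_change_24m: float = np.nan   # percentage points over 24 months
    category: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("CTRL", "BMD"):
            raise ValueError("group must be CTRL or BMD")
        if not 0 <= self.ff_baseline <= 100:
            raise ValueError("fat fraction must be within [0, 100]%")
        if self.category is not None:
            if self.category not in CATEGORIES:
                raise ValueError(f"unknown category {self.category!r}")
            if self.group == "CTRL" and self.category != "CTRL":
                raise ValueError("CTRL records never receive BMD categories")


def fat_fraction(si_fat: float, si_water: float) -> float:
    """Fat fraction in percent: ``SI_fat / (SI_fat + SI_water) * 100``."""
    if si_fat < 0 or si_water < 0:
        raise ValueError("signal intensities must be >= 0")
    total = si_fat + si_water
    if total == 0:
        raise ZeroDivisionError("fat and water signal are both zero")
    return 100.0 * si_fat / total


def muscle_mean_ff(per_slice_ff: Sequence[float], per_slice_area: Sequence[float]) -> float:
    """Area-weighted mean fat fraction across slices (ROI areas in mm^2)."""
    ff = np.asarray(per_slice_ff, dtype=float)
    area = np.asarray(per_slice_area, dtype=float)
    if ff.shape != area.shape:
        raise ValueError("fat-fraction and area lists must have equal length")
    if np.any(area <= 0):
        raise ValueError("slice areas must be > 0")
    return float(np.dot(ff, area) / area.sum())


def progression_curve(x: np.ndarray, amplitude: float, rate: float, offset: float) -> np.ndarray:
    """Expected 24-month fat-fraction change as a function of baseline FF.

    If fat replacement follows sigmoidal (logistic) growth in time toward a
    100% ceiling, a muscle at baseline fraction ``x`` advances to
    ``100 / (1 + exp(-rate) (100 - x)/x)`` one follow-up interval later.
    The implied change-versus-baseline curve rises from zero at 0% FF,
    peaks mid-range, and returns to zero at 100% FF (no room left to
    progress).  ``amplitude`` scales the curve (cohort heterogeneity) and
    ``offset`` absorbs measurement drift.
    """
    x = np.asarray(x, dtype=float)
    decay = math.exp(-rate)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (100.0 - x) / np.maximum(x, 1e-12), np.inf)
    advanced = 100.0 / (1.0 + decay * ratio)
    change = np.where((x > 0) & (x < 100), advanced - x, 0.0)
    return amplitude * change + offset


@dataclass
class SigmoidFit:
    """Sigmoidal-progression fit of fat-fraction change vs baseline FF.

    ``params = (amplitude, rate, offset)`` of :func:`progression_curve`;
    ``covariance`` is the least-squares parameter covariance and
    ``residual_sd`` the residual standard deviation.  ``thresholds`` are the
    two roots of the lower prediction band.  ``params is None`` marks the
    default (literature-derived) operating point.
    """

    params: tuple[float, float, float] | None
    covariance: np.ndarray | None
    thresholds: tuple[float, float]
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not (0 < lo < hi < 100):
            raise ValueError("thresholds must satisfy 0 < lower < upper < 100")

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise ValueError("default SigmoidFit carries no fitted curve")
        return progression_curve(np.asarray(x, dtype=float), *self.params)

    def lower_bound(self, x: np.ndarray) -> np.ndarray:
        """Fit minus one SD of the prediction band (fit SE + residual scatter)."""
        if self.params is None or self.covariance is None:
            raise ValueError("default SigmoidFit carries no fitted curve")
        x = np.asarray(x, dtype=float)
        eps = 1e-6
        grads = []
        for k in range(len(self.params)):
            p_hi = list(self.params)
            p_lo = list(self.params)
            p_hi[k] += eps
            p_lo[k] -= eps
            grads.append((progression_curve(x, *p_hi) - progression_curve(x, *p_lo)) / (2 * eps))
        jac = np.stack(grads, axis=-1)
        var = np.einsum("...i,ij,...j->...", jac, self.covariance, jac)
        return self.predict(x) - np.sqrt(np.maximum(var, 0.0) + self.residual_sd**2)


def derive_thresholds(records: Sequence[MuscleRecord] | pd.DataFrame | None = None) -> SigmoidFit:
    """Fit the progression curve and locate the staging thresholds.

    With no records, returns the published operating point (13.5, 81.5)
    without a fitted curve.  Otherwise fits :func:`progression_curve` to
    (ff_baseline, ff_change_24m) by least squares and returns the outermost
    two roots of the lower prediction band on (0, 100): outside the
    thresholds the band includes zero change, i.e. progression is not
    credible.  Fewer than two roots (e.g. flat change data, where the
    fitted curve collapses onto its offset) is a derivation failure.
    """
    if records is None or (hasattr(records, "__len__") and len(records) == 0):
        return SigmoidFit(params=None, covariance=None, thresholds=DEFAULT_THRESHOLDS)
    if isinstance(records, pd.DataFrame):
        x = records["ff_baseline"].to_numpy(dtype=float)
        y = records["ff_change_24m"].to_numpy(dtype=float)
    else:
        x = np.array([r.ff_baseline for r in records], dtype=float)
        y = np.array([r.ff_change_24m for r in records], dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 20:
        raise ThresholdDerivationError("need at least 20 records spanning the fat-fraction range")

    try:
        params, cov = curve_fit(
            progression_curve, x, y, p0=(1.0, 1.0, 0.0), maxfev=20000,
            bounds=([0.0, 1e-3, -30.0], [20.0, 10.0, 30.0]),
        )
    except RuntimeError as err:
        raise ThresholdDerivationError(f"progression fit failed: {err}") from err
    resid = y - progression_curve(x, *params)
    dof = max(len(x) - len(params), 1)
    fit = SigmoidFit(
        params=tuple(float(p) for p in params),
        covariance=cov,
        thresholds=DEFAULT_THRESHOLDS,
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )

    grid = np.linspace(0.5, 99.5, 991)
    lower = fit.lower_bound(grid)
    sign_changes = np.flatnonzero(np.diff(np.sign(lower)) != 0)
    roots = [
        brentq(lambda v: float(fit.lower_bound(np.array([v]))[0]), grid[i], grid[i + 1])
        for i in sign_changes
    ]
    if len(roots) < 2:
        raise ThresholdDerivationError(
            f"lower bound crosses zero {len(roots)} time(s) in (0, 100); need two"
        )
    fit.thresholds = (float(roots[0]), float(roots[-1]))
    return fit


def categorize(ff_baseline: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Stage a BMD muscle by baseline fat fraction.

    ``<= lower`` -> BMD_pre; strictly between -> BMD_prog; ``>= upper`` ->
    BMD_end (excluded from biomarker analyses).  The boundary conventions
    are inclusive at both thresholds' outer sides, so the three categories
    partition [0, 100] exactly.
    """
    if not 0 <= ff_baseline <= 100:
        raise ValueError("fat fraction must be within [0, 100]%")
    lo, hi = thresholds
    if ff_baseline <= lo:
        return "BMD_pre"
    if ff_baseline >= hi:
        return "BMD_end"
    return "BMD_prog"
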