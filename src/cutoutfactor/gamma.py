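"""Gamma-index comparison of planar relative-output distributions.

The gamma index combines a dose-difference criterion (Delta_D, in percent of
a global normalization value) and a distance-to-agreement criterion (Delta_d,
in mm) into a single per-point quantity:

    gamma(r_ref) = min over r_eval of
                   sqrt( |r_eval - r_ref|^2 / Delta_d^2
                         + delta(r_eval, r_ref)^2 / Delta_D^2 )

where delta is the dose difference between the evaluated point and the
reference point.  A reference point passes when gamma <= 1; the passing rate
is the percentage of passing points among those retained by the low-dose
threshold.  The standard clinical criteria (and the defaults here) are
3% / 3 mm.

Normalization is global at the reference maximum by default, which gives the
best achievable global passing rate; a local mode (per-point denominators) is
available but off by default.

The minimization searches a disk of radius 3 x Delta_d around each reference
point, sampling the evaluated distribution on a bilinearly upsampled grid
(3 x by default) for sub-pixel agreement.  Reference points whose full search
window leaves the evaluated extent are flagged and excluded from the
passing-rate denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["PlanarDistribution", "GammaResult", "gamma_index", "passing_rate"]

#: Fractional slack on the gamma <= 1 pass test, absorbing floating-point
#: round-off when a candidate lands exactly on a criterion boundary.
_PASS_TOL = 1e-9

DEFAULT_LOW_DOSE_THRESHOLD_PCT = 10.0


@dataclass
class PlanarDistribution:
    """Planar relative dose/output grid.

    ``values[row, col]`` with row increasing in y; ``origin`` is the physical
    (x_cm, y_cm) of pixel (0, 0)'s center.
    """

    values: np.ndarray
    resolution_mm: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("distribution must be a non-empty 2-D grid")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distribution values must be finite and non-negative")
        if self.resolution_mm <= 0:
            raise ValueError("resolution must be positive")
        self.values = v

    @property
    def extent_cm(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the pixel-center lattice."""
        res = self.resolution_mm / 10.0
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, x0 + (nx - 1) * res, y0, y0 + (ny - 1) * res)


@dataclass
class GammaResult:
    """Per-point gamma values and the summary passing rate."""

    gamma_map: np.ndarray
    dose_criterion_pct: float
    dta_mm: float
    normalization_value: float
    window_complete: np.ndarray
    reference_values: np.ndarray = field(repr=False)
    passing_rate_pct: float = float("nan")
    n_evaluated: int = 0
    n_edge_excluded: int = 0


def gamma_index(
    reference: PlanarDistribution,
    evaluated: PlanarDistribution,
    dose_pct: float = 3.0,
    dta_mm: float = 3.0,
    search_factor: float = 3.0,
    upsample: int = 3,
    local: bool = False,
    low_dose_threshold_pct: float = DEFAULT_LOW_DOSE_THRESHOLD_PCT,
) -> GammaResult:
    """Compute the gamma map of ``evaluated`` against ``reference``.

    Parameters
    ----------
    reference, evaluated:
        Planar distributions with overlapping physical extents; resolutions
        must match (origins may differ).
    dose_pct:
        Dose-difference criterion Delta_D, percent of the normalization value.
    dta_mm:
        Distance-to-agreement criterion Delta_d in mm.
    search_factor:
        Search-disk radius as a multiple of ``dta_mm``.
    upsample:
        Sub-pixel sampling factor for the evaluated grid (bilinear).
    local:
        Use per-point dose denominators instead of the global reference
        maximum.
    low_dose_threshold_pct:
        Reference-dose cutoff (percent of normalization) for the summary
        passing rate stored on the result.
    """
    if dose_pct <= 0 or dta_mm <= 0:
        raise ValueError("gamma criteria must be positive")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if abs(reference.resolution_mm - evaluated.resolution_mm) > 1e-9:
        raise ValueError("reference and evaluated resolutions must match")
    rx0, rx1, ry0, ry1 = reference.extent_cm
    ex0, ex1, ey0, ey1 = evaluated.extent_cm
    if rx1 < ex0 or ex1 < rx0 or ry1 < ey0 or ey1 < ry0:
        raise ValueError("reference and evaluated extents are disjoint")

    norm = float(reference.values.max())
    if norm <= 0:
        raise ValueError("zero normalization value (reference maximum)")

    res_cm = reference.resolution_mm / 10.0
    step_cm = res_cm / upsample
    step_mm = reference.resolution_mm / upsample
    radius_mm = search_factor * dta_mm
    noff = int(math.floor(radius_mm / step_mm + 1e-9))

    # evaluated values sampled once onto the reference lattice refined by
    # `upsample` and extended by the search radius; NaN outside its extent
    ny, nx = reference.values.shape
    fy = reference.origin[1] + np.arange(-noff, (ny - 1) * upsample + noff + 1) * step_cm
    fx = reference.origin[0] + np.arange(-noff, (nx - 1) * upsample + noff + 1) * step_cm
    ey = evaluated.origin[1] + np.arange(evaluated.values.shape[0]) * res_cm
    ex = evaluated.origin[0] + np.arange(evaluated.values.shape[1]) * res_cm
    interp = RegularGridInterpolator(
        (ey, ex), evaluated.values, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    fine = interp(np.stack([FY.ravel(), FX.ravel()], axis=1)).reshape(FY.shape)

    ref = reference.values
    if local:
        dose_denom = (dose_pct / 100.0) * np.where(ref > 0, ref, np.inf)
    else:
        dose_denom = (dose_pct / 100.0) * norm

    best = np.full(ref.shape, np.inf)
    complete = np.ones(ref.shape, dtype=bool)
    for oy in range(-noff, noff + 1):
        for ox in range(-noff, noff + 1):
            d_mm = step_mm * math.hypot(oy, ox)
            if d_mm > radius_mm + 1e-9:
                continue
            cand = fine[noff + oy :: upsample, noff + ox :: upsample][:ny, :nx]
            g2 = (d_mm / dta_mm) ** 2 + ((cand - ref) / dose_denom) ** 2
            best = np.fmin(best, g2)  # fmin ignores NaN candidates
            complete &= np.isfinite(cand)
    gamma_map = np.sqrt(best)

    result = GammaResult(
        gamma_map=gamma_map,
        dose_criterion_pct=float(dose_pct),
        dta_mm=float(dta_mm),
        normalization_value=norm,
        window_complete=complete,
        reference_values=ref,
    )
    try:
        result.passing_rate_pct = passing_rate(result, low_dose_threshold_pct)
    except ValueError:
        pass  # no points above threshold; rate stays NaN
    return result


def passing_rate(
    result: GammaResult,
    low_dose_threshold_pct: float = DEFAULT_LOW_DOSE_THRESHOLD_PCT,
) -> float:
    """Percentage of points with gamma <= 1 above the low-dose threshold.

    Points whose reference value is below ``low_dose_threshold_pct`` percent
    of the normalization value, and points whose search window exits the
    evaluated extent, are excluded from the denominator (a threshold of 0
    reproduces the unmasked rate over complete-window points).
    """
    if low_dose_threshold_pct < 0:
        raise ValueError("threshold must be non-negative")
    cutoff = (low_dose_threshold_pct / 100.0) * result.normalization_value
    include = (
        (result.reference_values >= cutoff)
        & result.window_complete
        & np.isfinite(result.gamma_map)
    )
    n = int(np.count_nonzero(include))
    if n == 0:
        raise ValueError("no points above the low-dose threshold")
    passed = np.count_nonzero(result.gamma_map[include] <= 1.0 + _PASS_TOL)
    result.n_evaluated = n
    result.n_edge_excluded = int(np.count_nonzero(~result.window_complete))
    return 100.0 * passed / n
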