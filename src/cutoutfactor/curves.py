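"""Circular-field output-factor curves.

An electron *output factor* (OF) is the ratio of dose per monitor unit for a
given field to that of the reference open applicator (here a 10 x 10 cm cone),
measured on the central axis at the depth of maximum dose, d_max.  Cutout
output-factor prediction starts from OF measurements for a family of circular
cutouts of increasing radius at one (beam energy, SSD) combination.  This
module represents those measurements as a continuous curve OF(r):

* the curve interpolates every measured sample exactly,
* it extrapolates as a constant plateau beyond the largest measured radius
  (measured circular-field curves level off by r ~ 4 cm),
* it descends monotonically to OF(0) = 0 below the smallest radius.

The origin convention OF(0) = 0 is what makes the downstream annular kernel
telescope exactly: summing the kernel over a disk of radius R returns OF(R)
identically, so circular fields are reproduced by construction.

The module also provides the inverse-square extension of a nominal-SSD curve
to an extended SSD using the effective SSD (the distance from the virtual
electron source to the nominal-SSD plane), and the symmetric percentage
difference used to compare output factors computed from two kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "BeamGeometry",
    "OutputFactorCurve",
    "fit_curve",
    "extend_by_inverse_square",
    "merge_curves",
    "inverse_square_factor",
    "percentage_difference",
]

#: Default smallest radius (cm) covered by the inverse-square extension.
DEFAULT_ISL_MIN_RADIUS_CM = 4.0

_INTERPOLATION_MODES = ("monotone_cubic", "linear")


@dataclass(frozen=True)
class BeamGeometry:
    """Source-to-surface geometry for one electron beam setup.

    Parameters
    ----------
    ssd0_cm:
        Nominal source-to-surface distance (cm); 100 cm for standard setups.
    ssd_ext_cm:
        Extended SSD (cm) at which the output factor is wanted.
    ssd_eff_cm:
        Effective SSD (cm): distance from the virtual electron source to the
        nominal-SSD plane.  Taken from commissioning data, not estimated here.
    dmax_cm:
        Depth of maximum dose (cm) for this energy.
    """

    ssd0_cm: float = 100.0
    ssd_ext_cm: float = 100.0
    ssd_eff_cm: float = 95.0
    dmax_cm: float = 1.5

    def __post_init__(self) -> None:
        for name in ("ssd0_cm", "ssd_ext_cm", "ssd_eff_cm", "dmax_cm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite length, got {v!r}")


def inverse_square_factor(geom: BeamGeometry) -> float:
    """Inverse-square ratio OF_0 / OF_ext for extending a curve to a larger SSD.

    The factor is ((SSD_eff + d_max + SSD_ext - SSD_0) / (SSD_eff + d_max))**2,
    i.e. the squared ratio of virtual-source-to-point distances at the extended
    and nominal setups.  It exceeds 1 whenever SSD_ext > SSD_0.
    """
    denom = geom.ssd_eff_cm + geom.dmax_cm
    if denom <= 0:
        raise ValueError("SSD_eff + d_max must be positive")
    return ((denom + geom.ssd_ext_cm - geom.ssd0_cm) / denom) ** 2


@dataclass
class OutputFactorCurve:
    """Measured (or derived) circular-cutout output factors at one (energy, SSD).

    The curve is evaluable on the whole continuous domain r >= 0: it passes
    through every sample exactly, is pinned to OF(0) = 0, and is constant at
    the plateau value beyond the largest sample.

    Attributes
    ----------
    radii_cm:
        Strictly increasing, positive sample radii (cm).
    of_values:
        Positive, dimensionless output factors at those radii.
    energy_label:
        Free-text beam label, e.g. ``"6E"``.
    ssd_cm:
        Source-to-surface distance of the measurement (cm).
    interpolation:
        ``"monotone_cubic"`` (shape-preserving PCHIP; default) or ``"linear"``.
    isl_derived:
        True when the samples were derived from an inverse-square extension
        rather than measured directly.
    """

    radii_cm: np.ndarray
    of_values: np.ndarray
    energy_label: str = ""
    ssd_cm: float = 100.0
    interpolation: str = "monotone_cubic"
    isl_derived: bool = False
    _interp: PchipInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_cm, dtype=float)
        v = np.asarray(self.of_values, dtype=float)
        if r.ndim != 1 or v.ndim != 1 or r.size != v.size:
            raise ValueError("radii and output factors must be 1-D and equal-length")
        if r.size < 2:
            raise ValueError("insufficient samples: need at least 2 (radius, OF) pairs")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(v))):
            raise ValueError("radii and output factors must be finite")
        if np.any(r <= 0):
            raise ValueError("sample radii must be positive")
        if np.any(np.diff(r) <= 0):
            raise ValueError("sample radii must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("output factors must be positive")
        if self.interpolation not in _INTERPOLATION_MODES:
            raise ValueError(
                f"interpolation must be one of {_INTERPOLATION_MODES}, "
                f"got {self.interpolation!r}"
            )
        self.radii_cm = r
        self.of_values = v
        if self.interpolation == "monotone_cubic":
            knots = np.concatenate(([0.0], r))
            vals = np.concatenate(([self.origin_value], v))
            self._interp = PchipInterpolator(knots, vals, extrapolate=False)

    @property
    def origin_value(self) -> float:
        """OF at r = 0 (zero: a fully blocked field delivers no output)."""
        return 0.0

    @property
    def plateau(self) -> float:
        """Asymptotic OF used for constant extrapolation beyond ``r_max``."""
        return float(self.of_values[-1])

    @property
    def r_max_cm(self) -> float:
        """Largest measured radius (cm)."""
        return float(self.radii_cm[-1])

    def evaluate(self, r_cm):
        """Evaluate OF at radius ``r_cm`` (cm); scalar or array.

        Returns the measured value exactly at measured radii, the plateau for
        r > r_max, and 0 at r = 0.  Negative or non-finite radii are errors.
        """
        r = np.asarray(r_cm, dtype=float)
        if not np.all(np.isfinite(r)):
            raise ValueError("radius must be finite")
        if np.any(r < 0):
            raise ValueError("radius must be non-negative")
        rc = np.minimum(r, self.r_max_cm)
        if self.interpolation == "linear":
            out = np.interp(rc, np.concatenate(([0.0], self.radii_cm)),
                            np.concatenate(([self.origin_value], self.of_values)))
        else:
            out = self._interp(rc)
        if np.isscalar(r_cm) or r.ndim == 0:
            return float(out)
        return np.asarray(out, dtype=float)

    def __call__(self, r_cm):
        return self.evaluate(r_cm)


def fit_curve(
    radii_cm,
    of_values,
    energy_label: str = "",
    ssd_cm: float = 100.0,
    interpolation: str = "monotone_cubic",
) -> OutputFactorCurve:
    """Fit an interpolating output-factor curve through measured samples.

    The fit is a shape-preserving monotone piecewise cubic (PCHIP) through
    (0, 0) and all samples, so monotone measurements give a monotone curve
    with no overshoot; ``interpolation="linear"`` selects piecewise-linear
    segments instead.  Beyond the largest radius the curve is the constant
    plateau value.
    """
    return OutputFactorCurve(
        radii_cm=np.asarray(radii_cm, dtype=float),
        of_values=np.asarray(of_values, dtype=float),
        energy_label=energy_label,
        ssd_cm=ssd_cm,
        interpolation=interpolation,
    )


def extend_by_inverse_square(
    curve: OutputFactorCurve,
    geom: BeamGeometry,
    min_radius_cm: float = DEFAULT_ISL_MIN_RADIUS_CM,
) -> OutputFactorCurve:
    """Derive extended-SSD output factors for large radii from a nominal curve.

    For radii >= ``min_radius_cm`` (default 4 cm, where the effective SSD no
    longer changes appreciably with field size) the extended-SSD output factor
    is OF_ext(r) = OF_0(r) / inverse_square_factor(geom).  Samples below the
    cutoff cannot be derived this way and must come from direct extended-SSD
    measurements; combine them with :func:`merge_curves`.

    Returns a curve containing only the derived subset, flagged with
    ``isl_derived=True`` and carrying ``ssd_cm = geom.ssd_ext_cm``.
    """
    if geom.ssd_ext_cm < geom.ssd0_cm:
        raise ValueError("SSD_ext must be >= SSD_0 for the extension use case")
    factor = inverse_square_factor(geom)
    keep = curve.radii_cm >= min_radius_cm
    if np.count_nonzero(keep) < 2:
        raise ValueError(
            f"insufficient samples: need >= 2 radii at or above {min_radius_cm} cm"
        )
    return OutputFactorCurve(
        radii_cm=curve.radii_cm[keep].copy(),
        of_values=curve.of_values[keep] / factor,
        energy_label=curve.energy_label,
        ssd_cm=geom.ssd_ext_cm,
        interpolation=curve.interpolation,
        isl_derived=True,
    )


def merge_curves(
    measured_small: OutputFactorCurve,
    derived_large: OutputFactorCurve,
    split_radius_cm: float = DEFAULT_ISL_MIN_RADIUS_CM,
) -> OutputFactorCurve:
    """Combine directly measured small radii with inverse-square-derived large radii.

    Samples with r < ``split_radius_cm`` come from ``measured_small`` and the
    rest from ``derived_large``; both curves must be at the same SSD.
    """
    if abs(measured_small.ssd_cm - derived_large.ssd_cm) > 1e-9:
        raise ValueError(
            "cannot merge curves at different SSDs "
            f"({measured_small.ssd_cm} vs {derived_large.ssd_cm} cm)"
        )
    lo = measured_small.radii_cm < split_radius_cm
    hi = derived_large.radii_cm >= split_radius_cm
    radii = np.concatenate((measured_small.radii_cm[lo], derived_large.radii_cm[hi]))
    vals = np.concatenate((measured_small.of_values[lo], derived_large.of_values[hi]))
    return OutputFactorCurve(
        radii_cm=radii,
        of_values=vals,
        energy_label=measured_small.energy_label or derived_large.energy_label,
        ssd_cm=measured_small.ssd_cm,
        interpolation=measured_small.interpolation,
        isl_derived=derived_large.isl_derived,
    )


def percentage_difference(cof_a: float, cof_b: float) -> float:
    """Symmetric percentage difference between two output factors.

    100 * |a - b| / (0.5 * (a + b)): the absolute difference relative to the
    arithmetic mean.  Symmetric, non-negative, and zero iff the values agree.
    """
    if not (math.isfinite(cof_a) and math.isfinite(cof_b)):
        raise ValueError("output factors must be finite")
    if cof_a <= 0 or cof_b <= 0:
        raise ValueError("output factors must be positive")
    return 100.0 * abs(cof_a - cof_b) / (0.5 * (cof_a + cof_b))
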