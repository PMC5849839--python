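"""Synthetic inputs with the structure the convolution method assumes.

Real commissioning data — circular-cutout output-factor tables, cutout
polygons, film scans — are site-specific.  These generators emulate their
structure so that every stage of the pipeline is testable end to end:

* output-factor curves rise monotonically and plateau by r ~ 4 cm at an
  energy-dependent asymptote, like measured circular-field data (saturating
  exponential family; any monotone family with a plateau would do — this is
  a fixture, not a physics model);
* cutout shapes: circles, rectangles, and radially perturbed irregular
  outlines like clinical breast-boost cutouts;
* "film" distributions: a computed output map with sub-pixel misregistration
  and Gaussian noise, as a stand-in for a digitized film measurement.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .curves import OutputFactorCurve, fit_curve
from .engine import COFMap
from .gamma import PlanarDistribution
from .geometry import CutoutShape

__all__ = [
    "CurveModelParams",
    "PRESETS",
    "DEFAULT_RADII_CM",
    "synth_of_curve",
    "synth_cutout",
    "synth_film",
]

#: Measurement radii mirroring a circular-cutout commissioning protocol:
#: 1 to 6 cm in 1 cm steps (6 cm is the largest circle that fits a 15 x 15 cone).
DEFAULT_RADII_CM = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass(frozen=True)
class CurveModelParams:
    """Parameters of the saturating-exponential output-factor model.

    OF(r) = plateau * (1 - exp(-(r / rise_scale_cm) ** shape_exponent))

    ``plateau`` is the large-field asymptote; ``rise_scale_cm`` sets how fast
    lateral scatter equilibrium is reached (larger = slower rise, as for
    low-energy beams whose kernels spread towards the edge); the exponent
    shapes the knee.  ``noise_sd`` adds zero-mean Gaussian measurement noise
    (absolute OF units), truncated to keep samples positive.
    """

    plateau: float = 1.0
    rise_scale_cm: float = 1.6
    shape_exponent: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.plateau > 0 and self.rise_scale_cm > 0):
            raise ValueError("plateau and rise scale must be positive")
        if self.shape_exponent < 1:
            raise ValueError("shape exponent must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def noiseless(self, r):
        r = np.asarray(r, dtype=float)
        return self.plateau * (1.0 - np.exp(-((r / self.rise_scale_cm) ** self.shape_exponent)))


#: Beam-energy presets.  Asymptotes 1.0 / 0.9 / 0.8 mirror typical 6, 9 and
#: 15 MeV circular-field curves; the rise scale shrinks with energy so the
#: low-energy kernel spreads towards its edge while the high-energy kernel
#: concentrates output at the center.
PRESETS: dict[str, CurveModelParams] = {
    "6E-like": CurveModelParams(plateau=1.0, rise_scale_cm=1.6, shape_exponent=2.0),
    "9E-like": CurveModelParams(plateau=0.9, rise_scale_cm=1.2, shape_exponent=1.8),
    "15E-like": CurveModelParams(plateau=0.8, rise_scale_cm=0.9, shape_exponent=1.6),
}


def synth_of_curve(
    params: CurveModelParams,
    radii_cm=DEFAULT_RADII_CM,
    energy_label: str = "",
    ssd_cm: float = 100.0,
    interpolation: str = "monotone_cubic",
) -> OutputFactorCurve:
    """Generate a synthetic circular-cutout output-factor curve.

    Samples the saturating-exponential model at ``radii_cm`` and adds seeded
    truncated-Gaussian noise; with ``noise_sd=0`` the curve is strictly
    increasing towards the plateau.
    """
    radii = np.asarray(radii_cm, dtype=float)
    of = params.noiseless(radii)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        noise = rng.normal(0.0, params.noise_sd, size=radii.shape)
        of = np.maximum(of + noise, 1e-6)
    return fit_curve(radii, of, energy_label=energy_label, ssd_cm=ssd_cm,
                     interpolation=interpolation)


def synth_cutout(
    kind: str,
    *,
    radius_cm: float = 3.0,
    width_cm: float = 4.0,
    height_cm: float = 6.0,
    amplitude: float = 0.3,
    n_harmonics: int = 4,
    n_vertices: int = 128,
    center=(0.0, 0.0),
    seed: int = 0,
    label: str = "",
) -> CutoutShape:
    """Generate a synthetic cutout polygon.

    ``kind="circle"``: regular ``n_vertices``-gon of radius ``radius_cm``.
    ``kind="rectangle"``: axis-aligned ``width_cm`` x ``height_cm`` rectangle.
    ``kind="irregular"``: radial perturbation of a circle,
    r(theta) = R * (1 + a * sum_k c_k sin(k theta + phi_k)) with seeded
    coefficients normalized so the total perturbation stays within +-a; for
    amplitude a < 0.5 the outline is star-shaped, hence simple.
    """
    cx, cy = center
    if kind == "circle":
        if radius_cm <= 0:
            raise ValueError("radius must be positive")
        theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        verts = np.column_stack([cx + radius_cm * np.cos(theta),
                                 cy + radius_cm * np.sin(theta)])
    elif kind == "rectangle":
        if width_cm <= 0 or height_cm <= 0:
            raise ValueError("rectangle dimensions must be positive")
        w, h = width_cm / 2.0, height_cm / 2.0
        verts = np.array([[cx - w, cy - h], [cx + w, cy - h],
                          [cx + w, cy + h], [cx - w, cy + h]])
    elif kind == "irregular":
        if radius_cm <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= amplitude < 0.5:
            raise ValueError("amplitude must be in [0, 0.5) to guarantee a simple outline")
        rng = np.random.default_rng(seed)
        k = np.arange(1, n_harmonics + 1)
        coeff = rng.uniform(0.3, 1.0, size=n_harmonics)
        coeff /= coeff.sum()
        phase = rng.uniform(0.0, 2.0 * math.pi, size=n_harmonics)
        theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        r = radius_cm * (1.0 + amplitude * (coeff[None, :]
                         * np.sin(k[None, :] * theta[:, None] + phase[None, :])).sum(axis=1))
        verts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    else:
        raise ValueError(f"unknown cutout kind {kind!r}")
    return CutoutShape(vertices=verts, label=label or kind)


def synth_film(
    cof_map: COFMap,
    noise_sd_pct: float = 0.0,
    shift_mm: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> PlanarDistribution:
    """Emulate a registered planar film measurement of a computed output map.

    The map is resampled with a (possibly sub-pixel) rigid shift — the film
    appears shifted by ``shift_mm`` = (dx, dy) relative to the computation —
    then seeded Gaussian noise of ``noise_sd_pct`` percent of the map maximum
    is added, clipped at zero.  Regions shifted in from outside the map are
    blocked (zero).
    """
    if noise_sd_pct < 0:
        raise ValueError("noise SD must be non-negative")
    res_cm = cof_map.resolution_mm / 10.0
    ny, nx = cof_map.values.shape
    ys = cof_map.origin[1] + np.arange(ny) * res_cm
    xs = cof_map.origin[0] + np.arange(nx) * res_cm
    interp = RegularGridInterpolator((ys, xs), cof_map.values, method="linear",
                                     bounds_error=False, fill_value=0.0)
    dx_cm, dy_cm = shift_mm[0] / 10.0, shift_mm[1] / 10.0
    YY, XX = np.meshgrid(ys - dy_cm, xs - dx_cm, indexing="ij")
    values = interp(np.stack([YY.ravel(), XX.ravel()], axis=1)).reshape(ny, nx)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd_pct / 100.0 * float(cof_map.values.max())
        values = values + rng.normal(0.0, sd, size=values.shape)
    values = np.maximum(values, 0.0)
    return PlanarDistribution(values=values, resolution_mm=cof_map.resolution_mm,
                              origin=cof_map.origin)
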