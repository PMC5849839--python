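"""Annular convolution kernels built from circular-field output factors.

The field behind a cutout is decomposed into concentric annuli.  The annular
output factor (AOF) of the annulus (r, r + dr) is the OF difference between
the circular fields of radius r + dr and r.  Distributing each AOF uniformly
over the pixels whose centers fall in that annulus yields a circularly
symmetric 2-D kernel OK[n1, n2] of per-pixel output contributions at (by
default) 1 mm resolution.  Convolving this kernel with a binary aperture mask
then integrates the contribution of every open pixel, giving the cutout
output factor at every point of the plane.

Because OF(0) = 0, the per-annulus weights telescope: the kernel summed over
the annulus-binned disk of radius K*dr equals OF(K*dr) exactly, so circular
fields are reproduced by construction irrespective of the pixel size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .curves import OutputFactorCurve

__all__ = ["ConvolutionKernel", "annulus_index", "build_kernel", "kernel_profile"]

# tolerance (in units of delta_r) for pixel distances that land exactly on an
# annulus boundary: floor(d/dr + EPS) keeps Pythagorean-exact distances such
# as hypot(3,4)=5 in the outer, half-open bin [5, 6).
_BIN_EPS = 1e-9


@dataclass
class ConvolutionKernel:
    """Circularly symmetric per-pixel output-contribution kernel.

    Attributes
    ----------
    values:
        M x M array (M odd) of dimensionless per-pixel contributions; all
        pixels in one annulus share one value and pixels beyond the support
        radius are zero.
    resolution_mm:
        Pixel pitch in mm (1 mm by default).
    delta_r_mm:
        Annulus width in mm; defaults to the pixel pitch.
    center_index:
        (row, col) of the r = 0 pixel — the exact middle of the grid.
    max_radius_cm:
        Support radius in cm.
    energy_label, ssd_cm:
        Provenance of the source curve.
    has_negative_aof:
        True when the source curve produced at least one negative annular
        output factor (possible measurement noise).
    """

    values: np.ndarray
    resolution_mm: float
    delta_r_mm: float
    center_index: tuple[int, int]
    max_radius_cm: float
    energy_label: str = ""
    ssd_cm: float = 100.0
    has_negative_aof: bool = False

    @property
    def n_annuli(self) -> int:
        return int(math.floor(10.0 * self.max_radius_cm / self.delta_r_mm + _BIN_EPS))

    @property
    def half_width(self) -> int:
        return self.center_index[0]

    def annulus_indices(self) -> np.ndarray:
        """Annulus index of every kernel pixel."""
        half = self.half_width
        offs = np.arange(-half, half + 1)
        d_mm = self.resolution_mm * np.hypot(offs[:, None], offs[None, :])
        return np.floor(d_mm / self.delta_r_mm + _BIN_EPS).astype(int)


def annulus_index(
    offset_row: int, offset_col: int, resolution_mm: float, delta_r_mm: float
) -> int:
    """Annulus bin of a pixel at integer grid offset from the kernel center.

    Bins are half-open: pixel-center distance d = resolution * hypot(row, col)
    falls in annulus k when k*dr <= d < (k+1)*dr.
    """
    if not math.isfinite(delta_r_mm) or delta_r_mm <= 0:
        raise ValueError("delta_r must be positive")
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    d = resolution_mm * math.hypot(offset_row, offset_col)
    return int(math.floor(d / delta_r_mm + _BIN_EPS))


def build_kernel(
    curve: OutputFactorCurve,
    resolution_mm: float = 1.0,
    max_radius_cm: float | None = None,
    delta_r_mm: float | None = None,
    clip_negative_aof: bool = False,
    negative_aof_error: bool = False,
) -> ConvolutionKernel:
    """Build the 2-D annular output kernel from an output-factor curve.

    For each annulus k the annular output factor is
    AOF_k = OF((k+1)*dr) - OF(k*dr); every pixel whose center lies in annulus
    k receives AOF_k / NP_k, where NP_k counts the kernel pixels in that
    annulus.  Pixels beyond ``max_radius_cm`` are zero.

    Parameters
    ----------
    curve:
        Source output-factor curve, evaluable up to ``max_radius_cm``.
    resolution_mm:
        Pixel pitch; 1 mm default.
    max_radius_cm:
        Kernel support radius; defaults to the curve's largest measured
        radius (beyond which the annular differences vanish anyway under the
        constant-plateau extrapolation).
    delta_r_mm:
        Annulus width; defaults to ``resolution_mm``.
    clip_negative_aof:
        Clip negative AOF values (noisy measurements) to zero.  Off by
        default because clipping breaks the telescoping identity; a warning
        is emitted and the kernel flagged instead.
    negative_aof_error:
        Raise instead of warn on negative AOF.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    if delta_r_mm is None:
        delta_r_mm = resolution_mm
    if delta_r_mm <= 0:
        raise ValueError("delta_r must be positive")
    if max_radius_cm is None:
        max_radius_cm = curve.r_max_cm
    n_annuli = int(math.floor(10.0 * max_radius_cm / delta_r_mm + _BIN_EPS))
    if n_annuli < 1 or 10.0 * max_radius_cm < resolution_mm:
        raise ValueError("max_radius must cover at least one pixel/annulus")

    edges_cm = np.arange(n_annuli + 1) * (delta_r_mm / 10.0)
    of_at_edges = curve.evaluate(edges_cm)
    aof = np.diff(of_at_edges)
    # ignore interpolation round-off (~1e-18) on flat plateaus; real
    # measurement noise produces differences orders of magnitude larger
    has_negative = bool(np.any(aof < -1e-12))
    if has_negative:
        if negative_aof_error:
            raise ValueError("negative annular output factor (non-monotone curve)")
        warnings.warn(
            "negative annular output factor encountered (possible measurement "
            "noise); kernel flagged via has_negative_aof",
            RuntimeWarning,
            stacklevel=2,
        )
        if clip_negative_aof:
            aof = np.maximum(aof, 0.0)

    # largest integer pixel offset strictly inside the support radius
    q = n_annuli * delta_r_mm / resolution_mm
    half = int(math.floor(q - _BIN_EPS))
    offs = np.arange(-half, half + 1)
    d_mm = resolution_mm * np.hypot(offs[:, None], offs[None, :])
    kidx = np.floor(d_mm / delta_r_mm + _BIN_EPS).astype(int)
    inside = kidx < n_annuli
    counts = np.bincount(kidx[inside], minlength=n_annuli)
    per_pixel = np.zeros(n_annuli)
    occupied = counts > 0
    per_pixel[occupied] = aof[occupied] / counts[occupied]
    values = np.where(inside, per_pixel[np.minimum(kidx, n_annuli - 1)], 0.0)

    return ConvolutionKernel(
        values=values,
        resolution_mm=float(resolution_mm),
        delta_r_mm=float(delta_r_mm),
        center_index=(half, half),
        max_radius_cm=float(max_radius_cm),
        energy_label=curve.energy_label,
        ssd_cm=curve.ssd_cm,
        has_negative_aof=has_negative,
    )


def kernel_profile(kernel: ConvolutionKernel) -> list[tuple[float, float]]:
    """Per-annulus radial profile: (inner radius in cm, per-pixel value).

    One entry per annulus of the support; annuli that contain no kernel pixel
    (possible for coarse pixels and narrow annuli) report a value of 0.
    """
    kidx = kernel.annulus_indices()
    n = kernel.n_annuli
    inside = kidx < n
    counts = np.bincount(kidx[inside], minlength=n)
    sums = np.bincount(kidx[inside], weights=kernel.values[inside], minlength=n)
    radii = np.arange(n) * kernel.delta_r_mm / 10.0
    prof = np.zeros(n)
    occ = counts > 0
    prof[occ] = sums[occ] / counts[occ]
    return [(float(r), float(v)) for r, v in zip(radii, prof)]
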