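"""Plain-text CSV readers/writers for curves, polygons, kernels, masks and maps.

All grid files share one dialect: `# key=value` header lines followed by a
dense comma-separated grid, written at full float precision so that a
write -> read round-trip is bit-exact.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np

from .curves import OutputFactorCurve, fit_curve
from .engine import COFMap
from .gamma import PlanarDistribution
from .geometry import ApertureMask, CutoutShape
from .kernel import ConvolutionKernel

__all__ = [
    "read_curve", "write_curve",
    "read_shape", "write_shape",
    "read_kernel", "write_kernel",
    "read_mask", "write_mask",
    "read_cof_map", "write_cof_map",
    "read_planar", "write_planar",
]

_FMT = "%.17g"  # round-trips float64 exactly


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        for token in line.lstrip("#").split():
            if "=" in token:
                key, val = token.split("=", 1)
                meta[key] = val
    return meta


def _split_file(path) -> tuple[dict[str, str], list[str]]:
    header, body = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        (header if line.startswith("#") else body).append(line)
    return _parse_header(header), body


def write_curve(curve: OutputFactorCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# energy={curve.energy_label} ssd_cm={_FMT % curve.ssd_cm}\n")
        fh.write(f"# interpolation={curve.interpolation} isl_derived={int(curve.isl_derived)}\n")
        fh.write("radius_cm,output_factor\n")
        for r, v in zip(curve.radii_cm, curve.of_values):
            fh.write(f"{_FMT % r},{_FMT % v}\n")


def read_curve(path) -> OutputFactorCurve:
    meta, body = _split_file(path)
    if body and body[0].lower().startswith("radius"):
        body = body[1:]
    rows = [tuple(float(x) for x in line.split(",")) for line in body]
    if not rows:
        raise ValueError(f"no samples in curve file {path}")
    radii, of = zip(*rows)
    curve = fit_curve(
        radii, of,
        energy_label=meta.get("energy", ""),
        ssd_cm=float(meta.get("ssd_cm", 100.0)),
        interpolation=meta.get("interpolation", "monotone_cubic"),
    )
    curve.isl_derived = bool(int(meta.get("isl_derived", 0)))
    return curve


def write_shape(shape: CutoutShape, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label={shape.label}\n")
        fh.write("# x_cm,y_cm — vertices of a closed simple polygon\n")
        for x, y in shape.vertices:
            fh.write(f"{_FMT % x},{_FMT % y}\n")


def read_shape(path) -> CutoutShape:
    meta, body = _split_file(path)
    body = [line for line in body if not line[0].isalpha()]
    verts = np.array([[float(x) for x in line.split(",")] for line in body])
    return CutoutShape(vertices=verts, label=meta.get("label", ""))


def _write_grid(values: np.ndarray, header: str, path) -> None:
    buf = _stdio.StringIO()
    np.savetxt(buf, values, fmt=_FMT, delimiter=",")
    Path(path).write_text(header + buf.getvalue())


def _read_grid(body: list[str]) -> np.ndarray:
    return np.array([[float(x) for x in line.split(",")] for line in body])


def write_kernel(kernel: ConvolutionKernel, path) -> None:
    header = (
        f"# resolution_mm={_FMT % kernel.resolution_mm} "
        f"delta_r_mm={_FMT % kernel.delta_r_mm} "
        f"center={kernel.center_index[0]},{kernel.center_index[1]} "
        f"max_radius_cm={_FMT % kernel.max_radius_cm}\n"
        f"# energy={kernel.energy_label} ssd_cm={_FMT % kernel.ssd_cm} "
        f"has_negative_aof={int(kernel.has_negative_aof)}\n"
    )
    _write_grid(kernel.values, header, path)


def read_kernel(path) -> ConvolutionKernel:
    meta, body = _split_file(path)
    row, col = (int(x) for x in meta["center"].split(","))
    return ConvolutionKernel(
        values=_read_grid(body),
        resolution_mm=float(meta["resolution_mm"]),
        delta_r_mm=float(meta["delta_r_mm"]),
        center_index=(row, col),
        max_radius_cm=float(meta["max_radius_cm"]),
        energy_label=meta.get("energy", ""),
        ssd_cm=float(meta.get("ssd_cm", 100.0)),
        has_negative_aof=bool(int(meta.get("has_negative_aof", 0))),
    )


def write_mask(mask: ApertureMask, path) -> None:
    header = (
        f"# resolution_mm={_FMT % mask.resolution_mm} "
        f"origin_x_cm={_FMT % mask.origin[0]} origin_y_cm={_FMT % mask.origin[1]} "
        f"padding_cm={_FMT % mask.padding_cm}\n"
    )
    buf = _stdio.StringIO()
    np.savetxt(buf, mask.values, fmt="%d", delimiter=",")
    Path(path).write_text(header + buf.getvalue())


def read_mask(path) -> ApertureMask:
    meta, body = _split_file(path)
    return ApertureMask(
        values=_read_grid(body).astype(np.uint8),
        resolution_mm=float(meta["resolution_mm"]),
        origin=(float(meta["origin_x_cm"]), float(meta["origin_y_cm"])),
        padding_cm=float(meta.get("padding_cm", 0.0)),
    )


def write_cof_map(cof_map: COFMap, path) -> None:
    header = (
        f"# resolution_mm={_FMT % cof_map.resolution_mm} "
        f"origin_x_cm={_FMT % cof_map.origin[0]} origin_y_cm={_FMT % cof_map.origin[1]}\n"
        f"# energy={cof_map.energy_label} ssd_cm={_FMT % cof_map.ssd_cm}\n"
    )
    _write_grid(cof_map.values, header, path)


def read_cof_map(path) -> COFMap:
    meta, body = _split_file(path)
    return COFMap(
        values=_read_grid(body),
        resolution_mm=float(meta["resolution_mm"]),
        origin=(float(meta["origin_x_cm"]), float(meta["origin_y_cm"])),
        energy_label=meta.get("energy", ""),
        ssd_cm=float(meta.get("ssd_cm", 100.0)),
    )


def write_planar(dist: PlanarDistribution, path) -> None:
    header = (
        f"# resolution_mm={_FMT % dist.resolution_mm} "
        f"origin_x_cm={_FMT % dist.origin[0]} origin_y_cm={_FMT % dist.origin[1]}\n"
    )
    _write_grid(dist.values, header, path)


def read_planar(path) -> PlanarDistribution:
    meta, body = _split_file(path)
    return PlanarDistribution(
        values=_read_grid(body),
        resolution_mm=float(meta["resolution_mm"]),
        origin=(float(meta["origin_x_cm"]), float(meta["origin_y_cm"])),
    )
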