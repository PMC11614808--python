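"""Data model and I/O for multi-channel z-stacks and regions of interest.

Conventions
-----------
* Pixel data are indexed ``[channel][z][row][col]``.
* All vertex coordinates are 0-based ``(row, col)`` float pairs referring to
  pixel centers.
* Physical sizes are carried in micrometres; in-plane measurements only
  (``z_step_um`` is metadata).
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import FormatError, RoiKindError

__all__ = [
    "ImageStack",
    "RegionOfInterest",
    "read_stack",
    "write_stack",
    "read_roi",
    "write_roi",
    "read_imagej_roi",
    "polygon_area",
    "polyline_length",
    "point_in_polygon",
    "points_in_polygon",
    "distance_to_polyline",
]


@dataclass
class ImageStack:
    """A named-channel, multi-z image with physical pixel size.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, n_z, height, width)`` with
        non-negative intensities.
    channel_names
        Ordered unique channel names, one per channel plane.
    pixel_size_um
        In-plane pixel size (square pixels), must be > 0.
    z_step_um
        Axial step between z planes, metadata only.
    dtype_max
        Upper bound of the valid intensity range.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    z_step_um: float = 1.0
    dtype_max: float = 65535.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise FormatError(
                f"pixels must be 4-D (channel, z, row, col); got {self.pixels.ndim}-D"
            )
        if len(self.channel_names) != self.pixels.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channel planes"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be > 0")
        if self.z_step_um <= 0:
            raise FormatError("z_step_um must be > 0")
        if self.pixels.size and (
            np.nanmin(self.pixels) < 0 or np.nanmax(self.pixels) > self.dtype_max
        ):
            raise FormatError("intensities outside [0, dtype_max]")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, row, col) sub-array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None
        return self.pixels[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass
class RegionOfInterest:
    """A polygon (area) or polyline (curvilinear distance) ROI.

    ``vertices`` is an ``(n, 2)`` float array of 0-based (row, col) pixel
    coordinates. Polygons need at least 3 vertices, polylines at least 2.
    """

    kind: str
    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("polygon", "polyline"):
            raise RoiKindError(f"unknown ROI kind {self.kind!r}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise FormatError("vertices must be an (n, 2) array of (row, col)")
        n_min = 3 if self.kind == "polygon" else 2
        if len(self.vertices) < n_min:
            raise FormatError(f"{self.kind} needs at least {n_min} vertices")


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_stack(stack: ImageStack, path: str | Path, *, ome: bool = True) -> Path:
    """Write a stack to OME-TIFF (default) or plain TIFF plus a YAML sidecar.

    The sidecar is always written for plain TIFF; for OME-TIFF all metadata
    lives in the OME-XML header.
    """
    path = Path(path)
    data = stack.pixels
    if ome:
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "CZYX",
                "Channel": {"Name": list(stack.channel_names)},
                "PhysicalSizeX": stack.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": stack.z_step_um,
                "PhysicalSizeZUnit": "µm",
            },
        )
    else:
        # plain multi-page TIFF, planes ordered channel-major (C0z0, C0z1, ...)
        tifffile.imwrite(path, data.reshape((-1,) + data.shape[2:]))
        sidecar = {
            "channel_names": list(stack.channel_names),
            "pixel_size_um": float(stack.pixel_size_um),
            "z_step_um": float(stack.z_step_um),
            "dtype_max": float(stack.dtype_max),
            "plane_order": "channel_major",
        }
        _sidecar_path(path).write_text(yaml.safe_dump(sidecar))
    return path


def _dtype_max_for(arr: np.ndarray, declared: float | None) -> float:
    if declared is not None:
        return float(declared)
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return float(max(1.0, arr.max())) if arr.size else 1.0


def _parse_ome(xml_text: str) -> tuple[list[str], float | None, float | None]:
    root = ET.fromstring(xml_text)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    names: list[str] = []
    px = pz = None
    image = root.find(f"{ns}Image")
    if image is not None:
        pixels = image.find(f"{ns}Pixels")
        if pixels is not None:
            if pixels.get("PhysicalSizeX"):
                px = float(pixels.get("PhysicalSizeX"))
            if pixels.get("PhysicalSizeZ"):
                pz = float(pixels.get("PhysicalSizeZ"))
            for ch in pixels.findall(f"{ns}Channel"):
                names.append(ch.get("Name") or f"C{len(names)}")
    return names, px, pz


def read_stack(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read an OME-TIFF or plain TIFF (+ sidecar) stack.

    For plain TIFF without sidecar, ``channel_names`` must be given and the
    plane count must be divisible by the channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_xml = tif.ome_metadata
        axes = tif.series[0].axes if tif.series else ""

    meta_names: list[str] = []
    meta_px = meta_pz = None
    dtype_max = None
    if ome_xml:
        meta_names, meta_px, meta_pz = _parse_ome(ome_xml)
    else:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            meta_names = list(meta.get("channel_names", []))
            meta_px = meta.get("pixel_size_um")
            meta_pz = meta.get("z_step_um")
            dtype_max = meta.get("dtype_max")

    names = channel_names or meta_names
    if not names:
        raise FormatError(f"{path}: channel names not in metadata and not provided")

    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        # stack of planes: split into channels
        n_planes = data.shape[0]
        if n_planes % len(names) != 0:
            raise FormatError(
                f"{path}: {n_planes} planes not divisible by "
                f"{len(names)} channels (offending dimension: planes)"
            )
        n_z = n_planes // len(names)
        data = data.reshape(len(names), n_z, *data.shape[1:])
    elif data.ndim == 4:
        if "C" in axes and "Z" in axes and axes.index("Z") < axes.index("C"):
            data = np.moveaxis(data, axes.index("C"), 0)
            data = np.moveaxis(data, 1 + axes.replace("C", "").index("Z"), 1)
    else:
        raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")

    if data.shape[0] != len(names):
        raise FormatError(
            f"{path}: {data.shape[0]} channel planes but {len(names)} names "
            "(offending dimension: channel)"
        )

    return ImageStack(
        pixels=data,
        channel_names=list(names),
        pixel_size_um=float(pixel_size_um or meta_px or 1.0),
        z_step_um=float(z_step_um or meta_pz or 1.0),
        dtype_max=_dtype_max_for(data, dtype_max),
    )


# ---------------------------------------------------------------------------
# ROI I/O
# ---------------------------------------------------------------------------


def write_roi(roi: RegionOfInterest, path: str | Path) -> Path:
    """Write the structured-text ROI interchange format.

    Format: a ``label:`` line, a ``kind:`` line, then one ``row col`` pair
    per line. Comment lines start with ``#``.
    """
    path = Path(path)
    lines = [f"label: {roi.label}", f"kind: {roi.kind}"]
    lines += [f"{float(r)!r} {float(c)!r}" for r, c in roi.vertices]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_roi(path: str | Path) -> RegionOfInterest:
    """Read a structured-text ROI file (or an ImageJ ``.roi`` if binary)."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:4] == b"Iout":
        return read_imagej_roi(path)
    label, kind = "", ""
    verts: list[tuple[float, float]] = []
    for line in raw.decode().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("label:"):
            label = line.split(":", 1)[1].strip()
        elif line.startswith("kind:"):
            kind = line.split(":", 1)[1].strip()
        else:
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: bad vertex line {line!r}")
            verts.append((float(parts[0]), float(parts[1])))
    if not kind:
        raise FormatError(f"{path}: missing 'kind:' line")
    return RegionOfInterest(kind=kind, vertices=np.array(verts), label=label)


_IJ_POLYGON = 0
_IJ_LINE = 3
_IJ_FREELINE = 4
_IJ_POLYLINE = 5
_IJ_FREEHAND = 7


def read_imagej_roi(path: str | Path) -> RegionOfInterest:
    """Minimal reader for ImageJ ``.roi`` files (polygon/polyline variants).

    ImageJ stores (x, y) = (col, row) int16 offsets from the bounding box
    top-left; converted here to 0-based (row, col).
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"Iout":
        raise FormatError(f"{path}: not an ImageJ ROI file")
    roi_type = raw[6]
    top, left = struct.unpack(">hh", raw[8:12])
    n = struct.unpack(">h", raw[16:18])[0]
    kind_map = {
        _IJ_POLYGON: "polygon",
        _IJ_FREEHAND: "polygon",
        _IJ_POLYLINE: "polyline",
        _IJ_FREELINE: "polyline",
        _IJ_LINE: "polyline",
    }
    if roi_type not in kind_map:
        raise FormatError(f"{path}: unsupported ImageJ ROI type {roi_type}")
    if roi_type == _IJ_LINE:
        x1, y1, x2, y2 = struct.unpack(">ffff", raw[18:34])
        verts = np.array([[y1, x1], [y2, x2]])
    else:
        base = 64
        xs = struct.unpack(f">{n}h", raw[base : base + 2 * n])
        ys = struct.unpack(f">{n}h", raw[base + 2 * n : base + 4 * n])
        verts = np.array(
            [[top + y, left + x] for x, y in zip(xs, ys)], dtype=float
        )
    return RegionOfInterest(kind=kind_map[roi_type], vertices=verts, label=Path(path).stem)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def polygon_area(roi: RegionOfInterest, pixel_size_um: float) -> float:
    """Shoelace area of a polygon ROI in µm² (orientation-independent)."""
    if roi.kind != "polygon":
        raise RoiKindError(f"polygon_area needs a polygon ROI, got {roi.kind!r}")
    r = roi.vertices[:, 0]
    c = roi.vertices[:, 1]
    area_px2 = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    return float(area_px2 * pixel_size_um**2)


def polyline_length(roi: RegionOfInterest, pixel_size_um: float) -> float:
    """Sum of Euclidean segment lengths of a polyline ROI, in µm."""
    if roi.kind != "polyline":
        raise RoiKindError(f"polyline_length needs a polyline ROI, got {roi.kind!r}")
    d = np.diff(roi.vertices, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum() * pixel_size_um)


def point_in_polygon(point: tuple[float, float], vertices: np.ndarray) -> bool:
    """Even-odd (ray casting) point-in-polygon test in (row, col) coordinates."""
    return bool(points_in_polygon(np.asarray([point], float), vertices)[0])


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorized even-odd rule for an array of (row, col) points."""
    pts = np.asarray(points, dtype=float)
    v = np.asarray(vertices, dtype=float)
    r, c = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(v)
    for i in range(n):
        r1, c1 = v[i]
        r2, c2 = v[(i + 1) % n]
        crosses = (r1 > r) != (r2 > r)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (c < np.where(crosses, c_int, np.inf))
    return inside


def distance_to_polyline(point: tuple[float, float], vertices: np.ndarray) -> float:
    """Minimum Euclidean distance (px) from a point to a polyline."""
    p = np.asarray(point, dtype=float)
    v = np.asarray(vertices, dtype=float)
    a, b = v[:-1], v[1:]
    ab = b - a
    ap = p[None, :] - a
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip((ap * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.hypot(*(p[None, :] - proj).T)))
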