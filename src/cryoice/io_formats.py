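"""Micrograph stack I/O, preprocessing, and CVAT polygon annotations.

Reads MRC 2014 image stacks and multi-page TIFFs into :class:`TiltSeriesStack`
objects, normalizes micrographs for the segmentation model, parses polygon
annotations exported from CVAT (the "CVAT for images" XML dialect), and
rasterizes them into binary crystalline-ice masks.

The MRC reader/writer covers the 2014 standard's image-stack case (ispg = 0,
modes 0/1/2/6) with a fixed 1024-byte header; it intentionally does not handle
volumes, extended headers beyond skipping them, or exotic axis orderings.
"""

from __future__ import annotations

import logging
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "Micrograph", "TiltSeriesStack", "PolygonAnnotation", "SegmentationMask",
    "load_micrograph_stack", "write_mrc_stack", "preprocess",
    "parse_cvat_xml", "write_cvat_xml", "rasterize",
    "write_mask_png", "read_mask_png",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Micrograph:
    """One projection image plus acquisition metadata.

    image is a 2-D float array (unitless intensity); pixel_size_A is Å/pixel
    when known. lamella/series identifiers track the acquisition hierarchy
    (dataset -> lamella -> tilt series -> projection).
    """

    image: np.ndarray
    pixel_size_A: float | None = None
    source_id: str = ""
    lamella_id: str = ""
    series_id: str = ""
    tilt_index: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2 or min(self.image.shape) < 8:
            raise ValueError(
                f"micrograph image must be 2-D with sides >= 8, got {self.image.shape}")
        if self.tilt_index < 0:
            raise ValueError("tilt_index must be >= 0")


@dataclass
class TiltSeriesStack:
    micrographs: list[Micrograph]
    stack_path: str = ""

    def __post_init__(self):
        shapes = {m.image.shape for m in self.micrographs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent image shapes in stack: {shapes}")
        tilts = [m.tilt_index for m in self.micrographs]
        if len(set(tilts)) != len(tilts):
            raise ValueError("duplicate tilt_index values in stack")

    def __len__(self):
        return len(self.micrographs)

    def __iter__(self):
        return iter(self.micrographs)


@dataclass
class PolygonAnnotation:
    """A closed polygon in image pixel coordinates, (col, row) = CVAT (x, y)."""

    vertices: list[tuple[float, float]]
    label: str = "crystalline_ice"
    image_name: str = ""

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon on image {self.image_name!r} needs >= 3 vertices, "
                f"got {len(self.vertices)}")
        self.vertices = [(float(c), float(r)) for c, r in self.vertices]


@dataclass
class SegmentationMask:
    """Binary per-pixel labeling; 1 = crystalline (non-vitrified)."""

    mask: np.ndarray
    image_ref: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.mask = self.mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# MRC 2014 stacks
# ---------------------------------------------------------------------------

_MRC_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_mrc(path: Path) -> tuple[np.ndarray, float | None]:
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise ValueError(f"{path}: not an MRC file (header truncated)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    (ispg,) = struct.unpack_from("<i", raw, 88)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ValueError(f"{path}: missing MRC 2014 'MAP ' signature")
    if ispg != 0:
        raise ValueError(
            f"{path}: ispg={ispg} marks a 3-D volume, not an image stack")
    if mode not in _MRC_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {mode} "
                         f"(supported: {sorted(_MRC_DTYPES)})")
    dtype = np.dtype(_MRC_DTYPES[mode]).newbyteorder("<")
    start = 1024 + nsymbt
    count = nx * ny * max(nz, 1)
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=start)
    data = data.reshape(max(nz, 1), ny, nx).astype(np.float64)
    pixel = float(xlen) / mx if mx > 0 and xlen > 0 else None
    return data, pixel


def write_mrc_stack(path, images: np.ndarray, pixel_size_A: float | None = None,
                    mode: int = 2) -> None:
    """Write a (n, rows, cols) array as an MRC 2014 image stack.

    Fixture-grade writer: little-endian, no extended header, ispg = 0.
    """
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    nz, ny, nx = images.shape
    if mode not in _MRC_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}")
    dtype = np.dtype(_MRC_DTYPES[mode]).newbyteorder("<")
    data = images.astype(dtype)
    px = float(pixel_size_A) if pixel_size_A else 0.0
    hdr = bytearray(1024)
    struct.pack_into("<4i", hdr, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)          # mx, my, mz
    struct.pack_into("<3f", hdr, 40, px * nx, px * ny, px * nz)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)    # cell angles
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)             # mapc, mapr, maps
    fdata = images.astype(np.float64)
    struct.pack_into("<3f", hdr, 76, float(fdata.min()), float(fdata.max()),
                     float(fdata.mean()))
    struct.pack_into("<i", hdr, 88, 0)                    # ispg: image stack
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])        # little-endian stamp
    struct.pack_into("<f", hdr, 216, float(fdata.std()))
    Path(path).write_bytes(bytes(hdr) + data.tobytes())


def load_micrograph_stack(path, fmt: str = "auto") -> TiltSeriesStack:
    """Load an MRC 2014 stack or multi-page TIFF as a tilt series.

    One micrograph per stored slice, tilt_index = slice index; the pixel size
    is taken from the MRC header when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "mrc"
    if fmt == "mrc":
        data, pixel = _read_mrc(path)
    elif fmt == "tiff":
        import tifffile
        data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 2-D pages, got shape {data.shape}")
        pixel = None
    else:
        raise ValueError(f"unknown format {fmt!r}")
    mics = [
        Micrograph(image=sl, pixel_size_A=pixel, source_id=path.name,
                   series_id=path.stem, tilt_index=i)
        for i, sl in enumerate(data)
    ]
    return TiltSeriesStack(micrographs=mics, stack_path=str(path))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(m: Micrograph, target_long_side: int = 1024,
               clip_sigma: float = 3.0) -> Micrograph:
    """Normalize and resize a micrograph for the model.

    Intensities are z-scored, clipped at ±clip_sigma (robust against the hot
    pixels and fiducial shadows common in cryo-ET exports), then affinely
    rescaled to [0, 1] so that 0-sigma maps to 0.5. The image is resized with
    bilinear interpolation so its longer side equals target_long_side,
    preserving aspect ratio. A constant image maps to all 0.5 with a warning.
    """
    if target_long_side < 32:
        raise ValueError("target_long_side must be >= 32")
    if clip_sigma <= 0:
        raise ValueError("clip_sigma must be positive")
    img = m.image
    sd = img.std()
    if sd == 0:
        logger.warning("constant image %s: preprocessing to uniform 0.5",
                       m.source_id or "<unnamed>")
        z = np.zeros_like(img)
    else:
        z = (img - img.mean()) / sd
    z = np.clip(z, -clip_sigma, clip_sigma)
    out = (z + clip_sigma) / (2.0 * clip_sigma)
    h, w = out.shape
    long_side = max(h, w)
    if long_side != target_long_side:
        scale = target_long_side / long_side
        nh = target_long_side if h >= w else int(round(h * scale))
        nw = target_long_side if w > h else int(round(w * scale))
        out = _sk_resize(out, (nh, nw), order=1, anti_aliasing=False,
                         preserve_range=True)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after preprocessing")
    return replace(m, image=out)


# ---------------------------------------------------------------------------
# CVAT polygons
# ---------------------------------------------------------------------------

def parse_cvat_xml(xml_text: str) -> list[PolygonAnnotation]:
    """Parse polygons from a CVAT-for-images XML export.

    Each ``<polygon points="x1,y1;x2,y2;...">`` inside an ``<image>`` element
    becomes one annotation; CVAT (x, y) maps to image (col, row).
    """
    root = ET.fromstring(xml_text)
    out: list[PolygonAnnotation] = []
    for image_el in root.iter("image"):
        name = image_el.get("name", "")
        width = image_el.get("width")
        height = image_el.get("height")
        for poly_el in image_el.iter("polygon"):
            pts_attr = poly_el.get("points", "")
            verts = []
            for pair in filter(None, pts_attr.split(";")):
                fields = pair.split(",")
                try:
                    x, y = float(fields[0]), float(fields[1])
                except (ValueError, IndexError) as exc:
                    raise ValueError(
                        f"malformed points on image {name!r}: {pts_attr!r}") from exc
                verts.append((x, y))
            if len(verts) < 3:
                raise ValueError(
                    f"polygon on image {name!r} has {len(verts)} vertices (< 3)")
            if width and height:
                w, h = float(width), float(height)
                verts = [(min(max(x, -0.5), w - 0.5), min(max(y, -0.5), h - 0.5))
                         for x, y in verts]
            out.append(PolygonAnnotation(
                vertices=verts, label=poly_el.get("label", "crystalline_ice"),
                image_name=name))
    return out


def write_cvat_xml(annotations: list[PolygonAnnotation],
                   image_sizes: dict[str, tuple[int, int]] | None = None) -> str:
    """Serialize annotations in the CVAT-for-images dialect (fixture writer).

    image_sizes maps image name -> (height, width); written when provided so
    the parser can clip on read.
    """
    root = ET.Element("annotations")
    ET.SubElement(ET.SubElement(root, "meta"), "task")
    by_image: dict[str, list[PolygonAnnotation]] = {}
    for ann in annotations:
        by_image.setdefault(ann.image_name, []).append(ann)
    for idx, (name, anns) in enumerate(by_image.items()):
        attrs = {"id": str(idx), "name": name}
        if image_sizes and name in image_sizes:
            h, w = image_sizes[name]
            attrs.update(width=str(w), height=str(h))
        image_el = ET.SubElement(root, "image", attrs)
        for ann in anns:
            pts = ";".join(f"{x:.2f},{y:.2f}" for x, y in ann.vertices)
            ET.SubElement(image_el, "polygon",
                          {"label": ann.label, "points": pts, "occluded": "0"})
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray,
                       verts: np.ndarray) -> np.ndarray:
    """Even-odd containment of points (px, py); boundary counts as inside."""
    x0, y0 = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    eps = 1e-9
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        # boundary: distance from point to segment ab below eps
        abx, aby = bx - ax, by - ay
        denom = abx * abx + aby * aby
        if denom > 0:
            t = np.clip(((px - ax) * abx + (py - ay) * aby) / denom, 0.0, 1.0)
        else:
            t = np.zeros_like(px)
        dx = px - (ax + t * abx)
        dy = py - (ay + t * aby)
        on_edge |= dx * dx + dy * dy < eps * eps
        # even-odd ray cast toward +x
        cond = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (py - ay) / (by - ay + 0.0) * abx
        crosses = cond & (px < xint)
        inside ^= crosses
    return inside | on_edge


def rasterize(annotations: list[PolygonAnnotation], height: int,
              width: int) -> SegmentationMask:
    """Rasterize the union of polygons onto an integer pixel grid.

    A pixel is foreground iff its center (col, row) = (j, i), 0-based, lies
    inside (even-odd rule) or on the boundary of any polygon. Vertices outside
    the image are clipped to the half-pixel border.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be >= 1")
    mask = np.zeros((height, width), dtype=np.uint8)
    cols, rows = np.meshgrid(np.arange(width, dtype=np.float64),
                             np.arange(height, dtype=np.float64))
    for ann in annotations:
        verts = np.array(ann.vertices, dtype=np.float64)
        verts[:, 0] = np.clip(verts[:, 0], -0.5, width - 0.5)
        verts[:, 1] = np.clip(verts[:, 1], -0.5, height - 0.5)
        # restrict work to the polygon's bounding box
        j0 = max(int(np.floor(verts[:, 0].min())), 0)
        j1 = min(int(np.ceil(verts[:, 0].max())) + 1, width)
        i0 = max(int(np.floor(verts[:, 1].min())), 0)
        i1 = min(int(np.ceil(verts[:, 1].max())) + 1, height)
        if j0 >= j1 or i0 >= i1:
            continue
        sub = _points_in_polygon(cols[i0:i1, j0:j1], rows[i0:i1, j0:j1], verts)
        mask[i0:i1, j0:j1] |= sub.astype(np.uint8)
    return SegmentationMask(mask=mask)


# ---------------------------------------------------------------------------
# mask export
# ---------------------------------------------------------------------------

def write_mask_png(path, mask: SegmentationMask) -> None:
    import imageio.v3 as iio
    iio.imwrite(str(path), (mask.mask * 255).astype(np.uint8))


def read_mask_png(path) -> SegmentationMask:
    import imageio.v3 as iio
    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return SegmentationMask(mask=(arr > 127).astype(np.uint8))
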