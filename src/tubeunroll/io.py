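"""Readers and writers: image stacks, contour files, ImageJ ROI archives.

Contours come in two dialects:

* a JSON file ``{"slices": [{"h": 3, "inner": [[x, y], ...],
  "outer": [[x, y], ...]}, ...]}``;
* an ImageJ ROI ``.zip`` archive of polygon/freehand ROIs.  ImageJ ROI
  archives carry no role metadata, so the entry naming convention
  ``inner_*``/``outer_*`` is REQUIRED; the stack slice is taken from the
  ROI position field (1-based) or, failing that, from digits in the
  entry name.

The ROI codec implements the subset of the ImageJ ``.roi`` binary layout
needed for polygon outlines with sub-pixel coordinates (big-endian,
64-byte header, integer coordinates relative to the bounding box,
optional float coordinates when the sub-pixel option bit is set).
"""

from __future__ import annotations

import json
import struct
import zipfile
from pathlib import Path

import numpy as np
import tifffile


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# --------------------------------------------------------------------------
# image stacks


def read_stack(path) -> np.ndarray:
    """Read a grey-value stack: multi-page TIFF or a directory of TIFFs.

    Directory slices are taken in lexicographic file order.  All slices
    must agree in shape and dtype.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        dtypes = {s.dtype for s in slices}
        if len(shapes) > 1 or len(dtypes) > 1:
            raise FormatError("mixed slice dimensions or bit depths in stack directory")
        if any(s.ndim != 2 for s in slices):
            raise FormatError("stack directory must contain single-page 2D TIFFs")
        return np.stack(slices)
    vol = tifffile.imread(path)
    if vol.ndim == 2:
        vol = vol[None, :, :]
    if vol.ndim != 3:
        raise FormatError(f"expected a 2D/3D TIFF, got shape {vol.shape}")
    return vol


def write_stack(path, volume: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(volume), photometric="minisblack")


# --------------------------------------------------------------------------
# JSON contour dialect


def read_contours_json(path) -> list[tuple[int, np.ndarray, np.ndarray]]:
    with open(path) as fh:
        data = json.load(fh)
    if "slices" not in data:
        raise FormatError("contour JSON must have a top-level 'slices' list")
    out = []
    for entry in data["slices"]:
        try:
            h = int(entry["h"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError("each slice entry needs an integer 'h'") from exc
        for role in ("inner", "outer"):
            if role not in entry:
                raise FormatError(f"slice {h} is missing its '{role}' contour")
        inner = np.asarray(entry["inner"], dtype=float)
        outer = np.asarray(entry["outer"], dtype=float)
        if inner.ndim != 2 or inner.shape[1] != 2 or outer.ndim != 2 or outer.shape[1] != 2:
            raise FormatError(f"slice {h}: contours must be [[x, y], ...] lists")
        out.append((h, inner, outer))
    out.sort(key=lambda t: t[0])
    return out


def write_contours_json(path, slices: list[tuple[int, np.ndarray, np.ndarray]]) -> None:
    data = {
        "slices": [
            {"h": int(h), "inner": np.asarray(inner, float).tolist(),
             "outer": np.asarray(outer, float).tolist()}
            for h, inner, outer in slices
        ]
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


# --------------------------------------------------------------------------
# ImageJ ROI codec (polygon subset)

_MAGIC = b"Iout"
_VERSION = 228
_TYPE_POLYGON = 0
_TYPE_FREEHAND = 7
_OPT_SUBPIXEL = 128


def encode_imagej_roi(points: np.ndarray, position: int = 0) -> bytes:
    """Encode a polygon outline as ImageJ ``.roi`` bytes.

    ``position`` is the 1-based stack slice (0 = unset).  Sub-pixel float
    coordinates are always written alongside the rounded integer ones.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise FormatError("ROI needs an (N>=3, 2) point array")
    n = len(pts)
    left = int(np.floor(pts[:, 0].min()))
    top = int(np.floor(pts[:, 1].min()))
    right = int(np.ceil(pts[:, 0].max()))
    bottom = int(np.ceil(pts[:, 1].max()))
    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = _TYPE_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    struct.pack_into(">h", header, 50, _OPT_SUBPIXEL)
    struct.pack_into(">i", header, 56, int(position))
    body = bytearray()
    xi = np.clip(np.round(pts[:, 0]) - left, -32768, 32767).astype(int)
    yi = np.clip(np.round(pts[:, 1]) - top, -32768, 32767).astype(int)
    body += struct.pack(f">{n}h", *xi)
    body += struct.pack(f">{n}h", *yi)
    body += struct.pack(f">{n}f", *pts[:, 0])
    body += struct.pack(f">{n}f", *pts[:, 1])
    return bytes(header) + bytes(body)


def decode_imagej_roi(data: bytes) -> tuple[np.ndarray, int]:
    """Decode polygon/freehand ``.roi`` bytes to (points, position)."""
    if len(data) < 64 or data[0:4] != _MAGIC:
        raise FormatError("not an ImageJ ROI (bad magic)")
    roi_type = data[6]
    if roi_type not in (_TYPE_POLYGON, _TYPE_FREEHAND):
        raise FormatError(f"unsupported ROI type {roi_type}; need polygon or freehand")
    top, left = struct.unpack_from(">hh", data, 8)
    n = struct.unpack_from(">h", data, 16)[0]
    options = struct.unpack_from(">h", data, 50)[0]
    position = struct.unpack_from(">i", data, 56)[0]
    if n < 3:
        raise FormatError("ROI has fewer than 3 points")
    base = 64
    need = base + 4 * n
    if len(data) < need:
        raise FormatError("truncated ROI coordinate block")
    if options & _OPT_SUBPIXEL and len(data) >= need + 8 * n:
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=need)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=need + 4 * n)
        pts = np.column_stack([xs, ys]).astype(float)
    else:
        xi = np.frombuffer(data, dtype=">i2", count=n, offset=base)
        yi = np.frombuffer(data, dtype=">i2", count=n, offset=base + 2 * n)
        pts = np.column_stack([xi + left, yi + top]).astype(float)
    return pts, position


def _slice_from_name(name: str) -> int | None:
    digits = "".join(ch if ch.isdigit() else " " for ch in name).split()
    return int(digits[-1]) if digits else None


def read_roi_zip(path) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Read an ImageJ ROI zip following the inner_*/outer_* convention."""
    per_slice: dict[int, dict[str, np.ndarray]] = {}
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            stem = Path(name).stem.lower()
            if stem.startswith("inner"):
                role = "inner"
            elif stem.startswith("outer"):
                role = "outer"
            else:
                raise FormatError(
                    f"ROI entry {name!r} does not follow the inner_*/outer_* naming convention"
                )
            pts, position = decode_imagej_roi(zf.read(name))
            h = position - 1 if position > 0 else _slice_from_name(stem)
            if h is None:
                raise FormatError(f"cannot determine the slice of ROI entry {name!r}")
            per_slice.setdefault(h, {})[role] = pts
    out = []
    for h in sorted(per_slice):
        entry = per_slice[h]
        if "inner" not in entry or "outer" not in entry:
            raise FormatError(f"slice {h} is missing its inner or outer ROI")
        out.append((h, entry["inner"], entry["outer"]))
    return out


def write_roi_zip(path, slices: list[tuple[int, np.ndarray, np.ndarray]]) -> None:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for h, inner, outer in slices:
            zf.writestr(f"inner_{h:04d}.roi", encode_imagej_roi(inner, position=h + 1))
            zf.writestr(f"outer_{h:04d}.roi", encode_imagej_roi(outer, position=h + 1))


# --------------------------------------------------------------------------
# dispatch


def read_contours(path) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Read per-slice (h, inner, outer) boundary pairs from either dialect."""
    path = Path(path)
    if path.suffix.lower() == ".zip":
        return read_roi_zip(path)
    if path.suffix.lower() == ".json":
        return read_contours_json(path)
    raise FormatError(f"unrecognised contour file type: {path.suffix!r}")
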