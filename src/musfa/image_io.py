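"""Image, ROI, and table input/output.

Coordinate convention used throughout the package: images are indexed
``pixels[row, col]`` with row 0 at the top; rows run along the axial
(depth) direction and columns along the lateral direction. Polygon
vertices are continuous ``(col, row)`` pairs, 0-based, and pixel ``(i, j)``
has its center at the integer point ``(col=j, row=i)``. Polygon
containment is evaluated at pixel centers by the even-odd rule and is
boundary-inclusive.

ROI polygons are exchanged as JSON::

    {"image": "<free-text id>", "vertices": [[x0, y0], [x1, y1], ...]}

Ratings tables are exchanged as long-format CSV with columns
``subject, rater_or_trial, parameter, value``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputFormatError, ValidationError

RATINGS_COLUMNS = ("subject", "rater_or_trial", "parameter", "value")

# ITU-R BT.601 luminance weights, used when an RGB export is supplied.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BModeImage:
    """A grayscale B-mode frame with physical pixel spacing in mm."""

    pixels: np.ndarray
    spacing_axial: float
    spacing_lateral: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"pixels must be a 2D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValidationError("pixel intensities must be finite and >= 0")
        for name in ("spacing_axial", "spacing_lateral"):
            s = getattr(self, name)
            if not np.isfinite(s) or s <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {s!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIPolygon:
    """Ordered polygon vertices in ``(col, row)`` pixel coordinates."""

    vertices: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("polygon needs >= 3 (col, row) vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("polygon vertices must be finite")
        if _polygon_is_degenerate(v) or _polygon_self_intersects(v):
            raise ValidationError("polygon must be simple (non-degenerate, non-self-intersecting)")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class ROIMask:
    """Boolean raster of an ROI, congruent with its parent image."""

    mask: np.ndarray
    area_px: int = field(default=-1)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise ValidationError("mask must be a 2D boolean grid")
        object.__setattr__(self, "mask", m)
        n_true = int(m.sum())
        if self.area_px == -1:
            object.__setattr__(self, "area_px", n_true)
        elif self.area_px != n_true:
            raise ValidationError(f"area_px={self.area_px} but mask has {n_true} true pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _polygon_is_degenerate(v: np.ndarray) -> bool:
    # Repeated consecutive vertices or zero enclosed area.
    closed = np.vstack([v, v[:1]])
    if np.any(np.all(np.diff(closed, axis=0) == 0, axis=1)):
        return True
    x, y = v[:, 0], v[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return abs(area2) < 1e-12


def _segments_properly_intersect(p1, p2, q1, q2) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(q1, q2, p1)
    d2 = cross(q1, q2, p2)
    d3 = cross(p1, p2, q1)
    d4 = cross(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _polygon_self_intersects(v: np.ndarray) -> bool:
    n = len(v)
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # shared-vertex neighbours
            if _segments_properly_intersect(*edges[i], *edges[j]):
                return True
    return False


def load_bmode_image(
    path: str | Path,
    spacing_axial: float,
    spacing_lateral: float,
    source_id: str | None = None,
) -> BModeImage:
    """Read a PNG/TIFF (or DICOM) frame into a :class:`BModeImage`.

    Intensities are preserved without rescaling. RGB inputs are collapsed
    to luminance with BT.601 weights. For DICOM files the pixel-spacing
    attributes override the supplied spacings when present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _load_dicom(path, spacing_axial, spacing_lateral, source_id)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific
        raise IOError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise InputFormatError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = arr.astype(float) @ _LUMA
    elif arr.ndim != 2:
        raise InputFormatError(f"expected 2D grayscale or RGB image, got shape {arr.shape}")
    return BModeImage(
        pixels=arr,
        spacing_axial=spacing_axial,
        spacing_lateral=spacing_lateral,
        source_id=source_id if source_id is not None else path.name,
    )


def _load_dicom(path, spacing_axial, spacing_lateral, source_id):
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise IOError("reading DICOM requires the optional 'pydicom' package") from exc
    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    if arr.ndim == 3:
        arr = arr.astype(float) @ _LUMA
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None and len(spacing) == 2:
        spacing_axial, spacing_lateral = float(spacing[0]), float(spacing[1])
    return BModeImage(arr, spacing_axial, spacing_lateral, source_id or path.name)


def save_bmode_image(image: BModeImage, path: str | Path) -> None:
    """Write pixel data to PNG/TIFF. Integer grids are written bit-exactly
    (uint8/uint16); float grids are rounded into uint16 after clipping."""
    path = Path(path)
    px = image.pixels
    if np.issubdtype(px.dtype, np.integer):
        if px.max(initial=0) <= 255:
            out = px.astype(np.uint8)
        elif px.max(initial=0) <= 65535:
            out = px.astype(np.uint16)
        else:
            raise ValidationError("integer image exceeds 16-bit range")
    else:
        out = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    iio.imwrite(path, out)


def read_roi_json(path: str | Path) -> ROIPolygon:
    """Read an ROI polygon from the JSON dialect documented in this module."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        vertices = doc["vertices"]
        image_id = doc.get("image", "")
    except (TypeError, KeyError) as exc:
        raise InputFormatError(f"ROI JSON {path} missing 'vertices'") from exc
    return ROIPolygon(vertices=np.asarray(vertices, dtype=float), image_id=image_id)


def write_roi_json(polygon: ROIPolygon, path: str | Path) -> None:
    doc = {"image": polygon.image_id, "vertices": [[float(x), float(y)] for x, y in polygon.vertices]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def save_mask_png(mask: ROIMask, path: str | Path) -> None:
    """Export a mask as a 0/255 8-bit PNG."""
    iio.imwrite(Path(path), np.where(mask.mask, 255, 0).astype(np.uint8))


def rasterize_roi(polygon: ROIPolygon, shape: tuple[int, int]) -> ROIMask:
    """Rasterize a polygon into a boolean mask over an image of ``shape``.

    A pixel is inside iff its integer center satisfies the even-odd
    (crossing-number) rule or lies exactly on the polygon boundary.
    """
    rows, cols = int(shape[0]), int(shape[1])
    v = polygon.vertices
    if np.any(v[:, 0] < 0) or np.any(v[:, 0] >= cols) or np.any(v[:, 1] < 0) or np.any(v[:, 1] >= rows):
        raise ValidationError(f"polygon vertices fall outside [0, {cols})x[0, {rows})")

    jj, ii = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    px = jj.ravel()
    py = ii.ravel()
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)

    n = len(v)
    for k in range(n):
        x1, y1 = v[k]
        x2, y2 = v[(k + 1) % n]
        # Even-odd ray crossing: horizontal ray toward +x, half-open in y so a
        # vertex is counted once.
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < x_at)
        # Boundary inclusion: point on the closed segment.
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        cross = (px - x1) * dy - (py - y1) * dx
        dot = (px - x1) * dx + (py - y1) * dy
        on_edge |= (np.abs(cross) <= 1e-9 * max(1.0, np.sqrt(seg_len2))) & (dot >= -1e-9) & (
            dot <= seg_len2 + 1e-9
        )

    mask = (inside | on_edge).reshape(rows, cols)
    return ROIMask(mask=mask)


def read_ratings_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format ratings CSV and validate its layout.

    Returns the validated long table; use
    :func:`ratings_frame_to_tables` to pivot it into per-parameter
    subjects x raters grids. Missing (subject, rater) cells are legal
    here but are rejected when a grid is built.
    """
    df = pd.read_csv(path, dtype={"subject": str, "rater_or_trial": str, "parameter": str})
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"ratings CSV {path} missing columns: {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].index[0]
        raise InputFormatError(f"non-numeric value in ratings CSV {path} at row {bad}")
    df = df.assign(value=values.astype(float))
    dup = df.duplicated(subset=["subject", "rater_or_trial", "parameter"])
    if dup.any():
        first = df.loc[dup, ["subject", "rater_or_trial", "parameter"]].iloc[0].tolist()
        raise ValidationError(f"duplicate (subject, rater, parameter) rows in {path}: {first}")
    return df[list(RATINGS_COLUMNS)]


def ratings_frame_to_tables(df: pd.DataFrame):
    """Pivot a validated long table into ``{parameter: RatingsTable}``.

    Raises :class:`ValidationError` naming the first missing cell if any
    parameter's subjects x raters grid is incomplete.
    """
    from .reliability import RatingsTable  # local import to avoid a cycle

    tables = {}
    for parameter, sub in df.groupby("parameter", sort=True):
        wide = sub.pivot(index="subject", columns="rater_or_trial", values="value")
        if wide.isna().any().any():
            sub_idx, rater = next(
                (s, r) for s in wide.index for r in wide.columns if pd.isna(wide.loc[s, r])
            )
            raise ValidationError(
                f"incomplete ratings for parameter {parameter!r}: "
                f"missing subject={sub_idx!r}, rater_or_trial={rater!r}"
            )
        tables[parameter] = RatingsTable(
            values=wide.to_numpy(dtype=float),
            subject_ids=[str(s) for s in wide.index],
            rater_ids=[str(r) for r in wide.columns],
        )
    return tables


def write_ratings_table(tables, path: str | Path) -> None:
    """Write ``{parameter: RatingsTable}`` back to long-format CSV."""
    records = []
    for parameter in sorted(tables):
        t = tables[parameter]
        for i, s in enumerate(t.subject_ids):
            for j, r in enumerate(t.rater_ids):
                records.append((s, r, parameter, t.values[i, j]))
    pd.DataFrame(records, columns=list(RATINGS_COLUMNS)).to_csv(path, index=False)
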