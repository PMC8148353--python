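"""Containers and I/O for optic-disc tracings.

A tracing is either a filled binary raster (:class:`TraceMask`) or an
ordered boundary path (:class:`Polyline`).  Coordinate convention
throughout the package: 0-based pixel indices, ``x`` = column, ``y`` =
row, ``y`` increasing downward (raster convention).  Angles are measured
in degrees from the +x axis toward +y in this frame.

Masks are stored on disk as single-channel PNG/TIFF with foreground 255;
polylines as two-column ``x,y`` CSV (sub-pixel decimals allowed) or a
JSON list of ``[x, y]`` pairs.  A study is described by a manifest CSV
with columns ``image_id,dataset,condition,rater,path,kind``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import shapely
from PIL import Image
from scipy import ndimage

from .errors import InputError

CONDITIONS = ("glaucoma", "dr", "normal")

__all__ = [
    "CONDITIONS",
    "TraceMask",
    "Polyline",
    "ImageRecord",
    "load_mask",
    "save_mask",
    "load_polyline",
    "save_polyline",
    "polyline_to_mask",
    "mask_to_boundary",
    "load_study",
    "save_study",
]


@dataclass(frozen=True)
class TraceMask:
    """A filled disc tracing on a fixed image grid (boolean, rows x cols)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InputError(f"mask must be a non-empty 2-D grid, got shape {arr.shape}")
        object.__setattr__(self, "pixels", arr.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass(frozen=True)
class Polyline:
    """Ordered boundary points ``(x, y)`` of a tracing, sub-pixel allowed.

    Consecutive duplicate points are dropped on construction; for a
    closed path a trailing repeat of the first point is removed.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InputError(f"polyline points must be (n, 2), got {pts.shape}")
        if len(pts) > 1:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
            pts = pts[keep]
        if self.closed and len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if self.closed and len(pts) < 3:
            raise InputError("a closed polyline needs at least 3 distinct points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


Tracing = Union[TraceMask, Polyline]


@dataclass
class ImageRecord:
    """One image's labelled tracings.

    ``tracings`` maps rater label -> TraceMask or Polyline; precision
    metrics require a ``"ground_truth"`` entry.
    """

    image_id: str
    dataset: str
    condition: str
    shape: tuple[int, int]
    tracings: dict[str, Tracing] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InputError(
                f"condition {self.condition!r} not in {CONDITIONS} (image {self.image_id})"
            )
        for rater, tr in self.tracings.items():
            if isinstance(tr, TraceMask) and tr.shape != tuple(self.shape):
                raise InputError(
                    f"tracing {rater!r} shape {tr.shape} != record shape {self.shape}"
                )


# ---------------------------------------------------------------------------
# raster I/O


def load_mask(path: str | Path) -> TraceMask:
    """Read a raster image as a binary mask.

    Any pixel with a nonzero value in any channel is foreground — this is
    deliberately tolerant of anti-aliased exports of hand tracings.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read mask image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return TraceMask(arr > 0)


def save_mask(mask: TraceMask, path: str | Path) -> None:
    """Write a mask losslessly as single-channel 0/255."""
    path = Path(path)
    img = Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L")
    try:
        img.save(path)
    except OSError as exc:
        raise InputError(f"cannot write mask image {path}: {exc}") from exc


def load_polyline(path: str | Path, closed: bool = True) -> Polyline:
    """Read a polyline from ``x,y`` CSV or a JSON list of pairs."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        pts = json.loads(path.read_text())
        return Polyline(np.asarray(pts, dtype=float), closed=closed)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["x", "y"]:
            raise InputError(f"polyline CSV {path} must start with an 'x,y' header")
        pts = [(float(row[0]), float(row[1])) for row in reader if row]
    return Polyline(np.asarray(pts, dtype=float), closed=closed)


def save_polyline(poly: Polyline, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(poly.points.tolist()))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        writer.writerows(poly.points.tolist())


# ---------------------------------------------------------------------------
# conversions


def polyline_to_mask(poly: Polyline, shape: tuple[int, int]) -> TraceMask:
    """Rasterize the filled interior of a closed path.

    Open paths are auto-closed.  A pixel is foreground iff its center
    lies inside or on the polygon (inclusive pixel-center coverage) —
    the same rule ellipse rasterization uses, so the two raster paths
    agree to within genuine boundary quantization.
    """
    pts = np.asarray(poly.points, dtype=float)
    if len(pts) < 3:
        raise InputError("need at least 3 points to fill a polyline")
    xs, ys = pts[:, 0], pts[:, 1]
    # shoelace; degenerate (collinear) input has no interior
    area2 = np.abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
    if area2 < 1e-9:
        raise InputError("degenerate zero-area polygon")
    polygon = shapely.Polygon(pts)
    if not polygon.is_valid:
        polygon = shapely.make_valid(polygon)
    h, w = shape
    x0 = max(0, int(math.floor(xs.min())))
    x1 = min(w - 1, int(math.ceil(xs.max())))
    y0 = max(0, int(math.floor(ys.min())))
    y1 = min(h - 1, int(math.ceil(ys.max())))
    grid = np.zeros((h, w), dtype=bool)
    if x0 > x1 or y0 > y1:
        raise InputError("polygon lies entirely outside the image")
    gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = shapely.intersects_xy(polygon, gx.ravel(), gy.ravel()).reshape(gy.shape)
    grid[y0 : y1 + 1, x0 : x1 + 1] = inside
    return TraceMask(grid)


# Moore neighborhood, clockwise from north, as (dr, dc)
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


def _moore_trace(comp: np.ndarray) -> list[tuple[int, int]]:
    """Ordered clockwise outer-boundary pixels of a connected component.

    Moore-neighbor tracing with Jacob's stopping criterion: the walk ends
    when the start pixel is re-entered from its original backtrack
    position.
    """
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))  # row-major first foreground pixel
    h, w = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(comp[r, c])

    # start is the first pixel in row-major order, so its west neighbor
    # (possibly out of bounds) is guaranteed background
    start_back = (start[0], start[1] - 1)
    cur, back = start, start_back
    contour: list[tuple[int, int]] = []
    limit = 4 * int(comp.sum()) + 8
    for _ in range(limit):
        contour.append(cur)
        d = _MOORE_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            idx = (d + k) % 8
            cand = (cur[0] + _MOORE[idx][0], cur[1] + _MOORE[idx][1])
            if fg(*cand):
                pidx = (d + k - 1) % 8
                nxt = cand
                nxt_back = (cur[0] + _MOORE[pidx][0], cur[1] + _MOORE[pidx][1])
                break
        if nxt is None:  # isolated pixel
            break
        if nxt == start and nxt_back == start_back:
            break
        cur, back = nxt, nxt_back
    return contour


def mask_to_boundary(mask: TraceMask) -> Polyline:
    """Ordered outer contour of the largest 8-connected component.

    Interior holes are ignored; stray islands (smaller components) are
    dropped.  Returns pixel coordinates as an ``(x, y)`` polyline.
    """
    if mask.is_empty:
        raise InputError("cannot extract a boundary from an empty mask")
    labels, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        comp = labels == int(sizes.argmax())
    else:
        comp = mask.pixels
    contour = _moore_trace(comp)
    pts = np.array([(c, r) for r, c in contour], dtype=float)
    return Polyline(pts, closed=len(pts) >= 3)


# ---------------------------------------------------------------------------
# study manifests

_MANIFEST_COLUMNS = ["image_id", "dataset", "condition", "rater", "path", "kind"]


def load_study(manifest_path: str | Path) -> list[ImageRecord]:
    """Load a study from a manifest CSV.

    Paths in the manifest are resolved relative to the manifest's
    directory.  The record shape is taken from the first mask tracing;
    records containing only polylines get the tight bounding shape of
    their points (rounded up), which is sufficient for all metrics.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    groups: dict[str, dict] = {}
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise InputError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            g = groups.setdefault(
                row["image_id"],
                {"dataset": row["dataset"], "condition": row["condition"], "tracings": {}},
            )
            kind = row["kind"].strip().lower()
            p = base / row["path"]
            if kind == "mask":
                g["tracings"][row["rater"]] = load_mask(p)
            elif kind == "polyline":
                g["tracings"][row["rater"]] = load_polyline(p)
            else:
                raise InputError(f"unknown tracing kind {row['kind']!r} for {row['image_id']}")
    records = []
    for image_id, g in groups.items():
        shape = None
        for tr in g["tracings"].values():
            if isinstance(tr, TraceMask):
                shape = tr.shape
                break
        if shape is None:
            hi = max(tr.points.max(axis=0) for tr in g["tracings"].values())
            shape = (int(np.ceil(hi[1])) + 2, int(np.ceil(hi[0])) + 2)
        records.append(
            ImageRecord(
                image_id=image_id,
                dataset=g["dataset"],
                condition=g["condition"],
                shape=shape,
                tracings=g["tracings"],
            )
        )
    records.sort(key=lambda r: r.image_id)
    return records


def save_study(records: Sequence[ImageRecord], out_dir: str | Path) -> Path:
    """Write records as PNG masks / CSV polylines plus a manifest CSV.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    (out_dir / "tracings").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for rater, tr in sorted(rec.tracings.items()):
            if isinstance(tr, TraceMask):
                rel = f"tracings/{rec.image_id}_{rater}.png"
                save_mask(tr, out_dir / rel)
                kind = "mask"
            else:
                rel = f"tracings/{rec.image_id}_{rater}.csv"
                save_polyline(tr, out_dir / rel)
                kind = "polyline"
            rows.append([rec.image_id, rec.dataset, rec.condition, rater, rel, kind])
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest
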