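"""Reading, writing and orienting 65-point proximal-femur outlines.

The interchange format is the plain-text landmark "points" dialect produced
by statistical-shape-model annotation tools::

    version: 1
    n_points: 65
    {
    123.45 67.89
    ...
    }

or a two-column CSV (``x,y``, header optional).  Subject/hip/side metadata
travel in a JSON sidecar next to the points file.  Coordinates are carried
in whatever unit the annotation used (pixels or mm); the alpha-angle
geometry is unit-invariant so no conversion is ever performed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "N_POINTS",
    "FemurOutline",
    "LandmarkScheme",
    "PointsFormatError",
    "read_points",
    "write_points",
    "mirror_outline",
    "normalize_side",
]

N_POINTS = 65

_SIDES = ("left", "right")


class PointsFormatError(ValueError):
    """A points file violates the 65-point annotation contract."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Index ranges (0-based, inclusive) of the anatomic landmark groups.

    ``head_arc`` indexes the points on the femoral-head contour used for the
    circle of best fit; ``neck_seg_a``/``neck_seg_b`` are the two femoral-neck
    contour segments between which the narrowest neck section is searched.
    The upstream annotation labels its anatomically guided points ambiguously
    (a "point 65" cannot exist among 65 zero-based points), so the ranges are
    configurable; the defaults follow the published construction.
    """

    head_arc: tuple[int, int] = (19, 32)
    neck_seg_a: tuple[int, int] = (2, 15)
    neck_seg_b: tuple[int, int] = (37, 49)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("head_arc", self.head_arc),
            ("neck_seg_a", self.neck_seg_a),
            ("neck_seg_b", self.neck_seg_b),
        ):
            if not (0 <= lo <= hi <= N_POINTS - 1):
                raise ValueError(f"{name} range {lo}-{hi} outside 0-{N_POINTS - 1}")
        if self.head_arc[1] - self.head_arc[0] + 1 < 3:
            raise ValueError("head_arc needs at least 3 indices for a circle fit")
        a = set(self.indices("neck_seg_a"))
        b = set(self.indices("neck_seg_b"))
        if a & b:
            raise ValueError("neck segments must be disjoint")

    def indices(self, group: str) -> np.ndarray:
        lo, hi = getattr(self, group)
        return np.arange(lo, hi + 1)


@dataclass(frozen=True)
class FemurOutline:
    """An ordered 65-point planar outline of one proximal femur."""

    points: np.ndarray
    side: str
    subject_id: str = ""
    hip_id: str = ""
    source: str = ""
    units: str = "px"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise PointsFormatError(f"points must be (n, 2), got {pts.shape}")
        if pts.shape[0] != N_POINTS:
            raise PointsFormatError(
                f"expected {N_POINTS} outline points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise PointsFormatError("outline contains non-finite coordinates")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        object.__setattr__(self, "points", pts)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _parse_pts_dialect(lines: list[str], path: Path) -> np.ndarray:
    n_declared = None
    coords: list[tuple[float, float]] = []
    in_block = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("version:"):
            continue
        if line.startswith("n_points:"):
            try:
                n_declared = int(line.split(":", 1)[1])
            except ValueError:
                raise PointsFormatError(f"{path}:{lineno}: bad n_points line {line!r}")
            continue
        if line == "{":
            in_block = True
            continue
        if line == "}":
            in_block = False
            continue
        if in_block:
            parts = line.split()
            if len(parts) != 2:
                raise PointsFormatError(
                    f"{path}:{lineno}: expected 'x y', got {line!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise PointsFormatError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                )
    if n_declared is not None and n_declared != len(coords):
        raise PointsFormatError(
            f"{path}: header declares n_points: {n_declared} "
            f"but file contains {len(coords)} points"
        )
    return np.asarray(coords, dtype=float).reshape(-1, 2)


def _parse_csv(lines: list[str], path: Path) -> np.ndarray:
    coords: list[tuple[float, float]] = []
    for lineno, row in enumerate(csv.reader(lines), start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if lineno == 1:
            try:
                float(row[0])
            except ValueError:
                continue  # header row
        if len(row) < 2:
            raise PointsFormatError(f"{path}:{lineno}: expected two columns")
        try:
            coords.append((float(row[0]), float(row[1])))
        except ValueError:
            raise PointsFormatError(
                f"{path}:{lineno}: non-numeric coordinate in {row!r}"
            )
    return np.asarray(coords, dtype=float).reshape(-1, 2)


def read_points(path: str | Path, units: str = "px") -> FemurOutline:
    """Read a landmark points file (versioned dialect or CSV, auto-detected).

    Metadata (side, subject/hip ids) is taken from the JSON sidecar
    ``<file>.meta.json`` when present; the side defaults to ``left``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    first = next((ln.strip() for ln in lines if ln.strip()), "")
    if first.startswith("version:") or first.startswith("n_points:"):
        pts = _parse_pts_dialect(lines, path)
    else:
        pts = _parse_csv(lines, path)
    if pts.shape[0] != N_POINTS:
        raise PointsFormatError(
            f"{path}: expected {N_POINTS} outline points, found {pts.shape[0]}"
        )
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FemurOutline(
        points=pts,
        side=meta.get("side", "left"),
        subject_id=meta.get("subject_id", ""),
        hip_id=meta.get("hip_id", path.stem),
        source=meta.get("source", str(path)),
        units=meta.get("units", units),
    )


def write_points(outline: FemurOutline, path: str | Path) -> None:
    """Write the versioned points dialect plus a JSON metadata sidecar.

    Coordinates are formatted with ``repr``-level (shortest round-trip)
    precision, so ``read_points(write_points(...))`` is exact and repeated
    writes are byte-identical.
    """
    path = Path(path)
    lines = ["version: 1", f"n_points: {N_POINTS}", "{"]
    lines += [f"{float(x)!r} {float(y)!r}" for x, y in outline.points]
    lines += ["}", ""]
    path.write_text("\n".join(lines))
    meta = {
        "side": outline.side,
        "subject_id": outline.subject_id,
        "hip_id": outline.hip_id,
        "source": outline.source,
        "units": outline.units,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def mirror_outline(outline: FemurOutline) -> FemurOutline:
    """Mirror an outline about the vertical axis through its centroid.

    This is an isometry (all pairwise distances preserved) and an involution.
    The ``side`` label is flipped.
    """
    cx = outline.points[:, 0].mean()
    pts = outline.points.copy()
    pts[:, 0] = 2.0 * cx - pts[:, 0]
    other = "right" if outline.side == "left" else "left"
    return replace(outline, points=pts, side=other)


def normalize_side(outline: FemurOutline) -> FemurOutline:
    """Bring an outline into the common (left-hip) orientation.

    Right hips are mirrored about a vertical axis; left hips pass through
    unchanged.  One landmark index scheme then serves both sides.
    """
    if outline.side == "left":
        return outline
    if outline.side == "right":
        mirrored = mirror_outline(outline)
        return replace(mirrored, side="left")
    raise ValueError(f"unknown side {outline.side!r}")
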