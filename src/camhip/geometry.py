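"""Alpha-angle geometry on 65-point proximal-femur outlines.

The construction follows the published semi-automatic method: a circle of
best fit around the femoral head (landmarks 19-32), the midpoint of the
narrowest femoral-neck section (between landmark segments 2-15 and 37-49),
and the point where the bone contour leaves the head circle at the lateral
head/neck junction.  The alpha angle is the angle at the circle centre
between the ray to the neck midpoint and the ray to that departure point;
cam morphology is an alpha angle of at least 60 degrees.

All operations are unit- and orientation-invariant: only relative distances
and angles are used, so pixel or millimetre coordinates and either y-axis
convention give identical angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .shape_io import FemurOutline, LandmarkScheme, normalize_side

__all__ = [
    "Circle",
    "AlphaAngleResult",
    "MeasureConfig",
    "DegenerateGeometryError",
    "CAM_THRESHOLD_DEG",
    "fit_circle",
    "neck_narrowest",
    "departure_point",
    "alpha_angle",
    "classify_cam",
    "measure_hip",
]

#: Alpha-angle threshold (degrees) defining cam morphology.
CAM_THRESHOLD_DEG = 60.0


class DegenerateGeometryError(ValueError):
    """The input geometry does not admit the requested construction."""


@dataclass(frozen=True)
class Circle:
    center: np.ndarray
    radius: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        if c.shape != (2,) or not np.all(np.isfinite(c)):
            raise ValueError("center must be a finite planar point")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError("radius must be strictly positive and finite")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")
        object.__setattr__(self, "center", c)


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable measurement parameters (defaults documented in docs/methods.md)."""

    cam_threshold_deg: float = CAM_THRESHOLD_DEG
    #: departure tolerance as a fraction of the head radius
    tol_frac: float = 0.0025
    #: subdivisions per contour edge in the narrowest-neck search
    densify: int = 8
    #: circle-fit residual (fraction of radius) beyond which the fit is flagged
    poor_fit_frac: float = 0.05


@dataclass(frozen=True)
class AlphaAngleResult:
    """Full output of one hip measurement, intermediates included."""

    alpha_deg: float | None
    cam: bool | None
    circle: Circle
    neck_midpoint: np.ndarray
    neck_width: float
    departure_point: np.ndarray | None
    qc_flags: frozenset[str] = field(default_factory=frozenset)
    subject_id: str = ""
    hip_id: str = ""
    side: str = ""

    def __post_init__(self) -> None:
        if (self.alpha_deg is None) != ("no-departure" in self.qc_flags):
            raise ValueError("alpha_deg is absent iff qc_flags contains no-departure")
        if self.alpha_deg is not None and not (0.0 <= self.alpha_deg <= 180.0):
            raise ValueError("alpha_deg must lie in [0, 180]")


def fit_circle(points: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> Circle:
    """Geometric least-squares circle through >=3 non-collinear points.

    An algebraic (Kasa) linear solve provides the initial centre/radius;
    damped Gauss-Newton then minimises the sum of squared orthogonal
    distances to the circle.  Near-collinear configurations are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 planar points")
    centered = pts - pts.mean(axis=0)
    scale = np.sqrt((centered**2).sum(axis=1).mean())
    if scale == 0:
        raise DegenerateGeometryError("all points coincide")
    sv = np.linalg.svd(centered / scale, compute_uv=False)
    if sv[-1] < 1e-8:
        raise DegenerateGeometryError("points are collinear or nearly collinear")

    # Kasa initialisation: minimise ||x||^2 - 2 c.x + (|c|^2 - r^2) algebraically
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c0 = sol
    center = np.array([cx, cy])
    radius = float(np.sqrt(max(c0 + cx * cx + cy * cy, np.finfo(float).tiny)))

    # damped Gauss-Newton on residuals r_i = |p_i - c| - R
    lam = 1e-12
    params = np.array([center[0], center[1], radius])
    d = np.linalg.norm(pts - params[:2], axis=1)
    resid = d - params[2]
    cost = float(resid @ resid)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - params[:2], axis=1)
        d = np.where(d == 0, np.finfo(float).tiny, d)
        J = np.empty((len(pts), 3))
        J[:, 0] = (params[0] - pts[:, 0]) / d
        J[:, 1] = (params[1] - pts[:, 1]) / d
        J[:, 2] = -1.0
        resid = d - params[2]
        g = J.T @ resid
        H = J.T @ J
        step = np.linalg.solve(H + lam * np.eye(3), -g)
        new = params + step
        d_new = np.linalg.norm(pts - new[:2], axis=1)
        r_new = d_new - new[2]
        new_cost = float(r_new @ r_new)
        if new_cost <= cost:
            params, cost = new, new_cost
            lam = max(lam / 10.0, 1e-14)
        else:
            lam *= 10.0
            continue
        if np.max(np.abs(step)) < tol:
            break
    center = params[:2]
    radius = float(params[2])
    if radius <= 0:
        raise DegenerateGeometryError("circle fit collapsed to non-positive radius")
    d = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return Circle(center=center, radius=radius, rms_residual=rms)


def _densified(poly: np.ndarray, densify: int) -> np.ndarray:
    """Points of a polyline with `densify` subdivisions per edge (endpoints kept)."""
    if densify < 1:
        raise ValueError("densify must be >= 1")
    if len(poly) == 1 or densify == 1:
        return poly if densify == 1 else poly
    out = [poly[:1]]
    t = np.arange(1, densify + 1) / densify
    for a, b in zip(poly[:-1], poly[1:]):
        out.append(a + t[:, None] * (b - a))
    return np.vstack(out)


def neck_narrowest(
    outline: FemurOutline,
    scheme: LandmarkScheme | None = None,
    densify: int = 8,
) -> tuple[np.ndarray, float]:
    """Midpoint and width of the narrowest neck section.

    Both neck contour segments are linearly densified and the closest pair
    (one point per segment) is found by exhaustive search; ties resolve to
    the first pair in segment order.  Returns ``(midpoint, width)``.
    """
    scheme = scheme or LandmarkScheme()
    seg_a = outline.points[scheme.indices("neck_seg_a")]
    seg_b = outline.points[scheme.indices("neck_seg_b")]
    if len(seg_a) == 0 or len(seg_b) == 0:
        raise DegenerateGeometryError("empty neck segment")
    pa = _densified(seg_a, densify)
    pb = _densified(seg_b, densify)
    dist = cdist(pa, pb)
    i, j = np.unravel_index(np.argmin(dist), dist.shape)  # first pair on ties
    width = float(dist[i, j])
    midpoint = 0.5 * (pa[i] + pb[j])
    return midpoint, width


def departure_point(
    outline: FemurOutline,
    circle: Circle,
    scheme: LandmarkScheme | None = None,
    tol_frac: float = 0.0025,
) -> np.ndarray | None:
    """First contour point past the head arc that leaves the head circle.

    Walks the contour from the last head-arc landmark toward the superior
    neck segment and returns the point where the distance from the circle
    centre first crosses ``radius * (1 + tol_frac)``, linearly interpolated
    between the bracketing landmarks to the exact crossing of the tolerance
    circle.  Returns ``None`` when the contour never leaves the tolerance
    circle (a QC outcome, not an error).
    """
    scheme = scheme or LandmarkScheme()
    start = scheme.head_arc[1]
    stop = scheme.neck_seg_b[1]
    idx = np.arange(start, stop + 1)
    pts = outline.points[idx]
    thr = circle.radius * (1.0 + tol_frac)
    d = np.linalg.norm(pts - circle.center, axis=1)
    outside = d > thr
    # the crossing must be sustained by the following contour point, so an
    # isolated jitter excursion on the head arc is not mistaken for the
    # head/neck junction
    sustained = outside.copy()
    sustained[:-1] &= outside[1:]
    candidates = np.nonzero(sustained)[0]
    if candidates.size == 0:
        return None
    k = int(candidates[0])
    inside = np.nonzero(~outside[:k])[0]
    if inside.size == 0:
        return pts[k].copy()
    j = int(inside[-1])  # last point inside the tolerance circle before k
    # exact crossing of the tolerance circle along the bracketing chord
    p0, p1 = pts[j] - circle.center, pts[k] - circle.center
    dp = p1 - p0
    a = float(dp @ dp)
    b = 2.0 * float(p0 @ dp)
    c = float(p0 @ p0) - thr * thr
    disc = b * b - 4.0 * a * c
    if disc < 0 or a == 0:  # numerical fallback: bracketing point itself
        return pts[k].copy() + circle.center * 0.0
    lam = (-b + np.sqrt(disc)) / (2.0 * a)
    lam = float(np.clip(lam, 0.0, 1.0))
    return circle.center + p0 + lam * dp


def alpha_angle(
    circle: Circle, neck_midpoint: np.ndarray, departure: np.ndarray
) -> float:
    """Unsigned angle (degrees, in [0, 180]) at the circle centre.

    Measured between the ray to the neck midpoint and the ray to the
    departure point.
    """
    u = np.asarray(neck_midpoint, dtype=float) - circle.center
    v = np.asarray(departure, dtype=float) - circle.center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("point coincides with circle centre")
    cos = float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def classify_cam(alpha_deg: float, threshold: float = CAM_THRESHOLD_DEG) -> bool:
    """Cam morphology: alpha angle >= threshold (inclusive boundary)."""
    return bool(alpha_deg >= threshold)


def measure_hip(
    outline: FemurOutline,
    scheme: LandmarkScheme | None = None,
    config: MeasureConfig | None = None,
) -> AlphaAngleResult:
    """Full alpha-angle measurement of one hip.

    Composition: side normalisation -> head-circle fit -> narrowest-neck
    midpoint -> departure point -> alpha angle -> cam classification.
    All intermediates are returned; hips whose contour never leaves the
    head circle carry the ``no-departure`` QC flag and an undefined alpha.
    """
    scheme = scheme or LandmarkScheme()
    config = config or MeasureConfig()
    oriented = normalize_side(outline)
    try:
        circle = fit_circle(oriented.points[scheme.indices("head_arc")])
        midpoint, width = neck_narrowest(oriented, scheme, config.densify)
        dep = departure_point(oriented, circle, scheme, config.tol_frac)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"hip {outline.hip_id!r}: {exc}") from exc
    flags = set()
    if circle.rms_residual > config.poor_fit_frac * circle.radius:
        flags.add("poor-circle-fit")
    if dep is None:
        flags.add("no-departure")
        alpha = None
        cam = None
    else:
        try:
            alpha = alpha_angle(circle, midpoint, dep)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"hip {outline.hip_id!r}: {exc}") from exc
        cam = classify_cam(alpha, config.cam_threshold_deg)
    return AlphaAngleResult(
        alpha_deg=alpha,
        cam=cam,
        circle=circle,
        neck_midpoint=midpoint,
        neck_width=width,
        departure_point=dep,
        qc_flags=frozenset(flags),
        subject_id=outline.subject_id,
        hip_id=outline.hip_id,
        side=outline.side,
    )
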