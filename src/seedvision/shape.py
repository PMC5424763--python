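"""Fifteen shape descriptors of a segmented seed.

The features compare the seed silhouette with reference figures (equal-area
circle, minimum circumcircle, moment-equivalent ellipse) and quantify
asymmetry around the principal axes:

========  ========================  =================================
 number    name                      definition
========  ========================  =================================
  1        circularity 1             4*pi*A / P^2
  2        compactness 1             2*sqrt(pi*A) / P
  3        defect ratio              (A_circum - A) / A_circum
  4        circularity 2             4*A / (pi * Dmax^2)
  5        compactness 2             sqrt(4*A/pi) / Dmax
  6        ellipticity index         pi * a^2 / A
  7        elongation                Dmin / Dmax
  8        eccentricity              sqrt(a^2 - b^2) / a
  9        out of roundness          (Rmax - Rmin) / Rmean
 10        hull max angle            largest interior hull angle (deg)
 11        hull min angle            smallest interior hull angle (deg)
 12        max convex distance       deepest convexity defect (px)
 13-15     symmetry area ratios      |1 - (Ai+Aj)/(Ak+Al)| over the
                                     four principal-axis quadrants
========  ========================  =================================

Discretization conventions (chosen so the descriptors of rasterized
primitives track their continuous values within ~1-2%):

* ``A`` is the pixel count.
* ``P`` is the length of the marching-squares sub-pixel outline after
  arclength resampling (0.5 px) and light Gaussian smoothing (sigma 0.8 px)
  that removes the quantization staircase.
* Feret extents ``Dmax``/``Dmin`` are measured on the convex hull of the
  boundary-pixel corner points (pixels treated as unit squares); ``Dmin`` is
  the minimum caliper width over 1-degree rotations.
* The circumcircle is the minimum enclosing circle of the pixel-center
  boundary contour.
* ``a >= b`` are the semiaxes of the moment-equivalent ellipse, with the
  1/12 per-pixel variance term included.
* Quadrant areas split pixels lying on a principal axis evenly between the
  adjacent quadrants, so A1+A2+A3+A4 = A holds exactly and the partition is
  stable under 90-degree rotations and flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter1d
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import find_contours

from seedvision.imaging import SeedRegion

_AXIS_TOL = 1e-6  # px; pixels closer than this to a principal axis are split


@dataclass
class ShapeFeatures:
    """The 15 shape descriptors, numbered as in the feature-selection pool."""

    circularity1: float
    compactness1: float
    defect_ratio: float
    circularity2: float
    compactness2: float
    ellipticity_index: float
    elongation: float
    eccentricity: float
    out_of_roundness: float
    hull_max_angle: float
    hull_min_angle: float
    max_convex_distance: float
    sar1: float
    sar2: float
    sar3: float

    _ORDER = (
        "circularity1", "compactness1", "defect_ratio", "circularity2",
        "compactness2", "ellipticity_index", "elongation", "eccentricity",
        "out_of_roundness", "hull_max_angle", "hull_min_angle",
        "max_convex_distance", "sar1", "sar2", "sar3",
    )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        """Keyed by CSV column names shape_01 ... shape_15."""
        return {f"shape_{i + 1:02d}": float(getattr(self, k)) for i, k in enumerate(self._ORDER)}


@dataclass
class GeometrySummary:
    """Raw geometric measurements a :class:`ShapeFeatures` is derived from.

    ``contour`` is the pixel-center boundary (crop-local), ``hull_points``
    the ordered convex-hull vertices of the corner cloud used for Feret
    extents, and ``quadrant_areas`` the (A1, A2, A3, A4) principal-axis
    quadrant areas numbered counterclockwise from the first quadrant.
    """

    area: float
    perimeter: float
    d_max: float
    d_min: float
    circumcircle_area: float
    semi_major: float
    semi_minor: float
    axis_angle: float
    quadrant_areas: tuple[float, float, float, float]
    centroid: tuple[float, float]
    contour: np.ndarray
    hull_points: np.ndarray

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.perimeter > 0):
            raise ValueError("area and perimeter must be positive")
        if not (self.d_max >= self.d_min > 0):
            raise ValueError("need d_max >= d_min > 0")
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("need a >= b > 0")
        if not math.isclose(sum(self.quadrant_areas), self.area, rel_tol=1e-9):
            raise ValueError("quadrant areas must sum to the area")


def _subpixel_outline(mask: np.ndarray) -> np.ndarray:
    """Longest marching-squares iso-contour of the mask at level 0.5."""
    contours = find_contours(np.pad(mask, 1).astype(float), 0.5)
    outline = max(contours, key=len)
    return outline - 1.0


def _smoothed_perimeter(outline: np.ndarray, centroid: np.ndarray,
                        spacing: float = 0.5, sigma: float = 0.8) -> float:
    """Perimeter of the staircase-corrected closed outline.

    The outline is rotated to start at its vertex farthest from the centroid
    (an intrinsic point, so congruent shapes resample identically), resampled
    at uniform arclength, Gaussian-smoothed, and measured as a polygon.
    """
    pts = outline[:-1] if np.array_equal(outline[0], outline[-1]) else outline
    if len(pts) < 4:
        cc = np.vstack([pts, pts[:1]])
        return float(np.sqrt((np.diff(cc, axis=0) ** 2).sum(1)).sum())
    far = int(np.argmax(((pts - centroid) ** 2).sum(1)))
    pts = np.roll(pts, -far, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt((np.diff(closed, axis=0) ** 2).sum(1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(total / spacing), 8)
    si = np.linspace(0.0, total, n, endpoint=False)
    ry = np.interp(si, s, closed[:, 0])
    rx = np.interp(si, s, closed[:, 1])
    sy = gaussian_filter1d(ry, sigma / spacing, mode="wrap")
    sx = gaussian_filter1d(rx, sigma / spacing, mode="wrap")
    poly = np.column_stack([sy, sx])
    cc = np.vstack([poly, poly[:1]])
    return float(np.sqrt((np.diff(cc, axis=0) ** 2).sum(1)).sum())


def _corner_cloud(mask: np.ndarray) -> np.ndarray:
    """Corner points of the boundary pixels (each pixel a unit square)."""
    boundary = mask & ~binary_erosion(mask, np.ones((3, 3)), border_value=0)
    rows, cols = np.nonzero(boundary)
    pts = np.column_stack([rows, cols]).astype(np.float64)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)


def _feret_extents(hull_pts: np.ndarray) -> tuple[float, float]:
    """(Dmax, Dmin): max pairwise hull distance and min 1-degree caliper width."""
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
    d_max = float(np.sqrt(d2.max()))
    theta = np.deg2rad(np.arange(180))
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = hull_pts @ dirs.T  # (n_pts, 180)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return d_max, float(widths.min())


def _min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Welzl's algorithm (move-to-front) on a deterministically shuffled copy."""
    pts = [tuple(p) for p in np.asarray(points, dtype=np.float64)]
    order = np.random.default_rng(1830).permutation(len(pts))
    pts = [pts[i] for i in order]

    def circle_two(p, q):
        c = ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)
        r = math.dist(p, q) / 2.0
        return c, r

    def circle_three(p, q, r):
        ax, ay = p; bx, by = q; cx, cy = r
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
              + (cx * cx + cy * cy) * (ay - by)) / d
        uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
              + (cx * cx + cy * cy) * (bx - ax)) / d
        c = (ux, uy)
        return c, math.dist(c, p)

    def inside(c, r, p):
        return math.dist(c, p) <= r * (1 + 1e-10) + 1e-10

    c, r = pts[0], 0.0
    for i, p in enumerate(pts):
        if inside(c, r, p):
            continue
        c, r = p, 0.0
        for j, q in enumerate(pts[:i]):
            if inside(c, r, q):
                continue
            c, r = circle_two(p, q)
            for k in pts[:j]:
                if inside(c, r, k):
                    continue
                res = circle_three(p, q, k)
                if res is not None:
                    c, r = res
    return np.array(c), float(r)


def _quadrant_areas(ys: np.ndarray, xs: np.ndarray, centroid: np.ndarray,
                    angle: float) -> tuple[float, float, float, float]:
    """Pixel counts in the four quadrants cut by the principal axes.

    Quadrants are numbered counterclockwise starting from (+u, +v) where u is
    the major axis.  Pixels within ``_AXIS_TOL`` of an axis are split evenly
    between the adjacent quadrants (a quarter each at the origin), keeping the
    partition exact and symmetric.
    """
    dy = ys - centroid[0]
    dx = xs - centroid[1]
    cu, su = math.cos(angle), math.sin(angle)
    u = dx * cu + dy * su
    v = -dx * su + dy * cu
    # canonicalize axis directions by the third central moments so the
    # quadrant numbering is intrinsic to the shape (stable under rotation)
    if float((u ** 3).sum()) < -_AXIS_TOL:
        u = -u
    if float((v ** 3).sum()) < -_AXIS_TOL:
        v = -v
    on_u = np.abs(u) < _AXIS_TOL
    on_v = np.abs(v) < _AXIS_TOL
    wu_pos = np.where(on_u, 0.5, (u > 0).astype(np.float64))
    wv_pos = np.where(on_v, 0.5, (v > 0).astype(np.float64))
    a1 = float((wu_pos * wv_pos).sum())
    a2 = float(((1 - wu_pos) * wv_pos).sum())
    a3 = float(((1 - wu_pos) * (1 - wv_pos)).sum())
    a4 = float((wu_pos * (1 - wv_pos)).sum())
    return a1, a2, a3, a4


def summarize_geometry(region: SeedRegion) -> GeometrySummary:
    """Measure the geometric quantities the shape features are built from."""
    if region.area_px < 5:
        raise ValueError("region too small: need area_px >= 5")
    mask = region.mask
    ys, xs = np.nonzero(mask)
    area = float(region.area_px)
    centroid = np.array([ys.mean(), xs.mean()])

    # moment-equivalent ellipse; +1/12 is the per-pixel variance term
    dy = ys - centroid[0]
    dx = xs - centroid[1]
    mu20_raw = float((dx * dx).mean())
    mu02_raw = float((dy * dy).mean())
    mu11 = float((dx * dy).mean())
    raw_common = math.hypot(mu20_raw - mu02_raw, 2 * mu11)
    if (mu20_raw + mu02_raw - raw_common) / 2.0 < 1e-9:
        raise ValueError("degenerate (collinear) region: moment ellipse is flat")
    mu20 = mu20_raw + 1.0 / 12.0
    mu02 = mu02_raw + 1.0 / 12.0
    common = math.hypot(mu20 - mu02, 2 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    semi_major = 2.0 * math.sqrt(lam1)
    semi_minor = 2.0 * math.sqrt(lam2)
    angle = 0.5 * math.atan2(2 * mu11, mu20 - mu02)

    outline = _subpixel_outline(mask)
    perimeter = _smoothed_perimeter(outline, centroid)

    corners = _corner_cloud(mask)
    try:
        hull = ConvexHull(corners)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) region") from exc
    hull_points = corners[hull.vertices]
    d_max, d_min = _feret_extents(hull_points)

    _, circ_r = _min_enclosing_circle(region.contour.astype(np.float64))
    circumcircle_area = math.pi * circ_r ** 2 if circ_r > 0 else float("nan")
    if not circumcircle_area > 0:
        raise ValueError("degenerate circumcircle")

    quad = _quadrant_areas(ys.astype(np.float64), xs.astype(np.float64), centroid, angle)

    return GeometrySummary(
        area=area,
        perimeter=perimeter,
        d_max=d_max,
        d_min=d_min,
        circumcircle_area=circumcircle_area,
        semi_major=semi_major,
        semi_minor=semi_minor,
        axis_angle=angle,
        quadrant_areas=quad,
        centroid=(float(centroid[0]), float(centroid[1])),
        contour=region.contour.astype(np.float64),
        hull_points=hull_points,
    )


def _hull_interior_angles(hull_points: np.ndarray) -> np.ndarray:
    """Interior angle (degrees) at each vertex of the ordered hull polygon."""
    prev_pts = np.roll(hull_points, 1, axis=0)
    next_pts = np.roll(hull_points, -1, axis=0)
    v1 = prev_pts - hull_points
    v2 = next_pts - hull_points
    dot = (v1 * v2).sum(1)
    n1 = np.sqrt((v1 ** 2).sum(1))
    n2 = np.sqrt((v2 ** 2).sum(1))
    cosang = np.clip(dot / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _max_distance_to_hull(contour: np.ndarray) -> float:
    """Deepest convexity defect: max distance from contour to its own hull."""
    try:
        hull = ConvexHull(contour)
    except QhullError:
        return 0.0
    verts = contour[hull.vertices]
    seg_a = verts
    seg_b = np.roll(verts, -1, axis=0)
    ab = seg_b - seg_a  # (m, 2)
    ab2 = (ab ** 2).sum(1)
    ap = contour[:, None, :] - seg_a[None, :, :]  # (n, m, 2)
    t = np.clip((ap * ab[None, :, :]).sum(-1) / np.where(ab2 > 0, ab2, 1.0), 0.0, 1.0)
    proj = seg_a[None, :, :] + t[..., None] * ab[None, :, :]
    dists = np.sqrt(((contour[:, None, :] - proj) ** 2).sum(-1))
    return float(dists.min(axis=1).max())


def shape_features(geom: GeometrySummary) -> ShapeFeatures:
    """Evaluate the 15 descriptors from a :class:`GeometrySummary`."""
    A = geom.area
    P = geom.perimeter
    a, b = geom.semi_major, geom.semi_minor
    for name, den in [("circularity1", P), ("circularity2", geom.d_max),
                      ("defect_ratio", geom.circumcircle_area),
                      ("eccentricity", a), ("ellipticity_index", A)]:
        if den == 0:
            raise ZeroDivisionError(f"zero denominator computing {name}")

    radii = np.sqrt(((geom.contour - np.array(geom.centroid)) ** 2).sum(1))
    r_mean = float(radii.mean())
    if r_mean == 0:
        raise ZeroDivisionError("zero denominator computing out_of_roundness")
    angles = _hull_interior_angles(geom.hull_points)

    q1, q2, q3, q4 = geom.quadrant_areas
    for name, den in [("sar1", q3 + q4), ("sar2", q2 + q4), ("sar3", q2 + q3)]:
        if den == 0:
            raise ZeroDivisionError(f"zero denominator computing {name}")

    return ShapeFeatures(
        circularity1=4.0 * math.pi * A / P ** 2,
        compactness1=2.0 * math.sqrt(math.pi * A) / P,
        defect_ratio=(geom.circumcircle_area - A) / geom.circumcircle_area,
        circularity2=4.0 * A / (math.pi * geom.d_max ** 2),
        compactness2=math.sqrt(4.0 * A / math.pi) / geom.d_max,
        ellipticity_index=math.pi * a ** 2 / A,
        elongation=geom.d_min / geom.d_max,
        eccentricity=math.sqrt(max(a ** 2 - b ** 2, 0.0)) / a,
        out_of_roundness=(float(radii.max()) - float(radii.min())) / r_mean,
        hull_max_angle=float(angles.max()),
        hull_min_angle=float(angles.min()),
        max_convex_distance=_max_distance_to_hull(geom.contour),
        sar1=abs(1.0 - (q1 + q2) / (q3 + q4)),
        sar2=abs(1.0 - (q1 + q3) / (q2 + q4)),
        sar3=abs(1.0 - (q1 + q4) / (q2 + q3)),
    )


def shape_features_of_region(region: SeedRegion) -> ShapeFeatures:
    """Convenience: :func:`summarize_geometry` then :func:`shape_features`."""
    return shape_features(summarize_geometry(region))
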