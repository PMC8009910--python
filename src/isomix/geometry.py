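"""Mixing-space geometry diagnostics in the (δ13C_acetic, δ13C_formic) plane.

Under linear mass-balance mixing every mixture of a set of sources lies in
the convex hull of the source signatures.  A tropospheric point outside
that hull therefore cannot be explained by the current source set and
demands at least one additional source — the geometric argument that
motivates adding the secondary-biogenic end-member.

Axis convention: δ13C of acetic acid on the abscissa, formic acid on the
ordinate.  The reference "0.94 line" is the ray δ13C_F = 0.94·δ13C_A
through the origin.  Because tropospheric deltas are negative, the literal
quotient δ13C_F/δ13C_A and the geometric half-plane test order points in
OPPOSITE senses: for δA < 0, ratio > slope ⇔ δF < slope·δA (below the
line in the plane).  Both classifications are computed and labelled
explicitly rather than silently choosing one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "IsotopePoint",
    "SourcePolygon",
    "RatioLineResult",
    "convex_hull",
    "contains",
    "requires_additional_source",
    "ratio_line_classification",
]


@dataclass(frozen=True)
class IsotopePoint:
    """A point in the dual-tracer isotope plane, ‰ vs VPDB."""

    delta_acetic: float
    delta_formic: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.delta_acetic <= -1000 or self.delta_formic <= -1000:
            raise ValueError(
                f"δ13C must exceed −1000‰ ({self.label or 'point'}: "
                f"A={self.delta_acetic}, F={self.delta_formic})"
            )

    @property
    def xy(self) -> tuple[float, float]:
        return (self.delta_acetic, self.delta_formic)


@dataclass(frozen=True)
class SourcePolygon:
    """Convex region spanned by source signatures.

    ``vertices`` are ordered counter-clockwise; degenerate cases (a single
    point or a collinear segment) are allowed and handled by the
    containment predicates.
    """

    vertices: tuple[IsotopePoint, ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 1:
            raise ValueError("polygon needs at least one vertex")

    @property
    def coords(self) -> np.ndarray:
        return np.array([v.xy for v in self.vertices], dtype=float)

    def _shape(self):
        c = [v.xy for v in self.vertices]
        if len(c) == 1:
            return Point(c[0])
        if len(c) == 2:
            return LineString(c)
        return Polygon(c)


def convex_hull(points: list[IsotopePoint]) -> SourcePolygon:
    """Minimal convex polygon containing the points, vertices CCW.

    Degenerate inputs are reduced faithfully: one distinct point gives a
    point, collinear points give the extreme segment.
    """
    if not points:
        raise ValueError("need at least one point")
    coords = np.array([p.xy for p in points], dtype=float)
    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] == 1:
        keep = [_nearest_input(points, uniq[0])]
        return SourcePolygon(vertices=tuple(keep))
    try:
        hull = ConvexHull(coords)
    except QhullError:
        # collinear: keep the two extreme points along the spanning direction
        d = uniq - uniq[0]
        direction = d[np.argmax(np.linalg.norm(d, axis=1))]
        t = coords @ direction
        keep = [points[int(np.argmin(t))], points[int(np.argmax(t))]]
        return SourcePolygon(vertices=tuple(keep))
    return SourcePolygon(vertices=tuple(points[i] for i in hull.vertices))


def _nearest_input(points: list[IsotopePoint], xy: np.ndarray) -> IsotopePoint:
    dists = [np.hypot(p.delta_acetic - xy[0], p.delta_formic - xy[1]) for p in points]
    return points[int(np.argmin(dists))]


def contains(
    polygon: SourcePolygon, point: IsotopePoint, tol: float = 1e-9
) -> str:
    """Classify a point as ``"inside"``, ``"boundary"`` or ``"outside"``.

    ``tol`` is the boundary half-width in ‰ (default 1e−9).  For degenerate
    polygons (point/segment) classification is by distance: within ``tol``
    of the object counts as boundary, there is no interior.
    """
    if tol < 0:
        raise ValueError(f"tolerance must be ≥ 0, got {tol}")
    shape = polygon._shape()
    p = Point(point.xy)
    if shape.geom_type in ("Point", "LineString"):
        return "boundary" if shape.distance(p) <= tol else "outside"
    if shape.boundary.distance(p) <= tol:
        return "boundary"
    return "inside" if shape.covers(p) else "outside"


def requires_additional_source(
    mixtures: list[IsotopePoint],
    sources: list[IsotopePoint],
    tol: float = 1e-9,
) -> list[IsotopePoint]:
    """Mixture points outside the source hull — each demands a new source.

    An empty return means the current source set is geometrically
    sufficient to explain every mixture.
    """
    if len(sources) < 2:
        raise ValueError("need at least 2 sources to form an enclosure")
    hull = convex_hull(sources)
    return [m for m in mixtures if contains(hull, m, tol=tol) == "outside"]


@dataclass(frozen=True)
class RatioLineResult:
    """Classification of a point against the δ13C_F/δ13C_A reference line.

    ``ratio_class`` orders by the literal quotient δF/δA versus the slope;
    ``plane_class`` orders by the half-plane test δF vs slope·δA.  For
    points with δA < 0 the two are opposite whenever they are not "on".
    """

    ratio: float
    ratio_class: str  # quotient vs slope: above / on / below
    plane_class: str  # half-plane position in the (δA, δF) plane


def ratio_line_classification(
    point: IsotopePoint, slope: float = 0.94, tol: float = 0.005
) -> RatioLineResult:
    """Classify a point relative to the line δ13C_F = slope·δ13C_A.

    "on" means |δF/δA − slope| ≤ tol; equivalently, the point lies within
    tol·|δA| of the line, so the two classifications agree exactly on what
    counts as "on".
    """
    if point.delta_acetic == 0:
        raise ZeroDivisionError(
            f"δ13C_acetic = 0 for {point.label or 'point'}: ratio undefined"
        )
    if tol < 0:
        raise ValueError(f"tolerance must be ≥ 0, got {tol}")
    ratio = point.delta_formic / point.delta_acetic
    diff = ratio - slope
    if abs(diff) <= tol:
        ratio_class = plane_class = "on"
    else:
        ratio_class = "above" if diff > 0 else "below"
        resid = point.delta_formic - slope * point.delta_acetic
        plane_class = "above" if resid > 0 else "below"
    return RatioLineResult(ratio=ratio, ratio_class=ratio_class, plane_class=plane_class)
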