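"""Wing planform geometry: outline construction, area, aspect ratio.

Coordinate frame (the reconstruction is 2-D, dorsal view of one wing):
x is lateral (positive away from the body midline), y is longitudinal
(positive anterior), the midline is x = 0.  Segment sweep angles are
measured from the transverse (+x) axis with posterior sweep positive, so
a bone of length L at sweep angle a runs along (L cos a, -L sin a).

The outline of a single wing is closed along the midline: midline point
at the shoulder level, shoulder, the chained forelimb joints out to the
wingtip, the discretised Bezier trailing edge back to the ankle, then
hip and midline.  Wing area is twice the single-wing area; aspect ratio
is wingspan^2 / wing area (SI units).

The trailing edge is a cubic Bezier.  P0 sits at the ankle (the membrane
attaches at the ankle) and P3 at the wingtip; P2 coincides with P3 so
the curve straightens into the wingtip.  P1 is the intersection of two
construction lines: one through the ankle at 30 degrees to the tibia
axis (tilted into the wing, so the membrane rises from its deepest point
at the ankle), one through the wingtip at 30 degrees to the distalmost
phalanx (tilted toward the body).  With a posteriorly swept wing finger
this places P1 anterior and mid-wing, giving the classic pterosaur
planform: a deep proximal membrane tapering to a narrow outer wing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .growth import GrowthSeries

#: Leading-edge chain, proximal to distal.
LEADING_EDGE_ELEMENTS = ("humerus", "ulna_radius", "mcIV", "wp1", "wp2", "wp3", "wp4")

#: Bezier discretisation used for area computation.
N_BEZIER = 1024


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PostureSpec:
    """Sweep angles (degrees) defining a wing pose.

    ``sweep`` maps each forelimb element to its sweep angle from the
    transverse axis (posterior positive, range (-90, 90)); the femur is
    oriented ``femur_angle`` degrees postero-laterally from the
    acetabulum and the tibia runs parallel to the body midline.
    """

    name: str
    sweep: Mapping[str, float]
    femur_angle: float = 45.0
    tibia_parallel: bool = True

    def __post_init__(self) -> None:
        for el in LEADING_EDGE_ELEMENTS:
            if el not in self.sweep:
                raise GeometryError(f"posture {self.name!r} lacks angle for {el}")
            if not -90.0 < self.sweep[el] < 90.0:
                raise GeometryError(f"sweep angle for {el} outside (-90, 90)")
        if not 0.0 < self.femur_angle <= 90.0:
            raise GeometryError("femur_angle must be in (0, 90]")


@dataclass(frozen=True)
class BezierTrailingEdge:
    """Cubic Bezier control points (mm); P0 at the ankle, P3 = P2 at the tip."""

    P0: tuple[float, float]
    P1: tuple[float, float]
    P2: tuple[float, float]
    P3: tuple[float, float]


@dataclass(frozen=True)
class Planform:
    """A reconstructed single-wing outline with derived areas."""

    taxon: str
    wingspan_m: float
    outline: np.ndarray  # closed simple polyline, mm, shape (k, 2)
    single_wing_area_m2: float
    wing_area_m2: float
    aspect_ratio: float
    trailing_edge: BezierTrailingEdge
    posture: str = ""


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction vector")
    return v / n


def _rot(v: np.ndarray, degrees: float) -> np.ndarray:
    a = np.radians(degrees)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def build_leading_edge(
    lengths: Mapping[str, float],
    posture: PostureSpec,
    shoulder: tuple[float, float],
    combine_wp34: bool = False,
) -> np.ndarray:
    """Chain the wing-spar segments from the shoulder to the wingtip.

    Returns the joint coordinates (shoulder first, wingtip last) in mm.
    With ``combine_wp34`` the distal phalanges form one segment of their
    combined length at the average of the two sweep angles.
    """
    elements: list[tuple[float, float]] = []
    for el in LEADING_EDGE_ELEMENTS:
        if combine_wp34 and el == "wp3":
            L = lengths["wp3"] + lengths["wp4"]
            ang = 0.5 * (posture.sweep["wp3"] + posture.sweep["wp4"])
            elements.append((L, ang))
        elif combine_wp34 and el == "wp4":
            continue
        else:
            elements.append((lengths[el], posture.sweep[el]))
    pts = [np.asarray(shoulder, dtype=float)]
    for L, ang in elements:
        if not L > 0:
            raise GeometryError("non-positive segment length in leading edge")
        a = np.radians(ang)
        pts.append(pts[-1] + L * np.array([np.cos(a), -np.sin(a)]))
    return np.vstack(pts)


def build_hindlimb(
    femur: float,
    tibia: float,
    hip: tuple[float, float],
    posture: PostureSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Knee and ankle positions: femur postero-laterally, tibia posteriorly."""
    if femur < 0 or tibia < 0:
        raise GeometryError("non-positive hindlimb length")
    angle = posture.femur_angle if posture is not None else 45.0
    a = np.radians(angle)
    hip = np.asarray(hip, dtype=float)
    knee = hip + femur * np.array([np.cos(a), -np.sin(a)])
    ankle = knee + tibia * np.array([0.0, -1.0])
    return knee, ankle


def line_intersection(
    p: np.ndarray, d1: np.ndarray, q: np.ndarray, d2: np.ndarray
) -> np.ndarray:
    """Intersection of two parametric lines by 2x2 linear solve."""
    A = np.column_stack([d1, -d2])
    det = np.linalg.det(A)
    if abs(det) < 1e-12 * max(1.0, np.linalg.norm(d1) * np.linalg.norm(d2)):
        raise GeometryError("trailing-edge construction lines are parallel")
    t = np.linalg.solve(A, q - p)
    return p + t[0] * d1


def trailing_edge(
    ankle: Sequence[float],
    tibia_direction: Sequence[float],
    wingtip: Sequence[float],
    distal_phalanx_direction: Sequence[float],
    validate: bool = False,
) -> BezierTrailingEdge:
    """Construct the trailing-edge Bezier control points.

    The ankle line is the tibia axis rotated 30 degrees into the wing;
    the wingtip line is the distal phalanx axis rotated 30 degrees
    toward the body (anteriorly for a posteriorly swept finger).  The
    wing side is inferred from the tip-ankle lateral offset, so the
    construction is mirror-equivariant.  With ``validate``, an
    intersection lying outside the root-tip lateral interval raises
    :class:`GeometryError`.
    """
    P0 = np.asarray(ankle, dtype=float)
    P3 = np.asarray(wingtip, dtype=float)
    t_dir = _unit(tibia_direction)
    p_dir = _unit(distal_phalanx_direction)
    side = 1.0 if P3[0] >= P0[0] else -1.0
    d_ankle = _rot(t_dir, -30.0 * side)
    d_tip = _rot(p_dir, 30.0 * side)
    P1 = line_intersection(P0, d_ankle, P3, d_tip)
    if validate:
        lo, hi = sorted((P0[0], P3[0]))
        if not lo <= P1[0] <= hi:
            raise GeometryError(
                f"trailing-edge control point P1 at x={P1[0]:.1f} lies outside "
                f"the wing root-tip interval [{lo:.1f}, {hi:.1f}]"
            )
    return BezierTrailingEdge(
        P0=tuple(P0), P1=tuple(P1), P2=tuple(P3), P3=tuple(P3)
    )


def bezier_polyline(edge: BezierTrailingEdge, n: int = N_BEZIER) -> np.ndarray:
    """Sample the cubic Bezier at n uniform parameter values (t=0..1)."""
    if n < 2:
        raise GeometryError("need at least 2 samples")
    t = np.linspace(0.0, 1.0, n)[:, None]
    P0, P1, P2, P3 = (np.asarray(p, dtype=float) for p in
                      (edge.P0, edge.P1, edge.P2, edge.P3))
    return ((1 - t) ** 3 * P0 + 3 * (1 - t) ** 2 * t * P1
            + 3 * (1 - t) * t**2 * P2 + t**3 * P3)


def planform_area(outline: np.ndarray) -> float:
    """Area of a simple closed polyline by the shoelace formula."""
    pts = np.asarray(outline, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    from shapely.geometry import LineString

    if not LineString(pts).is_simple:
        raise GeometryError("outline is self-intersecting")
    x, y = pts[:-1, 0], pts[:-1, 1]
    xn, yn = pts[1:, 0], pts[1:, 1]
    return float(abs(np.sum(x * yn - xn * y)) / 2.0)


def build_planform(
    series: GrowthSeries,
    posture: PostureSpec,
    Z: float,
    combine_wp34: bool = False,
    n_bezier: int = N_BEZIER,
) -> Planform:
    """Assemble the single-wing outline at one grid wingspan.

    The shoulder sits at (L1, 0) and the hip at (L2, -L3); the outline
    runs midline -> shoulder -> leading-edge joints -> wingtip ->
    trailing-edge Bezier -> ankle -> hip -> midline and closes along the
    midline.  Wing area is twice the single-wing (shoelace) area and
    aspect ratio is Z^2 / wing area.
    """
    dims = series.at(Z)
    shoulder = (dims["L1"], 0.0)
    hip = np.array([dims["L2"], -dims["L3"]])
    joints = build_leading_edge(dims, posture, shoulder, combine_wp34)
    wingtip = joints[-1]
    knee, ankle = build_hindlimb(dims["femur"], dims["tibia"], hip, posture)
    if combine_wp34:
        distal_angle = 0.5 * (posture.sweep["wp3"] + posture.sweep["wp4"])
    else:
        distal_angle = posture.sweep["wp4"]
    a = np.radians(distal_angle)
    p_dir = np.array([np.cos(a), -np.sin(a)])
    edge = trailing_edge(ankle, (0.0, -1.0), wingtip, p_dir, validate=True)
    curve = bezier_polyline(edge, n_bezier)  # wingtip is t=1 end
    outline = np.vstack(
        [
            [0.0, 0.0],
            joints,            # shoulder ... wingtip
            curve[::-1][1:],   # tip -> ankle, tip itself already present
            hip,
            [0.0, -dims["L3"]],
            [0.0, 0.0],
        ]
    )
    area_mm2 = planform_area(outline)
    single_m2 = area_mm2 * 1e-6
    wing_m2 = 2.0 * single_m2
    return Planform(
        taxon=series.taxon,
        wingspan_m=Z,
        outline=outline,
        single_wing_area_m2=single_m2,
        wing_area_m2=wing_m2,
        aspect_ratio=Z**2 / wing_m2,
        trailing_edge=edge,
        posture=posture.name,
    )


def planform_svg(planform: Planform, stroke: str = "#d95f02") -> str:
    """Render a planform (mirrored about the midline) as a plain SVG string."""
    pts = planform.outline
    mirrored = pts[::-1] * np.array([-1.0, 1.0])
    xs = np.concatenate([pts[:, 0], mirrored[:, 0]])
    ys = np.concatenate([pts[:, 1], mirrored[:, 1]])
    pad = 0.05 * (xs.max() - xs.min() + 1.0)
    x0, x1 = xs.min() - pad, xs.max() + pad
    y0, y1 = ys.min() - pad, ys.max() + pad

    def path_of(poly: np.ndarray) -> str:
        # SVG y axis points down; anterior (+y) should point up
        cmds = [f"{'M' if i == 0 else 'L'} {p[0]:.2f} {-p[1]:.2f}"
                for i, p in enumerate(poly)]
        return " ".join(cmds) + " Z"

    w, h = x1 - x0, y1 - y0
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{x0:.2f} {-y1:.2f} {w:.2f} {h:.2f}">\n'
        f'  <title>{planform.taxon} wingspan {planform.wingspan_m:.2f} m, '
        f'AR {planform.aspect_ratio:.2f}</title>\n'
        f'  <path d="{path_of(pts)}" fill="none" stroke="{stroke}" '
        f'stroke-width="{0.003 * w:.3f}"/>\n'
        f'  <path d="{path_of(mirrored)}" fill="none" stroke="{stroke}" '
        f'stroke-width="{0.003 * w:.3f}"/>\n'
        f"</svg>\n"
    )
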