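"""Standardized cut planes and cross-section morphometrics.

Two size-independent anatomical landmarks — the styloid process tip and the
most dorsal point of the dorsal (Lister's) tubercle — define three cut
planes perpendicular to the bone's main axis in the standardized frame
(+z distal, +y dorsal, +x lateral):

* distal   : at the tubercle's most dorsal point,
* proximal : half the styloid-tubercle axial distance further proximal,
* middle   : halfway between the distal and proximal planes.

Each plane-mesh intersection is chained into closed contours; the
largest-area loop (the shaft section) is measured: maximum width
(medio-lateral extent), maximum depth (dorso-volar extent), perimeter and
shoelace area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "Landmarks",
    "CutPlane",
    "SectionContour",
    "Morphometrics",
    "LandmarkError",
    "detect_landmarks",
    "define_cut_planes",
    "cross_section",
    "section_morphometrics",
    "specimen_morphometrics",
]

PLANE_LABELS = ("distal", "middle", "proximal")


class LandmarkError(ValueError):
    """Raised when anatomical landmarks are not identifiable."""


@dataclass(frozen=True)
class Landmarks:
    """Anatomical landmark pair plus the standardized frame axes."""

    styloid_tip: np.ndarray
    tubercle_dorsal: np.ndarray
    axis: np.ndarray = None  # +z distal
    dorsal: np.ndarray = None  # +y
    lateral: np.ndarray = None  # +x

    def __post_init__(self) -> None:
        object.__setattr__(self, "styloid_tip", np.asarray(self.styloid_tip, float))
        object.__setattr__(self, "tubercle_dorsal", np.asarray(self.tubercle_dorsal, float))
        object.__setattr__(self, "axis",
                           np.array([0.0, 0.0, 1.0]) if self.axis is None
                           else np.asarray(self.axis, float))
        object.__setattr__(self, "dorsal",
                           np.array([0.0, 1.0, 0.0]) if self.dorsal is None
                           else np.asarray(self.dorsal, float))
        object.__setattr__(self, "lateral",
                           np.array([1.0, 0.0, 0.0]) if self.lateral is None
                           else np.asarray(self.lateral, float))
        if self.styloid_tip @ self.axis <= self.tubercle_dorsal @ self.axis:
            raise ValueError(
                "styloid tip must lie distal (greater main-axis coordinate) "
                "of the tubercle point"
            )


@dataclass(frozen=True)
class CutPlane:
    label: str
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        n = np.asarray(self.normal, float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))


@dataclass(frozen=True)
class SectionContour:
    """Closed CCW polygon in plane coordinates (x lateral, y dorsal, mm)."""

    vertices: np.ndarray  # (n, 2), first vertex not repeated
    plane: CutPlane

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("contour needs at least 3 planar vertices")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class Morphometrics:
    width: float
    depth: float
    perimeter: float
    area: float

    def as_dict(self) -> dict[str, float]:
        return {"width": self.width, "depth": self.depth,
                "perimeter": self.perimeter, "area": self.area}


def _tie_spread(candidates: np.ndarray, argmax_point: np.ndarray,
                coords: list[int]) -> float:
    """How far near-maximal candidates stray from the maximizer."""
    if len(candidates) < 2:
        return 0.0
    d = candidates[:, coords] - argmax_point[coords]
    return float(np.sqrt((d**2).sum(axis=1)).max())


def detect_landmarks(
    mesh: trimesh.Trimesh,
    tie_tolerance: float | None = None,
    spread_fraction: float = 0.35,
    distal_fraction: float = 0.25,
) -> Landmarks:
    """Locate the styloid tip and the dorsal tubercle point on an aligned mesh.

    The styloid tip is the surface point of maximal main-axis (+z)
    coordinate; the tubercle point is the most dorsal (+y) point within the
    distal ``distal_fraction`` of the axial extent.  A feature counts as a
    localized prominence only if every candidate within ``tie_tolerance`` of
    the maximum stays within ``spread_fraction`` of the bone's
    cross-sectional extent of the maximizer; a tie spread across a wide
    region (e.g. a plain cylinder's flat cap or straight dorsal line) raises
    a :class:`LandmarkError`.
    """
    v = np.asarray(mesh.vertices, float)
    if tie_tolerance is None:
        tie_tolerance = 0.6 * float(np.median(mesh.edges_unique_length))
    extent_xy = float(np.linalg.norm(v[:, :2].max(axis=0) - v[:, :2].min(axis=0)))
    spread_limit = spread_fraction * extent_xy

    z = v[:, 2]
    styloid = v[int(z.argmax())]
    styloid_candidates = v[z >= z.max() - tie_tolerance]
    spread = _tie_spread(styloid_candidates, styloid, [0, 1])
    if spread > spread_limit:
        raise LandmarkError(
            "landmarks not identifiable: no unique distal apex "
            f"(tie spread {spread:.1f} mm)"
        )

    axial_extent = float(z.max() - z.min())
    window = v[z >= z.max() - distal_fraction * axial_extent]
    y = window[:, 1]
    tubercle = window[int(y.argmax())]
    tub_candidates = window[y >= y.max() - tie_tolerance]
    spread = _tie_spread(tub_candidates, tubercle, [0, 2])
    if spread > spread_limit:
        raise LandmarkError(
            "landmarks not identifiable: no unique dorsal prominence in the "
            f"distal window (tie spread {spread:.1f} mm)"
        )
    if styloid[2] <= tubercle[2]:
        raise LandmarkError("styloid apex does not lie distal of the dorsal tubercle")
    return Landmarks(styloid_tip=styloid, tubercle_dorsal=tubercle)


def define_cut_planes(landmarks: Landmarks) -> tuple[CutPlane, CutPlane, CutPlane]:
    """Distal/middle/proximal planes from the landmark pair.

    With z_s, z_t the main-axis coordinates of styloid and tubercle and
    d = z_s - z_t > 0: distal at z_t, proximal at z_t - d/2, middle halfway
    between the two; all normals along the main axis, so the planes are
    equidistant (d/4 apart).
    """
    axis = landmarks.axis
    z_s = float(landmarks.styloid_tip @ axis)
    z_t = float(landmarks.tubercle_dorsal @ axis)
    d = z_s - z_t
    if d <= 0:
        raise ValueError("styloid-tubercle axial distance must be positive")
    planes = []
    for label, offset in (("distal", 0.0), ("middle", -d / 4.0), ("proximal", -d / 2.0)):
        origin = axis * (z_t + offset)
        planes.append(CutPlane(label=label, origin=origin, normal=axis))
    return tuple(planes)


def cross_section(mesh: trimesh.Trimesh, plane: CutPlane) -> SectionContour:
    """Intersect the mesh with a cut plane and return the largest closed loop.

    The intersection segments are chained into loops; non-watertight input
    leaving an open chain is an error, as is a plane that misses the mesh.
    The loop is returned counter-clockwise in (lateral, dorsal) plane
    coordinates.
    """
    path = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if path is None or len(path.entities) == 0:
        raise ValueError(
            f"plane {plane.label!r} at offset {plane.origin @ plane.normal:.2f} "
            "misses the mesh"
        )
    # project 3-D loops onto the standardized in-plane axes
    u = np.array([1.0, 0.0, 0.0])
    u = u - (u @ plane.normal) * plane.normal
    u /= np.linalg.norm(u)
    w = np.cross(plane.normal, u)

    loops: list[np.ndarray] = []
    for d in path.discrete:
        closed = np.allclose(d[0], d[-1], atol=1e-8)
        if not closed:
            gap = float(np.linalg.norm(d[0] - d[-1]))
            raise ValueError(
                f"open intersection chain (gap {gap:.3f} mm between "
                f"{d[0]} and {d[-1]}): is the mesh watertight?"
            )
        rel = d[:-1] - plane.origin
        loops.append(np.column_stack([rel @ u, rel @ w]))
    if not loops:
        raise ValueError(f"plane {plane.label!r} produced no closed contour")

    def shoelace(xy: np.ndarray) -> float:
        x, y = xy[:, 0], xy[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    areas = [abs(shoelace(l)) for l in loops]
    best = loops[int(np.argmax(areas))]
    if max(areas) < 1e-9:
        raise ValueError(f"degenerate (zero-area) contour at plane {plane.label!r}")
    if shoelace(best) < 0:
        best = best[::-1]
    return SectionContour(vertices=best, plane=plane)


def section_morphometrics(contour: SectionContour | np.ndarray) -> Morphometrics:
    """Width/depth (axis-aligned extents), perimeter and shoelace area."""
    xy = contour.vertices if isinstance(contour, SectionContour) else np.asarray(contour, float)
    if len(xy) < 3:
        raise ValueError("a contour needs at least 3 vertices")
    closedloop = np.vstack([xy, xy[:1]])
    perimeter = float(np.linalg.norm(np.diff(closedloop, axis=0), axis=1).sum())
    x, y = xy[:, 0], xy[:, 1]
    area = abs(0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return Morphometrics(
        width=float(x.max() - x.min()),
        depth=float(y.max() - y.min()),
        perimeter=perimeter,
        area=area,
    )


def specimen_morphometrics(mesh: trimesh.Trimesh,
                           landmarks: Landmarks | None = None) -> dict[str, Morphometrics]:
    """Landmarks -> planes -> sections -> morphometrics for one specimen."""
    if landmarks is None:
        landmarks = detect_landmarks(mesh)
    planes = define_cut_planes(landmarks)
    return {p.label: section_morphometrics(cross_section(mesh, p)) for p in planes}
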