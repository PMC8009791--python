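"""Landmark-defined reference plane, cross-section extraction and centroids.

The measurement plane is anchored on three external soft-tissue landmarks
(left porion, left and right exocanthion) and translated 40 mm along the
landmark-plane normal toward the cranial vertex.  The cranial outline is the
largest closed loop of the head representation's intersection with that
plane, expressed in an in-plane frame whose +x axis points anterior
(porion toward the exocanthion midpoint) and whose +y axis points to the
subject's left (right-handed with the plane normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure


class GeometryError(ValueError):
    """Degenerate geometric input (collinear landmarks, empty section, ...)."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkSet:
    """Three external landmarks in scanner coordinates (mm).

    Parameters
    ----------
    left_porion, left_exocanthion, right_exocanthion
        3-vectors in mm.  The triangle they span must be non-degenerate.
    """

    left_porion: np.ndarray
    left_exocanthion: np.ndarray
    right_exocanthion: np.ndarray

    def __post_init__(self) -> None:
        for name in ("left_porion", "left_exocanthion", "right_exocanthion"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        area = 0.5 * np.linalg.norm(
            np.cross(
                self.left_exocanthion - self.left_porion,
                self.right_exocanthion - self.left_porion,
            )
        )
        if area < 1e-6:
            raise GeometryError(
                "landmarks are collinear: triangle "
                f"porion={self.left_porion.tolist()}, "
                f"left_exocanthion={self.left_exocanthion.tolist()}, "
                f"right_exocanthion={self.right_exocanthion.tolist()} "
                f"has area {area:.3g} mm^2"
            )

    @property
    def centroid(self) -> np.ndarray:
        return (
            self.left_porion + self.left_exocanthion + self.right_exocanthion
        ) / 3.0


@dataclass(frozen=True)
class ReferencePlane:
    """Measurement plane with an in-plane anatomical frame.

    ``origin`` lies on the plane; ``normal`` is the unit superior direction;
    ``u`` (anterior) and ``v`` (left) are unit in-plane axes forming a
    right-handed triad (u, v, normal).
    """

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    offset_mm: float = 40.0

    def __post_init__(self) -> None:
        for name in ("origin", "normal", "u", "v"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise GeometryError("plane normal must be unit length")

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Project 3D points (n, 3) into (n, 2) in-plane mm coordinates."""
        d = np.atleast_2d(points) - self.origin
        return np.column_stack([d @ self.u, d @ self.v])

    def to_world(self, xy: np.ndarray) -> np.ndarray:
        """Lift (n, 2) in-plane coordinates back to 3D mm points."""
        xy = np.atleast_2d(xy)
        return self.origin + np.outer(xy[:, 0], self.u) + np.outer(xy[:, 1], self.v)


@dataclass
class Outline2D:
    """Closed cranial outline in an in-plane frame (mm).

    ``vertices`` is an (n, 2) array without a repeated closing vertex; the
    polygon is normalized to counter-clockwise orientation.  ``anterior_angle``
    and ``left_angle`` record where the anatomical directions point in this
    frame (radians from +x).
    """

    vertices: np.ndarray
    anterior_angle: float = 0.0
    left_angle: float | None = None
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("outline needs an (n>=3, 2) vertex array")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        # normalize to counter-clockwise
        if _shoelace_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v
        if self.left_angle is None:
            # viewed from superior with the plane normal out of the page,
            # left = normal x anterior, i.e. anterior rotated +90 deg
            self.left_angle = float((self.anterior_angle + np.pi / 2) % (2 * np.pi))
        if not self.polygon.is_simple:
            raise GeometryError("outline polygon is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def area(self) -> float:
        return float(_shoelace_area(self.vertices))


def _shoelace_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def plane_from_landmarks(
    lm: LandmarkSet,
    offset_mm: float = 40.0,
    head_points: np.ndarray | None = None,
) -> ReferencePlane:
    """Reference plane parallel to the landmark plane, ``offset_mm`` above it.

    The normal is oriented toward the cranial vertex.  When ``head_points``
    (any sample of the head representation, (n, 3) mm) is given, the normal
    points to the side of the landmark plane holding the bulk of those
    points — anatomically the cranium lies above the porion/exocanthion
    plane.  Without a hint the normal's largest-magnitude component is made
    positive (a documented convention for axis-aligned data).
    """
    n = np.cross(
        lm.left_exocanthion - lm.left_porion,
        lm.right_exocanthion - lm.left_porion,
    )
    n = n / np.linalg.norm(n)
    if head_points is not None:
        pts = np.atleast_2d(np.asarray(head_points, dtype=float))
        side = float(np.mean((pts - lm.centroid) @ n))
        if side < 0:
            n = -n
    else:
        if n[np.argmax(np.abs(n))] < 0:
            n = -n
    mid_exo = 0.5 * (lm.left_exocanthion + lm.right_exocanthion)
    u = mid_exo - lm.left_porion
    u = u - (u @ n) * n
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise GeometryError("anterior axis undefined: porion lies on the exocanthion midline normal")
    u = u / nu
    v = np.cross(n, u)
    origin = lm.centroid + offset_mm * n
    return ReferencePlane(origin=origin, normal=n, u=u, v=v, offset_mm=float(offset_mm))


def slice_outline(head, plane: ReferencePlane, resolution_mm: float | None = None) -> Outline2D:
    """Intersect a head representation with the reference plane.

    ``head`` is either a :class:`cranioquant.icv.VolumeMask` (binary voxel
    grid) or a ``trimesh.Trimesh`` surface.  Returns the largest-area closed
    intersection loop in in-plane coordinates, anterior mapped to +x.

    Voxel grids are resampled on the plane and contoured at the 0.5
    iso-level with marching squares, giving sub-voxel accuracy.
    """
    from .icv import VolumeMask  # local import to avoid a cycle

    if isinstance(head, VolumeMask):
        loops = _slice_volume(head, plane, resolution_mm)
    else:
        loops = _slice_mesh(head, plane)
    if not loops:
        raise GeometryError("plane does not intersect the head in a closed loop")
    areas = [abs(_shoelace_area(lp)) for lp in loops]
    best = loops[int(np.argmax(areas))]
    if max(areas) <= 1e-6:
        raise GeometryError(
            f"intersection is degenerate: {len(loops)} loop(s), largest area "
            f"{max(areas):.3g} mm^2"
        )
    return Outline2D(vertices=best, anterior_angle=0.0, left_angle=np.pi / 2)


def _slice_mesh(mesh, plane: ReferencePlane) -> list[np.ndarray]:
    section = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if section is None:
        return []
    loops = []
    for poly in section.discrete:
        poly = np.asarray(poly, dtype=float)
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if poly.shape[0] < 3:
            continue
        loops.append(plane.to_plane_coords(poly))
    return loops


def _slice_volume(mask, plane: ReferencePlane, resolution_mm: float | None) -> list[np.ndarray]:
    spacing = np.asarray(mask.spacing_mm, dtype=float)
    if resolution_mm is None:
        resolution_mm = float(spacing.min())
    # project voxel-grid corners into the plane to bound the sampling window
    shape = np.asarray(mask.voxels.shape, dtype=float)
    corners_idx = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    )
    corners_mm = mask.origin_mm + corners_idx * spacing
    uv = plane.to_plane_coords(corners_mm)
    pad = 2 * resolution_mm
    a = np.arange(uv[:, 0].min() - pad, uv[:, 0].max() + pad, resolution_mm)
    b = np.arange(uv[:, 1].min() - pad, uv[:, 1].max() + pad, resolution_mm)
    if a.size < 4 or b.size < 4:
        return []
    A, B = np.meshgrid(a, b, indexing="ij")
    pts = plane.to_world(np.column_stack([A.ravel(), B.ravel()]))
    idx = (pts - mask.origin_mm) / spacing
    vals = ndimage.map_coordinates(
        mask.voxels.astype(np.float32), idx.T, order=1, mode="constant", cval=0.0
    ).reshape(A.shape)
    loops = []
    for contour in measure.find_contours(vals, 0.5):
        if not np.allclose(contour[0], contour[-1]):
            continue  # open contour clipped by the window: not a closed loop
        xy = np.column_stack(
            [a[0] + contour[:-1, 0] * resolution_mm, b[0] + contour[:-1, 1] * resolution_mm]
        )
        if xy.shape[0] >= 3:
            loops.append(xy)
    return loops


def centroid(outline: Outline2D) -> tuple[float, float]:
    """Area centroid (center of mass of the enclosed region) in mm.

    Uses the polygon-moment (shoelace) centroid, *not* the vertex mean:
    the two differ whenever vertex density varies along the outline.
    """
    poly = outline.polygon
    if poly.area <= 1e-12:
        raise GeometryError("outline encloses zero area; centroid undefined")
    c = poly.centroid
    return (float(c.x), float(c.y))


def point_in_outline(outline: Outline2D, xy: tuple[float, float]) -> bool:
    return bool(outline.polygon.contains(Point(*xy)))
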