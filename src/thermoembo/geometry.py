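"""Structured cell-centered finite-volume grids with tagged boundaries.

The computational domain is an axis-aligned box in 1, 2 or 3 dimensions,
discretized into uniform cells. Boundary faces carry one of two tags:
``VESSEL`` for the tissue–vessel interface where the bolus is injected,
and ``FAR`` for the far boundary held at atmospheric pressure. A synthetic
vessel (a tube around a polyline centerline) is embedded by re-tagging the
boundary faces its lumen touches; the lumen itself is not meshed — the
vessel acts purely as an inflow interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "BoundaryTag",
    "StructuredMesh",
    "VesselSpec",
    "GeometryError",
    "make_box_mesh",
    "tag_vessel",
    "measure_boundary",
]

INTERIOR = 0


class BoundaryTag(IntEnum):
    """Tags for boundary faces; interior faces carry the sentinel 0."""

    FAR = 1
    VESSEL = 2


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate geometric input."""


@dataclass
class StructuredMesh:
    """Uniform axis-aligned cell-centered grid.

    Faces are stored flat: interior faces reference an owner and a
    neighbor cell; boundary faces reference an owner only (neighbor ``-1``)
    and carry a :class:`BoundaryTag`. Normals are unit vectors pointing
    from owner to neighbor (outward on the boundary).

    Attributes
    ----------
    shape : cells per axis.
    spacing : cell size per axis (m).
    cell_centers : (n_cells, dim) physical cell-center coordinates (m).
    face_owner, face_neighbor : cell indices per face (neighbor −1 on the
        boundary).
    face_area : face measure (m^2 in 3D, m in 2D, 1 in 1D).
    face_normal : (n_faces, dim) unit normals, owner → neighbor/outward.
    face_centroid : (n_faces, dim) face centroids.
    face_dist : center-to-center distance across the face (center-to-face
        distance for boundary faces); the two-point flux length scale.
    face_tag : 0 interior, else BoundaryTag value.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    extents: tuple[float, ...]
    cell_centers: np.ndarray
    cell_volume: float
    face_owner: np.ndarray
    face_neighbor: np.ndarray
    face_area: np.ndarray
    face_normal: np.ndarray
    face_centroid: np.ndarray
    face_dist: np.ndarray
    face_tag: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_faces(self) -> int:
        return len(self.face_owner)

    @property
    def interior(self) -> np.ndarray:
        """Boolean mask of interior faces."""
        return self.face_tag == INTERIOR

    def boundary_faces(self, tag: BoundaryTag | None = None) -> np.ndarray:
        """Indices of boundary faces, optionally restricted to one tag."""
        if tag is None:
            return np.flatnonzero(self.face_tag != INTERIOR)
        return np.flatnonzero(self.face_tag == int(tag))

    def cell_index(self, multi: Sequence[int]) -> int:
        """Flat cell index from per-axis indices (C order)."""
        return int(np.ravel_multi_index(tuple(multi), self.shape))


@dataclass
class VesselSpec:
    """Synthetic vessel: a tube of given radius around a centerline.

    The centerline is a list of segments (pairs of points, in meters, with
    as many coordinates as the mesh has dimensions); degenerate segments
    (both endpoints equal) describe a point source. Boundary faces whose
    centroid lies within ``radius`` of the centerline are tagged VESSEL.
    """

    segments: list[tuple[tuple[float, ...], tuple[float, ...]]]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("vessel radius must be positive")
        if not self.segments:
            raise GeometryError("vessel centerline needs at least one segment")


def make_box_mesh(extents: Sequence[float], cells: Sequence[int]) -> StructuredMesh:
    """Build a uniform box mesh; all boundary faces initially tagged FAR.

    Parameters
    ----------
    extents : physical size per axis (m).
    cells : cell count per axis.
    """
    extents = tuple(float(e) for e in extents)
    cells = tuple(int(c) for c in cells)
    if len(extents) != len(cells) or not 1 <= len(cells) <= 3:
        raise GeometryError("extents and cells must have matching length 1–3")
    if any(e <= 0 for e in extents) or any(c <= 0 for c in cells):
        raise GeometryError("extents and cell counts must be positive")

    dim = len(cells)
    spacing = tuple(e / c for e, c in zip(extents, cells))
    axes = [
        (np.arange(c) + 0.5) * h for c, h in zip(cells, spacing)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1)
    cell_volume = float(np.prod(spacing))

    owners, neighbors, areas, normals, centroids, dists, tags = (
        [], [], [], [], [], [], [],
    )

    idx = np.arange(np.prod(cells)).reshape(cells)
    for ax in range(dim):
        h = spacing[ax]
        area = cell_volume / h  # cross-section transverse to this axis
        normal = np.zeros(dim)
        normal[ax] = 1.0

        # interior faces between slice i and i+1 along ax
        sl_lo = [slice(None)] * dim
        sl_hi = [slice(None)] * dim
        sl_lo[ax] = slice(0, cells[ax] - 1)
        sl_hi[ax] = slice(1, cells[ax])
        own = idx[tuple(sl_lo)].ravel()
        nbr = idx[tuple(sl_hi)].ravel()
        mid = 0.5 * (centers[own] + centers[nbr])
        owners.append(own)
        neighbors.append(nbr)
        areas.append(np.full(len(own), area))
        normals.append(np.tile(normal, (len(own), 1)))
        centroids.append(mid)
        dists.append(np.full(len(own), h))
        tags.append(np.zeros(len(own), dtype=np.int8))

        # boundary faces at both ends
        for side, sgn in ((0, -1.0), (cells[ax] - 1, +1.0)):
            sl = [slice(None)] * dim
            sl[ax] = side
            own = np.atleast_1d(idx[tuple(sl)]).ravel()
            cent = centers[own].copy()
            cent[:, ax] += sgn * h / 2
            owners.append(own)
            neighbors.append(np.full(len(own), -1))
            areas.append(np.full(len(own), area))
            normals.append(np.tile(sgn * normal, (len(own), 1)))
            centroids.append(cent)
            dists.append(np.full(len(own), h / 2))
            tags.append(np.full(len(own), int(BoundaryTag.FAR), dtype=np.int8))

    return StructuredMesh(
        shape=cells,
        spacing=spacing,
        extents=extents,
        cell_centers=centers,
        cell_volume=cell_volume,
        face_owner=np.concatenate(owners),
        face_neighbor=np.concatenate(neighbors),
        face_area=np.concatenate(areas),
        face_normal=np.concatenate(normals),
        face_centroid=np.concatenate(centroids),
        face_dist=np.concatenate(dists),
        face_tag=np.concatenate(tags),
    )


def _dist_point_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each row of `points` to segment [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:  # degenerate segment == point
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def tag_vessel(mesh: StructuredMesh, spec: VesselSpec) -> StructuredMesh:
    """Re-tag boundary faces touched by the vessel tube as VESSEL (in place).

    A boundary face becomes VESSEL when its centroid lies within
    ``spec.radius`` of the vessel centerline. Raises
    :class:`GeometryError` when the tube misses the boundary entirely.
    """
    bnd = mesh.boundary_faces()
    cent = mesh.face_centroid[bnd]
    hit = np.zeros(len(bnd), dtype=bool)
    for a, b in spec.segments:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != (mesh.dim,) or b.shape != (mesh.dim,):
            raise GeometryError(
                f"segment endpoints must have {mesh.dim} coordinates"
            )
        hit |= _dist_point_segment(cent, a, b) <= spec.radius
    if not hit.any():
        raise GeometryError("vessel tube does not intersect the domain boundary")
    mesh.face_tag[bnd[hit]] = int(BoundaryTag.VESSEL)
    return mesh


def measure_boundary(mesh: StructuredMesh, tag: BoundaryTag) -> float:
    """Total measure (area / length / count) of boundary faces with `tag`."""
    tag = BoundaryTag(tag)  # raises for unknown tags
    faces = mesh.boundary_faces(tag)
    return float(mesh.face_area[faces].sum())
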