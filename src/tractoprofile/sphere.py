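"""Spherical tessellations used as quadrature and search grids for FODs.

The fiber orientation distribution (FOD) is an antipodally symmetric function
on the unit sphere.  Lobe segmentation and lobe integration both work on a
discrete tessellation: a subdivided icosahedron whose vertex set is closed
under the antipodal map, with a per-vertex solid-angle weight so that sums of
``amplitude * weight`` approximate spherical integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh


@dataclass(frozen=True)
class SphereMesh:
    """Unit-sphere tessellation with quadrature weights and adjacency.

    Attributes
    ----------
    vertices : (V, 3) float array
        Unit direction vectors.  The vertex set is antipodally symmetric.
    vertex_solid_angles : (V,) float array
        Positive quadrature weights summing to exactly ``4 * pi``.
    neighbors : (V, K) int array
        Vertex adjacency padded with the vertex's own index, so every row has
        the same length and always contains the vertex itself.
    antipodal_index : (V,) int array
        ``antipodal_index[v]`` is the vertex closest to ``-vertices[v]``.
    subdivisions : int
        Icosphere subdivision level this mesh was built from.
    """

    vertices: np.ndarray
    vertex_solid_angles: np.ndarray
    neighbors: np.ndarray
    antipodal_index: np.ndarray
    subdivisions: int = field(default=-1)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def integrate(self, amplitudes: np.ndarray) -> float:
        """Quadrature integral of a sampled spherical function."""
        return float(np.dot(np.asarray(amplitudes, dtype=float), self.vertex_solid_angles))


def _vertex_solid_angles(mesh: trimesh.Trimesh) -> np.ndarray:
    # Planar face areas shared equally among the three corners, then rescaled
    # so the weights sum to 4*pi exactly.  For icospheres at the subdivision
    # levels used here the planar/spherical discrepancy is well below 0.1%.
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    areas *= 4.0 * np.pi / areas.sum()
    return areas


def _neighbor_table(mesh: trimesh.Trimesh) -> np.ndarray:
    neigh = mesh.vertex_neighbors
    k = max(len(n) for n in neigh)
    table = np.empty((len(neigh), k + 1), dtype=np.int64)
    for v, ns in enumerate(neigh):
        row = list(ns) + [v] * (k + 1 - len(ns))
        table[v] = row
    return table


def _antipodal_index(vertices: np.ndarray) -> np.ndarray:
    # Icosahedral subdivision preserves the antipodal symmetry of the
    # icosahedron, so the nearest vertex to -v is -v itself up to rounding.
    dots = vertices @ vertices.T
    idx = np.argmin(dots, axis=1)
    if not np.allclose(vertices[idx], -vertices, atol=1e-8):
        raise ValueError("vertex set is not antipodally symmetric")
    return idx


@lru_cache(maxsize=8)
def icosphere_mesh(subdivisions: int = 4) -> SphereMesh:
    """Build a subdivided-icosahedron :class:`SphereMesh`.

    Level 3 has 642 vertices (321 axes), level 4 has 2562 (1281 axes).
    Level 4 is the default quadrature grid for AFD computation.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(tm.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    mesh = SphereMesh(
        vertices=verts,
        vertex_solid_angles=_vertex_solid_angles(tm),
        neighbors=_neighbor_table(tm),
        antipodal_index=_antipodal_index(verts),
        subdivisions=subdivisions,
    )
    mesh.vertices.setflags(write=False)
    mesh.vertex_solid_angles.setflags(write=False)
    return mesh
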