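"""Plane-strain triangle meshes of the transected brain inside a rigid skull.

The deformable brain cross-section is meshed with constant-strain triangles
from one of the shared outline profiles; the rigid skull (and the falx
along its superior arc) is an offset polyline surrounding the brain at a
uniform subarachnoid gap.  The cut plane is the modelled plane itself, so
the cover-plate constraint (in-plane translation only) is inherent to the
2-D kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path
from scipy.spatial import Delaunay

from . import geometry

__all__ = ["Mesh2D", "build_geometry", "triangle_quality", "DEFAULT_SKULL_GAP"]

# Brain surface to inner skull surface, mm.  Kept small: the axial
# connectors' rest length equals this gap, and only a near-zero rest
# length lets an axial spring resist tangential as well as radial motion
# of the boundary (the physical subarachnoid space is likewise sub-mm).
DEFAULT_SKULL_GAP = 0.3


@dataclass(frozen=True)
class Mesh2D:
    """Deformable brain mesh plus the rigid skull polyline.

    Attributes
    ----------
    nodes : (n, 2) float
        Brain node coordinates, mm.
    elements : (m, 3) int
        Positively oriented triangles (empty in boundary-only meshes).
    boundary_nodes : (b,) int
        Brain-surface node indices, ordered counter-clockwise.
    skull_points : (b, 2) float
        Rigid inner-skull polyline, one point opposite each boundary node.
    falx_slice : (2,) int
        Contiguous [start, stop) range into the skull ordering spanning the
        superior arc where the falx lies.
    profile : str
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_nodes: np.ndarray
    skull_points: np.ndarray
    falx_slice: tuple[int, int]
    profile: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_surface_nodes(self) -> int:
        return len(self.boundary_nodes)

    @property
    def falx_indices(self) -> np.ndarray:
        return np.arange(self.falx_slice[0], self.falx_slice[1])

    def skull_arclength(self) -> np.ndarray:
        """Cumulative arclength along the skull polyline (open), mm."""
        d = np.linalg.norm(np.diff(self.skull_points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )


def _even_arclength_outline(profile: str, spacing: float, radius: float) -> np.ndarray:
    dense = geometry.profile_points(profile, 2048, radius=radius)
    closed = np.vstack([dense, dense[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 8)
    targets = np.arange(n) * total / n
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def build_geometry(
    profile: str = "sagittal",
    target_edge: float = 4.0,
    radius: float = 25.0,
    skull_gap: float = DEFAULT_SKULL_GAP,
    interior: bool = True,
) -> Mesh2D:
    """Triangulate the chosen cross-section profile.

    Boundary nodes are spaced evenly in arclength at ``target_edge``;
    interior nodes sit on a hexagonal lattice clipped to the outline, and
    the interior is triangulated with Delaunay, dropping triangles outside
    the (possibly concave) outline.  ``interior=False`` builds a
    boundary-only mesh (surface nodes and skull polyline, no elements),
    which is enough for connector accounting.

    Raises ``ValueError`` for degenerate requests (edge too coarse for the
    profile's smallest feature).
    """
    outline = _even_arclength_outline(profile, target_edge, radius)
    n_b = len(outline)
    if n_b < 12:
        raise ValueError(
            f"target_edge={target_edge} mm too coarse for profile {profile!r}"
        )
    phi = np.arctan2(outline[:, 1], outline[:, 0])

    if interior:
        path = Path(outline)
        xmin, ymin = outline.min(axis=0)
        xmax, ymax = outline.max(axis=0)
        dx = target_edge
        dy = target_edge * np.sqrt(3.0) / 2.0
        ys = np.arange(ymin, ymax + dy, dy)
        pts = []
        for i, yv in enumerate(ys):
            xs = np.arange(xmin, xmax + dx, dx) + (0.5 * dx if i % 2 else 0.0)
            pts.append(np.column_stack([xs, np.full_like(xs, yv)]))
        grid = np.vstack(pts)
        inside = path.contains_points(grid)
        grid = grid[inside]
        # keep lattice points clear of the boundary so no sliver triangles form
        d2b = np.min(
            np.linalg.norm(grid[:, None, :] - outline[None, :, :], axis=-1), axis=1
        )
        grid = grid[d2b > 0.6 * target_edge]
        nodes = np.vstack([outline, grid])
        tri = Delaunay(nodes)
        cent = nodes[tri.simplices].mean(axis=1)
        keep = path.contains_points(cent)
        elements = tri.simplices[keep].astype(int)
        # enforce positive (CCW) orientation
        p = nodes[elements]
        signed = (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )
        flip = signed < 0
        elements[flip] = elements[flip][:, [0, 2, 1]]
        if len(elements) == 0:
            raise ValueError("degenerate mesh: no interior triangles")
    else:
        nodes = outline
        elements = np.empty((0, 3), dtype=int)

    normals = geometry.outward_normals(outline)
    skull = outline + skull_gap * normals

    in_arc = (phi >= geometry.FALX_ARC[0]) & (phi <= geometry.FALX_ARC[1])
    idx = np.flatnonzero(in_arc)
    if idx.size == 0:
        raise ValueError("no skull points in the falx arc; refine the boundary")
    falx_slice = (int(idx[0]), int(idx[-1]) + 1)

    return Mesh2D(
        nodes=nodes,
        elements=elements,
        boundary_nodes=np.arange(n_b),
        skull_points=skull,
        falx_slice=falx_slice,
        profile=profile,
    )


def triangle_quality(mesh: Mesh2D) -> np.ndarray:
    """Shape quality 4*sqrt(3)*A / sum(edge^2); 1 for equilateral triangles."""
    p = mesh.nodes[mesh.elements]
    a = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    b = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    area = mesh.element_areas()
    return 4.0 * np.sqrt(3.0) * area / (a**2 + b**2 + c**2)
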