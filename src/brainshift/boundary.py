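"""Brain-skull boundary condition: spring connectors and bridging veins.

The pia-arachnoid complex and CSF are represented by linear elastic spring
connectors joining every brain surface node to its nearest point on the
inner skull/falx surface.  A small number of surface nodes are instead
reserved for bridging veins: tension-only nonlinear axial elements
anchored along the falx arc, clustered anterior-posteriorly the way veins
cluster along the superior sagittal sinus (two short segments and two long
segments of 20/20/30/30% of the falx length; five veins in the first
segment, six in the third, none elsewhere, 11 in total).

Bridging-vein stress-stretch curves: the tabulated vein test data are not
part of this package, so two synthetic piecewise-linear curve families
with the qualitative shapes of the measured behaviours are shipped:
``post_cyclic`` (long compliant toe, then stiff rise - the weakest
tethering case) and ``high_rate`` (short toe, stiffest rise).  All knots
and the shared cross-sectional area are configuration values, not
measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh2D

__all__ = [
    "ConnectorSet",
    "BridgingVein",
    "VEIN_CURVES",
    "DEFAULT_VEIN_AREA_MM2",
    "DEFAULT_ULTIMATE_STRETCH",
    "attach_connectors",
    "place_bridging_veins",
    "vein_force",
]

logger = logging.getLogger(__name__)

#: Synthetic stress-stretch knot tables, (stretch, Cauchy stress Pa).
#: Shapes follow the qualitative vein behaviours (toe region then stiff
#: rise); the knots themselves are package defaults, not measured data.
VEIN_CURVES: dict[str, np.ndarray] = {
    "post_cyclic": np.array(
        [[1.00, 0.0], [1.25, 0.10e6], [1.45, 1.0e6], [1.65, 5.0e6]]
    ),
    "high_rate": np.array(
        [[1.00, 0.0], [1.08, 0.30e6], [1.25, 6.0e6], [1.45, 13.0e6]]
    ),
}

DEFAULT_VEIN_AREA_MM2 = 0.6   # shared cross-sectional area, synthetic default
DEFAULT_ULTIMATE_STRETCH = 1.8  # average ultimate stretch ratio, synthetic default


@dataclass(frozen=True)
class ConnectorSet:
    """Linear elastic springs between brain surface nodes and skull points.

    ``mode="cartesian"`` (default): the spring resists the full relative
    displacement vector of its endpoints away from the rest chord
    (corotated with the skull), i.e. both normal and tangential motion -
    the behaviour needed for the boundary to rigidify as k grows.
    ``mode="axial"``: force -k (length - rest length) along the current
    chord only; tangential sliding is then resisted only at second order.
    """

    brain_nodes: np.ndarray    # (c,) indices into mesh.nodes
    skull_indices: np.ndarray  # (c,) indices into mesh.skull_points
    stiffness: float           # N/m, identical for every connector
    rest_lengths: np.ndarray   # (c,) mm
    rest_vectors: np.ndarray = None  # type: ignore[assignment]  # (c, 2) mm, brain - skull at rest
    mode: str = "cartesian"

    def __len__(self) -> int:
        return len(self.brain_nodes)


@dataclass(frozen=True)
class BridgingVein:
    """Tension-only axial element from a brain surface node to the falx."""

    brain_node: int
    falx_index: int            # nearest index into mesh.skull_points
    falx_point: np.ndarray     # exact anchor on the falx polyline, mm
    initial_length: float      # mm
    area: float = DEFAULT_VEIN_AREA_MM2          # mm^2
    curve: str = "post_cyclic"
    knots: np.ndarray = field(default=None)      # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.knots is None:
            object.__setattr__(self, "knots", VEIN_CURVES[self.curve])
        k = np.asarray(self.knots, float)
        if k[0, 0] != 1.0 or k[0, 1] != 0.0:
            raise ValueError("stress-stretch curve must pass through (1, 0)")
        if np.any(np.diff(k[:, 0]) <= 0) or np.any(np.diff(k[:, 1]) < 0):
            raise ValueError("stress-stretch curve must be monotone non-decreasing")


def attach_connectors(
    mesh: Mesh2D,
    k: float,
    exclude: set[int] | frozenset[int] = frozenset(),
    mode: str = "cartesian",
) -> ConnectorSet:
    """One connector per non-reserved brain surface node to the nearest skull point.

    The spring is linear with stiffness ``k`` and acts in both tension and
    compression; see :class:`ConnectorSet` for the two force conventions.
    """
    if mode not in ("cartesian", "axial"):
        raise ValueError(f"unknown connector mode {mode!r}")
    keep = np.array([n for n in mesh.boundary_nodes if n not in exclude], dtype=int)
    if keep.size == 0:
        return ConnectorSet(keep, keep.copy(), k, np.empty(0),
                            np.empty((0, 2)), mode)
    d = np.linalg.norm(
        mesh.nodes[keep][:, None, :] - mesh.skull_points[None, :, :], axis=-1
    )
    nearest = np.argmin(d, axis=1)
    rest = d[np.arange(keep.size), nearest]
    rest_vec = mesh.nodes[keep] - mesh.skull_points[nearest]
    return ConnectorSet(keep, nearest.astype(int), float(k), rest, rest_vec, mode)


def place_bridging_veins(
    mesh: Mesh2D,
    counts: tuple[int, ...] = (5, 0, 6, 0),
    fractions: tuple[float, ...] = (0.20, 0.20, 0.30, 0.30),
    curve: str = "post_cyclic",
    area: float = DEFAULT_VEIN_AREA_MM2,
) -> list[BridgingVein]:
    """Distribute veins along the falx arc by segment fractions and counts.

    The falx arclength is divided anterior-to-posterior into segments of
    the given fractions; inside each populated segment with count c the
    anchors sit at arclength fractions i/(c+1), i = 1..c, which spaces
    them evenly and keeps them off the segment endpoints (no anchors at
    exact midline/segment junction points).  Each falx anchor connects to
    the nearest brain surface node (each node used at most once); those
    nodes become the vein reservations excluded from the general
    connectors.
    """
    if len(counts) != len(fractions):
        raise ValueError("counts and fractions must have the same length")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("segment fractions must sum to 1")
    f0, f1 = mesh.falx_slice
    falx_idx = np.arange(f0, f1)
    if sum(counts) > mesh.n_surface_nodes:
        raise ValueError(
            f"{sum(counts)} veins exceed the {mesh.n_surface_nodes} "
            "available brain surface nodes"
        )
    s_all = mesh.skull_arclength()
    s = s_all[falx_idx] - s_all[f0]
    total = s[-1]
    if total <= 0:
        raise ValueError("falx arc has zero length; refine the boundary")

    veins: list[BridgingVein] = []
    used_brain: set[int] = set()
    seg_start = 0.0
    for count, frac in zip(counts, fractions):
        seg_len = frac * total
        for i in range(1, count + 1):
            target = seg_start + seg_len * i / (count + 1)
            # exact anchor interpolated in arclength along the falx polyline
            ax = np.interp(target, s, mesh.skull_points[falx_idx, 0])
            ay = np.interp(target, s, mesh.skull_points[falx_idx, 1])
            anchor = np.array([ax, ay])
            fi = falx_idx[int(np.argmin(np.abs(s - target)))]
            cand = [n for n in mesh.boundary_nodes if n not in used_brain]
            dists = np.linalg.norm(mesh.nodes[cand] - anchor, axis=1)
            bn = int(cand[int(np.argmin(dists))])
            used_brain.add(bn)
            L0 = float(np.linalg.norm(mesh.nodes[bn] - anchor))
            veins.append(
                BridgingVein(brain_node=bn, falx_index=int(fi), falx_point=anchor,
                             initial_length=L0, area=area, curve=curve)
            )
        seg_start += seg_len
    return veins


def vein_force(current_length: float, vein: BridgingVein) -> float:
    """Axial tension (N) at the given length; zero in compression.

    stretch = L / L0; force = area x sigma(stretch) for stretch > 1 from
    the piecewise-linear stress-stretch curve, clamped (with a warning) at
    the last knot.  Units: area mm^2 x stress Pa = 1e-6 N per Pa mm^2.
    """
    if current_length <= 0:
        raise ValueError("current_length must be positive")
    lam = current_length / vein.initial_length
    if lam <= 1.0:
        return 0.0
    knots = np.asarray(vein.knots, float)
    if lam > knots[-1, 0]:
        logger.warning(
            "vein stretch %.3f beyond curve domain (last knot %.3f); clamping",
            lam, knots[-1, 0],
        )
        sigma = knots[-1, 1]
    else:
        sigma = float(np.interp(lam, knots[:, 0], knots[:, 1]))
    return vein.area * 1e-6 * sigma  # mm^2 * Pa -> N
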