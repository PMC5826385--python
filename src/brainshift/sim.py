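"""Reduced-order 2-D explicit dynamics of a brain section in a rotating skull.

The deformable brain cross-section (constant-strain triangles, Ogden/Prony
material, plane strain) sits inside a rigid skull polyline that follows
the prescribed angular-velocity pulse exactly.  Brain nodes evolve under
element stresses, spring-connector forces, tension-only bridging-vein
forces, penalty contact with Coulomb friction against the skull, and
light mass-proportional damping, integrated with the semi-implicit
central-difference scheme standard for explicit solid dynamics.

Internally everything runs in SI units (m, s, kg, Pa, N); the mesh and all
outputs are in millimetres, and the output is sampled at the video frame
rate so simulated trajectories flow through the same displacement
analysis as the physical experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import BridgingVein, ConnectorSet
from .displacement import DEFAULT_N_BASELINE, DotPair, relative_displacement
from .material import OgdenPronyMaterial, PronyHistory, deviatoric_kirchhoff_2d, ogden_energy
from .mesh import Mesh2D
from .pulse import RotationPulse, cfc_filter
from .tracking import MarkerTrack
from . import geometry

__all__ = [
    "SimulationConfig",
    "SimResult",
    "simulate",
    "extract_model_displacements",
    "default_marker_map",
    "stable_dt",
]

#: Intact (non-transected) brain mass the model normalises to; the
#: hemisection carries half of it.
INTACT_BRAIN_MASS_KG = 0.0446


@dataclass(frozen=True)
class SimulationConfig:
    """Solver controls.

    dt
        Time step in s; ``None`` derives ``dt_safety`` x the stability bound from the
        dilatational wave speed, connector/contact stiffness and vein
        tangent stiffness.
    friction_mu
        Coulomb coefficient for brain-skull contact (0.2 default).
    contact_penalty
        Normal penalty stiffness per surface node, N/m.
    damping_ratio
        Mass-proportional damping as a fraction of critical for the
        rigid-translation mode on the connectors (0.05 default; light
        enough to leave the displacement waveform intact while keeping
        the sliding boundary numerically tame at the softest stiffnesses).
    thickness
        Out-of-plane thickness in mm; ``None`` scales it so the section
        carries half the intact brain mass at the material density.
    cfc_class
        Channel class for pre-filtering the input pulse (``None`` skips).
    """

    dt: float | None = None
    friction_mu: float = 0.2
    contact_penalty: float = 5000.0
    damping_ratio: float = 0.05
    thickness: float | None = None
    output_rate: float = 2500.0
    cfc_class: float | None = 200.0
    dt_safety: float = 0.5
    seed: int = 0
    track_energy: bool = False
    vein_stretch_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction_mu < 0:
            raise ValueError("friction_mu must be >= 0")


@dataclass
class SimResult:
    """Sampled trajectories of one simulation (mm, s)."""

    times: np.ndarray                 # (n_t,)
    brain_positions: np.ndarray       # (n_t, n_nodes, 2) mm, laboratory frame
    skull_positions: np.ndarray       # (n_t, n_skull, 2) mm
    theta: np.ndarray                 # (n_t,) rad
    mesh: Mesh2D
    energies: np.ndarray | None = None      # (n_t, 2) kinetic, elastic (J)
    max_vein_stretch: float = 0.0
    vein_stretch_exceeded: bool = False

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def stable_dt(
    mesh: Mesh2D,
    material: OgdenPronyMaterial,
    connectors: ConnectorSet,
    veins: list[BridgingVein],
    config: SimulationConfig,
    node_mass: np.ndarray,
) -> float:
    """``dt_safety`` x the explicit stability bound (CFL and stiffest spring)."""
    p = mesh.nodes[mesh.elements] * 1e-3
    edges = np.concatenate([
        np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
        np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
        np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
    ])
    m_pwave = material.bulk_modulus + 4.0 * material.mu0 / 3.0
    c_d = np.sqrt(m_pwave / material.rho)
    dt_cfl = float(edges.min() / c_d)

    m_surf = node_mass[mesh.boundary_nodes].min()
    k_candidates = [config.contact_penalty]
    if len(connectors):
        k_candidates.append(connectors.stiffness)
    for v in veins:
        knots = np.asarray(v.knots, float)
        slope = np.max(np.diff(knots[:, 1]) / np.diff(knots[:, 0]))  # Pa per stretch
        k_candidates.append(v.area * 1e-6 * slope / (v.initial_length * 1e-3))
    k_max = max(k_candidates)
    dt_spring = 2.0 / np.sqrt(k_max / m_surf)
    return config.dt_safety * min(dt_cfl, dt_spring)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def simulate(
    mesh: Mesh2D,
    material: OgdenPronyMaterial,
    connectors: ConnectorSet,
    veins: list[BridgingVein],
    pulse: RotationPulse,
    config: SimulationConfig = SimulationConfig(),
    rotation_center: tuple[float, float] = geometry.DEFAULT_ROTATION_CENTER,
) -> SimResult:
    """Run the rotation experiment on the given mesh.

    Skull points follow the rigid rotation of the (CFC-filtered) pulse
    exactly; brain nodes integrate explicitly.  Aborts with a diagnostic on
    element inversion or energy blow-up.
    """
    if len(mesh.elements) == 0:
        raise ValueError("simulate requires a mesh with interior elements")

    nodes_m = mesh.nodes * 1e-3
    skull_m = mesh.skull_points * 1e-3
    center = np.asarray(rotation_center, float) * 1e-3

    areas_m2 = mesh.element_areas() * 1e-6
    total_area = float(areas_m2.sum())
    if config.thickness is not None:
        thickness = config.thickness * 1e-3
    else:
        thickness = 0.5 * INTACT_BRAIN_MASS_KG / (material.rho * total_area)
    elem_mass = material.rho * thickness * areas_m2
    node_mass = np.zeros(mesh.n_nodes)
    np.add.at(node_mass, mesh.elements.ravel(), np.repeat(elem_mass / 3.0, 3))

    # reference element geometry
    X = nodes_m[mesh.elements]                      # (m, 3, 2)
    Dm = np.stack([X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]], axis=-1)  # (m, 2, 2)
    Dm_inv = np.linalg.inv(Dm)

    w_in = pulse.angular_velocity
    if config.cfc_class is not None:
        w_in = cfc_filter(w_in, 1.0 / pulse.dt, config.cfc_class)
    theta_grid = np.concatenate(
        [[0.0], np.cumsum(0.5 * (w_in[1:] + w_in[:-1]) * np.diff(pulse.time))]
    )

    dt = config.dt if config.dt is not None else stable_dt(
        mesh, material, connectors, veins, config, node_mass
    )
    t_end = float(pulse.time[-1])
    n_steps = int(np.ceil(t_end / dt))

    # damping: fraction of critical for the rigid mode on the connectors
    if len(connectors):
        omega_rigid = np.sqrt(
            len(connectors) * connectors.stiffness / node_mass.sum()
        )
        damp = 2.0 * config.damping_ratio * omega_rigid
    else:
        damp = 0.0

    history = PronyHistory(material, len(mesh.elements))
    K_bulk = material.bulk_modulus

    surf = mesh.boundary_nodes
    out_norm = geometry.outward_normals(mesh.nodes[surf])   # reference frame
    conn_rest = connectors.rest_lengths * 1e-3
    conn_rest_vec = (
        connectors.rest_vectors * 1e-3 if connectors.rest_vectors is not None
        else np.empty((0, 2))
    )
    vein_brain = np.array([v.brain_node for v in veins], dtype=int)
    vein_anchor_rel = (
        np.array([v.falx_point for v in veins]).reshape(-1, 2) * 1e-3 - center
    )
    vein_L0 = np.array([v.initial_length for v in veins]) * 1e-3
    vein_area = np.array([v.area for v in veins]) * 1e-6
    if veins:
        vein_knots = [np.asarray(v.knots, float) for v in veins]

    x = nodes_m.copy()
    v = np.zeros_like(x)

    out_dt = 1.0 / config.output_rate
    n_out = int(np.floor(t_end / out_dt)) + 1
    out_times = np.arange(n_out) * out_dt
    out_brain = np.empty((n_out, mesh.n_nodes, 2))
    out_skull = np.empty((n_out, len(skull_m), 2))
    out_theta = np.empty(n_out)
    out_energy = np.empty((n_out, 2)) if config.track_energy else None
    next_out = 0
    max_vein_stretch = 0.0

    skull_rel = skull_m - center
    domain_scale = float(np.abs(nodes_m).max() + np.abs(center).max()) + 1.0

    def record(i_out: int, t: float, theta: float, skull_now: np.ndarray) -> None:
        out_brain[i_out] = x * 1e3
        out_skull[i_out] = skull_now * 1e3
        out_theta[i_out] = theta
        if out_energy is not None:
            ke = 0.5 * float(np.sum(node_mass[:, None] * v**2))
            Fd = np.einsum(
                "mab,mbc->mac",
                np.stack([x[mesh.elements][:, 1] - x[mesh.elements][:, 0],
                          x[mesh.elements][:, 2] - x[mesh.elements][:, 0]], axis=-1),
                Dm_inv,
            )
            J = Fd[:, 0, 0] * Fd[:, 1, 1] - Fd[:, 0, 1] * Fd[:, 1, 0]
            C = np.einsum("mji,mjk->mik", Fd, Fd)
            trC = C[:, 0, 0] + C[:, 1, 1]
            lam1sq = np.maximum(trC / 2 + np.sqrt(np.maximum((trC / 2) ** 2 - J**2, 0)), 1e-12)
            lam2sq = np.maximum(trC - lam1sq, 1e-12)
            Jm13 = np.maximum(J, 1e-12) ** (-1.0 / 3.0)
            lams = np.stack(
                [np.sqrt(lam1sq) * Jm13, np.sqrt(lam2sq) * Jm13, Jm13], axis=-1
            )
            W = ogden_energy(lams, material.mu0, material.alpha)
            W_vol = 0.5 * K_bulk * (J - 1.0) ** 2
            pe = float(np.sum((W + W_vol) * areas_m2 * thickness))
            if len(connectors):
                d = x[connectors.brain_nodes] - skull_now[connectors.skull_indices]
                if connectors.mode == "cartesian":
                    u = d - conn_rest_vec @ _rotation(theta).T
                    pe += 0.5 * connectors.stiffness * float(np.sum(u * u))
                else:
                    ext = np.linalg.norm(d, axis=1) - conn_rest
                    pe += 0.5 * connectors.stiffness * float(np.sum(ext**2))
            out_energy[i_out] = (ke, pe)

    theta_now = 0.0
    R = _rotation(theta_now)
    record(0, 0.0, theta_now, center + skull_rel @ R.T)
    next_out = 1

    for step in range(1, n_steps + 1):
        t = step * dt
        theta_now = float(np.interp(t, pulse.time, theta_grid))
        omega_now = float(np.interp(t, pulse.time, w_in))
        R = _rotation(theta_now)
        skull_now = center + skull_rel @ R.T

        f = np.zeros_like(x)

        # --- element stresses ---
        xe = x[mesh.elements]
        Ds = np.stack([xe[:, 1] - xe[:, 0], xe[:, 2] - xe[:, 0]], axis=-1)
        Fd = np.einsum("mab,mbc->mac", Ds, Dm_inv)
        try:
            tau_inst, J = deviatoric_kirchhoff_2d(Fd, material.mu0, material.alpha)
        except ValueError as exc:
            raise RuntimeError(
                f"element inversion at step {step} (t={t:.5f} s): {exc}"
            ) from exc
        tau_dev = history.relax(tau_inst, dt)
        eye = np.eye(2)
        sigma = tau_dev / J[:, None, None] + (K_bulk * (J - 1.0))[:, None, None] * eye
        Finv = np.linalg.inv(Fd)
        P = J[:, None, None] * np.einsum("mij,mkj->mik", sigma, Finv)
        H = -np.einsum("m,mij,mkj->mik", areas_m2 * thickness, P, Dm_inv)
        np.add.at(f, mesh.elements[:, 1], H[:, :, 0])
        np.add.at(f, mesh.elements[:, 2], H[:, :, 1])
        np.add.at(f, mesh.elements[:, 0], -(H[:, :, 0] + H[:, :, 1]))

        # --- connectors ---
        if len(connectors):
            xb = x[connectors.brain_nodes]
            xs = skull_now[connectors.skull_indices]
            d = xb - xs
            if connectors.mode == "cartesian":
                u = d - conn_rest_vec @ R.T
                f[connectors.brain_nodes] += -connectors.stiffness * u
            else:  # axial
                L = np.linalg.norm(d, axis=1)
                Ls = np.where(L > 1e-12, L, 1.0)
                fmag = -connectors.stiffness * (L - conn_rest)
                f[connectors.brain_nodes] += (fmag / Ls)[:, None] * d

        # --- bridging veins (tension only) ---
        if len(veins):
            xb = x[vein_brain]
            xf = center + vein_anchor_rel @ R.T
            d = xf - xb
            L = np.linalg.norm(d, axis=1)
            lam = L / vein_L0
            max_vein_stretch = max(max_vein_stretch, float(lam.max()))
            sig = np.array([
                float(np.interp(min(la, kn[-1, 0]), kn[:, 0], kn[:, 1])) if la > 1 else 0.0
                for la, kn in zip(lam, vein_knots)
            ])
            fmag = vein_area * sig
            Ls = np.where(L > 1e-12, L, 1.0)
            f[vein_brain] += (fmag / Ls)[:, None] * d

        # --- contact with the skull polyline ---
        xsur = x[surf]
        n_lab = out_norm @ R.T
        gap = np.einsum("ij,ij->i", xsur - skull_now, n_lab)
        pen = gap > 0.0
        if pen.any():
            fn = config.contact_penalty * gap[pen]
            f[surf[pen]] -= fn[:, None] * n_lab[pen]
            # Coulomb-capped viscous tangential force (stick regularisation)
            tang = np.column_stack([-n_lab[pen][:, 1], n_lab[pen][:, 0]])
            v_skull = omega_now * np.column_stack(
                [-(xsur[pen][:, 1] - center[1]), xsur[pen][:, 0] - center[0]]
            )
            v_rel = np.einsum("ij,ij->i", v[surf[pen]] - v_skull, tang)
            cap = config.friction_mu * fn
            ft = -np.clip(v_rel / 1e-3, -1.0, 1.0) * cap
            f[surf[pen]] += ft[:, None] * tang

        a = f / node_mass[:, None] - damp * v
        v = v + dt * a
        x = x + dt * v

        if not np.all(np.isfinite(x)) or np.abs(x).max() > 10.0 * domain_scale:
            raise RuntimeError(
                f"energy blow-up at step {step} (t={t:.5f} s): "
                "positions diverged; reduce dt or stiffness"
            )

        while next_out < n_out and out_times[next_out] <= t + 0.5 * dt:
            record(next_out, t, theta_now, skull_now)
            next_out += 1

    result = SimResult(
        times=out_times,
        brain_positions=out_brain,
        skull_positions=out_skull,
        theta=out_theta,
        mesh=mesh,
        energies=out_energy,
        max_vein_stretch=max_vein_stretch,
    )
    if config.vein_stretch_threshold is not None:
        result.vein_stretch_exceeded = max_vein_stretch > config.vein_stretch_threshold
    return result


def default_marker_map(
    mesh: Mesh2D,
    n_brain: int = 13,
    n_rigid: int = 6,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> dict:
    """Virtual ink-dot map: evenly spaced surface nodes and skull points.

    Returns ``{marker_id: (label, indices)}`` where brain indices refer to
    mesh nodes and rigid indices to skull points.  ``exclude`` skips
    nodes (e.g. vein-reserved ones, which at coarse resolution would put a
    marker on an unconnected node - a mesh artifact a physical ink dot
    would not see).
    """
    avail = np.array([n for n in mesh.boundary_nodes if n not in exclude])
    nb = len(avail)
    if n_brain > nb:
        raise ValueError(f"requested {n_brain} brain markers, {nb} nodes available")
    bsel = avail[np.linspace(0, nb - 1, n_brain, dtype=int)]
    rsel = np.linspace(0, len(mesh.skull_points) - 1, n_rigid, dtype=int)
    marker_map = {}
    for i, n in enumerate(bsel):
        marker_map[i] = ("brain", [int(n)])
    for j, s in enumerate(rsel):
        marker_map[n_brain + j] = ("rigid", [int(s)])
    return marker_map


def extract_model_displacements(
    result: SimResult,
    marker_map: dict,
    motion_start_frame: int,
    n_baseline: int = DEFAULT_N_BASELINE,
    superior_mask: np.ndarray | None = None,
) -> list[DotPair]:
    """Run the measurement pipeline on virtual markers of a simulation.

    Each virtual marker position is the mean of its mapped node (or skull
    point) positions per output step - the same dot-to-node averaging used
    when registering physical ink dots onto the model.  Pairs are formed
    brain -> nearest rigid at frame 0 and analysed identically to the
    physical experiments (baseline subtraction, motion maxima).
    """
    brain_tracks, rigid_tracks = [], []
    n_t = len(result.times)
    frames = list(range(n_t))
    for mid, (label, idxs) in sorted(marker_map.items()):
        if len(idxs) == 0:
            raise ValueError(f"marker {mid} maps to an empty node set")
        if label == "brain":
            pos = result.brain_positions[:, idxs, :].mean(axis=1)
            brain_tracks.append(
                MarkerTrack(mid, frames, list(pos), label="brain")
            )
        else:
            pos = result.skull_positions[:, idxs, :].mean(axis=1)
            rigid_tracks.append(
                MarkerTrack(mid, frames, list(pos), label="rigid")
            )
    from .displacement import pair_markers  # local import avoids cycle at module load

    pairs = pair_markers(brain_tracks, rigid_tracks, superior_mask)
    return [
        relative_displacement(bt, rt, motion_start_frame, n_baseline,
                              mm_per_px=1.0, superior=sup)
        for bt, rt, sup in pairs
    ]
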