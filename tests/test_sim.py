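import numpy as np
import pytest

from brainshift import boundary, sim
from brainshift.displacement import pooled_mean
from brainshift.material import OgdenPronyMaterial
from brainshift.mesh import build_geometry
from brainshift.pulse import generate_pulse
from brainshift.sim import (
    SimulationConfig,
    default_marker_map,
    extract_model_displacements,
    simulate,
)


def _run(mesh, k, pulse, material, veins=(), config=None, exclude=frozenset()):
    conn = boundary.attach_connectors(mesh, k, exclude=exclude)
    return simulate(mesh, material, conn, list(veins), pulse,
                    config or SimulationConfig())


def _pair_maxima(mesh, result, pulse, n_brain=10, n_rigid=5, exclude=frozenset()):
    mm = default_marker_map(mesh, n_brain, n_rigid, exclude=exclude)
    start = int(round(pulse.motion_start_time() * 2500))
    pairs = extract_model_displacements(result, mm, start)
    return np.array([p.max_disp_motion for p in pairs])


class TestSimulate:
    def test_zero_pulse_no_motion(self, circle_mesh, material):
        dt = 1e-4
        quiet = generate_pulse(1e-9, 1.0, 1.0, 1e-12, pad_before=0.01, pad_after=0.01)
        res = _run(circle_mesh, 100.0, quiet, material)
        disp = np.linalg.norm(
            res.brain_positions - res.brain_positions[0], axis=-1
        )
        assert disp.max() < 1e-6

    def test_rigid_limit_small_displacement(self, circle_mesh, material, gentle_pulse):
        """At k = 1e6 N/m the boundary is effectively rigid: pair maxima
        stay below 0.02 mm."""
        res = _run(circle_mesh, 1e6, gentle_pulse, material)
        mx = _pair_maxima(circle_mesh, res, gentle_pulse)
        assert mx.max() < 0.02

    def test_peak_near_end_of_deceleration(self, sagittal_mesh, material,
                                           standard_pulse, sagittal_veins):
        """With the calibration-range stiffness, the pooled relative
        displacement trace peaks late in the pulse, around the end of
        deceleration."""
        reserved = {v.brain_node for v in sagittal_veins}
        res = _run(sagittal_mesh, 100.0, standard_pulse, material,
                   veins=sagittal_veins, exclude=reserved)
        mm = default_marker_map(sagittal_mesh, 10, 5, exclude=reserved)
        start = int(round(standard_pulse.motion_start_time() * 2500))
        pairs = extract_model_displacements(res, mm, start)
        # pooled |rel_disp| over time
        pooled = np.mean([np.abs(p.rel_disp) for p in pairs], axis=0)
        t_peak = res.times[int(np.argmax(pooled))]
        w = np.abs(standard_pulse.angular_velocity)
        t_decel_start = standard_pulse.time[int(np.argmax(w))]
        t_end = standard_pulse.time[
            np.flatnonzero(w > 0.01 * standard_pulse.peak_velocity)[-1]
        ]
        assert t_peak > t_decel_start  # in or after the deceleration phase
        assert t_peak < t_end + 0.03   # not drifting into late free ringing

    def test_stiffness_monotonicity(self, circle_mesh, material, standard_pulse):
        veins = boundary.place_bridging_veins(circle_mesh)
        reserved = {v.brain_node for v in veins}
        means = []
        for k in (50.0, 200.0, 800.0):
            res = _run(circle_mesh, k, standard_pulse, material,
                       veins=veins, exclude=reserved)
            means.append(_pair_maxima(circle_mesh, res, standard_pulse,
                                      exclude=reserved).mean())
        assert means[0] > means[1] > means[2]

    def test_geometry_dominance(self, material, standard_pulse):
        """At equal stiffness and pulse, the smooth circular section slides
        more than the irregular sagittal section."""
        k = 150.0
        out = {}
        for name in ("circle", "sagittal"):
            mesh = build_geometry(name, 5.0, radius=25.0)
            veins = boundary.place_bridging_veins(mesh)
            reserved = {v.brain_node for v in veins}
            res = _run(mesh, k, standard_pulse, material,
                       veins=veins, exclude=reserved)
            out[name] = _pair_maxima(mesh, res, standard_pulse,
                                     exclude=reserved).mean()
        assert out["circle"] > out["sagittal"]

    def test_energy_conservation_free_ringing(self, circle_mesh):
        """With damping, contact and viscous relaxation effectively off,
        total mechanical energy drifts < 2% while the brain rings freely
        after a small pulse."""
        elastic = OgdenPronyMaterial(C1=1e-9, C2=1e-9)
        pulse = generate_pulse(5.0, 2e3, 2e3, 0.05,
                               pad_before=0.005, pad_after=0.08)
        cfg = SimulationConfig(damping_ratio=0.0, track_energy=True,
                               dt_safety=0.2, contact_penalty=0.0,
                               friction_mu=0.0)
        res = _run(circle_mesh, 100.0, pulse, elastic, config=cfg)
        total = res.energies.sum(axis=1)
        # compare over the free-ringing tail (pulse over, skull at rest)
        tail = res.times > (pulse.duration - 0.07)
        e = total[tail]
        assert e.max() > 0  # it is actually ringing
        assert (e.max() - e.min()) / e.max() < 0.02

    def test_element_inversion_diagnostic(self, material):
        mesh = build_geometry("circle", 6.0, radius=25.0)
        # violent pulse with a stiff dragged boundary and no contact
        # backing shears the interior past inversion
        pulse = generate_pulse(300.0, 8e4, 8e4, 4.0, pad_before=0.002)
        with pytest.raises(RuntimeError, match="inversion|blow-up"):
            _run(mesh, 5e3, pulse, material,
                 config=SimulationConfig(contact_penalty=0.0, damping_ratio=0.0))

    def test_tension_only_veins_inactive_when_slack(self, circle_mesh, material,
                                                    gentle_pulse):
        """With a rigid boundary the veins never stretch, so results with
        and without veins coincide."""
        veins = boundary.place_bridging_veins(circle_mesh)
        res_v = _run(circle_mesh, 1e5, gentle_pulse, material, veins=veins)
        res_0 = _run(circle_mesh, 1e5, gentle_pulse, material)
        assert res_v.max_vein_stretch < 1.005
        assert np.allclose(res_v.brain_positions, res_0.brain_positions, atol=1e-4)

    def test_output_rate(self, circle_mesh, material, gentle_pulse):
        res = _run(circle_mesh, 100.0, gentle_pulse, material)
        assert res.frame_rate == pytest.approx(2500.0)

    def test_skull_follows_pulse_exactly(self, circle_mesh, material, gentle_pulse):
        res = _run(circle_mesh, 100.0, gentle_pulse, material)
        assert res.theta[-1] == pytest.approx(gentle_pulse.total_angle, rel=2e-2)
        d = np.linalg.norm(
            np.diff(
                np.linalg.norm(
                    res.skull_positions - res.skull_positions[:, :1], axis=-1
                ),
                axis=0,
            )
        )
        assert d < 1e-8  # rigid: inter-point distances never change


class TestMarkerExtraction:
    def test_single_node_map_equals_node_trajectory(self, circle_mesh, material,
                                                    gentle_pulse):
        res = _run(circle_mesh, 200.0, gentle_pulse, material)
        nid = int(circle_mesh.boundary_nodes[0])
        mm = {0: ("brain", [nid]), 1: ("rigid", [0])}
        start = int(round(gentle_pulse.motion_start_time() * 2500))
        pairs = extract_model_displacements(res, mm, start)
        assert len(pairs) == 1

    def test_four_node_rigid_patch_virtual_marker(self, circle_mesh, material,
                                                  gentle_pulse):
        """Averaging rigidly co-moving skull points keeps the virtual
        marker rigid to numerical precision."""
        res = _run(circle_mesh, 200.0, gentle_pulse, material)
        virt = res.skull_positions[:, [0, 1, 2, 3], :].mean(axis=1)
        ref = res.skull_positions[:, 5, :]
        d = np.linalg.norm(virt - ref, axis=1)
        assert np.ptp(d) < 1e-9

    def test_empty_node_set_error(self, circle_mesh, material, gentle_pulse):
        res = _run(circle_mesh, 200.0, gentle_pulse, material)
        with pytest.raises(ValueError, match="empty"):
            extract_model_displacements(res, {0: ("brain", [])}, 10)

    def test_softer_boundary_larger_displacement_per_pair(
        self, circle_mesh, material, standard_pulse
    ):
        veins = boundary.place_bridging_veins(circle_mesh)
        reserved = {v.brain_node for v in veins}
        r1 = _pair_maxima(circle_mesh,
                          _run(circle_mesh, 60.0, standard_pulse, material,
                               veins=veins, exclude=reserved),
                          standard_pulse, exclude=reserved)
        r2 = _pair_maxima(circle_mesh,
                          _run(circle_mesh, 600.0, standard_pulse, material,
                               veins=veins, exclude=reserved),
                          standard_pulse, exclude=reserved)
        assert r1.mean() > r2.mean()
        assert np.mean(r1 >= r2) > 0.7  # holds for most pairs individually


def test_boundary_only_mesh_rejected(material, gentle_pulse):
    m = build_geometry("circle", 3.0, interior=False)
    conn = boundary.attach_connectors(m, 100.0)
    with pytest.raises(ValueError, match="interior"):
        simulate(m, material, conn, [], gentle_pulse)
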