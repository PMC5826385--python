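import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainshift import displacement as disp
from brainshift.displacement import (
    ExperimentRecord,
    extract_maxima,
    motion_end_frame,
    pair_markers,
    pooled_mean,
    relative_displacement,
    summarize,
    superior_tercile_mask,
    wilcoxon_paired,
)
from brainshift.synth import LagModel, MarkerLayout, generate_layout, rasterize, synthesize_trajectories
from brainshift.tracking import MarkerTrack, track_stack


def _track(mid, positions, label=None):
    positions = np.asarray(positions, float)
    return MarkerTrack(mid, list(range(len(positions))), list(positions), label=label)


def _pair_from_distance(dist, motion_start, n_baseline=50):
    """Build a brain/rigid track pair realising the given distance series."""
    brain = _track(0, np.column_stack([dist, np.zeros_like(dist)]))
    rigid = _track(1, np.zeros((len(dist), 2)))
    return relative_displacement(brain, rigid, motion_start, n_baseline=n_baseline)


class TestPairing:
    def test_single_pair(self):
        pairs = pair_markers([_track(0, [[0, 0]])], [_track(1, [[5, 0]])])
        assert len(pairs) == 1

    def test_nearest_rigid_chosen(self):
        rigid = [_track(10, [[10, 0]]), _track(11, [[3, 0]])]
        pairs = pair_markers([_track(0, [[0, 0]])], rigid)
        assert pairs[0][1].marker_id == 11

    def test_equidistant_tie_lowest_id(self):
        rigid = [_track(7, [[5, 0]]), _track(3, [[-5, 0]])]
        pairs = pair_markers([_track(0, [[0, 0]])], rigid)
        assert pairs[0][1].marker_id == 3

    def test_thirteen_brain_six_rigid_gives_thirteen_pairs(self):
        lay = generate_layout(13, 6, "sagittal", seed=1)
        brain = [_track(i, [p]) for i, p in enumerate(lay.brain_positions)]
        rigid = [_track(100 + i, [p]) for i, p in enumerate(lay.rigid_positions)]
        assert len(pair_markers(brain, rigid)) == 13

    def test_no_rigid_tracks_error(self):
        with pytest.raises(ValueError, match="no rigid tracks"):
            pair_markers([_track(0, [[0, 0]])], [])


class TestRelativeDisplacement:
    def test_constant_distance_zero(self):
        pair = _pair_from_distance(np.full(80, 10.0), motion_start=50)
        assert np.allclose(pair.rel_disp, 0.0, atol=1e-12)
        assert pair.max_disp_motion == 0.0

    def test_hand_worked_example(self):
        """Baseline 10 over 50 frames; 10.5, 11, 10.2 afterwards gives
        rel_disp 0.5, 1.0, 0.2 with maximum 1.0."""
        dist = np.concatenate([np.full(50, 10.0), [10.5, 11.0, 10.2]])
        pair = _pair_from_distance(dist, motion_start=50)
        assert pair.baseline_distance == pytest.approx(10.0)
        assert np.allclose(pair.rel_disp[50:], [0.5, 1.0, 0.2])
        assert pair.max_disp_motion == pytest.approx(1.0)

    def test_baseline_window_mean_zero(self):
        rng = np.random.default_rng(0)
        dist = 10.0 + rng.normal(0, 0.3, 130)
        pair = _pair_from_distance(dist, motion_start=60)
        baseline_window = (pair.frames >= 10) & (pair.frames < 60)
        assert pair.rel_disp[baseline_window].mean() == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_premotion_frames(self):
        with pytest.raises(ValueError, match="pre-motion frames"):
            _pair_from_distance(np.full(60, 10.0), motion_start=30)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        bpos = rng.uniform(0, 50, (120, 2))
        rpos = bpos + [8.0, 1.0] + rng.normal(0, 0.1, (120, 2))
        p1 = relative_displacement(_track(0, bpos), _track(1, rpos), 60)
        p2 = relative_displacement(_track(0, 3.0 * bpos), _track(1, 3.0 * rpos), 60)
        assert np.allclose(p2.rel_disp, 3.0 * p1.rel_disp, atol=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        bpos = rng.uniform(0, 50, (120, 2))
        rpos = bpos + [8.0, 1.0] + rng.normal(0, 0.1, (120, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        p1 = relative_displacement(_track(0, bpos), _track(1, rpos), 60)
        p2 = relative_displacement(_track(0, bpos @ R.T), _track(1, rpos @ R.T), 60)
        assert np.allclose(p2.rel_disp, p1.rel_disp, atol=1e-9)

    def test_mm_conversion_applied_once(self):
        dist = np.concatenate([np.full(50, 10.0), [12.0]])
        pair = _pair_from_distance(dist, motion_start=50)
        brain = _track(0, np.column_stack([dist, np.zeros_like(dist)]))
        rigid = _track(1, np.zeros((len(dist), 2)))
        half = relative_displacement(brain, rigid, 50, mm_per_px=0.5)
        assert half.max_disp_motion == pytest.approx(0.5 * pair.max_disp_motion)

    def test_end_to_end_truth_recovery(self, standard_pulse):
        """A 1.0 mm ground-truth lag aimed along the pair chord is recovered
        through rasterisation + tracking + pairing within 0.05 mm."""
        # brain dots with rigid partners placed radially outward, so the
        # inward-radial lag projects fully onto each pair distance
        phi = np.linspace(0.3, 2 * np.pi, 6, endpoint=False)
        brain = np.column_stack([24 * np.cos(phi), 24 * np.sin(phi)])
        rigid = np.column_stack([33 * np.cos(phi), 33 * np.sin(phi)])
        lay = MarkerLayout(
            np.vstack([brain, rigid]),
            np.array(["brain"] * 6 + ["rigid"] * 6), 2.5, "circle",
        )
        traj = synthesize_trajectories(
            lay, standard_pulse,
            LagModel(1.0, direction="inward_radial"), noise_sd=0.0,
        )
        stack = rasterize(traj, lay)
        tracks = track_stack(stack)
        assert len(tracks) == 12
        from brainshift import synth as s

        first_px = s.mm_to_px(traj.positions[0])
        for tr in tracks:
            m = int(np.argmin(np.linalg.norm(first_px - tr.first_position, axis=1)))
            tr.label = str(lay.labels[m])
        bt = [t for t in tracks if t.label == "brain"]
        rt = [t for t in tracks if t.label == "rigid"]
        start = int(np.ceil(standard_pulse.motion_start_time() * stack.frame_rate))
        for b, r, _ in pair_markers(bt, rt):
            pair = relative_displacement(b, r, start, mm_per_px=0.41)
            assert pair.max_disp_motion == pytest.approx(1.0, abs=0.05)

    def test_premotion_error_tracks_noise_scale(self, standard_pulse):
        lay = generate_layout(8, 4, "sagittal", seed=3)
        traj = synthesize_trajectories(
            lay, standard_pulse, LagModel(1.0, direction="inward_radial"),
            noise_sd=0.31, seed=4,
        )
        # direct centroid tables (no rasterisation) at the video rate
        t = traj.time
        n_frames = int(np.floor((t[-1] - t[0]) * 2500)) + 1
        ft = t[0] + np.arange(n_frames) / 2500
        pos = np.stack(
            [np.column_stack([np.interp(ft, t, traj.positions[:, m, 0]),
                              np.interp(ft, t, traj.positions[:, m, 1])])
             for m in range(lay.n_markers)], axis=1,
        )
        bt = [_track(m, pos[:, m], "brain") for m in lay.brain_indices]
        rt = [_track(m, pos[:, m], "rigid") for m in lay.rigid_indices]
        start = int(np.ceil(standard_pulse.motion_start_time() * 2500))
        errs = [
            relative_displacement(b, r, start).max_disp_premotion_error
            for b, r, _ in pair_markers(bt, rt)
        ]
        # error statistic is a max over 50 noisy frames: same order as the
        # noise sd, well below the 1 mm motion signal
        assert 0.3 < np.mean(errs) < 1.5


class TestMaximaAndWindows:
    def test_all_zero_series(self):
        motion = np.zeros(10, bool)
        motion[5:] = True
        assert extract_maxima(np.zeros(10), motion, ~motion) == (0.0, 0.0)

    def test_monotone_ramp_max_at_end(self):
        rel = np.concatenate([np.zeros(50), np.linspace(0, 2, 30)])
        motion = np.arange(80) >= 50
        mx, _ = extract_maxima(rel, motion, ~motion)
        assert mx == pytest.approx(2.0)

    def test_disjoint_window_validation(self):
        w = np.ones(10, bool)
        with pytest.raises(ValueError, match="disjoint"):
            extract_maxima(np.zeros(10), w, w)

    def test_motion_end_detection(self):
        rel = np.concatenate([np.linspace(0, 2, 40), np.full(40, 2.0)])
        end = motion_end_frame(rel, rate_threshold=0.01, n_consecutive=25)
        assert 40 <= end <= 70


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        a = np.arange(10.0)
        with pytest.warns(UserWarning):
            stat, p = wilcoxon_paired(a, a)
        assert p == 1.0

    def test_uniform_shift_minimal_p(self):
        """A +1 shift on 20 pairs (no ties) gives statistic 0 and the exact
        two-sided minimum p = 2 / 2^20."""
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 10, 20)
        a = b + 1.0
        stat, p = wilcoxon_paired(a, b)
        assert stat == 0.0
        assert p == pytest.approx(2.0 / 2**20, rel=1e-9)

    def test_separated_samples_tiny_p(self):
        rng = np.random.default_rng(1)
        motion = rng.uniform(0.5, 1.5, 41)
        error = rng.uniform(0.0, 0.4, 41)
        _, p = wilcoxon_paired(motion, error)
        assert p < 1e-5

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [0.5, 1.5])


class TestSummaries:
    def test_pooled_rotation1_worked_example(self):
        """Per-animal means (1.00, 0.63, 0.58) with counts (13, 14, 14)
        pool to 0.73 mm."""
        assert pooled_mean([1.00, 0.63, 0.58], [13, 14, 14]) == pytest.approx(0.73, abs=0.005)

    def test_pooled_error_worked_example(self):
        means = [0.32, 0.28, 0.28, 0.31, 0.33, 0.31]
        counts = [13, 13, 14, 14, 14, 14]
        assert pooled_mean(means, counts) == pytest.approx(0.31, abs=0.005)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_pooled_mean_identity_property(self, n_groups, seed):
        """Count-weighted pooling equals the direct mean over the union."""
        rng = np.random.default_rng(seed)
        groups = [rng.uniform(0, 2, rng.integers(1, 20)) for _ in range(n_groups)]
        pooled = pooled_mean([g.mean() for g in groups], [len(g) for g in groups])
        assert pooled == pytest.approx(np.concatenate(groups).mean(), rel=1e-12)

    def test_summarize_pools_union_not_mean_of_means(self):
        e1 = ExperimentRecord(52, 9.6, 6.8, np.array([1.0, 1.0]), np.array([0.3, 0.3]))
        e2 = ExperimentRecord(50, 8.4, 8.6, np.full(8, 0.5), np.full(8, 0.2))
        table = summarize([e1, e2])
        pooled = table.iloc[-1]
        union = np.concatenate([e1.max_displacements, e2.max_displacements])
        assert pooled["mean_max_disp"] == pytest.approx(union.mean())
        assert pooled["n_pairs"] == 10
        assert pooled["sd_max_disp"] == pytest.approx(np.std(union, ddof=1))

    def test_single_experiment_pooled_equals_row(self):
        e = ExperimentRecord(52, 9.6, 6.8, np.array([1.0, 0.6, 0.8]), np.array([0.3, 0.2, 0.4]))
        table = summarize([e])
        assert table.iloc[0]["mean_max_disp"] == pytest.approx(table.iloc[-1]["mean_max_disp"])

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            summarize([])


def test_superior_tercile_mask():
    pos = np.array([[0, 0], [0, 5], [0, 10]])
    assert list(superior_tercile_mask(pos, y_up=True)) == [False, False, True]
    assert list(superior_tercile_mask(pos, y_up=False)) == [True, False, False]
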