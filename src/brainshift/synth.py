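"""Synthetic rotating-head experiments with tracked surface markers.

Emulates the physical transection preparation: ink dots (2-3 mm) on the cut
brain surface and on the surrounding rigid skull/potting annulus, filmed at
2,500 fps (320x480 px, ~0.41 mm/px) during a ~65 degree rotation.  Rigid
markers follow the prescribed rotation exactly; brain markers additionally
lag the skull by a configurable relative-displacement waveform with two
peaks whose maximum falls at the end of deceleration, mimicking the
measured brain-skull displacement time course.  Sub-pixel centroid noise at
the measured ~0.3 mm scale can be added on top.

Every stage records its ground truth so the downstream segmentation,
tracking and displacement pipeline can be validated end to end.

Coordinate conventions (defined here, used everywhere):

* physical frame: x right / y up, millimetres, origin at the brain-section
  centroid;
* image frame: 0-based (row, col) with origin at the top-left pixel centre;
  a marker at physical (x, y) mm maps to column ``cx + x * px_per_mm`` and
  row ``cy - y * px_per_mm`` where (cx, cy) is the image centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .pulse import RotationPulse

__all__ = [
    "MarkerLayout",
    "LagModel",
    "GroundTruthTrajectories",
    "FrameStack",
    "generate_layout",
    "lag_waveform",
    "synthesize_trajectories",
    "rasterize",
    "mm_to_px",
    "px_to_mm",
    "DEFAULT_PX_PER_MM",
    "DEFAULT_FRAME_RATE",
    "DEFAULT_SHAPE",
]

DEFAULT_PX_PER_MM = 1.0 / 0.41
DEFAULT_FRAME_RATE = 2500.0
DEFAULT_SHAPE = (320, 480)  # (rows, cols)

_RIGID_ANNULUS_OFFSET = 9.0  # mm outward of the outline for skull/potting dots
_BRAIN_INSET = 2.5           # mm inward of the outline for brain-surface dots


@dataclass(frozen=True)
class MarkerLayout:
    """Marker positions for one synthetic experiment (physical frame, mm)."""

    positions: np.ndarray          # (n, 2) mm
    labels: np.ndarray             # (n,) '<U5', 'brain' or 'rigid'
    dot_diameter: float            # mm
    profile: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels))

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def brain_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "brain")

    @property
    def rigid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "rigid")

    @property
    def brain_positions(self) -> np.ndarray:
        return self.positions[self.brain_indices]

    @property
    def rigid_positions(self) -> np.ndarray:
        return self.positions[self.rigid_indices]


def generate_layout(
    n_brain: int,
    n_rigid: int,
    geometry_profile: str = "sagittal",
    seed: int = 0,
    dot_diameter: float = 2.5,
    circle_radius: float = 25.0,
) -> MarkerLayout:
    """Place brain dots along the cortex periphery and rigid dots on the annulus.

    Markers are spread at even arclength with a small seeded jitter; no two
    centres come closer than one dot diameter.  Raises ``ValueError`` naming
    the maximum feasible count when a ring cannot hold the request.
    """
    if n_brain < 0 or n_rigid < 0:
        raise ValueError("marker counts must be non-negative")
    rng = np.random.default_rng(seed)

    outline = geometry.profile_points(geometry_profile, 720, radius=circle_radius)
    normals = geometry.outward_normals(outline)
    brain_ring = outline - _BRAIN_INSET * normals
    rigid_ring = outline + _RIGID_ANNULUS_OFFSET * normals

    def ring_positions(ring: np.ndarray, count: int, what: str) -> np.ndarray:
        if count == 0:
            return np.empty((0, 2))
        seglen = np.linalg.norm(np.diff(np.vstack([ring, ring[:1]]), axis=0), axis=1)
        total = float(seglen.sum())
        max_count = int(total // dot_diameter)
        if count > max_count:
            raise ValueError(
                f"cannot place {count} {what} markers on a {total:.0f} mm ring "
                f"with {dot_diameter} mm dots; maximum feasible count is {max_count}"
            )
        s_nodes = np.concatenate([[0.0], np.cumsum(seglen)])
        spacing = total / count
        # jitter bounded by the arclength slack so neighbours keep one
        # dot diameter of separation even in the worst draw
        jmax = min(0.25 * spacing, 0.45 * max(spacing - dot_diameter, 0.0))
        for _ in range(50):  # retry until the chordal separation holds too
            s = (np.arange(count) + 0.5) * spacing
            s = s + rng.uniform(-1.0, 1.0, count) * jmax
            s = np.mod(s, total)
            xs = np.interp(s, s_nodes, np.concatenate([ring[:, 0], ring[:1, 0]]))
            ys = np.interp(s, s_nodes, np.concatenate([ring[:, 1], ring[:1, 1]]))
            pts = np.column_stack([xs, ys])
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if count == 1 or d.min() >= dot_diameter:
                return pts
        raise ValueError(
            f"could not satisfy the {dot_diameter} mm separation for {count} "
            f"{what} markers; maximum feasible count is {max_count}"
        )

    brain = ring_positions(brain_ring, n_brain, "brain")
    rigid = ring_positions(rigid_ring, n_rigid, "rigid")
    positions = np.vstack([brain, rigid])
    labels = np.array(["brain"] * n_brain + ["rigid"] * n_rigid)
    return MarkerLayout(positions, labels, dot_diameter, geometry_profile)


@dataclass(frozen=True)
class LagModel:
    """Brain-relative-to-skull displacement waveform parameters.

    The waveform is a sum of two smooth bumps tied to the acceleration and
    deceleration phases of the pulse plus a residual plateau, normalised so
    its global maximum equals ``peak_rel_disp`` exactly at the end of
    deceleration.  ``direction`` sets where the offset acts:

    * ``"tangential"`` - opposite the local direction of skull motion
      (rotational inertia acts tangentially); default.
    * ``"inward_radial"`` - toward the section centroid, i.e. directly away
      from the rigid annulus, so the full lag projects onto the
      brain-rigid pair distance measured downstream.
    """

    peak_rel_disp: float = 1.0        # mm
    accel_peak_ratio: float = 0.5     # first (acceleration) bump amplitude
    residual_fraction: float = 0.2    # post-motion plateau, fraction of peak
    direction: str = "tangential"

    @property
    def enabled(self) -> bool:
        return self.peak_rel_disp > 0


def lag_waveform(pulse: RotationPulse, lag: LagModel) -> np.ndarray:
    """Relative-displacement magnitude (mm) on the pulse time grid.

    Two local maxima: one inside the acceleration phase, the global one at
    the end of deceleration; afterwards the waveform relaxes to
    ``residual_fraction`` of the peak.
    """
    t = pulse.time
    if not lag.enabled:
        return np.zeros_like(t)
    w = np.abs(pulse.angular_velocity)
    thr = 0.01 * pulse.peak_velocity
    moving = np.flatnonzero(w > thr)
    if moving.size == 0:
        return np.zeros_like(t)
    t0, t1 = t[moving[0]], t[moving[-1]]          # motion start / decel end
    t_peakv = t[int(np.argmax(w))]                # end of acceleration phase
    s_acc = max((t_peakv - t0) / 3.0, pulse.dt)
    s_dec = max((t1 - t_peakv) / 3.0, pulse.dt)

    g1 = np.exp(-0.5 * ((t - t_peakv) / s_acc) ** 2)
    g2 = np.exp(-0.5 * ((t - t1) / s_dec) ** 2)
    # smoothstep saturating exactly at the decel end, so the residual does
    # not push the maximum past t1
    u = np.clip((t - t_peakv) / max(t1 - t_peakv, pulse.dt), 0.0, 1.0)
    step = u * u * (3.0 - 2.0 * u)

    res = lag.residual_fraction
    raw = lag.accel_peak_ratio * g1 + (1.0 - res) * g2 + res * step
    raw[t < t0] = 0.0
    return lag.peak_rel_disp * raw / raw.max()


@dataclass(frozen=True)
class GroundTruthTrajectories:
    """Per-marker laboratory-frame trajectories plus recorded ground truth."""

    time: np.ndarray                        # (n_t,) s
    positions: np.ndarray                   # (n_t, n_markers, 2) mm, noisy
    truth_positions: np.ndarray             # (n_t, n_markers, 2) mm, pre-noise
    relative_displacement_truth: np.ndarray  # (n_t, n_brain) mm
    layout: MarkerLayout
    rotation_center: tuple[float, float]
    angle: np.ndarray = field(default=None)  # type: ignore[assignment]


def synthesize_trajectories(
    layout: MarkerLayout,
    pulse: RotationPulse,
    lag: LagModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rotation_center: tuple[float, float] = geometry.DEFAULT_ROTATION_CENTER,
) -> GroundTruthTrajectories:
    """Rigid rotation for all markers, plus the lag offset for brain markers.

    The lag offset is applied in the corotating (skull) frame, so the
    recorded truth is exactly the brain marker's displacement relative to
    the rigid structure.  Gaussian jitter of ``noise_sd`` mm per coordinate
    is added after the truth is recorded.
    """
    lag = lag or LagModel(peak_rel_disp=0.0)
    if lag.peak_rel_disp < 0:
        raise ValueError("peak_rel_disp must be >= 0")
    rng = np.random.default_rng(seed)

    theta = pulse.angle()
    c = np.asarray(rotation_center, dtype=float)
    rel = layout.positions - c                              # (n, 2)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    w = lag_waveform(pulse, lag)                            # (n_t,)
    offsets = np.zeros((layout.n_markers, 2))
    bidx = layout.brain_indices
    if lag.enabled and bidx.size:
        if lag.direction == "tangential":
            # unit vector opposite the direction of (positive-theta) motion
            v = np.column_stack([-rel[bidx, 1], rel[bidx, 0]])
            d = -v / np.linalg.norm(v, axis=1, keepdims=True)
        elif lag.direction == "inward_radial":
            p = layout.positions[bidx]
            d = -p / np.linalg.norm(p, axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown lag direction {lag.direction!r}")
        offsets[bidx] = d

    # corotating-frame positions: rel + w(t) * offset, then rotate
    body = rel[None, :, :] + w[:, None, None] * offsets[None, :, :]
    x = cos_t[:, None] * body[:, :, 0] - sin_t[:, None] * body[:, :, 1]
    y = sin_t[:, None] * body[:, :, 0] + cos_t[:, None] * body[:, :, 1]
    truth = np.stack([x, y], axis=-1) + c

    positions = truth.copy()
    if noise_sd > 0:
        positions = positions + rng.normal(0.0, noise_sd, positions.shape)

    rel_truth = np.repeat(w[:, None], bidx.size, axis=1)
    return GroundTruthTrajectories(
        time=pulse.time.copy(),
        positions=positions,
        truth_positions=truth,
        relative_displacement_truth=rel_truth,
        layout=layout,
        rotation_center=tuple(c),
        angle=theta,
    )


@dataclass(frozen=True)
class FrameStack:
    """Rasterised grayscale video frames of a synthetic experiment."""

    frames: np.ndarray        # (n_frames, rows, cols) uint8
    px_per_mm: float
    frame_rate: float
    times: np.ndarray         # (n_frames,) s

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def mm_to_px(
    xy_mm: np.ndarray,
    px_per_mm: float = DEFAULT_PX_PER_MM,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> np.ndarray:
    """Physical (x, y) mm -> image (x_px=col, y_px=row); see module docstring."""
    xy_mm = np.asarray(xy_mm, dtype=float)
    rows, cols = shape
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    out = np.empty_like(xy_mm)
    out[..., 0] = cx + xy_mm[..., 0] * px_per_mm
    out[..., 1] = cy - xy_mm[..., 1] * px_per_mm
    return out


def px_to_mm(
    xy_px: np.ndarray,
    px_per_mm: float = DEFAULT_PX_PER_MM,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> np.ndarray:
    xy_px = np.asarray(xy_px, dtype=float)
    rows, cols = shape
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    out = np.empty_like(xy_px)
    out[..., 0] = (xy_px[..., 0] - cx) / px_per_mm
    out[..., 1] = (cy - xy_px[..., 1]) / px_per_mm
    return out


def rasterize(
    trajectories: GroundTruthTrajectories,
    layout: MarkerLayout | None = None,
    px_per_mm: float = DEFAULT_PX_PER_MM,
    frame_rate: float = DEFAULT_FRAME_RATE,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    background: float = 190.0,
    dot_intensity: float = 40.0,
    flicker_amplitude: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """Render anti-aliased dark dots on a light background at the video rate.

    Trajectories are linearly resampled in time to ``frame_rate``.  Dot
    coverage per pixel uses an area-weighted edge ramp so the rendered
    centroid matches the true centre well below one pixel.  ``flicker_amplitude``
    (fraction of background) emulates frame-to-frame ambient-light variation.

    Raises ``ValueError`` listing the first offending marker and frame if a
    dot leaves the field of view.
    """
    layout = layout or trajectories.layout
    rng = np.random.default_rng(seed)
    rows, cols = shape

    t = trajectories.time
    n_frames = int(np.floor((t[-1] - t[0]) * frame_rate)) + 1
    ft = t[0] + np.arange(n_frames) / frame_rate
    n_mark = trajectories.positions.shape[1]
    pos = np.empty((n_frames, n_mark, 2))
    for m in range(n_mark):
        pos[:, m, 0] = np.interp(ft, t, trajectories.positions[:, m, 0])
        pos[:, m, 1] = np.interp(ft, t, trajectories.positions[:, m, 1])
    pos_px = mm_to_px(pos, px_per_mm, shape)

    radius_px = 0.5 * layout.dot_diameter * px_per_mm
    lo = pos_px - radius_px
    hi = pos_px + radius_px
    bad = (lo[..., 0] < 0) | (lo[..., 1] < 0) | (hi[..., 0] > cols - 1) | (hi[..., 1] > rows - 1)
    if bad.any():
        f, m = np.argwhere(bad)[0]
        raise ValueError(
            f"marker {m} leaves the field of view at frame {f} "
            f"(centre {pos_px[f, m]} px, radius {radius_px:.1f} px)"
        )

    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    win = int(np.ceil(radius_px)) + 2
    for f in range(n_frames):
        bg = background * (1.0 + flicker_amplitude * rng.uniform(-1.0, 1.0))
        img = np.full((rows, cols), bg, dtype=float)
        for m in range(n_mark):
            xc, yc = pos_px[f, m]
            r0 = max(int(np.floor(yc)) - win, 0)
            r1 = min(int(np.ceil(yc)) + win + 1, rows)
            c0 = max(int(np.floor(xc)) - win, 0)
            c1 = min(int(np.ceil(xc)) + win + 1, cols)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            d = np.hypot(xx - xc, yy - yc)
            coverage = np.clip(radius_px - d + 0.5, 0.0, 1.0)
            img[r0:r1, c0:c1] -= (bg - dot_intensity) * coverage
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)
    return FrameStack(frames=frames, px_per_mm=px_per_mm, frame_rate=frame_rate, times=ft)
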