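"""Brain-skull relative displacement from paired marker tracks.

Each brain-surface dot is matched to the nearest rigid (skull/potting) dot
in the first analysis frame.  For each pair, the inter-centroid distance is
computed per frame; the mean distance over the 50 frames before motion
defines the pair's baseline, and the signed relative displacement is the
per-frame distance minus that baseline.  Two scalars summarise each pair:
the maximum relative displacement during motion, and the maximum over the
pre-motion window, which serves as the measurement-error estimate.
Experiment- and cohort-level summaries pool pairs with count-weighted
means, and paired Wilcoxon signed-rank tests compare displacement
populations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import MarkerTrack

__all__ = [
    "DotPair",
    "ExperimentRecord",
    "pair_markers",
    "relative_displacement",
    "extract_maxima",
    "motion_end_frame",
    "wilcoxon_paired",
    "pooled_mean",
    "summarize",
    "superior_tercile_mask",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BASELINE = 50


@dataclass
class DotPair:
    """A brain marker paired with its nearest rigid marker."""

    brain_id: int
    rigid_id: int
    frames: np.ndarray              # common frame indices
    rel_disp: np.ndarray            # mm, signed (distance - baseline)
    baseline_distance: float        # mm
    max_disp_motion: float          # mm
    max_disp_premotion_error: float  # mm
    superior: bool = False


@dataclass
class ExperimentRecord:
    """Per-pair results of one rotation experiment plus its kinematics."""

    peak_velocity: float            # rad/s
    peak_accel: float               # krad/s^2
    peak_decel: float               # krad/s^2
    max_displacements: np.ndarray   # mm, one per pair
    errors: np.ndarray              # mm, one per pair
    superior: np.ndarray | None = None  # bool mask per pair

    @property
    def n_pairs(self) -> int:
        return len(self.max_displacements)


def superior_tercile_mask(first_positions: np.ndarray, y_up: bool = False) -> np.ndarray:
    """Flag markers in the top tercile of the bounding box at frame 0.

    Image coordinates have row (y) increasing downward, so by default
    'superior' means the smallest y; pass ``y_up=True`` for physical-frame
    coordinates.
    """
    y = np.asarray(first_positions, float)[:, 1]
    lo, hi = y.min(), y.max()
    if hi == lo:
        return np.ones_like(y, dtype=bool)
    frac = (y - lo) / (hi - lo)
    return frac >= 2.0 / 3.0 if y_up else frac <= 1.0 / 3.0


def pair_markers(
    brain_tracks: list[MarkerTrack],
    rigid_tracks: list[MarkerTrack],
    superior_mask: np.ndarray | None = None,
) -> list[tuple[MarkerTrack, MarkerTrack, bool]]:
    """Match each brain track to the nearest rigid track at its first frame.

    Pairing is many-to-one: several brain dots may share a rigid dot.  An
    exact distance tie resolves to the rigid track with the lowest
    marker id (logged).  ``superior_mask`` flags brain tracks (by list
    position) lying on the superior cortical surface.
    """
    if not rigid_tracks:
        raise ValueError("no rigid tracks available for pairing")
    rigid_first = np.asarray([t.first_position for t in rigid_tracks])
    rigid_order = np.argsort([t.marker_id for t in rigid_tracks], kind="stable")
    pairs = []
    for i, bt in enumerate(brain_tracks):
        d = np.linalg.norm(rigid_first - bt.first_position, axis=1)
        dmin = d.min()
        winners = np.flatnonzero(np.isclose(d, dmin, rtol=0.0, atol=1e-12))
        if len(winners) > 1:
            ids = [rigid_tracks[w].marker_id for w in winners]
            logger.info(
                "brain track %s equidistant to rigid tracks %s; choosing lowest id",
                bt.marker_id, ids,
            )
            winner = min(winners, key=lambda w: rigid_tracks[w].marker_id)
        else:
            winner = int(winners[0])
        sup = bool(superior_mask[i]) if superior_mask is not None else False
        pairs.append((bt, rigid_tracks[winner], sup))
    return pairs


def relative_displacement(
    brain_track: MarkerTrack,
    rigid_track: MarkerTrack,
    motion_start_frame: int,
    n_baseline: int = DEFAULT_N_BASELINE,
    mm_per_px: float = 1.0,
    superior: bool = False,
) -> DotPair:
    """Baseline-subtracted inter-centroid distance series for one pair.

    Distances are Euclidean in the tracking frame and converted to mm once
    via ``mm_per_px``.  ``motion_start_frame`` must be preceded by at least
    ``n_baseline`` common frames; the baseline is the mean distance over
    the ``n_baseline`` frames immediately before motion.
    """
    bf = {f: i for i, f in enumerate(brain_track.frames)}
    rf = {f: i for i, f in enumerate(rigid_track.frames)}
    common = sorted(set(bf) & set(rf))
    if not common:
        raise ValueError("tracks share no frames")
    frames = np.asarray(common)
    bp = brain_track.positions_array[[bf[f] for f in common]]
    rp = rigid_track.positions_array[[rf[f] for f in common]]
    dist = np.linalg.norm(bp - rp, axis=1) * mm_per_px

    pre = np.flatnonzero(frames < motion_start_frame)
    if pre.size < n_baseline:
        raise ValueError(
            f"only {pre.size} pre-motion frames available; "
            f"{n_baseline} required (short by {n_baseline - pre.size})"
        )
    base_idx = pre[-n_baseline:]
    baseline = float(dist[base_idx].mean())
    rel = dist - baseline

    motion = frames >= motion_start_frame
    premo = np.zeros_like(motion)
    premo[base_idx] = True
    max_motion, max_err = extract_maxima(rel, motion, premo)
    return DotPair(
        brain_id=brain_track.marker_id,
        rigid_id=rigid_track.marker_id,
        frames=frames,
        rel_disp=rel,
        baseline_distance=baseline,
        max_disp_motion=max_motion,
        max_disp_premotion_error=max_err,
        superior=superior,
    )


def extract_maxima(
    rel_disp: np.ndarray,
    motion_window: np.ndarray,
    premotion_window: np.ndarray,
) -> tuple[float, float]:
    """Maxima of the relative displacement over two disjoint frame windows."""
    motion_window = np.asarray(motion_window, bool)
    premotion_window = np.asarray(premotion_window, bool)
    if not motion_window.any() or not premotion_window.any():
        raise ValueError("motion and pre-motion windows must be non-empty")
    if (motion_window & premotion_window).any():
        raise ValueError("motion and pre-motion windows must be disjoint")
    rel = np.asarray(rel_disp, float)
    return float(rel[motion_window].max()), float(rel[premotion_window].max())


def motion_end_frame(
    rel_disp: np.ndarray,
    rate_threshold: float = 0.01,
    n_consecutive: int = 25,
) -> int:
    """Index where the brain has stopped moving.

    Operationalised as the first sample after which the per-frame rate of
    change stays below ``rate_threshold`` mm/frame for ``n_consecutive``
    frames; falls back to the last frame if that never happens.
    """
    rate = np.abs(np.diff(np.asarray(rel_disp, float)))
    below = rate < rate_threshold
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= n_consecutive:
            return i + 1
    return len(rel_disp) - 1


def wilcoxon_paired(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Uses the exact null distribution for n <= 25 when there are no zero
    differences or tied magnitudes, else the normal approximation with
    tie/zero handling.  All-zero differences return p = 1 with a warning.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be equal-length 1-D arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    exact_ok = d.size <= 25 and np.all(d != 0)
    res = stats.wilcoxon(a, b, alternative="two-sided",
                         method="exact" if exact_ok else "approx")
    return float(res.statistic), float(res.pvalue)


def pooled_mean(means, counts) -> float:
    """Count-weighted pooled mean sum(n_i m_i) / sum(n_i)."""
    means = np.asarray(means, float)
    counts = np.asarray(counts, float)
    if means.shape != counts.shape or means.size == 0:
        raise ValueError("means and counts must be equal-length and non-empty")
    return float(np.sum(means * counts) / np.sum(counts))


def summarize(experiments: list[ExperimentRecord], label: str = "overall") -> pd.DataFrame:
    """Per-experiment rows plus a pooled row over the union of pairs.

    Pooled displacement/error statistics are computed over the union of
    pair-level values (count-weighted, not a mean of means); kinematic
    peaks are averaged per experiment.  Standard deviations use the n-1
    denominator.
    """
    if not experiments:
        raise ValueError("no experiments to summarize")
    rows = []
    for i, e in enumerate(experiments):
        rows.append({
            "experiment": i,
            "peak_velocity": e.peak_velocity,
            "peak_accel": e.peak_accel,
            "peak_decel": e.peak_decel,
            "mean_max_disp": float(np.mean(e.max_displacements)),
            "sd_max_disp": float(np.std(e.max_displacements, ddof=1))
            if e.n_pairs > 1 else np.nan,
            "mean_error": float(np.mean(e.errors)),
            "sd_error": float(np.std(e.errors, ddof=1)) if e.n_pairs > 1 else np.nan,
            "n_pairs": e.n_pairs,
        })
    all_disp = np.concatenate([e.max_displacements for e in experiments])
    all_err = np.concatenate([e.errors for e in experiments])
    rows.append({
        "experiment": label,
        "peak_velocity": float(np.mean([e.peak_velocity for e in experiments])),
        "peak_accel": float(np.mean([e.peak_accel for e in experiments])),
        "peak_decel": float(np.mean([e.peak_decel for e in experiments])),
        "mean_max_disp": float(np.mean(all_disp)),
        "sd_max_disp": float(np.std(all_disp, ddof=1)) if all_disp.size > 1 else np.nan,
        "mean_error": float(np.mean(all_err)),
        "sd_error": float(np.std(all_err, ddof=1)) if all_err.size > 1 else np.nan,
        "n_pairs": int(all_disp.size),
    })
    return pd.DataFrame(rows)
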