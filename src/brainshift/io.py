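"""Readers and writers for the package's plain-text and HDF5 interchange formats.

CSV is the canonical tabular interchange (pulses, centroid tables, marker
trajectories, sweep results), HDF5 holds simulated node trajectories, and
frame stacks go to multi-page TIFF.  Simulated and physical trajectories
share the same CSV dialect so both flow through identical analysis code.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .mesh import Mesh2D
from .synth import FrameStack, GroundTruthTrajectories, mm_to_px
from .tracking import MarkerTrack

__all__ = [
    "write_trajectories_csv",
    "read_trajectories_csv",
    "tracks_to_frame",
    "tracks_from_frame",
    "write_frames_tiff",
    "read_frames_tiff",
    "write_mesh",
    "read_mesh",
    "write_sim_h5",
    "read_sim_h5",
]


def tracks_to_frame(tracks: list[MarkerTrack]) -> pd.DataFrame:
    """Tracks -> long table with columns frame, marker_id, label, x_px, y_px."""
    recs = []
    for t in tracks:
        for f, (xp, yp) in zip(t.frames, t.positions_array):
            recs.append((f, t.marker_id, t.label or "", xp, yp))
    df = pd.DataFrame(recs, columns=["frame", "marker_id", "label", "x_px", "y_px"])
    return df.sort_values(["frame", "marker_id"], ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[MarkerTrack]:
    tracks = []
    for mid, g in df.groupby("marker_id"):
        g = g.sort_values("frame")
        label = str(g["label"].iloc[0]) or None
        tracks.append(MarkerTrack(
            marker_id=int(mid),
            frames=[int(f) for f in g["frame"]],
            positions=[np.array([x, y]) for x, y in zip(g["x_px"], g["y_px"])],
            label=label if label else None,
        ))
    return tracks


def write_trajectories_csv(
    path,
    trajectories: GroundTruthTrajectories,
    px_per_mm: float,
    shape: tuple[int, int],
    frame_rate: float,
    mm_twin_path=None,
) -> None:
    """Ground-truth trajectories -> pixel-coordinate CSV (plus optional mm twin)."""
    t = trajectories.time
    n_frames = int(np.floor((t[-1] - t[0]) * frame_rate)) + 1
    ft = t[0] + np.arange(n_frames) / frame_rate
    recs, recs_mm = [], []
    for m in range(trajectories.positions.shape[1]):
        label = str(trajectories.layout.labels[m])
        x = np.interp(ft, t, trajectories.positions[:, m, 0])
        y = np.interp(ft, t, trajectories.positions[:, m, 1])
        px = mm_to_px(np.column_stack([x, y]), px_per_mm, shape)
        for f in range(n_frames):
            recs.append((f, m, label, px[f, 0], px[f, 1]))
            recs_mm.append((f, m, label, x[f], y[f]))
    pd.DataFrame(
        recs, columns=["frame", "marker_id", "label", "x_px", "y_px"]
    ).to_csv(path, index=False)
    if mm_twin_path is not None:
        pd.DataFrame(
            recs_mm, columns=["frame", "marker_id", "label", "x_mm", "y_mm"]
        ).to_csv(mm_twin_path, index=False)


def read_trajectories_csv(path) -> list[MarkerTrack]:
    df = pd.read_csv(path)
    return tracks_from_frame(df)


def write_frames_tiff(path, stack: FrameStack) -> None:
    tifffile.imwrite(path, stack.frames, metadata={
        "px_per_mm": stack.px_per_mm, "frame_rate": stack.frame_rate,
    })


def read_frames_tiff(path, px_per_mm: float, frame_rate: float) -> FrameStack:
    frames = tifffile.imread(path)
    times = np.arange(len(frames)) / frame_rate
    return FrameStack(frames=frames, px_per_mm=px_per_mm,
                      frame_rate=frame_rate, times=times)


def write_mesh(prefix, mesh: Mesh2D) -> None:
    """Mesh -> ``<prefix>_nodes.csv``, ``<prefix>_elements.csv``, ``<prefix>_tags.json``."""
    prefix = Path(prefix)
    pd.DataFrame(mesh.nodes, columns=["x_mm", "y_mm"]).to_csv(
        f"{prefix}_nodes.csv", index_label="node"
    )
    pd.DataFrame(mesh.elements, columns=["n0", "n1", "n2"]).to_csv(
        f"{prefix}_elements.csv", index_label="element"
    )
    tags = {
        "boundary_nodes": mesh.boundary_nodes.tolist(),
        "skull_points": mesh.skull_points.tolist(),
        "falx_slice": list(mesh.falx_slice),
        "profile": mesh.profile,
    }
    Path(f"{prefix}_tags.json").write_text(json.dumps(tags))


def read_mesh(prefix) -> Mesh2D:
    prefix = Path(prefix)
    nodes = pd.read_csv(f"{prefix}_nodes.csv", index_col="node").to_numpy(float)
    elements = pd.read_csv(f"{prefix}_elements.csv", index_col="element").to_numpy(int)
    tags = json.loads(Path(f"{prefix}_tags.json").read_text())
    return Mesh2D(
        nodes=nodes,
        elements=elements,
        boundary_nodes=np.asarray(tags["boundary_nodes"], int),
        skull_points=np.asarray(tags["skull_points"], float),
        falx_slice=tuple(tags["falx_slice"]),
        profile=tags["profile"],
    )


def write_sim_h5(path, result) -> None:
    """Simulation result -> HDF5 (time, node, xy), millimetres."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=result.times)
        h5.create_dataset("brain_positions", data=result.brain_positions)
        h5.create_dataset("skull_positions", data=result.skull_positions)
        h5.create_dataset("theta", data=result.theta)
        h5.attrs["max_vein_stretch"] = result.max_vein_stretch


def read_sim_h5(path) -> dict:
    with h5py.File(path, "r") as h5:
        return {
            "times": h5["times"][:],
            "brain_positions": h5["brain_positions"][:],
            "skull_positions": h5["skull_positions"][:],
            "theta": h5["theta"][:],
            "max_vein_stretch": float(h5.attrs["max_vein_stretch"]),
        }
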