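"""Idealised 2-D cross-section profiles of the neonatal porcine brain.

Both the synthetic-experiment generator and the simulator mesh builder draw
their outlines from here so that marker layouts and finite element
geometry agree.  Profiles are closed star-shaped curves r(phi) about the
section centroid, in millimetres:

``sagittal``
    Irregular hemisection outline: smooth superior arc, a posterior
    cerebellar lobe, a motion-restricting brainstem notch at the
    posterior-inferior boundary (foramen magnum potting), and an anterior
    olfactory prominence.  x points anterior, y superior.
``axial``
    Smooth ovoid, the rounder cross-section of an axially transected head.
``circle``
    Calibration/benchmark profile.

The skull inner surface is modelled as the brain outline offset outward by
a uniform subarachnoid gap; the falx segment is the superior arc of that
skull curve.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PROFILES",
    "profile_radius",
    "profile_points",
    "perimeter_length",
    "outward_normals",
    "FALX_ARC",
    "DEFAULT_ROTATION_CENTER",
]

PROFILES = ("sagittal", "axial", "circle")

# Rotation centre sits in the cervical spine just below the brain,
# close enough that a 65 degree sweep keeps every marker in the camera
# view; configurable everywhere it is consumed.  mm, section frame (y up).
DEFAULT_ROTATION_CENTER = (0.0, -35.0)

# Falx spans the superior arc of the skull: polar-angle window in radians.
FALX_ARC = (np.pi / 4, 3 * np.pi / 4)

_SAG_BASE = (30.0, 24.0)  # semi-axes of the underlying ellipse, mm
_AXIAL_BASE = (28.0, 22.0)


def _bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump in angle."""
    d = np.angle(np.exp(1j * (phi - center)))
    return np.exp(-0.5 * (d / width) ** 2)


def profile_radius(profile: str, phi: np.ndarray, radius: float = 25.0) -> np.ndarray:
    """Radius r(phi) in mm of the chosen cross-section outline.

    ``radius`` only applies to the circle profile.
    """
    phi = np.asarray(phi, dtype=float)
    if profile == "circle":
        return np.full_like(phi, float(radius))
    if profile == "axial":
        a, b = _AXIAL_BASE
        r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        # mild anterior taper for an egg-shaped ovoid, still smooth
        return r * (1.0 + 0.04 * np.cos(phi))
    if profile == "sagittal":
        a, b = _SAG_BASE
        r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        r = r + 5.0 * _bump(phi, np.deg2rad(-35.0), 0.28)   # cerebellar lobe
        r = r - 7.0 * _bump(phi, np.deg2rad(-75.0), 0.20)   # brainstem notch
        r = r + 3.5 * _bump(phi, np.deg2rad(195.0), 0.25)   # olfactory prominence
        return np.maximum(r, 5.0)
    raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")


def profile_points(profile: str, n: int, radius: float = 25.0) -> np.ndarray:
    """Closed outline sampled at ``n`` equally spaced angles; shape (n, 2) mm."""
    if n < 8:
        raise ValueError("need at least 8 perimeter points")
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = profile_radius(profile, phi, radius)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def perimeter_length(points: np.ndarray) -> float:
    """Length of the closed polygon through ``points`` (mm)."""
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals of a closed counter-clockwise polygon."""
    nxt = np.roll(points, -1, axis=0)
    prv = np.roll(points, 1, axis=0)
    tang = nxt - prv
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    lens = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm = nrm / np.where(lens > 0, lens, 1.0)
    # orient outward relative to the centroid
    c = points.mean(axis=0)
    flip = np.sum((points - c) * nrm, axis=1) < 0
    nrm[flip] *= -1.0
    return nrm
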