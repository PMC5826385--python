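"""Published summary measurements used as calibration and validation inputs.

These are the printed per-experiment summaries of the neonatal (3- to
5-day-old) piglet transection rotation experiments (three sagittally
transected specimens, two ~65 degree rotations each at ~52 rad/s; plus
three earlier axially transected specimens), and the connector-stiffness
sweep of the matching finite element head model: for each tested boundary
stiffness, the slope of the no-intercept regression of simulated on
measured maximum brain-skull displacement, with its 95% confidence
interval, over all pairs (``a_all``) and the superior-only subset
(``a_sup``).  They are inputs the calibration machinery consumes, e.g. to
re-derive pooled cohort rows or to run the selection rule on the published
sweep.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "sagittal_rotation_summaries",
    "axial_rotation_summaries",
    "reference_stiffness_sweep",
]


def sagittal_rotation_summaries() -> pd.DataFrame:
    """Per-experiment summaries of the six sagittal rotations.

    Columns: animal, rotation, peak_velocity (rad/s), peak_accel /
    peak_decel (krad/s^2), mean/sd of per-pair maximum displacement (mm),
    mean/sd of per-pair pre-motion error (mm), n_pairs.
    """
    rows = [
        (1, 1, 52, 9.6, 6.8, 1.00, 0.41, 0.32, 0.16, 13),
        (1, 2, 51, 10.3, 7.4, 1.07, 0.40, 0.28, 0.17, 13),
        (2, 1, 50, 8.4, 8.6, 0.63, 0.36, 0.28, 0.19, 14),
        (2, 2, 51, 9.5, 8.1, 0.68, 0.29, 0.31, 0.37, 14),
        (3, 1, 52, 6.2, 9.0, 0.58, 0.27, 0.33, 0.29, 14),
        (3, 2, 54, 7.7, 11.2, 0.66, 0.26, 0.31, 0.21, 14),
    ]
    return pd.DataFrame(rows, columns=[
        "animal", "rotation", "peak_velocity", "peak_accel", "peak_decel",
        "mean_max_disp", "sd_max_disp", "mean_error", "sd_error", "n_pairs",
    ])


def axial_rotation_summaries() -> pd.DataFrame:
    """Per-experiment summaries of the three earlier axial rotations."""
    rows = [
        (1, 52, 6.2, 6.9, 1.71, 0.40),
        (2, 53, 6.7, 6.3, 1.50, 0.56),
        (3, 54, 5.5, 6.6, 1.31, 0.56),
    ]
    return pd.DataFrame(rows, columns=[
        "animal", "peak_velocity", "peak_accel", "peak_decel",
        "mean_max_disp", "sd_max_disp",
    ])


def reference_stiffness_sweep() -> pd.DataFrame:
    """The published connector-stiffness sweep (slopes and 95% CIs).

    15 rows: 14 distinct stiffnesses with post-cyclic vein behaviour plus
    one repeat of 46.133 N/m with high-rate vein behaviour.  3,460 N/m is
    the stiffness previously calibrated for axial-plane rotations.
    """
    rows = [
        (4000.0, 0.769, 0.684, 0.854, 0.665, 0.582, 0.749, "post_cyclic"),
        (3750.0, 0.769, 0.684, 0.855, 0.666, 0.582, 0.749, "post_cyclic"),
        (3460.0, 0.770, 0.685, 0.855, 0.666, 0.582, 0.750, "post_cyclic"),
        (3250.0, 0.770, 0.685, 0.855, 0.666, 0.583, 0.750, "post_cyclic"),
        (3000.0, 0.771, 0.686, 0.856, 0.667, 0.583, 0.750, "post_cyclic"),
        (2595.0, 0.772, 0.687, 0.857, 0.668, 0.584, 0.751, "post_cyclic"),
        (2000.0, 0.774, 0.700, 0.859, 0.669, 0.586, 0.753, "post_cyclic"),
        (1730.0, 0.775, 0.690, 0.861, 0.670, 0.587, 0.754, "post_cyclic"),
        (692.0, 0.789, 0.703, 0.875, 0.678, 0.596, 0.761, "post_cyclic"),
        (346.0, 0.812, 0.724, 0.899, 0.687, 0.608, 0.766, "post_cyclic"),
        (138.4, 0.930, 0.826, 1.034, 0.784, 0.695, 0.874, "post_cyclic"),
        (69.2, 1.002, 0.879, 1.125, 0.883, 0.753, 1.014, "post_cyclic"),
        (46.133, 1.082, 0.939, 1.226, 0.984, 0.823, 1.144, "post_cyclic"),
        (46.133, 1.081, 0.938, 1.225, 0.981, 0.821, 1.142, "high_rate"),
        (34.6, 1.149, 0.990, 1.308, 1.056, 0.874, 1.239, "post_cyclic"),
    ]
    df = pd.DataFrame(rows, columns=[
        "stiffness", "a_all", "ci_all_low", "ci_all_high",
        "a_sup", "ci_sup_low", "ci_sup_high", "vein_variant",
    ])
    df["n_all"] = 41
    df["n_sup"] = -1  # superior-only pair count not part of the summary
    return df
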