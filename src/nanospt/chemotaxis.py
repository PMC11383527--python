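"""Directional cell-migration metrics from single-cell tracks.

The chemoattractant gradient axis is fixed as +x in the data files
(importers must rotate coordinates accordingly).  Per cell:

* accumulated distance — sum of segment lengths along the path;
* Euclidean distance — straight-line start-to-end distance;
* forward migration index FMI_x = (x_end − x_start) / accumulated distance
  (FMI_y analogous), in [−1, 1];
* straightness = Euclidean / accumulated, in [0, 1];
* toward_gradient — net x displacement > 0.

Group values are unweighted per-cell averages (one cell, one vote), the
standard convention of chemotaxis track analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("nanospt")


def track_metrics(track: pd.DataFrame) -> dict:
    """Metrics of one cell track (columns ``frame, x_um, y_um``)."""
    track = track.sort_values("frame")
    if len(track) < 2:
        raise ValueError("track needs at least 2 points")
    xy = track[["x_um", "y_um"]].to_numpy(dtype=float)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    accumulated = float(seg.sum())
    if accumulated == 0:
        raise ValueError("zero accumulated distance; metrics undefined")
    net = xy[-1] - xy[0]
    euclid = float(np.linalg.norm(net))
    return {
        "accumulated_dist_um": accumulated,
        "euclidean_dist_um": euclid,
        "fmi_x": float(net[0]) / accumulated,
        "fmi_y": float(net[1]) / accumulated,
        "straightness": euclid / accumulated,
        "toward_gradient": bool(net[0] > 0),
    }


def all_track_metrics(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-cell metrics table; degenerate cells are excluded with a warning."""
    rows = []
    for cid, sub in tracks.groupby("cell_id", sort=True):
        try:
            m = track_metrics(sub)
        except ValueError as err:
            logger.warning("cell %s excluded from chemotaxis metrics: %s", cid, err)
            continue
        rows.append({"cell_id": cid, **m})
    return pd.DataFrame(rows)


def group_chemotaxis_summary(tracks: pd.DataFrame) -> dict:
    """Mean ± SD of FMI and straightness, and the fraction moving toward +x."""
    metrics = all_track_metrics(tracks)
    if len(metrics) == 0:
        raise ValueError("no valid cell tracks")
    return {
        "n_cells": int(len(metrics)),
        "fmi_x_mean": float(metrics["fmi_x"].mean()),
        "fmi_x_sd": float(metrics["fmi_x"].std(ddof=1)) if len(metrics) > 1 else 0.0,
        "fmi_y_mean": float(metrics["fmi_y"].mean()),
        "fmi_y_sd": float(metrics["fmi_y"].std(ddof=1)) if len(metrics) > 1 else 0.0,
        "straightness_mean": float(metrics["straightness"].mean()),
        "straightness_sd": float(metrics["straightness"].std(ddof=1)) if len(metrics) > 1 else 0.0,
        "fraction_toward_gradient": float(metrics["toward_gradient"].mean()),
    }


def reorigin_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Spider-plot coordinates: every track translated to start at (0, 0).

    Adds a ``direction`` label per cell: "toward" when the net x
    displacement is positive, "away" otherwise.
    """
    out = []
    for cid, sub in tracks.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame").copy()
        sub["x_um"] = sub["x_um"] - sub["x_um"].iloc[0]
        sub["y_um"] = sub["y_um"] - sub["y_um"].iloc[0]
        sub["direction"] = "toward" if sub["x_um"].iloc[-1] > 0 else "away"
        out.append(sub)
    if not out:
        return tracks.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


def plot_spider(tracks: pd.DataFrame, ax=None):
    """Spider plot: re-origined tracks, toward-gradient black, away red."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    re = reorigin_tracks(tracks)
    for _, sub in re.groupby("cell_id"):
        color = "black" if sub["direction"].iloc[0] == "toward" else "red"
        ax.plot(sub["x_um"], sub["y_um"], color=color, linewidth=0.7)
    ax.axhline(0, color="gray", linewidth=0.5)
    ax.axvline(0, color="gray", linewidth=0.5)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_aspect("equal")
    return ax
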