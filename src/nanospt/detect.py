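"""Spot detection and trajectory linking.

A deliberately simple, deterministic stage: Laplacian-of-Gaussian blob
detection with sub-pixel centroid refinement, and frame-to-frame linking as
a gated minimum-total-squared-displacement bipartite assignment with short
gap closing.  Externally produced trajectory CSVs (any tracker) are equally
accepted by the downstream quantification.

Determinism: detections are canonically ordered by (y, x) within each
frame, so the resulting track set is invariant to the input ordering of
detections, and equal-cost assignment ties resolve reproducibly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .io import ImageStack

_BIG = 1e18


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_spots(frame: np.ndarray, psf_sigma_px: float = 1.0,
                 snr_min: float = 4.0) -> pd.DataFrame:
    """Detect diffraction-limited spots in one frame.

    Local maxima of the (sign-flipped, scale-normalised) LoG response above
    ``snr_min`` times the robust response noise are refined to sub-pixel
    position by an intensity-weighted centroid in a ``2*ceil(3σ)+1`` window
    after subtracting the window-perimeter median as local background.
    Returns a DataFrame with columns ``x_px, y_px, window_sum_au`` sorted by
    (y, x); empty when nothing passes.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_spots expects a single 2-D frame")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")

    resp = -ndimage.gaussian_laplace(frame, psf_sigma_px) * psf_sigma_px ** 2
    resp -= np.median(resp)  # remove the DC bias of the truncated kernel
    # robust noise scale, floored at a small fraction of the peak response
    # (noise-free images must not admit discretisation ripples as maxima)
    # and at an absolute epsilon relative to the image scale
    noise = max(_robust_sd(resp),
                2e-3 * float(resp.max()) / max(snr_min, 1.0),
                1e-9 * max(1.0, float(frame.max())))
    if resp.max() <= snr_min * noise:
        return pd.DataFrame(columns=["x_px", "y_px", "window_sum_au"])
    is_max = (ndimage.maximum_filter(resp, size=3) == resp) & (resp > snr_min * noise)
    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        return pd.DataFrame(columns=["x_px", "y_px", "window_sum_au"])

    # non-maximum suppression of plateau duplicates / shoulder maxima
    order = np.argsort(resp[ys, xs])[::-1]
    min_sep = max(2.0, 2.0 * psf_sigma_px)
    kept: list[tuple[int, int]] = []
    for i in order:
        y, x = int(ys[i]), int(xs[i])
        if all((y - ky) ** 2 + (x - kx) ** 2 >= min_sep ** 2 for ky, kx in kept):
            kept.append((y, x))

    # sub-pixel refinement: centroid of the positive LoG response, which is
    # compact (zero-crossing at ~1.4 sigma) and hence robust to neighbours
    w = max(2, int(math.ceil(2 * psf_sigma_px)))
    h, wdt = frame.shape
    jy, jx = np.mgrid[-w:w + 1, -w:w + 1]
    rows = []
    for y, x in kept:
        if y < w or y >= h - w or x < w or x >= wdt - w:
            continue  # cannot center the refinement window: drop border peaks
        wgt = np.clip(resp[y - w:y + w + 1, x - w:x + w + 1], 0, None)
        tot = wgt.sum()
        if tot <= 0:
            continue
        cy = y + float((wgt * jy).sum() / tot)
        cx = x + float((wgt * jx).sum() / tot)
        ry, rx = int(np.rint(cy)), int(np.rint(cx))
        if ry < 1 or ry >= h - 1 or rx < 1 or rx >= wdt - 1:
            continue
        wsum = float(frame[ry - 1:ry + 2, rx - 1:rx + 2].sum())
        rows.append((cx, cy, wsum))
    det = pd.DataFrame(rows, columns=["x_px", "y_px", "window_sum_au"])
    return det.sort_values(["y_px", "x_px"], kind="mergesort").reset_index(drop=True)


def detect_stack(stack: ImageStack, psf_sigma_px: float = 1.0,
                 snr_min: float = 4.0) -> pd.DataFrame:
    """Detect spots in every frame; returns frame, x_px, y_px, window_sum_au."""
    out = []
    for t in range(stack.n_frames):
        det = detect_spots(stack.frames[t], psf_sigma_px, snr_min)
        det.insert(0, "frame", t + 1)
        out.append(det)
    if not out:
        return pd.DataFrame(columns=["frame", "x_px", "y_px", "window_sum_au"])
    return pd.concat(out, ignore_index=True)


def default_max_disp_px(pixel_size_um: float, frame_interval_s: float,
                        d_max_um2_s: float = 0.2) -> float:
    """Linking gate: 3× the RMS frame displacement at a generous D_max."""
    return 3.0 * math.sqrt(4.0 * d_max_um2_s * frame_interval_s) / pixel_size_um


class _Track:
    __slots__ = ("track_id", "rows", "last_xy", "last_frame")

    def __init__(self, track_id: int, frame: int, x: float, y: float, w: float):
        self.track_id = track_id
        self.rows = [(frame, x, y, w)]
        self.last_xy = (x, y)
        self.last_frame = frame

    def add(self, frame: int, x: float, y: float, w: float) -> None:
        self.rows.append((frame, x, y, w))
        self.last_xy = (x, y)
        self.last_frame = frame


def link_tracks(detections: pd.DataFrame, max_disp_px: float,
                max_gap: int = 2) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    Per frame, open tracks (last seen within ``max_gap + 1`` frames) are
    assigned to detections by minimising total squared displacement under
    the ``max_disp_px`` gate (optimal bipartite assignment with miss/birth
    alternatives); unassigned detections start new tracks.  Gap closing uses
    the same gate against the track's last known position.

    Returns a trajectory table ``track_id, frame, x_px, y_px, intensity_au``
    where ``intensity_au`` is the detection's raw 3×3 window sum.  Frames
    skipped inside a track are its gaps (recoverable via
    :func:`track_gaps`).
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    required = {"frame", "x_px", "y_px"}
    if not required <= set(detections.columns):
        raise ValueError(f"detections need columns {sorted(required)}")
    det = detections.copy()
    if "window_sum_au" not in det.columns:
        det["window_sum_au"] = np.nan

    tracks: list[_Track] = []
    next_id = 0
    gate2 = max_disp_px ** 2
    for frame in sorted(det["frame"].unique()):
        sub = det[det["frame"] == frame].sort_values(
            ["y_px", "x_px"], kind="mergesort")
        xy = sub[["x_px", "y_px"]].to_numpy(dtype=float)
        ws = sub["window_sum_au"].to_numpy(dtype=float)
        nd = len(sub)
        open_tracks = [tr for tr in tracks if frame - tr.last_frame <= max_gap + 1]
        open_tracks.sort(key=lambda tr: tr.track_id)
        nt = len(open_tracks)
        assigned = np.full(nd, -1, dtype=int)  # index into open_tracks
        if nt and nd:
            last = np.array([tr.last_xy for tr in open_tracks])
            cost = ((last[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
            cost[cost > gate2] = _BIG
            # augmented square matrix with miss (track unmatched) and
            # birth (detection unmatched) alternatives at the gate cost
            size = nt + nd
            M = np.full((size, size), _BIG)
            M[:nt, :nd] = cost
            M[nt:, nd:] = 0.0
            for i in range(nt):
                M[i, nd + i] = gate2
            for j in range(nd):
                M[nt + j, j] = gate2
            ri, ci = linear_sum_assignment(M)
            for i, j in zip(ri, ci):
                if i < nt and j < nd and M[i, j] < _BIG:
                    assigned[j] = i
        for j in range(nd):
            x, y, w = float(xy[j, 0]), float(xy[j, 1]), float(ws[j])
            if assigned[j] >= 0:
                open_tracks[assigned[j]].add(int(frame), x, y, w)
            else:
                tracks.append(_Track(next_id, int(frame), x, y, w))
                next_id += 1

    rows = [(tr.track_id, f, x, y, w)
            for tr in sorted(tracks, key=lambda t: t.track_id)
            for (f, x, y, w) in tr.rows]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "intensity_au"])


def track_gaps(tracks: pd.DataFrame) -> pd.DataFrame:
    """Missing (track_id, frame) pairs inside each track's frame span."""
    rows = []
    for tid, sub in tracks.groupby("track_id", sort=True):
        frames = set(sub["frame"].astype(int))
        lo, hi = min(frames), max(frames)
        rows.extend((tid, f) for f in range(lo, hi + 1) if f not in frames)
    return pd.DataFrame(rows, columns=["track_id", "frame"])


def detect_and_track(stack: ImageStack, psf_sigma_px: float = 1.0,
                     snr_min: float = 4.0, max_disp_px: float | None = None,
                     max_gap: int = 2) -> pd.DataFrame:
    """Convenience: detect in every frame, then link."""
    if max_disp_px is None:
        max_disp_px = default_max_disp_px(stack.pixel_size_um,
                                          stack.frame_interval_s)
    det = detect_stack(stack, psf_sigma_px, snr_min)
    return link_tracks(det, max_disp_px=max_disp_px, max_gap=max_gap)
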