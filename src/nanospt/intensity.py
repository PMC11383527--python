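"""Intensity quantification and monomer-calibrated stoichiometry.

The measurement chain:

1. Locate the cell: threshold the temporal-median image and keep the
   largest connected component.
2. Per-frame background K0: the 80th-percentile gray value (linear
   interpolation) of in-mask pixels, after excluding a 5×5 neighbourhood
   around every detection in that frame.
3. Per-particle intensity: the 3×3 pixel window sum centred on the rounded
   particle position minus 9·K0, averaged over the first 20 frames of the
   trajectory (photon-fluctuation smoothing).  The average is truncated at
   the first detected photobleaching step so a bleach event inside the
   window cannot deflate the estimate, and the window sum is divided by the
   sub-pixel PSF aperture fraction so the estimate is offset-free.
4. Monomer calibration: Gaussian fit of the intensity distribution of a
   monomeric calibrant (reference 980 ± 89 a.u.) and a single-exponential
   fit of its single-step photobleach times (reference τ0 ≈ 5 s = 50
   frames at 100 ms/frame); the 20-frame averaging window is checked
   against τ0.
5. Stoichiometry: particle intensity divided by the monomer reference,
   rounded (half-to-even) and floored at 1; particles with ≤2 receptors are
   monomers-plus-dimers, ≥3 are nanoclusters.  MSI is the unweighted group
   mean of per-particle intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ImageStack
from .simulate import aperture_fraction, centered_window_fraction

logger = logging.getLogger("nanospt")


class NoCellError(RuntimeError):
    """Raised when no cell foreground can be segmented."""


@dataclass
class BackgroundEstimate:
    """Per-frame background gray value K0 at quantile ``q``."""

    k0: np.ndarray           # (n_frames,)
    q: float = 0.80
    n_pixels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class CalibrationResult:
    """Gaussian monomer-intensity reference."""

    mu_mono: float
    sigma_mono: float
    n_particles: int
    residual: float = float("nan")  # rms deviation of histogram fit, if used
    degenerate: bool = False


@dataclass
class PhotobleachFit:
    """Single-exponential photobleaching time constant."""

    tau0_s: float
    tau0_frames: float
    n_traces: int
    exponential_like: bool = True


@dataclass
class GroupSummary:
    n_particles: int
    pct_mono_dimer: float
    pct_nanocluster: float
    msi_au: float


# ---------------------------------------------------------------------------
# segmentation and background

def segment_cell(stack: ImageStack) -> np.ndarray:
    """Binary cell mask from the temporal-median image (largest component)."""
    med = np.median(stack.frames.astype(float), axis=0)
    if float(med.max() - med.min()) <= 1e-9:
        raise NoCellError("temporal-median image is uniform; no cell found")
    th = threshold_otsu(med)
    mask = med > th
    if not mask.any() or mask.all():
        raise NoCellError("thresholding produced an empty or full-field mask")
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoCellError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def estimate_background(stack: ImageStack, cell_mask: np.ndarray,
                        detections: pd.DataFrame | None = None,
                        q: float = 0.80) -> BackgroundEstimate:
    """Per-frame K0 = q-quantile of in-mask background pixel gray values.

    A 5×5 block around every detection in a frame is excluded from that
    frame's background distribution.  Quantiles use numpy's linear
    interpolation convention.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    F = stack.n_frames
    h, w = cell_mask.shape
    by_frame: dict[int, np.ndarray] = {}
    if detections is not None and len(detections):
        for f, sub in detections.groupby("frame"):
            by_frame[int(f)] = sub[["x_px", "y_px"]].to_numpy(dtype=float)
    k0 = np.empty(F)
    npix = np.empty(F, dtype=int)
    for t in range(F):
        excl = np.zeros((h, w), dtype=bool)
        for x, y in by_frame.get(t + 1, ()):
            cx, cy = int(np.rint(x)), int(np.rint(y))
            excl[max(cy - 2, 0):cy + 3, max(cx - 2, 0):cx + 3] = True
        sel = cell_mask & ~excl
        if not sel.any():
            raise ValueError(f"frame {t + 1}: all in-mask pixels excluded")
        vals = stack.frames[t][sel].astype(float)
        k0[t] = float(np.quantile(vals, q))
        npix[t] = int(sel.sum())
    return BackgroundEstimate(k0=k0, q=q, n_pixels=npix)


# ---------------------------------------------------------------------------
# photobleach step detection

def _two_segment_split(trace: np.ndarray) -> tuple[int, float, float]:
    """Best two-constant-segment split of a 1-D trace.

    Returns (split index s, pre-mean of trace[:s], post-mean of trace[s:])
    minimising total squared error, 1 <= s <= n-1.
    """
    n = len(trace)
    cs = np.cumsum(trace)
    tot = cs[-1]
    s = np.arange(1, n)
    m1 = cs[:-1] / s
    m2 = (tot - cs[:-1]) / (n - s)
    # maximising explained sum of squares == minimising SSE
    gain = s * m1 ** 2 + (n - s) * m2 ** 2
    best = int(np.argmax(gain))
    return best + 1, float(m1[best]), float(m2[best])


def trace_noise_sd(trace: np.ndarray) -> float:
    """Robust per-frame noise sd from first differences (step-tolerant)."""
    diffs = np.diff(np.asarray(trace, dtype=float))
    return 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / math.sqrt(2)


def first_step_frame(trace: np.ndarray, min_drop_frac: float = 0.15,
                     min_drop_sigma: float = 4.0,
                     noise_sd: float | None = None,
                     _depth: int = 0) -> int | None:
    """First significant downward intensity step (1-based first dark frame).

    Recursive two-segment change-point search: a split is significant when
    the pre/post mean drop exceeds both ``min_drop_frac`` of the pre-mean
    and ``min_drop_sigma`` noise units (noise estimated once on the whole
    trace); the earliest significant split is returned, or None when the
    trace shows no step.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 4 or _depth > 12:
        return None
    if noise_sd is None:
        noise_sd = trace_noise_sd(trace)
    s, m1, m2 = _two_segment_split(trace)
    drop = m1 - m2
    if m1 > 0 and drop > max(min_drop_frac * m1, min_drop_sigma * noise_sd):
        earlier = first_step_frame(trace[:s], min_drop_frac, min_drop_sigma,
                                   noise_sd, _depth + 1)
        return earlier if earlier is not None else s + 1
    return None


def single_step_time(trace: np.ndarray, frame_interval_s: float) -> float | None:
    """Bleach time of a single-step (monomer) trace, in seconds.

    The step at first dark frame d is interval-censored in
    [(d−1)Δt, dΔt) and left-truncated (a fluorophore dark from frame 1 is
    never observed), so the reported time is (d − 1.5)·Δt for d ≥ 2, which
    makes the exponential maximum-likelihood mean unbiased to O(Δt²/τ).
    Returns None for traces with no step (censored) or dark-from-start.
    """
    d = first_step_frame(np.asarray(trace, dtype=float), min_drop_frac=0.5)
    if d is None or d < 2:
        return None
    pre = np.mean(trace[:d - 1])
    post = np.mean(trace[d - 1:])
    if pre <= 0 or post > 0.5 * pre:
        return None  # not a full single step to background
    return (d - 1.5) * frame_interval_s


# ---------------------------------------------------------------------------
# per-particle intensity

class ExcludedTrackError(ValueError):
    """Raised when a track cannot yield a valid intensity estimate."""


def particle_intensity(track: pd.DataFrame, stack: ImageStack,
                       background: BackgroundEstimate,
                       window_frames: int = 20,
                       psf_sigma_px: float | None = None,
                       truncate_at_step: bool = True) -> float:
    """Background-subtracted mean 3×3-window intensity of one track (a.u.).

    For each of the first ``window_frames`` frames of the track the
    intensity is the 3×3 pixel sum centred on the rounded particle position
    minus 9·K0 of that frame; the mean over the window is returned, floored
    at 0.  When ``psf_sigma_px`` is given, each frame's value is divided by
    the sub-pixel aperture fraction of the window (offset correction).
    When ``truncate_at_step`` is set, the average stops at the first
    detected photobleaching step.
    """
    track = track.sort_values("frame")
    if len(track) < window_frames:
        raise ExcludedTrackError(
            f"track shorter than window ({len(track)} < {window_frames})")
    frames = track["frame"].to_numpy(dtype=int)
    xs = track["x_px"].to_numpy(dtype=float)
    ys = track["y_px"].to_numpy(dtype=float)
    h, w = stack.frames.shape[1:]
    cfrac = centered_window_fraction(psf_sigma_px) if psf_sigma_px else None

    vals = []
    for f, x, y in zip(frames, xs, ys):
        cx, cy = int(np.rint(x)), int(np.rint(y))
        if cx < 1 or cx >= w - 1 or cy < 1 or cy >= h - 1:
            raise ExcludedTrackError("3×3 window crosses the image border")
        win = stack.frames[f - 1, cy - 1:cy + 2, cx - 1:cx + 2].astype(float)
        v = float(win.sum()) - 9.0 * float(background.k0[f - 1])
        if cfrac is not None:
            fx = float(aperture_fraction(x - cx, psf_sigma_px))
            fy = float(aperture_fraction(y - cy, psf_sigma_px))
            v *= cfrac / (fx * fy)
        vals.append(v)
    return _windowed_mean(np.array(vals), window_frames, truncate_at_step)


def _windowed_mean(trace: np.ndarray, window_frames: int,
                   truncate_at_step: bool, min_pre_frames: int = 3) -> float:
    stop = min(len(trace), window_frames)
    if truncate_at_step:
        d = first_step_frame(trace[:min(len(trace), 2 * window_frames)])
        if d is not None:
            if d - 1 < min_pre_frames:
                raise ExcludedTrackError(
                    "bleaching step too early for a stable intensity average")
            stop = min(stop, d - 1)
    return max(0.0, float(np.mean(trace[:stop])))


def trace_intensity(track: pd.DataFrame, window_frames: int = 20,
                    truncate_at_step: bool = True) -> float:
    """Windowed mean of a fast-path track's ``intensity_au`` column."""
    track = track.sort_values("frame")
    if len(track) < window_frames:
        raise ExcludedTrackError(
            f"track shorter than window ({len(track)} < {window_frames})")
    return _windowed_mean(track["intensity_au"].to_numpy(dtype=float),
                          window_frames, truncate_at_step)


def extract_traces(tracks: pd.DataFrame, stack: ImageStack,
                   background: BackgroundEstimate,
                   psf_sigma_px: float | None = None) -> pd.DataFrame:
    """Per-frame background-subtracted (and aperture-corrected) intensities.

    Returns the track table with ``intensity_au`` replaced by the corrected
    window signal; tracks whose window crosses the border are dropped (and
    logged).
    """
    out = []
    h, w = stack.frames.shape[1:]
    cfrac = centered_window_fraction(psf_sigma_px) if psf_sigma_px else None
    for tid, sub in tracks.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        f = sub["frame"].to_numpy(dtype=int)
        x = sub["x_px"].to_numpy(dtype=float)
        y = sub["y_px"].to_numpy(dtype=float)
        cx = np.rint(x).astype(int)
        cy = np.rint(y).astype(int)
        if (cx < 1).any() or (cx >= w - 1).any() or (cy < 1).any() or (cy >= h - 1).any():
            logger.info("track %s: window crosses border; excluded", tid)
            continue
        vals = np.array([
            float(stack.frames[fi - 1, cyi - 1:cyi + 2, cxi - 1:cxi + 2].sum())
            - 9.0 * float(background.k0[fi - 1])
            for fi, cxi, cyi in zip(f, cx, cy)
        ])
        if cfrac is not None:
            fx = aperture_fraction(x - cx, psf_sigma_px)
            fy = aperture_fraction(y - cy, psf_sigma_px)
            vals = vals * cfrac / (fx * fy)
        sub = sub.copy()
        sub["intensity_au"] = vals
        out.append(sub)
    if not out:
        return tracks.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# calibration fits

def fit_monomer_reference(intensities: np.ndarray,
                          method: str = "mle") -> CalibrationResult:
    """Gaussian fit of monomeric-calibrant particle intensities.

    ``method="mle"`` uses the maximum-likelihood estimates (sample mean and
    sd); ``method="histogram"`` least-squares a Gaussian to a histogram.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 calibration particles, got {len(x)}")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        logger.warning("degenerate calibration input: zero variance")
        return CalibrationResult(mu_mono=mu, sigma_mono=0.0,
                                 n_particles=len(x), degenerate=True)
    if method == "histogram":
        from scipy.optimize import curve_fit
        counts, edges = np.histogram(x, bins="fd", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(v, a, m, s):
            return a * np.exp(-0.5 * ((v - m) / s) ** 2)

        popt, _ = curve_fit(gauss, centers, counts,
                            p0=[counts.max(), mu, sigma])
        resid = float(np.sqrt(np.mean((gauss(centers, *popt) - counts) ** 2)))
        return CalibrationResult(mu_mono=float(popt[1]),
                                 sigma_mono=abs(float(popt[2])),
                                 n_particles=len(x), residual=resid)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    return CalibrationResult(mu_mono=mu, sigma_mono=sigma, n_particles=len(x))


def fit_photobleaching(bleach_times_s: np.ndarray,
                       frame_interval_s: float) -> PhotobleachFit:
    """Single-exponential-decay fit of single-step photobleach times.

    The exponential maximum-likelihood time constant is the sample mean.
    Inputs must be positive; a distribution whose coefficient of variation
    is far from 1 (an exponential has CV = 1) is flagged non-exponential.
    """
    t = np.asarray(bleach_times_s, dtype=float)
    if len(t) < 100:
        raise ValueError(f"need >= 100 bleach times, got {len(t)}")
    if np.any(t <= 0):
        raise ValueError("bleach times must be strictly positive")
    tau = float(np.mean(t))
    cv = float(np.std(t, ddof=1) / tau) if tau > 0 else 0.0
    ok = 0.5 <= cv <= 1.5
    if not ok:
        logger.warning("bleach-time distribution CV=%.2f, not exponential-like", cv)
    return PhotobleachFit(tau0_s=tau, tau0_frames=tau / frame_interval_s,
                          n_traces=len(t), exponential_like=ok)


def check_window_vs_bleaching(window_frames: int, fit: PhotobleachFit) -> bool:
    """True when the averaging window is safely shorter than τ0 (in frames)."""
    ok = window_frames < fit.tau0_frames
    if not ok:
        logger.warning(
            "intensity window (%d frames) is not shorter than the "
            "photobleaching constant (%.1f frames); intensity averages will "
            "be bleaching-biased", window_frames, fit.tau0_frames)
    return ok


def calibrate_monomer(tracks: pd.DataFrame, frame_interval_s: float,
                      window_frames: int = 20, min_pre_frames: int = 5
                      ) -> tuple[CalibrationResult, PhotobleachFit]:
    """Full monomer calibration from calibrant traces.

    Expects a trajectory table whose ``intensity_au`` column holds
    background-subtracted window signals (fast-path simulator output or
    :func:`extract_traces` of a calibration movie).  Per trace, the single
    photobleaching step is located; the bleach time enters the exponential
    fit and the pre-step frames (at least ``min_pre_frames``, at most
    ``window_frames``) enter the Gaussian intensity fit.
    """
    intensities: list[float] = []
    times: list[float] = []
    for _, sub in tracks.groupby("track_id", sort=True):
        trace = sub.sort_values("frame")["intensity_au"].to_numpy(dtype=float)
        d = first_step_frame(trace, min_drop_frac=0.5)
        t = single_step_time(trace, frame_interval_s)
        if t is not None:
            times.append(t)
        n_pre = len(trace) if d is None else d - 1
        if n_pre >= min_pre_frames:
            m = float(np.mean(trace[:min(window_frames, n_pre)]))
            # a real calibrant particle must emit above the noise floor;
            # fast-path traces of fluorophores dark from frame 1 are pure
            # noise (an imaged particle like that would never be detected)
            diffs = np.diff(trace)
            noise = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs))))
            if m > max(5.0 * noise / math.sqrt(2), 0.0):
                intensities.append(m)
    calib = fit_monomer_reference(np.array(intensities))
    bleach = fit_photobleaching(np.array(times), frame_interval_s)
    return calib, bleach


# ---------------------------------------------------------------------------
# stoichiometry and group summary

def estimate_stoichiometry(mean_intensity_au: float,
                           calibration: CalibrationResult
                           ) -> tuple[float, int]:
    """(ratio, receptor count): intensity over the monomer reference.

    The count is the ratio rounded half-to-even and floored at 1; particles
    with non-positive intensity are rejected (no defined count).
    """
    if calibration.mu_mono <= 0:
        raise ValueError("calibration mean must be positive")
    if mean_intensity_au <= 0:
        raise ExcludedTrackError("non-positive particle intensity")
    ratio = mean_intensity_au / calibration.mu_mono
    count = max(1, int(np.round(ratio)))
    return ratio, count


def summarize_particles(traces: pd.DataFrame, calibration: CalibrationResult,
                        window_frames: int = 20,
                        truncate_at_step: bool = True) -> pd.DataFrame:
    """Per-particle summary from background-subtracted traces.

    Returns columns ``track_id, mean_intensity_au, stoichiometry_ratio,
    receptor_count, aggregation_class``; tracks shorter than the window or
    with unusable intensities are skipped (logged).
    """
    rows = []
    for tid, sub in traces.groupby("track_id", sort=True):
        try:
            m = trace_intensity(sub, window_frames, truncate_at_step)
            ratio, count = estimate_stoichiometry(m, calibration)
        except (ExcludedTrackError, ValueError) as err:
            logger.info("track %s excluded from stoichiometry: %s", tid, err)
            continue
        rows.append((tid, m, ratio, count,
                     "nanocluster" if count >= 3 else "mono_dimer"))
    return pd.DataFrame(rows, columns=[
        "track_id", "mean_intensity_au", "stoichiometry_ratio",
        "receptor_count", "aggregation_class"])


def classify_aggregation(particles: pd.DataFrame) -> GroupSummary:
    """Group fractions of monomers-plus-dimers (≤2) vs nanoclusters (≥3), and MSI."""
    if len(particles) == 0:
        raise ValueError("no summarized particles")
    counts = particles["receptor_count"].to_numpy()
    nano = float(np.mean(counts >= 3)) * 100.0
    msi = float(np.mean(np.clip(particles["mean_intensity_au"].to_numpy(), 0, None)))
    return GroupSummary(n_particles=len(particles),
                        pct_mono_dimer=100.0 - nano,
                        pct_nanocluster=nano,
                        msi_au=msi)
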