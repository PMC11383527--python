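"""Ground-truth synthetic data for single-particle TIRF quantification.

The generator emulates the acquisition regime the downstream analysis
assumes: 500 frames at 10 Hz (100 ms/frame), sparse particles
(< 4.5 particles/μm²), each particle a cluster of 1..k fluorophore-tagged
receptors.  Per-fluorophore brightness is drawn once per fluorophore from a
Gaussian (reference 980 ± 89 a.u.) and stays constant until the fluorophore
photobleaches in a single step at an exponentially distributed time
(lifetime ~5 s).  Mobile particles diffuse as 2-D Brownian motion
(basal D ≈ 0.02 μm²/s) with reflecting boundaries; immobile particles move
only through localization noise.  Rendering uses an isotropic Gaussian PSF;
Poisson shot noise and Gaussian read noise are applied after rendering and
can be switched off for exact tests.

Brightness convention: a fluorophore's amplitude is the signal it deposits
in a 3×3 pixel window centered on the particle, i.e. the same quantity the
analysis measures.  The rendered PSF is scaled so a pixel-centered source's
3×3 sum equals its amplitude.

Cell tracks for chemotaxis are biased persistent random walks: bias 0 is an
isotropic persistent walk, bias 1 is straight-line motion along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from .io import ImageStack

NEVER = -1  # sentinel: fluorophore never bleaches within the movie

_SQRT2 = math.sqrt(2.0)


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + special.erf(np.asarray(z) / _SQRT2))


def aperture_fraction(dx: float | np.ndarray, sigma: float) -> np.ndarray:
    """Per-axis fraction of a Gaussian PSF inside a 3-pixel aperture.

    ``dx`` is the source offset from the aperture's central pixel center.
    """
    dx = np.asarray(dx, dtype=float)
    return _norm_cdf((1.5 - dx) / sigma) - _norm_cdf((-1.5 - dx) / sigma)


def centered_window_fraction(sigma: float) -> float:
    """2-D fraction of a pixel-centered Gaussian PSF inside its 3×3 window."""
    f = float(aperture_fraction(0.0, sigma))
    return f * f


@dataclass(frozen=True, eq=False)
class SimulationConfig:
    """Acquisition, photophysics and motion parameters of the simulator.

    Defaults are the regime of the quantification method: 10 Hz, 500
    frames, monomer brightness 980 ± 89 a.u., bleach lifetime 5 s, basal
    mobile D 0.02 μm²/s, density below 4.5 particles/μm².
    ``bleach_lifetime_s = inf`` disables photobleaching.
    """

    fov_px: int = 64
    pixel_size_um: float = 0.1
    frame_count: int = 500
    frame_interval_s: float = 0.1
    monomer_mean_au: float = 980.0
    monomer_sd_au: float = 89.0
    bleach_lifetime_s: float = 5.0
    background_level_au: float = 100.0
    cell_extra_background_au: float = 100.0
    cell_radius_frac: Optional[float] = 0.45
    read_noise_sd_au: float = 10.0
    shot_noise: bool = True
    psf_sigma_px: float = 1.0
    stoichiometry_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.30, 3: 0.10, 4: 0.05}
    )
    particle_density_per_um2: float = 1.0
    n_particles: Optional[int] = None  # overrides density when set
    mobile_fraction: float = 0.85
    d_mobile_um2_s: float = 0.02
    loc_noise_sd_um: float = 0.03
    k_max: int = 10
    particle_cap: int = 20000
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.fov_px < 8:
            raise ValueError("fov_px must be >= 8")
        for name in ("pixel_size_um", "frame_interval_s", "monomer_mean_au",
                     "bleach_lifetime_s", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("monomer_sd_au", "background_level_au",
                     "cell_extra_background_au", "read_noise_sd_au",
                     "particle_density_per_um2", "d_mobile_um2_s",
                     "loc_noise_sd_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.cell_radius_frac is not None and not (
                0.05 < self.cell_radius_frac <= 0.5):
            raise ValueError("cell_radius_frac must be in (0.05, 0.5]")
        pmf = self.stoichiometry_pmf
        if not pmf:
            raise ValueError("stoichiometry_pmf must be non-empty")
        if any((not isinstance(k, (int, np.integer))) or k < 1 or k > self.k_max
               for k in pmf):
            raise ValueError(f"stoichiometry counts must be integers in 1..{self.k_max}")
        if any(v < 0 for v in pmf.values()):
            raise ValueError("stoichiometry probabilities must be >= 0")
        if abs(sum(pmf.values()) - 1.0) > 1e-9:
            raise ValueError("stoichiometry_pmf must sum to 1 within 1e-9")
        return self

    @property
    def fov_um(self) -> float:
        return self.fov_px * self.pixel_size_um

    def cell_area_um2(self) -> float:
        """Area over which particles are placed (cell disc, or full field)."""
        if self.cell_radius_frac is None:
            return self.fov_um ** 2
        r = self.cell_radius_frac * self.fov_um
        return math.pi * r * r


def monomer_config(config: SimulationConfig) -> SimulationConfig:
    """The same acquisition with a monomer-only stoichiometry (calibrant)."""
    return replace(config, stoichiometry_pmf={1: 1.0})


@dataclass
class GroundTruth:
    """Validation labels for one simulated dataset.

    ``particles``: one row per particle (particle_id, true_count,
    motion_class, true_d_um2_s, x0_px, y0_px, edge_flag).
    ``fluorophores``: one row per fluorophore (particle_id, amplitude_au,
    bleach_time_s, first_dark_frame; ``first_dark_frame = -1`` means the
    fluorophore never bleaches within the movie).
    ``positions_px``: (n_particles, n_frames, 2) true x, y per frame.
    ``amplitudes_au``: (n_particles, n_frames) summed unbleached amplitude.
    """

    particles: pd.DataFrame
    fluorophores: pd.DataFrame
    positions_px: Optional[np.ndarray] = None
    amplitudes_au: Optional[np.ndarray] = None

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def counts_alive_at(self, frame: int = 1) -> pd.Series:
        """Per-particle fluorophores still emitting at the given frame.

        A fluorophore dark before acquisition starts is invisible to any
        intensity measurement, so recovery is scored against the count
        alive at the first analysed frame, not the nominal count.
        """
        fl = self.fluorophores
        alive = (fl["first_dark_frame"] == NEVER) | (fl["first_dark_frame"] > frame)
        counts = fl.loc[alive].groupby("particle_id").size()
        return counts.reindex(self.particles["particle_id"], fill_value=0)

    def isolated_particles(self, min_separation_px: float = 4.0,
                           through_frame: int = 20) -> np.ndarray:
        """Particle ids never closer than ``min_separation_px`` to another
        particle during the first ``through_frame`` frames (3×3-window
        quantification is undefined for overlapping PSFs)."""
        if self.positions_px is None:
            raise ValueError("ground truth has no per-frame positions")
        pos = self.positions_px[:, :through_frame, :]
        n = pos.shape[0]
        ok = np.ones(n, dtype=bool)
        for t in range(pos.shape[1]):
            d = np.linalg.norm(pos[:, None, t, :] - pos[None, :, t, :], axis=2)
            np.fill_diagonal(d, np.inf)
            ok &= d.min(axis=1) >= min_separation_px
        return self.particles["particle_id"].to_numpy()[ok]


# ---------------------------------------------------------------------------
# particle drawing

def _draw_particles(config: SimulationConfig, rng: np.random.Generator):
    c = config
    area = c.cell_area_um2()
    if c.n_particles is not None:
        n = int(c.n_particles)
    else:
        n = int(rng.poisson(c.particle_density_per_um2 * area))
    if c.n_particles is None and c.particle_density_per_um2 * area > c.particle_cap:
        raise ValueError(
            f"expected particle count {c.particle_density_per_um2 * area:.0f} "
            f"exceeds cap {c.particle_cap}; lower particle_density_per_um2 or "
            f"raise particle_cap"
        )
    if n > c.particle_cap:
        raise ValueError(f"n_particles {n} exceeds cap {c.particle_cap}")

    # positions: uniform over the cell disc, or over the field interior
    if c.cell_radius_frac is not None:
        r_px = c.cell_radius_frac * c.fov_px
        center = (c.fov_px - 1) / 2.0
        rad = r_px * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2 * math.pi
        x0 = center + rad * np.cos(ang)
        y0 = center + rad * np.sin(ang)
    else:
        x0 = rng.random(n) * (c.fov_px - 1)
        y0 = rng.random(n) * (c.fov_px - 1)

    ks = np.array(sorted(c.stoichiometry_pmf), dtype=int)
    ps = np.array([c.stoichiometry_pmf[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    counts = rng.choice(ks, size=n, p=ps) if n else np.zeros(0, dtype=int)

    mobile = rng.random(n) < c.mobile_fraction
    true_d = np.where(mobile, c.d_mobile_um2_s, 0.0)

    margin = 3.0
    edge = ((x0 < margin) | (x0 > c.fov_px - 1 - margin)
            | (y0 < margin) | (y0 > c.fov_px - 1 - margin))

    particles = pd.DataFrame({
        "particle_id": np.arange(n, dtype=int),
        "true_count": counts,
        "motion_class": np.where(mobile, "mobile", "immobile"),
        "true_d_um2_s": true_d,
        "x0_px": x0,
        "y0_px": y0,
        "edge_flag": edge,
    })

    # fluorophores
    n_fluor = int(counts.sum())
    pid = np.repeat(np.arange(n), counts) if n else np.zeros(0, dtype=int)
    amps = rng.normal(c.monomer_mean_au, c.monomer_sd_au, size=n_fluor)
    while np.any(amps <= 0):  # physical brightness is positive
        bad = amps <= 0
        amps[bad] = rng.normal(c.monomer_mean_au, c.monomer_sd_au, size=bad.sum())
    if math.isinf(c.bleach_lifetime_s):
        bleach_t = np.full(n_fluor, np.inf)
    else:
        bleach_t = rng.exponential(c.bleach_lifetime_s, size=n_fluor)
    n_on = np.floor(bleach_t / c.frame_interval_s)  # frames emitted
    first_dark = np.where(n_on >= c.frame_count, NEVER, n_on + 1).astype(int)

    fluorophores = pd.DataFrame({
        "particle_id": pid,
        "amplitude_au": amps,
        "bleach_time_s": bleach_t,
        "first_dark_frame": first_dark,
    })
    return particles, fluorophores


def _amplitude_series(fluorophores: pd.DataFrame, n_particles: int,
                      n_frames: int) -> np.ndarray:
    """(n_particles, n_frames) summed unbleached amplitude per frame."""
    amp = np.zeros((n_particles, n_frames))
    for pid, a, fd in zip(fluorophores["particle_id"].to_numpy(),
                          fluorophores["amplitude_au"].to_numpy(),
                          fluorophores["first_dark_frame"].to_numpy()):
        stop = n_frames if fd == NEVER else int(fd) - 1
        amp[pid, :stop] += a
    return amp


def _reflect(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    q = np.mod(p - lo, 2 * span)
    return lo + np.minimum(q, 2 * span - q)


def _true_positions(config: SimulationConfig, particles: pd.DataFrame,
                    rng: np.random.Generator) -> np.ndarray:
    """(n, F, 2) Brownian/static true positions with reflecting boundaries."""
    c = config
    n, F = len(particles), c.frame_count
    pos = np.zeros((n, F, 2))
    pos[:, 0, 0] = particles["x0_px"].to_numpy()
    pos[:, 0, 1] = particles["y0_px"].to_numpy()
    mobile = (particles["motion_class"] == "mobile").to_numpy()
    if F > 1:
        step_px = math.sqrt(2 * c.d_mobile_um2_s * c.frame_interval_s) / c.pixel_size_um
        steps = np.zeros((n, F - 1, 2))
        if mobile.any() and step_px > 0:
            steps[mobile] = rng.normal(0.0, step_px, size=(mobile.sum(), F - 1, 2))
        pos[:, 1:, :] = pos[:, :1, :] + np.cumsum(steps, axis=1)
        pos = _reflect(pos, -0.5, c.fov_px - 0.5)
    return pos


# ---------------------------------------------------------------------------
# rendering

def _background_image(config: SimulationConfig) -> np.ndarray:
    c = config
    img = np.full((c.fov_px, c.fov_px), float(c.background_level_au))
    if c.cell_radius_frac is not None and c.cell_extra_background_au > 0:
        center = (c.fov_px - 1) / 2.0
        yy, xx = np.mgrid[0:c.fov_px, 0:c.fov_px]
        disc = (xx - center) ** 2 + (yy - center) ** 2 <= (c.cell_radius_frac * c.fov_px) ** 2
        img[disc] += c.cell_extra_background_au
    return img


def cell_mask_truth(config: SimulationConfig) -> np.ndarray:
    """True cell-disc mask of a simulated movie (all-True when no disc)."""
    c = config
    if c.cell_radius_frac is None:
        return np.ones((c.fov_px, c.fov_px), dtype=bool)
    center = (c.fov_px - 1) / 2.0
    yy, xx = np.mgrid[0:c.fov_px, 0:c.fov_px]
    return (xx - center) ** 2 + (yy - center) ** 2 <= (c.cell_radius_frac * c.fov_px) ** 2


def _render_frame(shape: tuple[int, int], x: np.ndarray, y: np.ndarray,
                  flux: np.ndarray, sigma: float) -> np.ndarray:
    """Render pixel-integrated Gaussian sources onto a zero image."""
    img = np.zeros(shape)
    if len(x) == 0:
        return img
    half = max(3, int(math.ceil(4 * sigma)))
    w = 2 * half + 1
    cx = np.rint(x).astype(int)
    cy = np.rint(y).astype(int)
    rel = np.arange(-half, half + 2) - 0.5  # pixel edges relative to center pixel
    zx = (rel[None, :] + cx[:, None] - x[:, None]) / sigma
    zy = (rel[None, :] + cy[:, None] - y[:, None]) / sigma
    wx = np.diff(_norm_cdf(zx), axis=1)
    wy = np.diff(_norm_cdf(zy), axis=1)
    patch = flux[:, None, None] * wy[:, :, None] * wx[:, None, :]
    iy = cy[:, None] + np.arange(-half, half + 1)[None, :]
    ix = cx[:, None] + np.arange(-half, half + 1)[None, :]
    IY = np.broadcast_to(iy[:, :, None], (len(x), w, w))
    IX = np.broadcast_to(ix[:, None, :], (len(x), w, w))
    ok = (IY >= 0) & (IY < shape[0]) & (IX >= 0) & (IX < shape[1])
    np.add.at(img, (IY[ok], IX[ok]), patch[ok])
    return img


def _apply_noise(img: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = img
    if config.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if config.read_noise_sd_au > 0:
        out = out + rng.normal(0.0, config.read_noise_sd_au, size=out.shape)
    return np.clip(out, 0, None)


def simulate_receptor_movie(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a TIRF-like movie of PSF-blurred receptor particles.

    Returns the image stack (uint16) and the full ground truth, including
    per-frame true positions and unbleached-amplitude sums for scoring.
    """
    c = config.validate()
    rng = np.random.default_rng(c.seed)
    particles, fluorophores = _draw_particles(c, rng)
    amp = _amplitude_series(fluorophores, len(particles), c.frame_count)
    pos = _true_positions(c, particles, rng)
    bg = _background_image(c)
    cfrac = centered_window_fraction(c.psf_sigma_px)

    frames = np.empty((c.frame_count, c.fov_px, c.fov_px), dtype=np.uint16)
    for t in range(c.frame_count):
        active = amp[:, t] > 0
        img = bg + _render_frame(
            bg.shape, pos[active, t, 0], pos[active, t, 1],
            amp[active, t] / cfrac, c.psf_sigma_px,
        )
        img = _apply_noise(img, c, rng)
        frames[t] = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    stack = ImageStack(frames=frames, pixel_size_um=c.pixel_size_um,
                       frame_interval_s=c.frame_interval_s)
    gt = GroundTruth(particles=particles, fluorophores=fluorophores,
                     positions_px=pos, amplitudes_au=amp)
    return stack, gt


def simulate_calibration_movie(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Monomer-only calibration movie (stoichiometry forced to {1: 1})."""
    return simulate_receptor_movie(monomer_config(config))


# ---------------------------------------------------------------------------
# image-free fast path

def simulate_trajectories(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw trajectories and window intensities without rendering images.

    The returned table has one row per particle and frame with columns
    ``track_id, frame, x_px, y_px, intensity_au``; ``intensity_au`` is the
    background-subtracted 3×3-window-equivalent signal (sum of unbleached
    fluorophore amplitudes plus, when enabled, shot noise of the window
    counts and 3-pixel-row read noise).  Positions carry localization noise.
    """
    c = config.validate()
    rng = np.random.default_rng(c.seed)
    particles, fluorophores = _draw_particles(c, rng)
    n, F = len(particles), c.frame_count
    amp = _amplitude_series(fluorophores, n, F)
    pos = _true_positions(c, particles, rng)

    loc_px = c.loc_noise_sd_um / c.pixel_size_um
    obs = pos + rng.normal(0.0, loc_px, size=pos.shape) if loc_px > 0 else pos.copy()

    intens = amp.copy()
    if c.shot_noise:
        # Gaussian approximation of Poisson counting noise over the 3x3 window
        var = np.clip(amp, 0, None) + 9.0 * (
            c.background_level_au + c.cell_extra_background_au
            if c.cell_radius_frac is not None else c.background_level_au)
        intens = intens + rng.normal(0.0, 1.0, size=amp.shape) * np.sqrt(var)
    if c.read_noise_sd_au > 0:
        intens = intens + rng.normal(0.0, 3.0 * c.read_noise_sd_au, size=amp.shape)

    tracks = pd.DataFrame({
        "track_id": np.repeat(np.arange(n, dtype=int), F),
        "frame": np.tile(np.arange(1, F + 1, dtype=int), n),
        "x_px": obs[:, :, 0].ravel(),
        "y_px": obs[:, :, 1].ravel(),
        "intensity_au": intens.ravel(),
    })
    gt = GroundTruth(particles=particles, fluorophores=fluorophores,
                     positions_px=pos, amplitudes_au=amp)
    return tracks, gt


def simulate_calibration_tracks(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Monomer-only fast-path trajectories (calibration fixture)."""
    return simulate_trajectories(monomer_config(config))


# ---------------------------------------------------------------------------
# chemotaxis cell tracks

def simulate_cell_tracks(n_cells: int, n_steps: int, step_um: float = 5.0,
                         bias: float = 0.0, seed: int = 0,
                         persistence: float = 1.0,
                         frame_interval: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biased persistent random walks for directional-migration analysis.

    Each step has fixed length ``step_um``; the direction is a persistent
    update of the previous direction blended toward +x with weight ``bias``:
    bias 0 gives an isotropic persistent walk, bias 1 straight +x motion.
    Returns (tracks, truth) with tracks columns ``cell_id, frame, x_um,
    y_um`` and per-cell true bias in truth.
    """
    if n_cells < 1 or n_steps < 1:
        raise ValueError("n_cells and n_steps must be >= 1")
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    rng = np.random.default_rng(seed)
    theta0 = rng.random(n_cells) * 2 * math.pi
    d = np.stack([np.cos(theta0), np.sin(theta0)], axis=1)
    if bias == 1.0:
        d = np.tile([1.0, 0.0], (n_cells, 1))
    pos = np.zeros((n_cells, n_steps + 1, 2))
    ex = np.array([1.0, 0.0])
    for t in range(n_steps):
        phi = rng.random(n_cells) * 2 * math.pi
        noise = np.stack([np.cos(phi), np.sin(phi)], axis=1)
        r = d + persistence * noise
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        d = (1.0 - bias) * r + bias * ex
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pos[:, t + 1] = pos[:, t] + step_um * d
    tracks = pd.DataFrame({
        "cell_id": np.repeat(np.arange(n_cells, dtype=int), n_steps + 1),
        "frame": np.tile(np.arange(n_steps + 1, dtype=int) * frame_interval, n_cells),
        "x_um": pos[:, :, 0].ravel(),
        "y_um": pos[:, :, 1].ravel(),
    })
    truth = pd.DataFrame({"cell_id": np.arange(n_cells, dtype=int), "bias": bias})
    return tracks, truth


# ---------------------------------------------------------------------------
# ground-truth matching (validation utility)

def match_tracks_to_truth(tracks: pd.DataFrame, gt: GroundTruth,
                          max_radius_px: float = 2.0) -> pd.DataFrame:
    """Match reconstructed tracks to true particles by per-frame proximity.

    For each track, every detection is compared against the true positions
    of all particles in the same frame; the track is assigned to the
    particle closest to its detections on average (within
    ``max_radius_px``), with the fraction of detections belonging to that
    particle reported as ``purity``.  Unmatchable tracks get particle_id -1.
    """
    if gt.positions_px is None:
        raise ValueError("ground truth has no per-frame positions")
    pos = gt.positions_px  # (n, F, 2)
    rows = []
    for tid, sub in tracks.groupby("track_id", sort=True):
        f = sub["frame"].to_numpy(dtype=int) - 1
        xy = sub[["x_px", "y_px"]].to_numpy()
        d = np.linalg.norm(pos[:, f, :] - xy[None, :, :], axis=2)  # (n, len)
        nearest = np.argmin(d, axis=0)
        within = d[nearest, np.arange(len(f))] <= max_radius_px
        if not within.any():
            rows.append((tid, -1, 0.0, len(f)))
            continue
        ids, counts = np.unique(nearest[within], return_counts=True)
        best = ids[np.argmax(counts)]
        purity = counts.max() / len(f)
        rows.append((tid, int(best), float(purity), len(f)))
    return pd.DataFrame(rows, columns=["track_id", "particle_id", "purity", "n_frames"])
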