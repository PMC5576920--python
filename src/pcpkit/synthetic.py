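"""Synthetic microscopy generators with ground truth.

Every input class the analysis pipeline consumes can be produced here with
known ground truth: two-type co-culture snapshots whose heterotypic
interfaces accumulate signal under a steep Hill rule, bleach-recovery
movies governed by 1D diffusion plus membrane-cytoplasm exchange,
two-channel boundaries with a fixed sub-resolution normal offset between
the channels, and single-pair induction time series with a fluorophore
maturation delay.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import InvalidParameterError, NoiseModel, SimConfig

__all__ = [
    "PopulationParams",
    "GroundTruthSnapshot",
    "FrapTruth",
    "RainbowTruth",
    "PairInduction",
    "PairTimeseriesTruth",
    "simulate_snapshot",
    "simulate_frap_movie",
    "render_boundary_frap_movie",
    "render_tirf_frap_movie",
    "simulate_rainbow",
    "simulate_pair_timeseries",
    "render_pair_movie",
    "hill",
]


def hill(x, K: float, n: float):
    """Hill response x^n / (K^n + x^n), safe at x = 0 and for steep n."""
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    # logistic in log space avoids overflow for large exponents
    r = expit(n * (np.log(np.maximum(x, 1e-300)) - math.log(K)))
    return np.where(x <= 0, 0.0, r)


def apply_noise(image: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Poisson-Gaussian camera noise: shot noise at the given gain plus read noise."""
    out = np.asarray(image, dtype=float)
    if noise.poisson_gain > 0:
        out = rng.poisson(np.maximum(out, 0.0) / noise.poisson_gain) * noise.poisson_gain
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, out.shape)
    return out


# ---------------------------------------------------------------------------
# co-culture snapshots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Cell population and accumulation-rule parameters for snapshots.

    Expression levels are log-normal per channel (median in a.u.,
    sigma_log in natural-log units). A heterotypic interface accumulates
    with probability

        p = f_max * H(I_Ds; K_Ds, n) * H(I_Fat; K_Fat, n)

    where H is a Hill function and I_Fat / I_Ds are the flanking cells'
    true expression levels. The steep default exponent (n = 16) acts as a
    soft threshold gate on each channel and yields the sharply separated
    accumulating / non-accumulating populations seen in co-culture data.
    """

    n_cells: int = 120
    fat_fraction: float = 0.5
    ds_fraction: float = 0.5  # remainder is dual-expressing
    fat_median: float = 300.0
    fat_sigma_log: float = 0.8
    ds_median: float = 200.0
    ds_sigma_log: float = 0.8
    background: float = 5.0  # a.u. per channel
    cell_radius: float = 10.0  # µm, sets nucleus spacing
    K_Ds: float = 150.0
    K_Fat: float = 150.0
    hill_n: float = 16.0
    f_max: float = 0.95
    stripe_gain: float = 5.0  # stripe amplitude in units of the channel median
    nucleus_sigma: float = 3.0  # µm, rendered nucleus width
    min_contact: float = 2.0  # µm; shorter contacts never form a stable zone

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise InvalidParameterError("n_cells must be >= 0")
        for name in ("fat_median", "ds_median", "fat_sigma_log", "ds_sigma_log",
                     "K_Ds", "K_Fat", "hill_n", "cell_radius"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def accumulation_probability(self, i_fat, i_ds):
        """The generator's accumulation rule; the oracle for all rule tests."""
        return self.f_max * hill(i_ds, self.K_Ds, self.hill_n) * hill(i_fat, self.K_Fat, self.hill_n)


@dataclass
class GroundTruthSnapshot:
    """A rendered snapshot plus complete ground truth.

    image          : (3, H, W) float array, channels (green, red, blue).
    label_map      : per-pixel cell id, 0 = background.
    cell_table     : cell_id, cell_type, true_I_Fat, true_I_Ds, nucleus_row/col.
    interface_table: cell_a < cell_b, heterotypic, accumulating, p_accum.
    accum_mask     : boolean truth mask of rendered accumulating-stripe pixels.
    """

    image: np.ndarray
    label_map: np.ndarray
    cell_table: pd.DataFrame
    interface_table: pd.DataFrame
    accum_mask: np.ndarray
    config: SimConfig
    population: PopulationParams


def _poisson_disc(rng, shape, n, min_dist):
    """Rejection-sample up to n points with pairwise distance >= min_dist.

    Points are confined to a central ellipse so the rendered tissue forms a
    patch surrounded by true background, as in a real co-culture field.
    """
    pts: list[tuple[float, float]] = []
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.46 * h, 0.46 * w
    tries = 0
    while len(pts) < n and tries < 4000 * max(n, 1):
        tries += 1
        p = (rng.uniform(2, h - 2), rng.uniform(2, w - 2))
        if ((p[0] - cy) / ay) ** 2 + ((p[1] - cx) / ax) ** 2 > 1.0:
            continue
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_dist**2 for q in pts):
            pts.append(p)
    return np.array(pts, dtype=float).reshape(-1, 2)


def _interfaces_from_labels(label_map: np.ndarray) -> dict[tuple[int, int], int]:
    """Adjacent-label pairs and their contact length in 4-neighbour pixel pairs."""
    pairs: dict[tuple[int, int], int] = {}
    los, his = [], []
    for a, b in ((label_map[:, :-1], label_map[:, 1:]),
                 (label_map[:-1, :], label_map[1:, :])):
        sel = (a != b) & (a > 0) & (b > 0)
        los.append(np.minimum(a[sel], b[sel]))
        his.append(np.maximum(a[sel], b[sel]))
    lo = np.concatenate(los) if los else np.array([], int)
    hi = np.concatenate(his) if his else np.array([], int)
    if lo.size:
        keys, counts = np.unique(lo.astype(np.int64) << 32 | hi.astype(np.int64),
                                 return_counts=True)
        pairs = {(int(k >> 32), int(k & 0xFFFFFFFF)): int(c)
                 for k, c in zip(keys, counts)}
    return pairs


def _interface_pixels(label_map: np.ndarray, a: int, b: int) -> np.ndarray:
    """Boolean mask of pixels of cells a or b that touch the other cell."""
    mask = np.zeros(label_map.shape, bool)
    la, lb = label_map == a, label_map == b
    for axis in (0, 1):
        sa = np.roll(lb, 1, axis=axis) | np.roll(lb, -1, axis=axis)
        mask |= la & sa
        sb = np.roll(la, 1, axis=axis) | np.roll(la, -1, axis=axis)
        mask |= lb & sb
    return mask


def simulate_snapshot(config: SimConfig, population: PopulationParams | None = None,
                      rng: np.random.Generator | None = None) -> GroundTruthSnapshot:
    """Render a two-type co-culture snapshot with full ground truth.

    Cells are laid out as a seeded random tessellation (Poisson-disc nuclei,
    nearest-nucleus territories clipped at twice the nominal cell radius).
    Heterotypic interfaces accumulate according to
    ``population.accumulation_probability``; accumulating interfaces are
    rendered as a bright colocalized stripe in both channels. The image is
    blurred by the PSF and corrupted by Poisson-Gaussian noise.
    """
    pop = population or PopulationParams()
    rng = rng or np.random.default_rng(config.seed)
    h, w = config.image_shape
    px_um = config.pixel_size / 1000.0  # µm per pixel

    img = np.full((3, h, w), pop.background, dtype=float)
    if pop.n_cells == 0:
        blurred = np.stack([ndimage.gaussian_filter(c, config.psf_sigma_px) for c in img])
        noisy = np.stack([apply_noise(c, config.noise, rng) for c in blurred])
        empty_cells = pd.DataFrame(columns=["cell_id", "cell_type", "true_I_Fat",
                                            "true_I_Ds", "nucleus_row", "nucleus_col"])
        empty_ifaces = pd.DataFrame(columns=["cell_a", "cell_b", "heterotypic",
                                             "accumulating", "p_accum", "length_px",
                                             "flank_I_Fat", "flank_I_Ds"])
        return GroundTruthSnapshot(noisy, np.zeros((h, w), np.int32), empty_cells,
                                   empty_ifaces, np.zeros((h, w), bool), config, pop)

    # nominal nucleus spacing: pack n_cells into the tissue ellipse (66% of
    # the frame), but never below 4 px
    spacing_px = max(4.0, 0.82 * math.sqrt(0.66 * h * w / pop.n_cells))
    nuclei = _poisson_disc(rng, (h, w), pop.n_cells, spacing_px)
    n = len(nuclei)

    rows, cols = np.mgrid[0:h, 0:w]
    tree = cKDTree(nuclei)
    dist, idx = tree.query(np.column_stack([rows.ravel(), cols.ravel()]))
    label_map = (idx + 1).astype(np.int32).reshape(h, w)
    r_max = 1.15 * spacing_px
    label_map[dist.reshape(h, w) > r_max] = 0

    # drop cells that lost all pixels (possible for tightly packed duplicates)
    present = np.unique(label_map)
    present = present[present > 0]

    types = rng.choice(
        np.array(["Fat", "Ds", "dual"]),
        size=n,
        p=[pop.fat_fraction, pop.ds_fraction,
           max(0.0, 1.0 - pop.fat_fraction - pop.ds_fraction)],
    )
    i_fat = np.where(np.isin(types, ["Fat", "dual"]),
                     rng.lognormal(math.log(pop.fat_median), pop.fat_sigma_log, n), 0.0)
    i_ds = np.where(np.isin(types, ["Ds", "dual"]),
                    rng.lognormal(math.log(pop.ds_median), pop.ds_sigma_log, n), 0.0)

    cell_table = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "cell_type": types,
        "true_I_Fat": i_fat,
        "true_I_Ds": i_ds,
        "nucleus_row": nuclei[:, 0],
        "nucleus_col": nuclei[:, 1],
    })
    cell_table = cell_table[cell_table.cell_id.isin(present)].reset_index(drop=True)

    # cytoplasm rendering
    fat_img = np.zeros((h, w))
    ds_img = np.zeros((h, w))
    lut_fat = np.zeros(n + 1)
    lut_ds = np.zeros(n + 1)
    lut_fat[cell_table.cell_id] = cell_table.true_I_Fat
    lut_ds[cell_table.cell_id] = cell_table.true_I_Ds
    fat_img = lut_fat[label_map]
    ds_img = lut_ds[label_map]

    # nuclei (blue)
    blue = np.zeros((h, w))
    sig_nuc = pop.nucleus_sigma / px_um
    for r, c in nuclei:
        blue[int(round(r)), int(round(c))] = 1.0
    blue = ndimage.gaussian_filter(blue, sig_nuc)
    if blue.max() > 0:
        blue *= 500.0 / blue.max()

    # interfaces and the accumulation rule
    pairs = _interfaces_from_labels(label_map)
    id2row = {int(cid): i for i, cid in enumerate(cell_table.cell_id)}
    recs = []
    accum_mask = np.zeros((h, w), bool)
    for (a, b), length in sorted(pairs.items()):
        ra, rb = id2row.get(a), id2row.get(b)
        if ra is None or rb is None:
            continue
        ta, tb = cell_table.cell_type[ra], cell_table.cell_type[rb]
        het = {ta, tb} == {"Fat", "Ds"}
        fa = max(cell_table.true_I_Fat[ra], cell_table.true_I_Fat[rb])
        da = max(cell_table.true_I_Ds[ra], cell_table.true_I_Ds[rb])
        p = float(pop.accumulation_probability(fa, da))
        if length * px_um < pop.min_contact:
            p = 0.0  # contact too short to nucleate a stable accumulation zone
        acc = bool(rng.random() < p)
        recs.append((a, b, het, acc, p, length, fa, da))
        if acc:
            stripe = _interface_pixels(label_map, a, b)
            accum_mask |= stripe
            fat_img = np.where(stripe, fat_img + pop.stripe_gain * pop.fat_median, fat_img)
            ds_img = np.where(stripe, ds_img + pop.stripe_gain * pop.ds_median, ds_img)

    interface_table = pd.DataFrame(
        recs, columns=["cell_a", "cell_b", "heterotypic", "accumulating",
                       "p_accum", "length_px", "flank_I_Fat", "flank_I_Ds"])

    img[0] += fat_img
    img[1] += ds_img
    img[2] += blue
    blurred = np.stack([ndimage.gaussian_filter(c, config.psf_sigma_px) for c in img])
    noisy = np.stack([apply_noise(c, config.noise, rng) for c in blurred])
    return GroundTruthSnapshot(noisy, label_map, cell_table, interface_table,
                               accum_mask, config, pop)


# ---------------------------------------------------------------------------
# FRAP: 1D diffusion + membrane-cytoplasm exchange
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapTruth:
    """Ground truth for a bleach-recovery simulation.

    D   : µm²/s, lateral diffusion coefficient.
    k   : 1/s, membrane-cytoplasm exchange rate (relaxation toward U0).
    A   : bleach depth in [0, 1]; U0: pre-bleach plateau, a.u.
    geometry : 'half' bleaches x > x0; 'stripe' bleaches |x - x0| < stripe_halfwidth.
    dx  : µm grid step; dt: s integration step (None = auto, 40% of the
          explicit-scheme stability bound dx²/(2D)).
    """

    D: float = 0.1
    k: float = 0.0
    A: float = 0.8
    U0: float = 100.0
    geometry: Literal["half", "stripe"] = "half"
    domain_length: float = 40.0  # µm
    x0: float | None = None  # bleach edge/centre, default domain midpoint
    stripe_halfwidth: float = 2.0  # µm
    dx: float = 0.1
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.D < 0 or self.k < 0:
            raise InvalidParameterError("D and k must be >= 0")
        if not 0 <= self.A <= 1:
            raise InvalidParameterError("A must be in [0, 1]")
        if self.dx <= 0 or self.domain_length <= 0:
            raise InvalidParameterError("dx and domain_length must be > 0")
        if self.dt is not None and self.D > 0 and self.dt >= self.stability_bound:
            raise InvalidParameterError(
                f"dt={self.dt} violates the explicit-scheme stability bound "
                f"dt < dx²/(2D) = {self.stability_bound:.3g} s")

    @property
    def stability_bound(self) -> float:
        return math.inf if self.D == 0 else self.dx**2 / (2.0 * self.D)


def simulate_frap_movie(truth: FrapTruth, duration: float, frame_interval: float,
                        noise_sigma: float = 0.0,
                        rng: np.random.Generator | None = None):
    """Integrate dc/dt = D d²c/dx² − k (c − U0) by explicit finite differences.

    Reflecting (zero-flux) boundaries; the initial condition is the ideal
    post-bleach profile scaled by the bleach depth A. Returns
    (frames, times, x) with frames of shape (n_frames, nx) sampled every
    ``frame_interval`` seconds starting at t = 0 (first post-bleach frame).

    This integrator is numerically independent of the fitting code and
    serves as its oracle.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    dx = truth.dx
    nx = int(round(truth.domain_length / dx)) + 1
    x = np.arange(nx) * dx
    x0 = truth.domain_length / 2.0 if truth.x0 is None else truth.x0

    c = np.full(nx, truth.U0, dtype=float)
    if truth.geometry == "half":
        c[x > x0] = truth.U0 * (1.0 - truth.A)
    elif truth.geometry == "stripe":
        c[np.abs(x - x0) < truth.stripe_halfwidth] = truth.U0 * (1.0 - truth.A)
    else:
        raise InvalidParameterError(f"unknown geometry {truth.geometry!r}")

    dt = truth.dt if truth.dt is not None else (
        0.4 * truth.stability_bound if truth.D > 0 else frame_interval / 10.0)
    dt = min(dt, frame_interval)
    n_frames = int(math.floor(duration / frame_interval)) + 1
    frames = np.empty((n_frames, nx))
    times = np.arange(n_frames) * frame_interval

    alpha = truth.D * dt / dx**2
    lap = np.empty_like(c)
    t = 0.0
    next_frame = 0
    # record, then step until each subsequent frame time is reached
    for i in range(n_frames):
        target = times[i]
        while t < target - 1e-12:
            step = min(dt, target - t)
            a = truth.D * step / dx**2
            lap[1:-1] = c[2:] - 2.0 * c[1:-1] + c[:-2]
            lap[0] = c[1] - c[0]
            lap[-1] = c[-2] - c[-1]
            c = c + a * lap
            if truth.k > 0:
                # exchange is linear relaxation toward U0: integrate exactly
                c = truth.U0 + (c - truth.U0) * math.exp(-truth.k * step)
            t += step
        frames[i] = c
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
    return frames, times, x


def render_boundary_frap_movie(truth: FrapTruth, duration: float, frame_interval: float,
                               config: SimConfig, boundary_row: int | None = None,
                               drift_px_per_frame: float = 0.0,
                               drift_along_px_per_frame: float = 0.0,
                               noise_sigma: float = 1.0,
                               texture_amp: float = 0.15):
    """Embed the 1D recovery profile as a horizontal boundary in a 2D movie.

    The boundary runs along image columns at ``boundary_row`` (optionally
    drifting down by ``drift_px_per_frame`` each frame, and/or sliding
    along its own axis by ``drift_along_px_per_frame``) with a Gaussian
    cross-section of the PSF width. A static multiplicative intensity
    texture (relative amplitude ``texture_amp``) rides along with the
    boundary, as real membrane signal does — it is what makes
    cross-correlation registration well-posed. Returns (movie, times, x_um)
    where movie has shape (n_frames, H, W).
    """
    frames, times, x = simulate_frap_movie(truth, duration, frame_interval)
    h, w = config.image_shape
    px_um = config.pixel_size / 1000.0
    row0 = h // 2 if boundary_row is None else boundary_row
    rng = np.random.default_rng(config.seed)
    sig = max(config.psf_sigma_px, 0.75)
    rr = np.arange(h)[:, None]
    movie = np.empty((len(times), h, w))
    texture = ndimage.gaussian_filter1d(rng.normal(0.0, 1.0, 4 * w), 3.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    for i in range(len(times)):
        cols = np.arange(w) - drift_along_px_per_frame * i
        line = np.interp(cols * px_um, x, frames[i])
        tex = 1.0 + texture_amp * np.interp(cols + w, np.arange(4 * w), texture)
        rowc = row0 + drift_px_per_frame * i
        cross = np.exp(-((rr - rowc) ** 2) / (2.0 * sig**2))
        movie[i] = cross * line[None, :] * tex[None, :]
    if noise_sigma > 0:
        movie = movie + rng.normal(0.0, noise_sigma, movie.shape)
    return movie, times, np.arange(w) * px_um


def render_tirf_frap_movie(truth: FrapTruth, duration: float, frame_interval: float,
                           config: SimConfig, photobleach_rate: float = 0.0,
                           noise_sigma: float = 1.0, dark_rows: int = 4):
    """A TIRF-style movie: uniform basal membrane with a vertical bleach stripe.

    The recovery profile varies along columns and is constant along rows
    (the stripe axis); the top/bottom ``dark_rows`` rows lie outside the
    TIRF footprint and stay dark (a background region). Optional global
    photobleaching multiplies every frame by exp(−photobleach_rate · t).
    Returns (movie, times, x_um).
    """
    frames, times, x = simulate_frap_movie(truth, duration, frame_interval)
    h, w = config.image_shape
    px_um = config.pixel_size / 1000.0
    rng = np.random.default_rng(config.seed)
    movie = np.zeros((len(times), h, w))
    for i in range(len(times)):
        line = np.interp(np.arange(w) * px_um, x, frames[i])
        movie[i, dark_rows:h - dark_rows] = (
            line[None, :] * math.exp(-photobleach_rate * times[i]))
    if noise_sigma > 0:
        movie = movie + rng.normal(0.0, noise_sigma, movie.shape)
    return movie, times, np.arange(w) * px_um


# ---------------------------------------------------------------------------
# rainbow boundaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RainbowTruth:
    """Ground truth for a two-channel boundary with a sub-resolution gap.

    gap             : nm, centre-to-centre separation along the local normal
                      (green at −gap/2, red at +gap/2).
    polyline        : (N, 2) array of (row, col) vertices in pixel coordinates.
    amplitude       : peak a.u. per channel (green, red).
    chromatic_shift : nm, uniform extra translation of the red channel along
                      the normal (an optional confound).
    snr             : amplitude / additive-noise sigma.
    """

    gap: float = 116.0
    polyline: np.ndarray = field(default_factory=lambda: np.array([[32.0, 4.0], [32.0, 92.0]]))
    amplitude: tuple[float, float] = (200.0, 200.0)
    chromatic_shift: float = 0.0
    snr: float = 10.0

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise InvalidParameterError("gap must be >= 0")
        if np.asarray(self.polyline).shape[0] < 2:
            raise InvalidParameterError("polyline needs at least 2 vertices")


def _resample_polyline(poly: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Equal-arclength resampling; returns (points, unit normals).

    The normal is the tangent rotated by +90°: n = (−t_col, t_row) in
    (row, col) coordinates, a fixed orientation convention shared with the
    straightening code.
    """
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.arange(0.0, total + step / 2, step)
    pts = np.column_stack([np.interp(si, s, poly[:, 0]), np.interp(si, s, poly[:, 1])])
    tan = np.gradient(pts, axis=0)
    tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tan[:, 1], tan[:, 0]])
    return pts, normal


def _render_curve(shape, pts, sigma_px, amp):
    """Intensity field of a line source at `pts` convolved with the PSF."""
    h, w = shape
    tree = cKDTree(pts)
    rows, cols = np.mgrid[0:h, 0:w]
    coords = np.column_stack([rows.ravel(), cols.ravel()])
    d, _ = tree.query(coords, distance_upper_bound=6.0 * sigma_px + 2.0)
    d = np.where(np.isfinite(d), d, np.inf)
    return (amp * np.exp(-0.5 * (d / sigma_px) ** 2)).reshape(h, w)


def simulate_rainbow(truth: RainbowTruth, config: SimConfig,
                     rng: np.random.Generator | None = None):
    """Render two line sources offset by the gap along the boundary normal.

    Returns (image, truth) with image of shape (2, H, W): channel 0 green,
    channel 1 red. Both are convolved with the Gaussian PSF; additive
    Gaussian noise of sigma = amplitude / snr is applied per channel.
    """
    rng = rng or np.random.default_rng(config.seed)
    pts, normal = _resample_polyline(truth.polyline, step=0.25)
    half = 0.5 * truth.gap / config.pixel_size  # px
    shift = truth.chromatic_shift / config.pixel_size
    sigma_px = max(config.psf_sigma_px, 1e-3)
    green = _render_curve(config.image_shape, pts - half * normal, sigma_px,
                          truth.amplitude[0])
    red = _render_curve(config.image_shape, pts + (half + shift) * normal, sigma_px,
                        truth.amplitude[1])
    img = np.stack([green, red])
    if truth.snr and truth.snr > 0:
        img = img + rng.normal(
            0.0, np.array(truth.amplitude)[:, None, None] / truth.snr, img.shape)
    return img, truth


# ---------------------------------------------------------------------------
# single-pair induction time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairInduction:
    """Induction model for a single Fat/Ds cell pair.

    Transcript levels rise linearly after doxycycline addition; observable
    (matured) Ds1-mCherry appears only after ``maturation_delay`` minutes
    and then grows quadratically (the integral of the linear transcript).
    Boundary accumulation follows a Hill threshold on the total Ds level,
    so the boundary fraction rises with expression; boundary Fat is a fixed
    stoichiometric ratio of boundary Ds.
    """

    mrna_slope: float = 1.0  # a.u./min of transcript
    maturation_delay: float = 100.0  # min
    baseline: float = 20.0  # a.u., pre-induction observable Ds
    protein_gain: float = 1.0  # a.u./min² quadratic observable rise
    total_fat: float = 5.0e4  # a.u., constant
    K_boundary: float = 5.0e3  # a.u., accumulation threshold on total Ds
    hill_n: float = 2.0
    r_max: float = 0.8  # plateau boundary/total Ds fraction
    stoichiometry: float = 0.5  # boundary_Fat / boundary_Ds
    noise_frac: float = 0.02  # multiplicative noise sd
    noise_floor: float = 2.0  # a.u. additive noise sd

    def __post_init__(self) -> None:
        if self.maturation_delay < 0:
            raise InvalidParameterError("maturation_delay must be >= 0")
        if self.mrna_slope < 0:
            raise InvalidParameterError("mrna_slope must be >= 0")


@dataclass
class PairTimeseriesTruth:
    """Trace table plus the generator's noiseless curves and true onset time."""

    table: pd.DataFrame  # time_min, total_Fat, total_Ds, boundary_Fat, boundary_Ds
    onset_time: float | None  # min; None when accumulation never rises
    clean: pd.DataFrame  # noiseless traces, same columns
    induction: PairInduction


def simulate_pair_timeseries(induction: PairInduction, duration: float,
                             frame_interval: float = 5.0,
                             rng: np.random.Generator | None = None,
                             seed: int = 0) -> PairTimeseriesTruth:
    """Simulate {total, boundary} × {Fat, Ds} traces for one cell pair.

    The true onset is the first time the noiseless boundary Ds trace exceeds
    five noise standard deviations above zero.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = rng or np.random.default_rng(seed)
    t = np.arange(0.0, duration + frame_interval / 2, frame_interval)
    rise = np.maximum(0.0, t - induction.maturation_delay)
    total_ds = induction.baseline + induction.protein_gain * induction.mrna_slope * rise**2
    ratio = induction.r_max * hill(total_ds, induction.K_boundary, induction.hill_n)
    boundary_ds = ratio * total_ds
    boundary_fat = induction.stoichiometry * boundary_ds
    total_fat = np.full_like(t, induction.total_fat)

    clean = pd.DataFrame({"time_min": t, "total_Fat": total_fat, "total_Ds": total_ds,
                          "boundary_Fat": boundary_fat, "boundary_Ds": boundary_ds})

    noise_sd = induction.noise_floor + induction.noise_frac * np.abs(
        clean[["total_Fat", "total_Ds", "boundary_Fat", "boundary_Ds"]].to_numpy())
    noisy = clean.copy()
    noisy[["total_Fat", "total_Ds", "boundary_Fat", "boundary_Ds"]] += rng.normal(
        0.0, noise_sd)

    thresh = 5.0 * (induction.noise_floor + induction.noise_frac * 0.0)
    above = boundary_ds > thresh
    onset = float(t[np.argmax(above)]) if above.any() else None
    return PairTimeseriesTruth(noisy, onset, clean, induction)


def render_pair_movie(truth: PairTimeseriesTruth, config: SimConfig,
                      noise_sigma: float = 1.0):
    """Render a pair time series as a two-cell movie.

    Two rectangular cells meet at the vertical midline; the accumulating
    boundary is a 3-px stripe at the contact. Per-frame region intensities
    are scaled so that summed fluorescence in each region matches the trace
    values. Returns (movie, masks) where movie has shape
    (n_frames, 2, H, W) and masks is a dict of boolean regions
    {'fat', 'ds', 'boundary'}.
    """
    h, w = config.image_shape
    mid = w // 2
    fat_mask = np.zeros((h, w), bool)
    ds_mask = np.zeros((h, w), bool)
    bd_mask = np.zeros((h, w), bool)
    m = max(2, h // 8)
    fat_mask[m:-m, m:mid - 1] = True
    ds_mask[m:-m, mid + 2:w - m] = True
    bd_mask[m:-m, mid - 1:mid + 2] = True

    tab = truth.clean
    n_frames = len(tab)
    rng = np.random.default_rng(config.seed)
    movie = np.zeros((n_frames, 2, h, w))
    for i in range(n_frames):
        g = np.zeros((h, w))
        r = np.zeros((h, w))
        g[fat_mask] = (tab.total_Fat[i] - tab.boundary_Fat[i]) / fat_mask.sum()
        r[ds_mask] = (tab.total_Ds[i] - tab.boundary_Ds[i]) / ds_mask.sum()
        g[bd_mask] += tab.boundary_Fat[i] / bd_mask.sum()
        r[bd_mask] += tab.boundary_Ds[i] / bd_mask.sum()
        movie[i, 0] = g
        movie[i, 1] = r
    if noise_sigma > 0:
        movie = movie + rng.normal(0.0, noise_sigma, movie.shape)
    return movie, {"fat": fat_mask, "ds": ds_mask, "boundary": bd_mask}
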