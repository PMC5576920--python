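"""Sub-resolution two-channel gap measurement and polarity classification.

An accumulating boundary imaged in two colors shows a 'rainbow': the red
(Ds1-mCherry) and green (Fat4-citrine) intensity ridges are offset by a
sub-resolution distance along the boundary normal, set by the extended
Fat4-Ds1 ectodomains. The boundary is straightened onto an
(arclength × normal) grid, each normal profile is fitted per channel with
a Gaussian, and the gap is the signed distance between the two fitted
centers. The gap sign defines the polarity direction, which is compared
with the cytoplasmic expression gradients of the two flanking cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import OptimizeWarning, curve_fit
from skimage.feature import peak_local_max

from .config import InvalidParameterError, PipelineConfig
from .synthetic import _resample_polyline

log = logging.getLogger(__name__)

__all__ = ["StraightenedBoundary", "GapProfile", "PolarityRecord",
           "GradientRecord", "straighten_boundary", "measure_gap",
           "register_channels", "expected_extended_length",
           "measure_gradients", "classify_alignment"]

CADHERIN_REPEAT_NM = 4.5  # length of one cadherin ectodomain repeat


@dataclass
class StraightenedBoundary:
    """Boundary-normal resampled image.

    data: (C, n_positions, n_offsets); offsets run from −halfwidth to
    +halfwidth in steps of ``step`` pixels along the normal
    n = (−t_col, t_row) (tangent rotated +90°, the A→B convention).
    """

    data: np.ndarray
    step: float  # px per sample along both axes
    offsets: np.ndarray  # px, signed normal offsets
    trimmed_positions: int = 0


@dataclass
class GapProfile:
    """Per-position peak separations along one boundary.

    Signed gaps (red center − green center along the normal) in nm; the
    mean/sd cover quality-passing positions only. unsigned_* summarize
    |gap|, the statistic shown in gap-distribution histograms.
    """

    centers_green: np.ndarray  # nm, signed along normal
    centers_red: np.ndarray
    gaps: np.ndarray  # nm, signed; NaN where a fit failed quality gates
    mean_gap: float
    sd_gap: float
    unsigned_mean: float
    unsigned_sd: float
    n_positions: int
    n_valid: int


@dataclass(frozen=True)
class PolarityRecord:
    boundary_id: int
    p: int  # green→red direction along the A→B normal; 0 = non-polarized
    g_fat: int  # low→high Fat gradient sign across A→B
    g_ds: int
    category: str  # both | Fat | Ds | NP


@dataclass
class GradientRecord:
    boundary_id: int
    cyto_fat: tuple[float, float]  # (cell A, cell B) cytoplasmic Fat totals
    cyto_ds: tuple[float, float]
    g_fat: int
    g_ds: int
    box_area_fraction: tuple[float, float]  # usable box area after exclusions
    reliable: bool


def straighten_boundary(image: np.ndarray, polyline: np.ndarray,
                        normal_halfwidth: float = 12.0,
                        step: float = 1.0) -> StraightenedBoundary:
    """Resample a (C, H, W) image onto an (arclength × normal) grid.

    Bilinear interpolation at equal arclength steps along the polyline and
    equal steps along the local normal. Positions whose normal line leaves
    the image are trimmed (and counted); the normal orientation is the
    tangent rotated by +90°, making signed offsets well defined.
    """
    image = np.asarray(image, float)
    if image.ndim == 2:
        image = image[None]
    poly = np.asarray(polyline, float)
    if poly.shape[0] < 2:
        raise InvalidParameterError("polyline needs at least 2 vertices")
    pts, normals = _resample_polyline(poly, step=step)
    offs = np.arange(-normal_halfwidth, normal_halfwidth + step / 2, step)
    rows = pts[:, 0][:, None] + offs[None, :] * normals[:, 0][:, None]
    cols = pts[:, 1][:, None] + offs[None, :] * normals[:, 1][:, None]
    h, w = image.shape[-2:]
    inside = ((rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)).all(axis=1)
    trimmed = int((~inside).sum())
    if trimmed:
        log.info("trimmed %d boundary positions whose normals leave the image",
                 trimmed)
    rows, cols = rows[inside], cols[inside]
    data = np.stack([ndimage.map_coordinates(c, [rows, cols], order=1)
                     for c in image])
    return StraightenedBoundary(data, step=step, offsets=offs,
                                trimmed_positions=trimmed)


def _gaussian(x, amp, center, width, offset):
    return amp * np.exp(-0.5 * ((x - center) / width) ** 2) + offset


def _fit_peak(offsets: np.ndarray, profile: np.ndarray, psf_sigma_px: float):
    """Gaussian peak fit with quality gates; returns (center, ok)."""
    amp0 = profile.max() - profile.min()
    p0 = (amp0, float(offsets[np.argmax(profile)]), max(psf_sigma_px, 1.0),
          float(profile.min()))
    try:
        with warnings.catch_warnings():
            # noise-only profiles give singular covariances; the quality
            # gates below reject them anyway
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_gaussian, offsets, profile, p0=p0,
                                maxfev=5000)
    except RuntimeError:
        return np.nan, False
    amp, center, width, offset = popt
    resid = profile - _gaussian(offsets, *popt)
    noise = np.std(resid)
    ok = (amp > 3.0 * max(noise, 1e-12)
          and offsets.min() < center < offsets.max()
          and 0.5 * psf_sigma_px < abs(width) < 5.0 * psf_sigma_px)
    return float(center), bool(ok)


def measure_gap(straightened: StraightenedBoundary, pixel_size: float,
                psf_sigma: float = 110.0) -> GapProfile:
    """Per-position Gaussian peak fits and the red−green center separation.

    pixel_size and psf_sigma in nm. Positions failing the fit quality
    gates (amplitude above noise, center inside the window, width within
    0.5–5 PSF sigmas) are excluded from the statistics.
    """
    if straightened.data.shape[0] < 2:
        raise InvalidParameterError("need two channels to measure a gap")
    n_pos = straightened.data.shape[1]
    if n_pos < 1:
        raise InvalidParameterError("no usable positions")
    psf_px = psf_sigma / pixel_size
    offs = straightened.offsets
    cg = np.full(n_pos, np.nan)
    cr = np.full(n_pos, np.nan)
    for i in range(n_pos):
        c1, ok1 = _fit_peak(offs, straightened.data[0, i], psf_px)
        c2, ok2 = _fit_peak(offs, straightened.data[1, i], psf_px)
        if ok1:
            cg[i] = c1 * pixel_size * 1.0
        if ok2:
            cr[i] = c2 * pixel_size * 1.0
    gaps = cr - cg  # nm; NaN wherever either fit failed
    valid = np.isfinite(gaps)
    if valid.any():
        mean = float(np.mean(gaps[valid]))
        sd = float(np.std(gaps[valid]))
        umean = float(np.mean(np.abs(gaps[valid])))
        usd = float(np.std(np.abs(gaps[valid])))
    else:
        log.warning("all positions failed the gap quality gates")
        mean = sd = umean = usd = float("nan")
    return GapProfile(cg, cr, gaps, mean, sd, umean, usd,
                      n_positions=n_pos, n_valid=int(valid.sum()))


def register_channels(green: np.ndarray, red: np.ndarray,
                      pixel_size: float | None = None,
                      min_distance: int = 5, match_radius: float = 3.0):
    """Bead-based translational registration between the two channels.

    Beads are detected as local maxima in both channels, matched by
    proximity and refined by intensity centroid; the offset is the mean
    red−green displacement (row, col) in px (and nm when pixel_size is
    given). Returns (offset_px, offset_nm, apply) where apply(red_image)
    shifts the red channel by the negated offset.
    """
    def _centroids(img):
        peaks = peak_local_max(img, min_distance=min_distance,
                               threshold_rel=0.2)
        cents = []
        h, w = img.shape
        for r, c in peaks:
            r0, r1 = max(r - 3, 0), min(r + 4, h)
            c0, c1 = max(c - 3, 0), min(c + 4, w)
            win = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
            tot = win.sum()
            if tot <= 0:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cents.append(((rr * win).sum() / tot, (cc * win).sum() / tot))
        return np.array(cents).reshape(-1, 2)

    cg = _centroids(np.asarray(green, float))
    cr = _centroids(np.asarray(red, float))
    if len(cg) < 3 or len(cr) < 3:
        raise InvalidParameterError("fewer than 3 beads detected in a channel")
    from scipy.spatial import cKDTree
    tree = cKDTree(cr)
    d, j = tree.query(cg, distance_upper_bound=match_radius)
    ok = np.isfinite(d)
    if ok.sum() < 3:
        raise InvalidParameterError("fewer than 3 matched beads")
    offset = (cr[j[ok]] - cg[ok]).mean(axis=0)

    def apply(red_image: np.ndarray) -> np.ndarray:
        return ndimage.shift(np.asarray(red_image, float), -offset, order=1,
                             mode="nearest")

    offset_nm = offset * pixel_size if pixel_size else None
    return offset, offset_nm, apply


def expected_extended_length(n_repeats: int,
                             repeat_length: float = CADHERIN_REPEAT_NM) -> float:
    """Extended ectodomain length in nm: n_repeats × repeat_length.

    With 34 cadherin repeats at 4.5 nm each this gives 153 nm, the expected
    span of a fully extended Fat4 ectodomain.
    """
    if n_repeats < 0:
        raise InvalidParameterError("n_repeats must be >= 0")
    return float(n_repeats) * float(repeat_length)


def _box_slices(center, half, shape):
    r0 = int(max(0, round(center[0] - half)))
    r1 = int(min(shape[0], round(center[0] + half)))
    c0 = int(max(0, round(center[1] - half)))
    c1 = int(min(shape[1], round(center[1] + half)))
    return slice(r0, r1), slice(c0, c1)


def measure_gradients(image: np.ndarray, polyline: np.ndarray,
                      cell_masks: tuple[np.ndarray, np.ndarray],
                      nuclei_mask: np.ndarray | None = None,
                      boundary_id: int = 0,
                      config: PipelineConfig | None = None,
                      pixel_size: float | None = None,
                      rel_floor: float = 0.05) -> GradientRecord:
    """Cytoplasmic Fat/Ds levels in boxes flanking the boundary.

    ``image``: (C, H, W) or (C, Z, H, W); z-stacks are reduced by a 5-slice
    summed projection around the central plane. Per flanking cell a square
    box (config.gradient_box µm) is placed at config.gradient_standoff µm
    from the boundary midpoint along the normal, restricted to the cell
    mask, with nucleus pixels and pixels above the per-cell vesicle
    percentile excluded. Gradient signs point from low to high across A→B
    and are 0 when the relative difference is below ``rel_floor``.
    """
    cfg = config or PipelineConfig()
    px_nm = pixel_size or cfg.pixel_size
    px_um = px_nm / 1000.0
    img = np.asarray(image, float)
    if img.ndim == 4:  # (C, Z, H, W): summed projection of 5 central slices
        z = img.shape[1]
        lo = max(0, z // 2 - 2)
        img = img[:, lo:lo + 5].sum(axis=1)
    pts, normals = _resample_polyline(np.asarray(polyline, float), step=1.0)
    mid = pts[len(pts) // 2]
    nvec = normals[len(normals) // 2]

    half_px = 0.5 * cfg.gradient_box / px_um
    standoff_px = (cfg.gradient_standoff + 0.5 * cfg.gradient_box) / px_um
    vals_fat, vals_ds, fracs = [], [], []
    for sign, mask in zip((-1.0, 1.0), cell_masks):
        center = mid + sign * standoff_px * nvec
        rs, cs = _box_slices(center, half_px, img.shape[-2:])
        sel = np.zeros(img.shape[-2:], bool)
        sel[rs, cs] = True
        sel &= mask.astype(bool)
        if nuclei_mask is not None:
            sel &= ~nuclei_mask.astype(bool)
        nominal = max((rs.stop - rs.start) * (cs.stop - cs.start), 1)
        cell_cyto = mask.astype(bool)
        if nuclei_mask is not None:
            cell_cyto = cell_cyto & ~nuclei_mask.astype(bool)
        for ch, sink in ((0, vals_fat), (1, vals_ds)):
            thr = np.percentile(img[ch][cell_cyto], cfg.vesicle_percentile) \
                if cell_cyto.any() else np.inf
            use = sel & (img[ch] <= thr)
            # area-normalized total: exclusions (nucleus, vesicles) must not
            # deflate the estimate, so scale the mean by the nominal box area
            sink.append(float(img[ch][use].mean()) * nominal if use.any()
                        else 0.0)
        fracs.append(sel.sum() / nominal)

    def _sign(a, b):
        denom = max(abs(a) + abs(b), 1e-12)
        if abs(b - a) / denom < rel_floor:
            return 0
        return 1 if b > a else -1

    g_fat = _sign(vals_fat[0], vals_fat[1])
    g_ds = _sign(vals_ds[0], vals_ds[1])
    reliable = all(f >= 0.25 for f in fracs)
    if not reliable:
        log.warning("gradient boxes for boundary %d lost >75%% of their area "
                    "to exclusions", boundary_id)
    return GradientRecord(boundary_id, (vals_fat[0], vals_fat[1]),
                          (vals_ds[0], vals_ds[1]), g_fat, g_ds,
                          (fracs[0], fracs[1]), reliable)


def classify_alignment(p: int, g_fat: int, g_ds: int) -> str:
    """Alignment of the polarity direction with the expression gradients.

    With the A→B normal convention the red (Ds) peak sits on the side the
    polarity sign points to, so polarity aligns with the Ds gradient iff
    p == g_ds, and with the Fat gradient iff p == −g_fat (the green peak
    on the high-Fat side). Returns 'both', 'Fat', 'Ds' or 'NP'.
    """
    for v in (p, g_fat, g_ds):
        if v not in (-1, 0, 1):
            raise InvalidParameterError("signs must be in {-1, 0, +1}")
    if p == 0:
        return "NP"
    ds_aligned = g_ds != 0 and p == g_ds
    fat_aligned = g_fat != 0 and p == -g_fat
    if ds_aligned and fat_aligned:
        return "both"
    if fat_aligned:
        return "Fat"
    if ds_aligned:
        return "Ds"
    return "NP"


def polarity_from_gap(boundary_id: int, gap: GapProfile, g_fat: int, g_ds: int,
                      config: PipelineConfig | None = None) -> PolarityRecord:
    """Polarity sign from a measured gap profile plus its alignment category.

    p = sign(mean signed gap); declared non-polarized when |mean gap| is
    below the config threshold (default 30 nm) or too few positions passed
    the quality gates.
    """
    cfg = config or PipelineConfig()
    if (gap.n_valid < cfg.min_gap_positions
            or not np.isfinite(gap.mean_gap)
            or abs(gap.mean_gap) < cfg.np_gap_threshold):
        p = 0
    else:
        p = 1 if gap.mean_gap > 0 else -1
    return PolarityRecord(boundary_id, p, g_fat, g_ds,
                          classify_alignment(p, g_fat, g_ds))
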