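"""FRAP analysis: erf bleach-profile fitting and diffusion/exchange estimation.

The bleach edge along a boundary is modelled per frame as

    f(x) = U0 · (1 − A · (1 + erf((x − x0)/L)) / 2)

for a half-boundary bleach, or as a difference of two erf edges sharing A
and L for a bleached stripe. Lateral diffusion widens the edge according
to L² = L0² + 4Dt, so a linear regression of L² on time yields D; the
membrane-cytoplasm exchange rate k is the time scale of the exponential
decay of the bleach depth A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import erf
from scipy.stats import ttest_ind

from .config import InvalidParameterError

log = logging.getLogger(__name__)

__all__ = ["Kymograph", "ErfFit", "StripeErfFit", "RecoveryFit",
           "extract_kymograph", "fit_erf_profile", "fit_stripe_profile",
           "fit_recovery", "tirf_frap_correct", "compare_groups",
           "erf_profile", "stripe_profile"]


def erf_profile(x, U0, A, x0, L):
    """Half-boundary bleach profile f(x) = U0·(1 − A·(1+erf((x−x0)/L))/2)."""
    return U0 * (1.0 - A * (1.0 + erf((x - x0) / L)) / 2.0)


def stripe_profile(x, U0, A, xl, xr, L):
    """Stripe bleach: two erf edges sharing depth A and width L."""
    return U0 * (1.0 - A * (erf((x - xl) / L) - erf((x - xr) / L)) / 2.0)


@dataclass
class Kymograph:
    """Registered intensity along a boundary over time.

    intensity: (n_frames, n_positions) a.u.; dx in µm per position step;
    dt in s per frame; shifts: per-frame registration shift applied, px.
    """

    intensity: np.ndarray
    dx: float
    dt: float
    shifts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flagged_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise InvalidParameterError("dx and dt must be > 0")


@dataclass(frozen=True)
class ErfFit:
    U0: float
    A: float
    x0: float  # µm
    L: float  # µm
    residual_rms: float
    L_var: float = np.nan  # variance of L from the fit covariance
    flat: bool = False  # no detectable edge; A pinned near 0


@dataclass(frozen=True)
class StripeErfFit:
    U0: float
    A: float
    xl: float
    xr: float
    L: float
    residual_rms: float
    L_var: float = np.nan
    flat: bool = False


@dataclass
class RecoveryFit:
    """Diffusion/exchange estimates from a kymograph.

    D in µm²/s (slope of L² vs t over 4), L0 in µm, k in 1/s from
    A(t) = A0·exp(−kt). frames lists the per-frame erf fits actually used.
    """

    D: float
    L0: float
    k: float
    A0: float
    frames: list
    times: np.ndarray
    n_excluded: int
    r2_L2: float


# ---------------------------------------------------------------------------
# kymograph extraction
# ---------------------------------------------------------------------------

def _sample_strip(frame: np.ndarray, pts: np.ndarray, normals: np.ndarray,
                  strip_width: int) -> np.ndarray:
    """Max over a normal strip at every arclength position (1 px offsets)."""
    hw = strip_width // 2
    offs = np.arange(-hw, hw + 1)
    rows = pts[:, 0][None, :] + offs[:, None] * normals[:, 0][None, :]
    cols = pts[:, 1][None, :] + offs[:, None] * normals[:, 1][None, :]
    vals = ndimage.map_coordinates(frame, [rows, cols], order=1, mode="nearest")
    return vals.max(axis=0)


def _register_1d(profile: np.ndarray, reference: np.ndarray,
                 highpass_sigma: float = 10.0):
    """Integer-then-parabolic sub-pixel shift maximizing cross-correlation.

    Both profiles are high-pass filtered first: the broad bleach edge
    widens between frames and would otherwise swamp the correlation peak,
    while the fine intensity texture along the boundary is what actually
    encodes the drift.
    """
    p = np.asarray(profile, float)
    r = np.asarray(reference, float)
    if highpass_sigma > 0:
        p = p - ndimage.gaussian_filter1d(p, highpass_sigma)
        r = r - ndimage.gaussian_filter1d(r, highpass_sigma)
    p = p - p.mean()
    r = r - r.mean()
    # 4x upsampling sharpens the correlation peak; parabolic refinement on
    # the upsampled grid gives the sub-pixel estimate
    up = 4
    n = len(p)
    xi = np.arange(0, n - 1 + 1.0 / up, 1.0 / up)
    pu = np.interp(xi, np.arange(n), p)
    ru = np.interp(xi, np.arange(n), r)
    cc = np.correlate(pu, ru, mode="full")
    i = int(np.argmax(cc))
    shift = (i - (len(ru) - 1)) / up
    if 0 < i < len(cc) - 1:
        denom = cc[i - 1] - 2 * cc[i] + cc[i + 1]
        if abs(denom) > 1e-12:
            shift += 0.5 * (cc[i - 1] - cc[i + 1]) / denom / up
    peak = cc[i] / max(np.sqrt((pu**2).sum() * (ru**2).sum()), 1e-12)
    return float(shift), float(peak)


def extract_kymograph(movie: np.ndarray, polyline: np.ndarray, dt: float,
                      pixel_size: float, strip_width: int = 9,
                      register: bool = True,
                      corr_floor: float = 0.2) -> Kymograph:
    """Sample the boundary signal per frame and register frames to the first.

    Per frame the intensity is sampled at 1-px arclength steps as the
    maximum over a ``strip_width``-wide strip normal to the polyline
    (default nine pixels). Frames are aligned to the first by integer-then-
    sub-pixel cross-correlation; frames whose correlation peak falls below
    ``corr_floor`` are flagged. pixel_size in nm; dt in s.
    """
    from .synthetic import _resample_polyline

    if strip_width % 2 == 0 or strip_width < 1:
        raise InvalidParameterError("strip_width must be odd")
    movie = np.asarray(movie, dtype=float)
    h, w = movie.shape[-2:]
    poly = np.asarray(polyline, float)
    if (poly < 0).any() or (poly[:, 0] > h - 1).any() or (poly[:, 1] > w - 1).any():
        raise InvalidParameterError("polyline leaves the frame bounds")
    pts, normals = _resample_polyline(poly, step=1.0)
    rows = np.stack([_sample_strip(f, pts, normals, strip_width) for f in movie])

    shifts = np.zeros(len(rows))
    flagged = []
    if register:
        # register consecutive frames (profiles evolve slowly, so adjacent
        # frames share their texture) and accumulate the pairwise shifts
        out = [rows[0]]
        cum = 0.0
        for i, row in enumerate(rows[1:], start=1):
            sh, peak = _register_1d(row, rows[i - 1])
            cum += sh
            shifts[i] = cum
            if peak < corr_floor:
                flagged.append(i)
            out.append(np.interp(np.arange(len(row)) + cum,
                                 np.arange(len(row)), row))
        rows = np.stack(out)
    return Kymograph(rows, dx=pixel_size / 1000.0, dt=dt,
                     shifts=shifts, flagged_frames=flagged)


# ---------------------------------------------------------------------------
# erf fitting
# ---------------------------------------------------------------------------

def _flat_fit(x, y):
    return ErfFit(U0=float(np.mean(y)), A=0.0, x0=float(np.mean(x)),
                  L=float(2 * (x[1] - x[0])), residual_rms=float(np.std(y)),
                  flat=True)


def fit_erf_profile(x: np.ndarray, y: np.ndarray) -> ErfFit:
    """Nonlinear least-squares fit of the half-boundary erf model.

    Initialization: U0 from the unbleached quartile mean, A from the
    min/max contrast, x0 at the steepest-gradient sample, L twice the
    sample spacing. A profile with no detectable edge returns A ≈ 0,
    flagged flat.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 8:
        raise InvalidParameterError("need at least 8 samples spanning the edge")
    dx = float(np.median(np.diff(x)))
    y_sorted = np.sort(y)
    q = max(len(y) // 4, 1)
    u0_init = float(y_sorted[-q:].mean())
    contrast = (y_sorted[-q:].mean() - y_sorted[:q].mean()) / max(u0_init, 1e-12)
    if contrast < 0.02:
        return _flat_fit(x, y)
    grad = np.gradient(ndimage.gaussian_filter1d(y, 1.0), x)
    x0_init = float(x[np.argmin(grad)])
    p0 = (u0_init, min(max(contrast, 1e-3), 1.0), x0_init, 2.0 * dx)
    try:
        popt, pcov = curve_fit(
            erf_profile, x, y, p0=p0,
            bounds=([0.0, 0.0, x.min() - 10 * dx, 0.25 * dx],
                    [np.inf, 1.0, x.max() + 10 * dx, (x.max() - x.min()) * 4]),
            maxfev=20000)
    except RuntimeError as exc:
        raise InvalidParameterError(f"erf fit failed to converge: {exc}") from exc
    resid = y - erf_profile(x, *popt)
    return ErfFit(U0=float(popt[0]), A=float(popt[1]), x0=float(popt[2]),
                  L=float(popt[3]), residual_rms=float(np.sqrt(np.mean(resid**2))),
                  L_var=float(pcov[3, 3]))


def fit_stripe_profile(x: np.ndarray, y: np.ndarray,
                       p0: tuple | None = None) -> StripeErfFit:
    """Two-edge stripe fit with shared bleach depth and width.

    ``p0`` warm-starts the optimizer (e.g. from the previous frame's fit):
    the depth and width of a widening stripe are anti-correlated under
    noise, and a warm start keeps the fit on the physical branch.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 8:
        raise InvalidParameterError("need at least 8 samples spanning the stripe")
    dx = float(np.median(np.diff(x)))
    y_sorted = np.sort(y)
    q = max(len(y) // 4, 1)
    u0_init = float(y_sorted[-q:].mean())
    contrast = (y_sorted[-q:].mean() - y_sorted[:q].mean()) / max(u0_init, 1e-12)
    if contrast < 0.02:
        f = _flat_fit(x, y)
        return StripeErfFit(f.U0, 0.0, float(x.mean()), float(x.mean()), f.L,
                            f.residual_rms, flat=True)
    if p0 is None:
        sm = ndimage.gaussian_filter1d(y, 1.0)
        xc = float(x[np.argmin(sm)])
        below = x[sm < u0_init * (1.0 - 0.5 * contrast)]
        half_w = max(0.5 * (below.max() - below.min()), dx) if len(below) else 2 * dx
        p0 = (u0_init, min(max(contrast, 1e-3), 1.0), xc - half_w, xc + half_w,
              2.0 * dx)
    try:
        popt, pcov = curve_fit(
            stripe_profile, x, y, p0=p0,
            bounds=([0.0, 0.0, x.min() - 10 * dx, x.min() - 10 * dx, 0.25 * dx],
                    [np.inf, 1.0, x.max() + 10 * dx, x.max() + 10 * dx,
                     (x.max() - x.min()) * 4]),
            maxfev=20000)
    except RuntimeError as exc:
        raise InvalidParameterError(f"stripe fit failed to converge: {exc}") from exc
    resid = y - stripe_profile(x, *popt)
    return StripeErfFit(U0=float(popt[0]), A=float(popt[1]), xl=float(popt[2]),
                        xr=float(popt[3]), L=float(popt[4]),
                        residual_rms=float(np.sqrt(np.mean(resid**2))),
                        L_var=float(pcov[4, 4]))


# ---------------------------------------------------------------------------
# recovery fitting: L² = L0² + 4Dt and A(t) = A0·exp(−kt)
# ---------------------------------------------------------------------------

def _weighted_linfit(t, y, w):
    W = np.asarray(w, float)
    if not np.all(np.isfinite(W)) or np.all(W <= 0):
        W = np.ones_like(t)
    Wn = W / W.sum()
    tm = (Wn * t).sum()
    ym = (Wn * y).sum()
    cov = (Wn * (t - tm) * (y - ym)).sum()
    var = (Wn * (t - tm) ** 2).sum()
    slope = cov / max(var, 1e-300)
    intercept = ym - slope * tm
    yhat = slope * t + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / max(ss_tot, 1e-300)
    return slope, intercept, r2


def fit_recovery(kymo: Kymograph, geometry: str = "half",
                 residual_gate: float = 0.2,
                 fit_A_offset: bool = False) -> RecoveryFit:
    """Per-frame erf fits, then D from L² vs t and k from the decay of A.

    Frames whose fit residual RMS exceeds ``residual_gate``·U0, or whose
    profile is flat, are excluded and counted. The L² regression is
    weighted by the per-frame variance of L when available. Time origin is
    the first post-bleach frame. Stripe kymographs additionally exclude
    frames whose fitted width exceeds 1.5× the stripe width from the L²
    regression (edges merged; width no longer identified).
    """
    n_frames = kymo.intensity.shape[0]
    if n_frames < 5:
        raise InvalidParameterError("need at least 5 post-bleach frames")
    x = np.arange(kymo.intensity.shape[1]) * kymo.dx
    fits = []
    times = []
    excluded = 0
    warm = None
    for i in range(n_frames):
        y = kymo.intensity[i]
        try:
            if geometry == "half":
                f = fit_erf_profile(x, y)
            else:
                f = fit_stripe_profile(x, y, p0=warm)
                if not f.flat:
                    warm = (f.U0, f.A, f.xl, f.xr, f.L)
        except InvalidParameterError:
            excluded += 1
            continue
        if f.flat or f.residual_rms > residual_gate * max(f.U0, 1e-12):
            excluded += 1
            continue
        fits.append(f)
        times.append(i * kymo.dt)
    if len(fits) < 3:
        # a genuinely static kymograph has no edge dynamics at all
        if all(getattr(f, "flat", False) for f in fits) or not fits:
            return RecoveryFit(D=0.0, L0=0.0, k=0.0, A0=0.0, frames=fits,
                               times=np.asarray(times), n_excluded=excluded,
                               r2_L2=np.nan)
        raise InvalidParameterError("fewer than 3 usable frames")

    t = np.asarray(times) - times[0]
    L = np.array([f.L for f in fits])
    A = np.array([f.A for f in fits])
    Lvar = np.array([f.L_var for f in fits])

    # L² regression gates: the edge width must be resolved on the grid and
    # its depth must clear the noise, otherwise L carries no information
    U0s = np.array([f.U0 for f in fits])
    resid = np.array([f.residual_rms for f in fits])
    use = (L >= 0.5 * kymo.dx) & (A >= 4.0 * resid / np.maximum(U0s, 1e-12))
    if geometry == "stripe":
        # once the two edges merge (L approaching the stripe width) depth and
        # width are no longer separately identifiable
        widths = np.array([f.xr - f.xl for f in fits])
        use &= L <= 0.75 * np.maximum(widths, 1e-12)
    if use.sum() < 3:
        use = np.ones(len(fits), bool)
    # var(L²) ≈ 4L²·var(L), with L floored at the grid step so a single
    # sharp-edge frame cannot dominate the regression
    w = 1.0 / np.maximum(4.0 * np.maximum(L[use], kymo.dx) ** 2 * Lvar[use], 1e-300)
    slope, intercept, r2 = _weighted_linfit(t[use], L[use] ** 2, w)
    D = max(slope / 4.0, 0.0)
    L0 = float(np.sqrt(max(intercept, 0.0)))

    # exchange rate from the decay of the bleach depth; for stripes only the
    # pre-merge frames carry an identifiable depth
    if geometry == "stripe":
        tA, Aa = t[use], A[use]
    else:
        tA, Aa = t, A
    k = 0.0
    A0 = float(Aa[0]) if len(Aa) else 0.0
    if len(Aa) >= 3 and Aa.max() > 0 and np.ptp(Aa) / Aa.max() >= 0.02:
        Apos = np.maximum(Aa, 1e-9)
        sl, ic, _ = _weighted_linfit(tA, np.log(Apos), np.ones_like(tA))
        k0 = max(-sl, 1e-9)
        if fit_A_offset:
            def model(tt, a0, kk, ainf):
                return a0 * np.exp(-kk * tt) + ainf
            p0 = (float(np.exp(ic)), k0, 0.0)
            bounds = ([0, 0, 0], [1.5, np.inf, 1.0])
        else:
            def model(tt, a0, kk):
                return a0 * np.exp(-kk * tt)
            p0 = (float(np.exp(ic)), k0)
            bounds = ([0, 0], [1.5, np.inf])
        try:
            popt, _ = curve_fit(model, tA, Aa, p0=p0, bounds=bounds, maxfev=20000)
            A0, k = float(popt[0]), float(popt[1])
        except RuntimeError:
            A0, k = float(np.exp(ic)), k0
    return RecoveryFit(D=float(D), L0=L0, k=float(k), A0=A0, frames=fits,
                       times=t, n_excluded=excluded, r2_L2=float(r2))


# ---------------------------------------------------------------------------
# TIRF-FRAP correction
# ---------------------------------------------------------------------------

def tirf_frap_correct(movie: np.ndarray, roi, background_roi, reference_roi,
                      dt: float, pixel_size: float, stripe_axis: int = 0) -> Kymograph:
    """Background- and photobleach-corrected 1D profile series.

    Per frame the background-ROI mean is subtracted, intensities are
    divided by the reference-ROI decay (normalized to 1 at t = 0) and
    averaged along the stripe axis inside the analysis ROI, giving one 1D
    profile per time point ready for the stripe-model recovery fit.
    ROIs are (row_slice, col_slice) tuples and must be disjoint.
    """
    movie = np.asarray(movie, float)

    def _sl(r):
        return (slice(*r[0]), slice(*r[1])) if not isinstance(r[0], slice) else tuple(r)

    roi_s, bg_s, ref_s = _sl(roi), _sl(background_roi), _sl(reference_roi)
    bg = movie[(slice(None),) + bg_s].mean(axis=(1, 2))
    ref = movie[(slice(None),) + ref_s].mean(axis=(1, 2)) - bg
    if np.any(ref <= 0):
        raise InvalidParameterError("reference ROI intensity reached 0")
    ref = ref / ref[0]
    corrected = (movie - bg[:, None, None]) / ref[:, None, None]
    profiles = corrected[(slice(None),) + roi_s].mean(axis=1 + stripe_axis)
    return Kymograph(profiles, dx=pixel_size / 1000.0, dt=dt)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def compare_groups(groups: dict[str, list[RecoveryFit]],
                   pairs: list[tuple[str, str]] | None = None):
    """Mean, SEM of D and k per condition, plus pairwise Welch-free t-tests.

    Groups of fewer than two fits are excluded. Returns
    (summary_table, pairwise_table).
    """
    rows = []
    kept = {}
    for name, fits in groups.items():
        if len(fits) < 2:
            log.info("group %r has fewer than 2 fits; excluded", name)
            continue
        D = np.array([f.D for f in fits])
        k = np.array([f.k for f in fits])
        kept[name] = (D, k)
        rows.append((name, len(fits), D.mean(), D.std(ddof=1) / np.sqrt(len(D)),
                     k.mean(), k.std(ddof=1) / np.sqrt(len(k))))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean_D", "sem_D",
                                          "mean_k", "sem_k"])
    if pairs is None:
        names = list(kept)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    prow = []
    for a, b in pairs:
        if a not in kept or b not in kept:
            continue
        pD = ttest_ind(kept[a][0], kept[b][0]).pvalue
        pk = ttest_ind(kept[a][1], kept[b][1]).pvalue
        prow.append((a, b, float(pD), float(pk)))
    pairwise = pd.DataFrame(prow, columns=["group_a", "group_b", "p_D", "p_k"])
    return summary, pairwise
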