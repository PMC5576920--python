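"""Single cell-pair accumulation dynamics and Fat:Ds stoichiometry.

Quantifies total and boundary fluorescence of a Fat4/Ds1 cell pair over
time, detects the threshold onset of boundary accumulation, measures the
Pearson correlation between boundary Fat and boundary Ds (the
stoichiometry of complex formation), and reports whether boundary Ds
rises faster than total Ds after onset (super-linear accumulation, the
signature of positive feedback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import pearsonr

from .config import InvalidParameterError

log = logging.getLogger(__name__)

__all__ = ["PairTimeseries", "StoichiometryResult", "quantify_pair",
           "detect_onset", "stoichiometry", "nonlinearity_index"]


@dataclass
class PairTimeseries:
    """Per-frame traces for one cell pair.

    table: time_min, total_Fat, total_Ds, boundary_Fat, boundary_Ds, plus
    missing_Fat / missing_Ds flags for frames where a cell type was not
    found. onset_time is filled by detect_onset (None = undefined).
    """

    table: pd.DataFrame
    onset_time: float | None = None

    def __post_init__(self) -> None:
        required = {"time_min", "total_Fat", "total_Ds",
                    "boundary_Fat", "boundary_Ds"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidParameterError(f"trace table missing columns {missing}")


@dataclass(frozen=True)
class StoichiometryResult:
    """Pearson correlation and slope of boundary Fat vs boundary Ds."""

    pearson_rho: float
    pearson_rho_log: float
    n_points: int
    slope: float
    span_decades: float  # log10(max/min) of boundary Ds


def quantify_pair(movie: np.ndarray, time_min: np.ndarray | None = None,
                  frame_interval: float = 5.0,
                  masks: dict[str, np.ndarray] | None = None,
                  smooth_px: float = 1.0) -> PairTimeseries:
    """Total and boundary fluorescence traces from a two-channel pair movie.

    movie: (T, 2, H, W) (green, red), average-projected if z-stacked.
    Cell regions are fixed across frames from the time-max projection per
    channel (the two-cell assay fixes identities); optional ``masks``
    {'fat','ds'} override them. Per frame, totals are background-subtracted
    sums over each region and the boundary signal is the sum over the
    per-frame overlap of the green and red areas. Frames where a channel's
    area is empty are flagged missing.
    """
    movie = np.asarray(movie, float)
    if movie.ndim == 5:  # (T, Z, C, H, W) → average projection
        movie = movie.mean(axis=1)
    if movie.ndim != 4 or movie.shape[1] < 2:
        raise InvalidParameterError("movie must be (T, C>=2, H, W)")
    n_frames = movie.shape[0]
    t = (np.arange(n_frames) * frame_interval if time_min is None
         else np.asarray(time_min, float))

    def _signal_mask(img):
        # background level and noise from the dark decile; a bright stripe
        # would dominate an Otsu split and hide the dimmer cytoplasm
        dark = img[img <= np.percentile(img, 10)]
        bg = float(np.median(dark))
        noise = 1.4826 * float(np.median(np.abs(dark - bg)))
        return img > bg + 6.0 * max(noise, 1e-9)

    green_max = movie[:, 0].max(axis=0)
    red_max = movie[:, 1].max(axis=0)
    if masks is not None:
        fat_region = masks["fat"].astype(bool)
        ds_region = masks["ds"].astype(bool)
    else:
        fat_region = _signal_mask(green_max)
        ds_region = _signal_mask(red_max)
    cell_region = fat_region | ds_region
    bg_region = ~ndimage.binary_dilation(cell_region, iterations=3)

    rows = []
    for i in range(n_frames):
        g = movie[i, 0]
        r = movie[i, 1]
        bg_g = np.median(g[bg_region]) if bg_region.any() else 0.0
        bg_r = np.median(r[bg_region]) if bg_region.any() else 0.0
        gs = ndimage.gaussian_filter(g, smooth_px) - bg_g
        rs = ndimage.gaussian_filter(r, smooth_px) - bg_r
        # per-frame overlap of the green and red areas = accumulating boundary
        overlap = _signal_mask(gs) & _signal_mask(rs)
        missing_fat = not fat_region.any()
        missing_ds = not ds_region.any()
        rows.append((
            t[i],
            float((g[fat_region] - bg_g).sum()) if not missing_fat else np.nan,
            float((r[ds_region] - bg_r).sum()) if not missing_ds else np.nan,
            float((g[overlap] - bg_g).sum()) if overlap.any() else 0.0,
            float((r[overlap] - bg_r).sum()) if overlap.any() else 0.0,
            missing_fat, missing_ds,
        ))
    table = pd.DataFrame(rows, columns=["time_min", "total_Fat", "total_Ds",
                                        "boundary_Fat", "boundary_Ds",
                                        "missing_Fat", "missing_Ds"])
    return PairTimeseries(table)


def detect_onset(series: PairTimeseries, channel: str = "boundary_Ds",
                 n_sigma: float = 5.0, persistence: int = 3) -> float | None:
    """Threshold onset: first time the boundary signal exceeds the baseline
    mean + 5 sd and stays above for at least ``persistence`` frames.

    The baseline is the first quartile of frames. Returns the onset time in
    minutes, or None when the threshold is never (persistently) exceeded.
    """
    tab = series.table
    if len(tab) < 10:
        raise InvalidParameterError("need at least 10 frames")
    y = tab[channel].to_numpy(float)
    t = tab.time_min.to_numpy(float)
    nb = max(len(y) // 4, 2)
    base = y[:nb]
    level = float(np.mean(base) + n_sigma * max(np.std(base), 1e-12))
    above = y > level
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            onset = float(t[i - persistence + 1])
            series.onset_time = onset
            return onset
    series.onset_time = None
    return None


def stoichiometry(boundary_fat: np.ndarray, boundary_ds: np.ndarray) -> StoichiometryResult:
    """Pearson correlation and slope of paired boundary intensities.

    rho is computed on the linear values (as well as on log values for the
    decade-spanning regime); the slope is the least-squares proportionality
    of boundary Fat on boundary Ds. The span is log10(max/min) of the
    positive boundary-Ds values.
    """
    bf = np.asarray(boundary_fat, float)
    bd = np.asarray(boundary_ds, float)
    if len(bf) != len(bd) or len(bf) < 3:
        raise InvalidParameterError("need at least 3 paired points")
    if np.std(bf) == 0 or np.std(bd) == 0:
        raise InvalidParameterError("zero variance in a boundary trace; rho undefined")
    rho = float(pearsonr(bf, bd).statistic)
    pos = (bf > 0) & (bd > 0)
    rho_log = (float(pearsonr(np.log(bf[pos]), np.log(bd[pos])).statistic)
               if pos.sum() >= 3 else float("nan"))
    slope = float(np.polyfit(bd, bf, 1)[0])
    span = float(np.log10(bd[pos].max() / bd[pos].min())) if pos.any() else 0.0
    return StoichiometryResult(rho, rho_log, int(len(bf)), slope, span)


def nonlinearity_index(series: PairTimeseries,
                       trend_floor: float = 1e-3):
    """Ratio boundary_Ds/total_Ds per frame and its post-onset trend.

    The trend is the sign of a linear fit to the post-onset ratio,
    normalized by the mean ratio and the post-onset duration; positive
    means the boundary grows super-linearly with the total (the hallmark
    of self-enhancing accumulation). Requires a defined onset.
    """
    if series.onset_time is None:
        raise InvalidParameterError("onset undefined; run detect_onset first")
    tab = series.table
    post = tab[tab.time_min >= series.onset_time]
    total = post.total_Ds.to_numpy(float)
    if np.any(total <= 0):
        raise InvalidParameterError("total_Ds must be positive post-onset")
    ratio = post.boundary_Ds.to_numpy(float) / total
    t = post.time_min.to_numpy(float)
    slope = float(np.polyfit(t, ratio, 1)[0]) if len(t) >= 2 else 0.0
    duration = max(t[-1] - t[0], 1e-12)
    norm = slope * duration / max(np.mean(ratio), 1e-12)
    trend = 0 if abs(norm) < trend_floor else (1 if norm > 0 else -1)
    full_ratio = np.where(tab.total_Ds > 0,
                          tab.boundary_Ds / tab.total_Ds, np.nan)
    return pd.DataFrame({"time_min": tab.time_min, "ratio": full_ratio}), trend
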