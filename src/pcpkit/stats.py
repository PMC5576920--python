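"""Population statistics of boundary accumulation.

Fraction of accumulating boundaries versus expression, Hill-function
fitting with confidence intervals, log-binned joint distributions of the
flanking intensities, and threshold estimation as the balanced-accuracy
optimal axis-aligned separator between the accumulating and
non-accumulating classes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import InvalidParameterError

log = logging.getLogger(__name__)

__all__ = ["HillFit", "BoundaryDistribution2D", "ThresholdEstimate",
           "fraction_accumulating", "fit_hill", "joint_boundary_distribution",
           "load_boundary_workbook", "hill_from_workbook"]


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill fit y = f_max · xⁿ / (Kⁿ + xⁿ)."""

    n: float
    K: float
    f_max: float
    ci95_n: tuple[float, float]
    cov: np.ndarray
    residual_rms: float

    def predict(self, x):
        from scipy.special import expit

        x = np.asarray(x, dtype=float)
        return self.f_max * expit(self.n * (np.log(np.maximum(x, 1e-300))
                                            - np.log(self.K)))


@dataclass
class BoundaryDistribution2D:
    """Log-binned 2D class-conditional distributions of flanking intensities.

    Frequencies are normalized per bin by the two-class sum, so wherever
    the total count is positive the two normalized maps sum to exactly 1.
    """

    ds_edges: np.ndarray  # log10 a.u. bin edges (x axis)
    fat_edges: np.ndarray
    accumulating: np.ndarray  # counts, shape (n_fat_bins, n_ds_bins)
    non_accumulating: np.ndarray

    @property
    def normalized(self):
        total = self.accumulating + self.non_accumulating
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(total > 0, self.accumulating / total, np.nan)
        return acc, np.where(total > 0, 1.0 - acc, np.nan)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Axis-aligned (Ds, Fat) decision thresholds in a.u. (None = undefined).

    ``score`` is the value of the separation criterion at the optimum
    (accuracy by default; balanced accuracy when requested).
    """

    ds_threshold: float | None
    fat_threshold: float | None
    score: float | None
    criterion: str = "accuracy"


def fraction_accumulating(interfaces: pd.DataFrame, group: str = "group",
                          cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group fraction of accumulating heterotypic boundaries.

    ``interfaces`` needs columns heterotypic, accumulating, flank_I_Ds and a
    grouping column. mean_I_Ds is the mean over Ds-type cells when a cell
    table (with the same grouping column) is given, else the mean flanking
    Ds intensity of the group's heterotypic interfaces. Groups without
    heterotypic interfaces are excluded and logged.
    """
    if group not in interfaces.columns:
        interfaces = interfaces.assign(**{group: "all"})
    out = []
    for g, sub in interfaces.groupby(group, sort=True):
        het = sub[sub.heterotypic.astype(bool)]
        if len(het) == 0:
            log.info("group %r has no heterotypic interfaces; excluded", g)
            continue
        frac = float(het.accumulating.astype(bool).mean())
        if cells is not None and group in cells.columns:
            ds_cells = cells[(cells[group] == g) & (cells.cell_type == "Ds")]
            mean_ds = float(ds_cells.mean_I_Ds.mean()) if len(ds_cells) else np.nan
        else:
            mean_ds = float(het.flank_I_Ds.mean())
        out.append((g, frac, mean_ds, len(het)))
    return pd.DataFrame(out, columns=[group, "fraction", "mean_I_Ds", "n_heterotypic"])


def _hill_log(logx, n, logK, f_max):
    # Hill function is logistic in log-space: better conditioned for fitting
    return f_max / (1.0 + np.exp(-n * np.log(10) * (logx - logK)))


def fit_hill(x, y, f_max_bound: float = 1.0) -> HillFit:
    """Fit y = f_max·xⁿ/(Kⁿ+xⁿ) by unweighted least squares.

    The fit is performed on log10(x) (the Hill curve is logistic there,
    which conditions the problem) — predictions are identical. The 95% CI
    on n comes from the parameter covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InvalidParameterError("need at least 4 points to fit 3 parameters")
    if np.any(x <= 0):
        raise InvalidParameterError("x must be positive")
    if np.any((y < 0) | (y > 1)):
        raise InvalidParameterError("y must be fractions in [0, 1]")
    lx = np.log10(x)
    # initialization: K at the half-max crossing, n from the log-slope
    f0 = min(max(y.max(), 0.05), f_max_bound)
    half = 0.5 * f0
    order = np.argsort(lx)
    k0 = float(np.interp(half, y[order], lx[order])) if y.max() > half else float(np.median(lx))
    p0 = (2.0, k0, f0)
    try:
        popt, pcov = curve_fit(_hill_log, lx, y, p0=p0,
                               bounds=([1e-3, lx.min() - 3, 1e-3],
                                       [100.0, lx.max() + 3, f_max_bound]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise InvalidParameterError(f"Hill fit failed to converge: {exc}") from exc
    n, logK, f_max = popt
    se_n = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    resid = y - _hill_log(lx, *popt)
    return HillFit(n=float(n), K=float(10**logK), f_max=float(f_max),
                   ci95_n=(float(n - 1.96 * se_n), float(n + 1.96 * se_n)),
                   cov=pcov, residual_rms=float(np.sqrt(np.mean(resid**2))))


def _shift_to_floor(values: np.ndarray, floor: float) -> np.ndarray:
    """Shift intensities so the dimmest value maps to ``floor`` (default 10 a.u.),
    the cutoff used for log-scale binning."""
    return values - values.min() + floor


def joint_boundary_distribution(interfaces: pd.DataFrame, n_bins: int = 50,
                                floor: float = 10.0,
                                criterion: str = "accuracy"):
    """Log-binned 2D distributions of flanking (Ds, Fat) intensities and the
    estimated accumulation thresholds.

    Intensities are shifted so the dimmest cell has the floor value, then
    binned on even log10 grids. Thresholds are the axis-aligned separator
    (accumulating iff Ds ≥ T_Ds and Fat ≥ T_Fat) maximizing classification
    accuracy over the bin-edge grid; they are undefined when either class
    is empty. Plain accuracy is the default because its optimum sits where
    the accumulation probability crosses 1/2 — a fixed point of the
    underlying threshold rule, independent of how many boundaries happen to
    accumulate in a given batch. criterion='balanced' weights the two
    classes equally instead; its optimum shifts with the class balance and
    therefore drifts across induction times.
    """
    het = interfaces[interfaces.heterotypic.astype(bool)]
    if len(het) < 10:
        raise InvalidParameterError("need at least 10 heterotypic interfaces")
    ds = _shift_to_floor(het.flank_I_Ds.to_numpy(float), floor)
    fat = _shift_to_floor(het.flank_I_Fat.to_numpy(float), floor)
    acc = het.accumulating.to_numpy(bool)

    lds, lfat = np.log10(ds), np.log10(fat)
    ds_edges = np.linspace(np.log10(floor), lds.max() + 1e-9, n_bins + 1)
    fat_edges = np.linspace(np.log10(floor), lfat.max() + 1e-9, n_bins + 1)
    h_acc, _, _ = np.histogram2d(lfat[acc], lds[acc], bins=(fat_edges, ds_edges))
    h_non, _, _ = np.histogram2d(lfat[~acc], lds[~acc], bins=(fat_edges, ds_edges))
    dist = BoundaryDistribution2D(ds_edges, fat_edges, h_acc, h_non)

    if acc.all() or not acc.any():
        return dist, ThresholdEstimate(None, None, None, criterion)

    if criterion not in ("accuracy", "balanced"):
        raise InvalidParameterError("criterion must be 'accuracy' or 'balanced'")
    n_pos = int(acc.sum())
    n_neg = int((~acc).sum())
    n = n_pos + n_neg
    # vectorized grid search: cumulative class counts over the 2D histogram
    # give tp/tn for every (T_Ds, T_Fat) bin-edge pair at once
    cum_acc = np.cumsum(np.cumsum(h_acc[::-1, ::-1], 0), 1)[::-1, ::-1]
    cum_non = np.cumsum(np.cumsum(h_non[::-1, ::-1], 0), 1)[::-1, ::-1]
    tp = cum_acc  # accumulating points above both thresholds
    tn = n_neg - cum_non
    if criterion == "balanced":
        score = 0.5 * (tp / n_pos + tn / n_neg)
    else:
        score = (tp + tn) / n
    # the optimum is usually a plateau; take its median grid point so the
    # estimate does not jump to a plateau edge under sampling noise
    best = score.max()
    fi, di = np.nonzero(score >= best - 1e-12)
    tfat = float(np.median(fat_edges[:-1][fi]))
    tds = float(np.median(ds_edges[:-1][di]))
    est = ThresholdEstimate(float(10**tds), float(10**tfat), float(best),
                            criterion)
    return dist, est


# ---------------------------------------------------------------------------
# source-data workbook (per-cell intensity tables)
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(
    r"^(IDs|IFat|IFatDsAccumulating|IFatDsNonAccumulating)_([0-9.]+)h?$")


def load_boundary_workbook(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Parse a per-cell intensity workbook into a tidy table.

    Expected dialect: each worksheet row starts with a label in the first
    column — IDs_xh (Ds level of every cell in the x-hour batch), IFat_xh,
    IFatDsAccumulating_xh (cells flanking accumulating boundaries) or
    IFatDsNonAccumulating_xh — followed by numeric values across the row.
    Repeated labels are concatenated. Returns columns
    (label, hours, values) with values as float arrays.
    """
    from openpyxl import load_workbook

    wb = load_workbook(Path(path), read_only=True, data_only=True)
    ws = wb.worksheets[sheet] if isinstance(sheet, int) else wb[sheet]
    rows: dict[tuple[str, float], list[float]] = {}
    for row in ws.iter_rows(values_only=True):
        if not row or row[0] is None:
            continue
        m = _ROW_RE.match(str(row[0]).strip())
        if not m:
            continue
        key = (m.group(1), float(m.group(2)))
        vals = [float(v) for v in row[1:] if isinstance(v, (int, float))]
        rows.setdefault(key, []).extend(vals)
    recs = [(label, hours, np.asarray(vals, float))
            for (label, hours), vals in sorted(rows.items())]
    return pd.DataFrame(recs, columns=["label", "hours", "values"])


def hill_from_workbook(path: str | Path, sheet: int | str = 0) -> tuple[HillFit, pd.DataFrame]:
    """Fraction of accumulating boundaries vs mean Ds level, then a Hill fit.

    Per induction time x: fraction = (# cells flanking accumulating
    boundaries) / (# accumulating + # non-accumulating), mean Ds = mean of
    the IDs_xh row. Returns (HillFit, per-time summary table).
    """
    tidy = load_boundary_workbook(path, sheet)
    out = []
    for hours in sorted(tidy.hours.unique()):
        sub = {lab: v for lab, _, v in
               tidy[tidy.hours == hours].itertuples(index=False)}
        acc = sub.get("IFatDsAccumulating", np.array([]))
        non = sub.get("IFatDsNonAccumulating", np.array([]))
        ids = sub.get("IDs", np.array([]))
        total = len(acc) + len(non)
        if total == 0 or len(ids) == 0:
            continue
        out.append((hours, len(acc) / total, float(np.mean(ids))))
    table = pd.DataFrame(out, columns=["hours", "fraction", "mean_I_Ds"])
    fit = fit_hill(table.mean_I_Ds, table.fraction)
    return fit, table


def plot_hill(fit: HillFit, x, y, path: str | Path) -> None:
    """Save a fraction-vs-expression plot with the fitted Hill curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.logspace(np.log10(min(x)), np.log10(max(x)), 200)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.semilogx(x, y, "o", label="data")
    ax.semilogx(xs, fit.predict(xs), "-",
                label=f"Hill n={fit.n:.2f} (95% CI ±{fit.n - fit.ci95_n[0]:.2f})")
    ax.set_xlabel("mean Ds1 level (a.u.)")
    ax.set_ylabel("fraction accumulating")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
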