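"""Co-culture snapshot analysis.

Segments multi-channel snapshots into typed cells via a nuclei-seeded
watershed, detects colocalized boundary accumulation from a
median-normalized min(green, red) score, and assigns accumulation
components to cell-cell interfaces through the dual lattice (each mask
pixel belongs to the nearest interface pixel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .config import InvalidParameterError, PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["SnapshotImage", "project_stack", "segment_snapshot",
           "detect_accumulation", "build_interface_table", "analyze_snapshot",
           "refine_cell_means", "interface_graph"]

CELL_COLUMNS = ["cell_id", "cell_type", "mean_I_Fat", "mean_I_Ds", "area_px",
                "nucleus_row", "nucleus_col", "touches_border"]
INTERFACE_COLUMNS = ["interface_id", "cell_a", "cell_b", "heterotypic",
                     "accumulating", "flank_I_Fat", "flank_I_Ds", "length_px",
                     "accum_area_px"]


@dataclass
class SnapshotImage:
    """A projected multi-channel snapshot.

    channels: (3, H, W) float array ordered (green=Fat4, red=Ds1, blue=nuclei).
    pixel_size: nm per pixel.
    """

    channels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] < 2:
            raise InvalidParameterError("channels must be (C, H, W) with C >= 2")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")

    @property
    def green(self) -> np.ndarray:
        return self.channels[0]

    @property
    def red(self) -> np.ndarray:
        return self.channels[1]

    @property
    def blue(self) -> np.ndarray:
        if self.channels.shape[0] < 3:
            raise InvalidParameterError("no nuclear (blue) channel present")
        return self.channels[2]

    @property
    def px_um(self) -> float:
        return self.pixel_size / 1000.0


def project_stack(stack: np.ndarray) -> np.ndarray:
    """Average-intensity projection over the z axis.

    Accepts (Z, C, H, W) or (Z, H, W); a single slice is returned unchanged
    (minus the z axis). An empty stack is an error.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 3 or stack.shape[0] == 0:
        raise InvalidParameterError("stack must have at least one z slice")
    return stack.mean(axis=0)


def _normalized_channel(chan: np.ndarray, sigma_px: float):
    """Background-subtracted, foreground-median-normalized channel.

    Returns (normalized, foreground_mask, ok) where ok is False when the
    channel carries no real signal (foreground indistinguishable from
    noise), in which case the normalization is meaningless.
    """
    sm = ndimage.gaussian_filter(chan, sigma_px)
    # background level and noise from the dark decile (glass region)
    dark = sm[sm <= np.percentile(sm, 10)]
    bg = float(np.median(dark))
    noise = 1.4826 * float(np.median(np.abs(dark - bg)))
    fg = sm > bg + 6.0 * max(noise, 1e-9)
    scale = float(np.median(sm[fg]) - bg) if fg.any() else 0.0
    ok = fg.mean() > 0.005 and scale > 5.0 * max(noise, 1e-9)
    if not ok:
        return np.zeros_like(sm), np.zeros(sm.shape, bool), False
    return (sm - bg) / scale, fg, True


def segment_snapshot(image: SnapshotImage, config: PipelineConfig | None = None):
    """Nuclei-seeded watershed segmentation of the co-culture tissue.

    Nuclei are local maxima of the smoothed blue channel (minimum
    separation one nuclear diameter); the watershed floods the union of the
    Fat/Ds foreground from those seeds. Each cell is typed by smoothed
    channel dominance after per-channel median normalization ('dual' when
    both normalized channels clear their foreground level).

    Returns (label_map, cell_table).
    """
    cfg = config or PipelineConfig()
    sigma_px = cfg.smoothing_sigma / image.px_um
    g_norm, g_fg, g_ok = _normalized_channel(image.green, sigma_px)
    r_norm, r_fg, r_ok = _normalized_channel(image.red, sigma_px)
    foreground = g_fg | r_fg

    blue_sm = ndimage.gaussian_filter(image.blue, 2.0 / image.px_um)
    dark_b = blue_sm[blue_sm <= np.percentile(blue_sm, 10)]
    bg_b = float(np.median(dark_b))
    noise_b = 1.4826 * float(np.median(np.abs(dark_b - bg_b)))
    try:
        nuc_thr = threshold_otsu(blue_sm)
    except ValueError:
        nuc_thr = np.inf
    # the Otsu split must also clear the noise floor, otherwise a blank
    # nuclear channel yields spurious seeds
    nuc_mask = blue_sm > max(nuc_thr, bg_b + 6.0 * max(noise_b, 1e-9))
    if nuc_mask.any() and (~nuc_mask).any():
        contrast = float(np.median(blue_sm[nuc_mask])
                         - np.median(blue_sm[~nuc_mask]))
        if contrast < 10.0 * max(noise_b, 1e-9):
            nuc_mask[:] = False
    # peak_local_max suppresses in a square (Chebyshev) footprint; divide by
    # √2 so the Euclidean separation honoured is the configured one
    min_sep = max(1, int(round(cfg.nucleus_min_separation / image.px_um / 1.4142)))
    seeds = peak_local_max(blue_sm, min_distance=min_sep, labels=nuc_mask,
                           exclude_border=False)
    if len(seeds) == 0:
        log.warning("no nuclei found; returning empty segmentation")
        return (np.zeros(image.green.shape, np.int32),
                pd.DataFrame(columns=CELL_COLUMNS))

    markers = np.zeros(image.green.shape, np.int32)
    # deterministic ids: sort seeds by (row, col)
    order = np.lexsort((seeds[:, 1], seeds[:, 0]))
    for i, (r, c) in enumerate(seeds[order], start=1):
        markers[r, c] = i
    foreground |= nuc_mask
    labels = watershed(np.zeros_like(blue_sm), markers, mask=foreground)

    rows = []
    h, w = labels.shape
    border = np.zeros_like(labels, bool)
    border[0], border[-1], border[:, 0], border[:, -1] = True, True, True, True
    erode_px = max(1, int(round(cfg.smoothing_sigma / image.px_um)))
    for i, (r, c) in enumerate(seeds[order], start=1):
        mask = labels == i
        area = int(mask.sum())
        if area == 0:
            continue
        # type from the eroded interior: the rim carries PSF bleed from
        # neighbours and boundary stripes
        interior = ndimage.binary_erosion(mask, iterations=erode_px)
        tmask = interior if interior.any() else mask
        gn = float(np.mean(g_norm[tmask])) if g_ok else 0.0
        rn = float(np.mean(r_norm[tmask])) if r_ok else 0.0
        # dual: both channels at a substantial fraction of their foreground
        # median (PSF bleed from neighbours stays well below this)
        if g_ok and r_ok and gn > 0.3 and rn > 0.3:
            ctype = "dual"
        elif gn > rn and g_ok:
            ctype = "Fat"
        elif r_ok:
            ctype = "Ds"
        else:
            ctype = "unknown"
        rows.append((i, ctype, float(image.green[mask].mean()),
                     float(image.red[mask].mean()), area, float(r), float(c),
                     bool((mask & border).any())))
    return labels, pd.DataFrame(rows, columns=CELL_COLUMNS)


def detect_accumulation(image: SnapshotImage,
                        config: PipelineConfig | None = None) -> np.ndarray:
    """Binary mask of candidate accumulating-boundary pixels.

    The colocalization score is min(G', R') of background-subtracted,
    foreground-median-normalized channels, so the result is invariant to a
    joint affine rescale of the intensities; the mask is the Otsu threshold
    of that score followed by small-object removal. An empty mask is valid:
    if either channel carries no signal there is nothing colocalized.
    """
    cfg = config or PipelineConfig()
    sigma_px = 0.5 * cfg.smoothing_sigma / image.px_um
    g_norm, _, g_ok = _normalized_channel(image.green, sigma_px)
    r_norm, _, r_ok = _normalized_channel(image.red, sigma_px)
    if not (g_ok and r_ok):
        return np.zeros(image.green.shape, bool)
    score = np.minimum(g_norm, r_norm)
    try:
        thr = threshold_otsu(score)
    except ValueError:
        return np.zeros(score.shape, bool)
    # floor: genuine accumulation exceeds twice the median membrane level in
    # both channels; PSF overlap at plain heterotypic contacts stays below
    mask = score > max(thr, 2.0)
    min_px = max(1, int(round(cfg.small_object_area / image.px_um**2)))
    return remove_small_objects(mask, max_size=min_px - 1)


def _interface_adjacency(label_map: np.ndarray):
    """Interface pixel coordinates and pair ids from 4-neighbour contacts.

    Returns (pair_list, pix_coords, pix_pair_index, lengths) where
    pair_list[i] = (a, b) with a < b, pix_coords are (row, col) of every
    pixel adjacent to the other cell of its pair, pix_pair_index maps each
    such pixel to its pair, and lengths counts adjacent pixel pairs.
    """
    coords_all = []
    pair_of_pixel = []
    lengths: dict[tuple[int, int], int] = {}
    lm = label_map
    shifts = [((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
              ((slice(None, -1), slice(None)), (slice(1, None), slice(None)))]
    offsets = [(0, 1), (1, 0)]
    h, w = lm.shape
    for (sa, sb), (dr, dc) in zip(shifts, offsets):
        a = lm[sa]
        b = lm[sb]
        sel = (a != b) & (a > 0) & (b > 0)
        rr, cc = np.nonzero(sel)
        if dr == 0:
            ra, ca, rb, cb = rr, cc, rr, cc + 1
        else:
            ra, ca, rb, cb = rr, cc, rr + 1, cc
        la, lb_ = a[sel], b[sel]
        lo = np.minimum(la, lb_)
        hi = np.maximum(la, lb_)
        for L, H_ in zip(lo, hi):
            lengths[(int(L), int(H_))] = lengths.get((int(L), int(H_)), 0) + 1
        coords_all.append(np.column_stack([ra, ca]))
        coords_all.append(np.column_stack([rb, cb]))
        pk = np.column_stack([lo, hi])
        pair_of_pixel.append(pk)
        pair_of_pixel.append(pk)
    if not lengths:
        return [], np.empty((0, 2), int), np.empty(0, int), {}
    pair_list = sorted(lengths)
    pair_index = {p: i for i, p in enumerate(pair_list)}
    coords = np.concatenate(coords_all)
    pairs = np.concatenate(pair_of_pixel)
    pix_pair = np.array([pair_index[(int(a), int(b))] for a, b in pairs])
    return pair_list, coords, pix_pair, lengths


def build_interface_table(label_map: np.ndarray, accum_mask: np.ndarray,
                          cells: pd.DataFrame,
                          config: PipelineConfig | None = None,
                          pixel_size: float | None = None):
    """Enumerate cell-cell interfaces and flag accumulating ones.

    The accumulation mask is partitioned by the dual lattice: every mask
    pixel is assigned to the interface whose boundary pixels are nearest
    (ties and capture radius per config). Components farther than the
    capture radius from any interface are dropped and counted in the log.

    Returns (interface_table, dropped_area_px).
    """
    cfg = config or PipelineConfig()
    if label_map.shape != accum_mask.shape:
        raise InvalidParameterError("label map and mask must share a shape")
    px_um = (pixel_size or cfg.pixel_size) / 1000.0
    pair_list, coords, pix_pair, lengths = _interface_adjacency(label_map)
    n_pairs = len(pair_list)
    assigned = np.zeros(n_pairs, int)
    coverage = np.zeros(n_pairs)
    dropped = 0
    if n_pairs and accum_mask.any():
        tree = cKDTree(coords)
        mr, mc = np.nonzero(accum_mask)
        d, j = tree.query(np.column_stack([mr, mc]))
        cap = cfg.interface_assignment_radius / px_um
        ok = d <= cap
        dropped = int((~ok).sum())
        np.add.at(assigned, pix_pair[j[ok]], 1)
        if dropped:
            log.info("dropped %d accumulation-mask pixels beyond the dual-lattice "
                     "capture radius", dropped)
        # coverage: how much of the interface's extent the assigned mask
        # pixels span along the interface axis — a true stripe runs the full
        # length even when the watershed line is displaced a little, while
        # junction spill-over from a neighbouring stripe clumps at one end
        mask_pts = np.column_stack([mr, mc])[ok]
        mask_pair = pix_pair[j[ok]]
        for i in range(n_pairs):
            ipts = coords[pix_pair == i].astype(float)
            mpts = mask_pts[mask_pair == i].astype(float)
            if len(mpts) == 0 or len(ipts) < 2:
                continue
            centered = ipts - ipts.mean(axis=0)
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
            iproj = centered @ axis
            mproj = (mpts - ipts.mean(axis=0)) @ axis
            extent = iproj.max() - iproj.min()
            if extent <= 0:
                continue
            lo = max(mproj.min(), iproj.min())
            hi = min(mproj.max(), iproj.max())
            coverage[i] = max(hi - lo, 0.0) / extent
    elif accum_mask.any():
        dropped = int(accum_mask.sum())

    by_id = cells.set_index("cell_id") if len(cells) else cells
    recs = []
    for i, (a, b) in enumerate(pair_list):
        try:
            ca, cb = by_id.loc[a], by_id.loc[b]
        except KeyError:
            continue
        het = (ca.cell_type != cb.cell_type and "unknown" not in
               (ca.cell_type, cb.cell_type))
        fat_side = ca if ca.mean_I_Fat >= cb.mean_I_Fat else cb
        ds_side = ca if ca.mean_I_Ds >= cb.mean_I_Ds else cb
        length = lengths[(a, b)]
        # accumulating: the mask must blanket the interface's own pixels (a
        # true stripe covers nearly all of them; junction spill-over from a
        # neighbouring stripe covers only one end) and the contact must be
        # long enough to be a real interface
        min_len = cfg.min_interface_length / px_um
        is_acc = (assigned[i] >= max(4.0, 0.85 * length)
                  and coverage[i] >= 0.5 and length >= min_len)
        recs.append((i, a, b, bool(het), bool(is_acc),
                     float(fat_side.mean_I_Fat), float(ds_side.mean_I_Ds),
                     int(length), int(assigned[i])))
    table = pd.DataFrame(recs, columns=INTERFACE_COLUMNS)
    return table, dropped


def interface_graph(cells: pd.DataFrame, interfaces: pd.DataFrame):
    """The cell-adjacency graph: nodes are cells, edges are interfaces.

    Node attributes carry the cell type and mean intensities; edge
    attributes the heterotypic/accumulating flags and contact length.
    """
    import networkx as nx

    g = nx.Graph()
    for r in cells.itertuples():
        g.add_node(int(r.cell_id), cell_type=r.cell_type,
                   mean_I_Fat=float(r.mean_I_Fat),
                   mean_I_Ds=float(r.mean_I_Ds))
    for r in interfaces.itertuples():
        g.add_edge(int(r.cell_a), int(r.cell_b),
                   heterotypic=bool(r.heterotypic),
                   accumulating=bool(r.accumulating),
                   length_px=int(r.length_px))
    return g


def refine_cell_means(image: SnapshotImage, labels: np.ndarray,
                      cells: pd.DataFrame, accum_mask: np.ndarray,
                      config: PipelineConfig | None = None) -> pd.DataFrame:
    """Recompute per-cell channel means excluding accumulation pixels.

    The boundary stripe is much brighter than the cytoplasm and would
    otherwise inflate the expression estimate of every cell flanking an
    accumulating interface; the detected mask (dilated by the smoothing
    scale to catch its blur halo) is removed before averaging.
    """
    cfg = config or PipelineConfig()
    if not len(cells):
        return cells
    dilate = max(1, int(round(2 * cfg.smoothing_sigma / image.px_um)))
    excl = ndimage.binary_dilation(accum_mask, iterations=dilate)
    erode_px = max(1, int(round(cfg.smoothing_sigma / image.px_um)))
    # camera background from the dark decile of each channel
    bg_g = float(np.median(image.green[image.green
                                       <= np.percentile(image.green, 10)]))
    bg_r = float(np.median(image.red[image.red <= np.percentile(image.red, 10)]))
    out = cells.copy()
    for idx, row in out.iterrows():
        cell = labels == row.cell_id
        # interior average: the rim carries watershed misplacement and PSF
        # bleed from neighbours, the stripe carries the accumulation signal
        interior = ndimage.binary_erosion(cell, iterations=erode_px)
        mask = interior & ~excl
        if not mask.any():
            mask = cell & ~excl
        if not mask.any():
            mask = cell
        out.at[idx, "mean_I_Fat"] = max(float(image.green[mask].mean()) - bg_g, 0.0)
        out.at[idx, "mean_I_Ds"] = max(float(image.red[mask].mean()) - bg_r, 0.0)
    return out


def analyze_snapshot(image: SnapshotImage, config: PipelineConfig | None = None):
    """Full snapshot pipeline: segment, detect accumulation, build interfaces.

    Cell means are refined to exclude the detected accumulation stripe so
    flanking intensities estimate expression, not expression plus boundary.
    Returns (label_map, cell_table, interface_table, accum_mask).
    """
    cfg = config or PipelineConfig()
    labels, cells = segment_snapshot(image, cfg)
    mask = detect_accumulation(image, cfg)
    cells = refine_cell_means(image, labels, cells, mask, cfg)
    table, _ = build_interface_table(labels, mask, cells, cfg,
                                     pixel_size=image.pixel_size)
    return labels, cells, table, mask
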