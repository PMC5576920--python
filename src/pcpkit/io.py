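"""Readers, writers and run provenance.

TIFF/OME-TIFF image I/O via tifffile, plain-text polyline vertex files
(one "x,y" pair per line, 0-based pixel units, matching snake-export
conventions), CSV/JSON result tables, and a manifest recording every
artifact with its checksum, the configuration snapshot and the seed.
Pixel coordinates are 0-based (row, col) internally; polyline files store
(x, y) = (col, row).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import InvalidParameterError, PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["load_image", "save_image", "read_polyline", "write_polyline",
           "write_results"]


def _package_version() -> str:
    try:
        return _pkg_version("pcpkit")
    except PackageNotFoundError:
        return "unknown"


def save_image(path: str | Path, array: np.ndarray, axes: str = "CYX",
               pixel_size: float | None = None) -> None:
    """Write an array as OME-TIFF with an axes tag and optional pixel size (nm)."""
    meta: dict = {"axes": axes}
    if pixel_size is not None:
        # OME PhysicalSize is in µm
        meta["PhysicalSizeX"] = pixel_size / 1000.0
        meta["PhysicalSizeXUnit"] = "µm"
        meta["PhysicalSizeY"] = pixel_size / 1000.0
        meta["PhysicalSizeYUnit"] = "µm"
    tifffile.imwrite(Path(path), np.asarray(array, np.float32), ome=True,
                     metadata=meta)


def load_image(path: str | Path, config: PipelineConfig | None = None):
    """Read a TIFF/OME-TIFF and return (array, axes, pixel_size_nm).

    The channel axis is left in file order; channel roles come from the
    config's green/red/blue indices. Pixel size is taken from OME metadata
    when present; a config value wins over metadata (with a logged notice).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with tifffile.TiffFile(p) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        px_nm = None
        if tf.ome_metadata:
            import re
            m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
            if m:
                px_nm = float(m.group(1)) * 1000.0
    if config is not None:
        if px_nm is not None and abs(px_nm - config.pixel_size) > 1e-6:
            log.info("pixel size: config value %.3g nm overrides metadata %.3g nm",
                     config.pixel_size, px_nm)
        px_nm = config.pixel_size
    return np.asarray(arr, float), axes, px_nm


def read_polyline(path: str | Path) -> np.ndarray:
    """Read a plain-text vertex file (x,y per line, 0-based px) as (row, col)."""
    pts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y = [float(v) for v in line.replace(",", " ").split()[:2]]
        pts.append((y, x))
    if len(pts) < 2:
        raise InvalidParameterError(f"{path}: polyline needs at least 2 vertices")
    return np.asarray(pts, float)


def write_polyline(path: str | Path, polyline: np.ndarray) -> None:
    """Write (row, col) vertices as x,y lines (0-based pixel units)."""
    lines = [f"{c:.4f},{r:.4f}" for r, c in np.asarray(polyline, float)]
    Path(path).write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(out_dir: str | Path, tables: dict[str, pd.DataFrame] | None = None,
                  reports: dict[str, dict] | None = None,
                  config: PipelineConfig | None = None,
                  seed: int | None = None, force: bool = False) -> dict:
    """Write CSV tables and JSON reports plus a provenance manifest.

    The manifest lists every artifact with its sha256 checksum, the config
    snapshot, the seed and the package version. Existing artifact files
    raise unless ``force`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    for name, table in (tables or {}).items():
        path = out / f"{name}.csv"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force=True to overwrite)")
        table.to_csv(path, index=False)
        artifacts.append({"name": name, "path": path.name, "sha256": _sha256(path)})
    for name, report in (reports or {}).items():
        path = out / f"{name}.json"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force=True to overwrite)")
        path.write_text(json.dumps(report, indent=2, default=float) + "\n")
        artifacts.append({"name": name, "path": path.name, "sha256": _sha256(path)})
    manifest = {
        "artifacts": artifacts,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "version": _package_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("wrote %d artifacts to %s (seed=%s)", len(artifacts), out, seed)
    return manifest
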