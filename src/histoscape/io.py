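"""Readers, writers, the class-centroid extractor, and the pipeline runner.

Supported formats (all plain or standard formats; values are taken verbatim
as class codes):

* label images: single-channel integer TIFF or PNG, with an optional JSON
  sidecar (``<image>.json``) carrying resolution, nodata code and class names;
* point tables: CSV with columns ``x,y[,mark]``;
* ImageJ ROI files (``.roi`` and ``.zip`` sets) for point and
  polygon/polyline annotations (minimal reader/writer for the binary
  format); integer ROI coordinates are pixel indices and are converted to
  pixel-centre coordinates (+0.5) when building point patterns.
"""

from __future__ import annotations

import hashlib
import json
import struct
import warnings
import zipfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.measure import perimeter as sk_perimeter
from skimage.measure import regionprops

from .points import PointPattern, Window
from .raster import CategoricalRaster

__all__ = [
    "read_label_image",
    "write_label_image",
    "read_points_csv",
    "write_points_csv",
    "read_imagej_roi",
    "write_imagej_roi",
    "read_roi_zip",
    "roi_to_point_pattern",
    "extract_class_centroids",
    "function_to_csv",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# label images
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_label_image(path) -> CategoricalRaster:
    """Read a single-channel integer label image (TIFF or PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    else:
        values = iio.imread(path)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel label image, "
                         f"got shape {values.shape}")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return CategoricalRaster(
        values=values.astype(np.int64),
        resolution=float(meta.get("resolution", 1.0)),
        nodata_code=meta.get("nodata_code"),
        class_names={int(k): v for k, v in meta.get("class_names", {}).items()})


def write_label_image(raster: CategoricalRaster, path) -> None:
    path = Path(path)
    vmax = int(raster.values.max())
    dtype = np.uint8 if 0 <= raster.values.min() and vmax < 256 else np.uint16
    arr = raster.values.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    meta = {"resolution": raster.resolution}
    if raster.nodata_code is not None:
        meta["nodata_code"] = raster.nodata_code
    if raster.class_names:
        meta["class_names"] = {str(k): v for k, v in raster.class_names.items()}
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# CSV point tables
# ---------------------------------------------------------------------------

def read_points_csv(path, window: Window | None = None) -> PointPattern:
    """Read a CSV point table (columns x, y and optionally mark).

    If no window is given the bounding box of the points is used.
    """
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}, "
                             f"found {list(df.columns)}")
    pts = df[["x", "y"]].to_numpy(float)
    if window is None:
        window = Window(pts[:, 0].min(), pts[:, 0].max(),
                        pts[:, 1].min(), pts[:, 1].max())
    marks = df["mark"].to_numpy() if "mark" in df.columns else None
    return PointPattern(pts, window, marks)


def write_points_csv(pp: PointPattern, path) -> None:
    df = pd.DataFrame({"x": pp.points[:, 0], "y": pp.points[:, 1]})
    if pp.marks is not None:
        df["mark"] = pp.marks
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ImageJ ROI binary format (minimal: point / polygon / polyline)
# ---------------------------------------------------------------------------

_ROI_TYPES = {0: "polygon", 4: "freeline", 5: "polyline", 7: "freehand",
              10: "point"}
_ROI_CODES = {"polygon": 0, "polyline": 5, "point": 10}


def read_imagej_roi(source) -> dict:
    """Parse an ImageJ .roi file (point/polygon/polyline types).

    Returns ``{'type': str, 'coords': (n, 2) int array of (x, y) pixels}``.
    """
    data = source if isinstance(source, (bytes, bytearray)) else Path(source).read_bytes()
    if data[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI file (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in _ROI_TYPES:
        raise ValueError(f"unsupported ROI type code {roi_type}")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">H", data[16:18])[0]
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(int) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(int) + top
    return {"type": _ROI_TYPES[roi_type], "coords": np.column_stack([xs, ys])}


def write_imagej_roi(path, coords: np.ndarray, roi_type: str = "point") -> None:
    """Write a minimal ImageJ .roi file for integer pixel coordinates."""
    if roi_type not in _ROI_CODES:
        raise ValueError(f"unsupported ROI type {roi_type!r}")
    coords = np.asarray(coords)
    if not np.issubdtype(coords.dtype, np.integer):
        rounded = np.round(coords).astype(int)
        if not np.allclose(rounded, coords):
            warnings.warn("ROI coordinates rounded to integer pixels")
        coords = rounded
    left, top = int(coords[:, 0].min()), int(coords[:, 1].min())
    right, bottom = int(coords[:, 0].max()), int(coords[:, 1].max())
    n = len(coords)
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)           # version
    header[6] = _ROI_CODES[roi_type]
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    body = ((coords[:, 0] - left).astype(">i2").tobytes()
            + (coords[:, 1] - top).astype(">i2").tobytes())
    Path(path).write_bytes(bytes(header) + body)


def read_roi_zip(path) -> list:
    """Read a .zip set of ImageJ ROIs, in archive order."""
    rois = []
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            if name.endswith(".roi"):
                rois.append(read_imagej_roi(zf.read(name)))
    return rois


def roi_to_point_pattern(rois, window: Window,
                         resolution: float = 1.0) -> PointPattern:
    """Pool point-type ROI coordinates into a PointPattern.

    Integer ROI pixel coordinates are mapped to pixel centres
    (x + 0.5, y + 0.5) and scaled by the resolution.
    """
    if isinstance(rois, dict):
        rois = [rois]
    coords = np.vstack([r["coords"] for r in rois]).astype(float)
    return PointPattern((coords + 0.5) * resolution, window)


# ---------------------------------------------------------------------------
# class-centroid extraction (follicle-style)
# ---------------------------------------------------------------------------

def extract_class_centroids(raster: CategoricalRaster, class_code: int,
                            min_area_px: int = 50,
                            min_circularity: float = 0.4) -> PointPattern:
    """Centroids of rounded structures of one class.

    The class is masked, holes are filled, connected components (8-conn) are
    kept when their area is at least ``min_area_px`` pixels and their
    circularity 4*pi*A/P^2 is at least ``min_circularity``, and the area
    centroids are returned as a point pattern in the raster's full-extent
    window (pixel-centre coordinates, scaled by the resolution).
    """
    if class_code not in raster.classes():
        raise ValueError(f"class {class_code} not present in raster")
    mask = (raster.values == class_code) & raster.valid_mask()
    filled = ndimage.binary_fill_holes(mask)
    labels, _ = ndimage.label(filled, structure=np.ones((3, 3), bool))
    res = raster.resolution
    nrows, ncols = raster.shape
    pts = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        perim = sk_perimeter(labels == prop.label)
        circ = 1.0 if perim == 0 else min(4.0 * np.pi * prop.area / perim ** 2, 1.0)
        if circ < min_circularity:
            continue
        r, c = prop.centroid
        pts.append(((c + 0.5) * res, (r + 0.5) * res))
    if not pts:
        warnings.warn("no component passed the area/circularity filters; "
                      "returning an empty pattern")
    window = Window(0.0, ncols * res, 0.0, nrows * res)
    return PointPattern(np.array(pts).reshape(-1, 2), window)


# ---------------------------------------------------------------------------
# tidy writers and the pipeline runner
# ---------------------------------------------------------------------------

def function_to_csv(est, path, lo: np.ndarray | None = None,
                    hi: np.ndarray | None = None) -> None:
    """Write a FunctionEstimate (plus optional envelope bands) as CSV."""
    df = pd.DataFrame({"r": est.r, "value": est.value})
    if lo is not None:
        df["lo"] = lo
    if hi is not None:
        df["hi"] = hi
    df.to_csv(path, index=False)


_KNOWN_KEYS = {"rasters", "points", "out_dir", "seed", "connectivity",
               "window", "functions", "correction", "n_sim", "envelope"}


def run_pipeline(config: dict) -> dict:
    """Run raster -> metrics and points -> functions analyses from a config.

    Config keys: ``rasters`` (list of {case_id, path}), ``points`` (list of
    {case_id, path}), ``window`` [x0, x1, y0, y1], ``functions`` (subset of
    K/L/F/G/J), ``correction``, ``connectivity``, ``n_sim``/``envelope``,
    ``seed``, ``out_dir``.  Unknown keys are rejected.  Writes tidy CSVs and
    a manifest (with the config hash) listing every output; reruns with the
    same config are bit-reproducible.
    """
    from .metrics import all_metrics, metric_tables_to_tidy
    from .points import csr_envelope, estimate_function, summary_stats

    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    outputs = []

    frames = []
    for entry in config.get("rasters", []):
        raster = read_label_image(entry["path"])
        tabs = all_metrics(raster, connectivity=config.get("connectivity", 8))
        tidy = metric_tables_to_tidy(
            [tabs["class"], tabs["landscape"]], case_id=entry["case_id"])
        comp = pd.DataFrame([
            {"case_id": entry["case_id"], "level": "landscape", "id": 0,
             "metric": k, "value": v}
            for k, v in tabs["complexity"].as_dict().items()])
        frames.append(pd.concat([tidy, comp], ignore_index=True))
    if frames:
        path = out_dir / "landscape_metrics.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        outputs.append(path.name)

    rows = []
    for entry in config.get("points", []):
        win = config.get("window")
        window = Window(*win) if win else None
        pp = read_points_csv(entry["path"], window)
        stats_row = summary_stats(pp)
        stats_row["case_id"] = entry["case_id"]
        rows.append(stats_row)
        for fn in config.get("functions", []):
            corr = config.get("correction")
            if config.get("envelope"):
                env = csr_envelope(pp, which=fn,
                                   n_sim=config.get("n_sim", 99),
                                   kind=config["envelope"], rng_seed=seed,
                                   correction=corr)
                est = estimate_function(pp, fn, env["r"], corr)
                path = out_dir / f"{entry['case_id']}_{fn}.csv"
                function_to_csv(est, path, env["lo"], env["hi"])
            else:
                est = estimate_function(pp, fn, correction=corr)
                path = out_dir / f"{entry['case_id']}_{fn}.csv"
                function_to_csv(est, path)
            outputs.append(path.name)
    if rows:
        path = out_dir / "point_summaries.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs.append(path.name)

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config_hash": cfg_hash, "seed": seed, "outputs": outputs}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest
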