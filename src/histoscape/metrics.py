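"""FRAGSTATS-style landscape metrics and information-theoretic complexity.

Metrics are computed at three levels from a :class:`~histoscape.raster.CategoricalRaster`:

* patch level   — area, perimeter, shape index, Euclidean nearest neighbour;
* class level   — PLAND, NP, PD, LPI, total edge, edge density, mean patch
  area, aggregation index (AI);
* landscape     — NP, TE, ED, mean patch area, LPI, Shannon diversity and
  evenness, Simpson diversity, area-weighted AI, contagion (CONTAG).

plus the four holistic complexity metrics (marginal, conditional and joint
entropy and mutual information, in bits) of the class co-occurrence
distribution.

Edge conventions
----------------
Perimeters count 4-neighbour pixel edges on the patch boundary, *including*
edges against nodata and against the image border, scaled by the raster
resolution.  Class-level total edge is the sum of its patch perimeters.
Landscape-level total edge counts each unlike interior edge once plus edges
against nodata; the outer image border is excluded (it is tissue extent, not
class edge).  Metrics that are undefined for a given landscape (e.g. SHEI
with one class, ENN with one patch) are reported as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import (
    AdjacencyCounts,
    CategoricalRaster,
    PatchLabeling,
    adjacency_counts,
    label_patches,
)

__all__ = [
    "MetricTable",
    "ComplexityMetrics",
    "patch_metrics",
    "class_metrics",
    "landscape_level_metrics",
    "complexity_metrics",
    "feature_vector",
    "metric_tables_to_tidy",
]


class DegenerateLandscapeError(ValueError):
    """Raised when the adjacency structure carries no information."""


@dataclass
class MetricTable:
    """A table of metric values at one analysis level.

    ``table`` is indexed by patch id, class code, or a singleton 0 for the
    landscape level; columns are metric names.  Undefined values are NaN.
    """

    level: str  # 'patch' | 'class' | 'landscape'
    table: pd.DataFrame


@dataclass
class ComplexityMetrics:
    """Holistic landscape complexity from the class co-occurrence matrix."""

    marginal_entropy: float
    conditional_entropy: float
    joint_entropy: float
    mutual_information: float
    relative_mutual_information: float

    def as_dict(self) -> dict:
        return {
            "marginal_entropy": self.marginal_entropy,
            "conditional_entropy": self.conditional_entropy,
            "joint_entropy": self.joint_entropy,
            "mutual_information": self.mutual_information,
            "relative_mutual_information": self.relative_mutual_information,
        }


def _patch_perimeters(labeling: PatchLabeling) -> dict:
    """Boundary edge count per patch (edges vs other patches, nodata, border)."""
    ids = labeling.patch_ids
    pad = np.pad(ids, 1, constant_values=0)
    per = {}
    core = pad[1:-1, 1:-1]
    boundary = np.zeros_like(core)
    for a, b in (((0, -2), (1, -1)), ((2, None), (1, -1)),
                 ((1, -1), (0, -2)), ((1, -1), (2, None))):
        nb = pad[a[0]:a[1], b[0]:b[1]]
        boundary += (nb != core)
    sel = core > 0
    for pid, edges in zip(core[sel], boundary[sel]):
        per[int(pid)] = per.get(int(pid), 0) + int(edges)
    return per


def patch_metrics(labeling: PatchLabeling, raster: CategoricalRaster) -> MetricTable:
    """Per-patch area, perimeter, shape index and nearest-neighbour distance.

    * ``area``: pixel count x resolution^2.
    * ``perimeter``: boundary edge count x resolution.
    * ``shape_index``: 0.25 * perimeter / sqrt(area); 1 for a square patch.
    * ``enn``: shortest pixel-centre-to-pixel-centre distance to another
      patch of the same class (NaN when the class has a single patch).
    """
    res = raster.resolution
    sizes = labeling.patch_sizes()
    perims = _patch_perimeters(labeling)
    pids = sorted(labeling.patch_class)

    # group patch pixel coordinates by class for ENN
    coords: dict[int, np.ndarray] = {}
    for pid in pids:
        rr, cc = np.nonzero(labeling.patch_ids == pid)
        coords[pid] = np.column_stack([cc + 0.5, rr + 0.5]) * res

    by_class: dict[int, list[int]] = {}
    for pid in pids:
        by_class.setdefault(labeling.patch_class[pid], []).append(pid)

    enn = {}
    for cls, members in by_class.items():
        if len(members) < 2:
            for pid in members:
                enn[pid] = np.nan
            continue
        for pid in members:
            others = np.vstack([coords[q] for q in members if q != pid])
            tree = cKDTree(others)
            d, _ = tree.query(coords[pid], k=1)
            enn[pid] = float(np.min(d))

    rows = []
    for pid in pids:
        area = sizes[pid] * res * res
        perim = perims[pid] * res
        rows.append({
            "patch_id": pid,
            "class": labeling.patch_class[pid],
            "area": area,
            "perimeter": perim,
            "shape_index": 0.25 * perim / np.sqrt(area),
            "enn": enn[pid],
        })
    df = pd.DataFrame(rows).set_index("patch_id")
    return MetricTable(level="patch", table=df)


def _max_like_adjacencies(area_px: int) -> int:
    """Maximum single-count like adjacencies for a class of given pixel area.

    Standard largest-integer-square construction: with n = floor(sqrt(a)) and
    m = a - n^2, the maximum is 2n(n-1), plus 2m-1 if 0 < m <= n, plus 2m-2
    if m > n.
    """
    n = int(np.floor(np.sqrt(area_px)))
    m = area_px - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def class_metrics(labeling: PatchLabeling, raster: CategoricalRaster) -> MetricTable:
    """Class-level aggregation and area/edge metrics."""
    res = raster.resolution
    valid = raster.valid_mask()
    total_px = int(valid.sum())
    total_area = total_px * res * res
    adj = adjacency_counts(raster)
    adj_index = {int(c): i for i, c in enumerate(adj.classes)}

    sizes = labeling.patch_sizes()
    perims = _patch_perimeters(labeling)
    by_class: dict[int, list[int]] = {}
    for pid, cls in labeling.patch_class.items():
        by_class.setdefault(cls, []).append(pid)

    rows = []
    for cls in sorted(by_class):
        members = by_class[cls]
        areas_px = np.array([sizes[p] for p in members])
        area_px = int(areas_px.sum())
        te = sum(perims[p] for p in members) * res
        g_ii = adj.counts[adj_index[cls], adj_index[cls]] // 2  # single count
        max_g = _max_like_adjacencies(area_px)
        ai = 100.0 * g_ii / max_g if max_g > 0 else np.nan
        rows.append({
            "class": cls,
            "pland": 100.0 * area_px / total_px,
            "np": len(members),
            "pd": len(members) / total_area,
            "lpi": 100.0 * areas_px.max() / total_px,
            "te": te,
            "ed": te / total_area,
            "area_mn": areas_px.mean() * res * res,
            "ai": ai,
        })
    df = pd.DataFrame(rows).set_index("class")
    return MetricTable(level="class", table=df)


def _landscape_total_edge(raster: CategoricalRaster) -> int:
    """Unlike interior edges (once) plus edges against nodata; border excluded."""
    v = raster.values
    valid = raster.valid_mask()
    te = 0
    for (va, vb, ma, mb) in (
        (v[:, :-1], v[:, 1:], valid[:, :-1], valid[:, 1:]),
        (v[:-1, :], v[1:, :], valid[:-1, :], valid[1:, :]),
    ):
        if va.size == 0:
            continue
        both = ma & mb
        te += int(((va != vb) & both).sum())
        te += int((ma ^ mb).sum())  # valid/nodata edges
    return te


def landscape_level_metrics(labeling: PatchLabeling,
                            raster: CategoricalRaster) -> MetricTable:
    """Whole-landscape composition, configuration and diversity metrics."""
    res = raster.resolution
    valid = raster.valid_mask()
    total_px = int(valid.sum())
    total_area = total_px * res * res
    props = np.array(sorted(
        np.unique(raster.values[valid], return_counts=True)[1] / total_px))
    m = len(props)

    cls_tab = class_metrics(labeling, raster).table
    sizes = np.array(list(labeling.patch_sizes().values()), float)

    shdi = float(-(props * np.log(props)).sum())
    shei = shdi / np.log(m) if m > 1 else np.nan
    simpson = float(1.0 - (props ** 2).sum())

    # area-weighted class aggregation index
    w = cls_tab["pland"] / 100.0
    ai_vals = cls_tab["ai"]
    ok = ai_vals.notna()
    ai_land = float((w[ok] * ai_vals[ok]).sum() / w[ok].sum()) if ok.any() else np.nan

    contag = _contagion(raster) if m > 1 else np.nan
    te = _landscape_total_edge(raster) * res

    df = pd.DataFrame([{
        "np": labeling.n_patches,
        "te": te,
        "ed": te / total_area,
        "area_mn": sizes.mean() * res * res,
        "lpi": 100.0 * sizes.max() / total_px,
        "shdi": shdi,
        "shei": shei,
        "sidi": simpson,
        "ai": ai_land,
        "contag": contag,
    }], index=[0])
    return MetricTable(level="landscape", table=df)


def _contagion(raster: CategoricalRaster) -> float:
    """FRAGSTATS contagion (percent) from class adjacency probabilities."""
    adj = adjacency_counts(raster)
    m = len(adj.classes)
    valid = raster.valid_mask()
    codes, counts = np.unique(raster.values[valid], return_counts=True)
    p = counts / counts.sum()
    g = adj.counts.astype(float)
    row_sum = g.sum(axis=1)
    if np.any(row_sum == 0):
        return np.nan
    pik = p[:, None] * g / row_sum[:, None]
    nz = pik > 0
    s = float((pik[nz] * np.log(pik[nz])).sum())
    return (1.0 + s / (2.0 * np.log(m))) * 100.0


def complexity_metrics(adjacency: AdjacencyCounts) -> ComplexityMetrics:
    """Entropy-based landscape complexity, in bits.

    The co-occurrence distribution p(i, j) is the normalised double-counted
    4-neighbour adjacency matrix.  Marginal entropy H(x) is taken over the
    row marginal (the adjacency-weighted class distribution); joint entropy
    H(x, y) over pairs; conditional H(y|x) = H(x, y) - H(x); mutual
    information I = H(x) - H(y|x); relative MI = I / H(x) (NaN when
    H(x) = 0, i.e. a single-class landscape).
    """
    total = adjacency.total
    if total == 0:
        raise DegenerateLandscapeError(
            "degenerate landscape: no pixel adjacencies to analyse")
    p = adjacency.counts / total
    px = p.sum(axis=1)

    def h(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hx = h(px)
    hxy = h(p.ravel())
    hcond = hxy - hx
    mi = hx - hcond
    rel = mi / hx if hx > 0 else np.nan
    return ComplexityMetrics(hx, hcond, hxy, mi, rel)


def metric_tables_to_tidy(tables: list[MetricTable], case_id: str) -> pd.DataFrame:
    """Concatenate metric tables into a tidy long table.

    Columns: case_id, level, id, metric, value.
    """
    frames = []
    for mt in tables:
        long = mt.table.reset_index().melt(
            id_vars=mt.table.index.name or "index",
            var_name="metric", value_name="value")
        long.columns = ["id", "metric", "value"]
        long.insert(0, "level", mt.level)
        long.insert(0, "case_id", case_id)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def feature_vector(raster: CategoricalRaster, connectivity: int = 8) -> dict:
    """Flat class+landscape+complexity metric dict for one raster.

    Keys are ``c<code>_<metric>`` for class-level metrics and the metric name
    for landscape-level and complexity metrics; the natural feature row for
    case-level machine-learning tables.
    """
    tabs = all_metrics(raster, connectivity)
    row: dict = {}
    for code, rec in tabs["class"].table.iterrows():
        for metric, value in rec.items():
            row[f"c{code}_{metric}"] = value
    for metric, value in tabs["landscape"].table.iloc[0].items():
        row[metric] = value
    row.update(tabs["complexity"].as_dict())
    return row


def all_metrics(raster: CategoricalRaster, connectivity: int = 8) -> dict:
    """Convenience: patch/class/landscape tables plus complexity metrics."""
    labeling = label_patches(raster, connectivity)
    adj = adjacency_counts(raster)
    return {
        "patch": patch_metrics(labeling, raster),
        "class": class_metrics(labeling, raster),
        "landscape": landscape_level_metrics(labeling, raster),
        "complexity": complexity_metrics(adj),
    }
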