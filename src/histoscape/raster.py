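"""Categorical rasters: classified histology images as landscapes.

A classified histological image (e.g. nuclei / cytoplasm / vascular channels)
is represented as a 2-D integer label map.  Pixel (row, col) maps to the
point (x = col + 0.5, y = row + 0.5) in pixel units, origin at the top-left
corner, y increasing downward.  This convention is used by every module in
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CategoricalRaster",
    "PatchLabeling",
    "AdjacencyCounts",
    "label_patches",
    "adjacency_counts",
    "class_proportions",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCT8 = np.ones((3, 3), bool)


class EmptyLandscapeError(ValueError):
    """Raised when a raster contains no analysable (non-nodata) pixels."""


@dataclass
class CategoricalRaster:
    """A 2-D map of integer class codes with a physical pixel size.

    Parameters
    ----------
    values
        2-D array of non-negative integer class codes.
    resolution
        Pixel edge length in physical units (default 1.0, i.e. pixels).
    nodata_code
        Optional code marking pixels outside the tissue; these pixels are
        excluded from every metric.
    class_names
        Optional mapping class code -> human-readable name.
    """

    values: np.ndarray
    resolution: float = 1.0
    nodata_code: int | None = None
    class_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.isfinite(self.values)):
                raise ValueError("class codes must be finite integers")
            as_int = self.values.astype(np.int64)
            if not np.array_equal(as_int, self.values):
                raise ValueError("class codes must be integers")
            self.values = as_int
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not self.valid_mask().any():
            raise EmptyLandscapeError("empty landscape: every pixel is nodata")

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of analysable pixels."""
        if self.nodata_code is None:
            return np.ones(self.values.shape, bool)
        return self.values != self.nodata_code

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def classes(self) -> np.ndarray:
        """Sorted class codes present in the raster (nodata excluded)."""
        return np.unique(self.values[self.valid_mask()])


@dataclass
class PatchLabeling:
    """Connected-component decomposition of a raster into patches.

    ``patch_ids`` has the raster's shape with 0 for nodata; patch ids are
    dense from 1.  ``patch_class`` maps patch id -> class code.
    """

    patch_ids: np.ndarray
    patch_class: dict
    connectivity: int

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    def patch_sizes(self) -> dict:
        ids, counts = np.unique(self.patch_ids[self.patch_ids > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class AdjacencyCounts:
    """Symmetric double-counted 4-neighbour class co-occurrence matrix.

    ``counts[i, j]`` is the number of ordered 4-neighbour pixel pairs
    (a, b) with class(a) = classes[i] and class(b) = classes[j]; pairs
    touching nodata are excluded.
    """

    classes: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def label_patches(raster: CategoricalRaster, connectivity: int = 8) -> PatchLabeling:
    """Decompose the raster into maximal same-class connected patches.

    Labelling is deterministic: classes are visited in ascending code order
    and components within a class in scan order, so ids are reproducible.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT4 if connectivity == 4 else _STRUCT8
    valid = raster.valid_mask()
    patch_ids = np.zeros(raster.shape, dtype=np.int64)
    patch_class: dict[int, int] = {}
    next_id = 1
    for code in raster.classes():
        mask = (raster.values == code) & valid
        lab, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        patch_ids[mask] = lab[mask] + (next_id - 1)
        for k in range(n):
            patch_class[next_id + k] = int(code)
        next_id += n
    return PatchLabeling(patch_ids=patch_ids, patch_class=patch_class,
                         connectivity=connectivity)


def adjacency_counts(raster: CategoricalRaster) -> AdjacencyCounts:
    """Count ordered 4-neighbour class pairs (double-count convention)."""
    classes = raster.classes()
    index = {int(c): i for i, c in enumerate(classes)}
    m = len(classes)
    counts = np.zeros((m, m), dtype=np.int64)
    v = raster.values
    valid = raster.valid_mask()

    def accumulate(a, b, va, vb):
        ok = va & vb
        if not ok.any():
            return
        ia = np.vectorize(index.__getitem__, otypes=[np.int64])(a[ok])
        ib = np.vectorize(index.__getitem__, otypes=[np.int64])(b[ok])
        np.add.at(counts, (ia, ib), 1)
        np.add.at(counts, (ib, ia), 1)

    if v.shape[1] > 1:  # horizontal neighbours
        accumulate(v[:, :-1], v[:, 1:], valid[:, :-1], valid[:, 1:])
    if v.shape[0] > 1:  # vertical neighbours
        accumulate(v[:-1, :], v[1:, :], valid[:-1, :], valid[1:, :])
    return AdjacencyCounts(classes=classes, counts=counts)


def class_proportions(raster: CategoricalRaster, mask: np.ndarray | None = None) -> dict:
    """Proportion of (non-nodata, optionally masked-in) pixels per class.

    Returns a mapping class code -> proportion; proportions sum to 1.
    """
    sel = raster.valid_mask()
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != raster.shape:
            raise ValueError("mask shape must match raster shape")
        sel = sel & mask
    total = int(sel.sum())
    if total == 0:
        raise ValueError("no pixels selected")
    codes, counts = np.unique(raster.values[sel], return_counts=True)
    return {int(c): n / total for c, n in zip(codes, counts)}
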