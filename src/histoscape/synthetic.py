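"""Synthetic tissue landscapes and annotation patterns with known ground truth.

These generators emulate every input the framework consumes — classified
label rasters with controllable clumpiness, point patterns with controllable
clustering or regularity, jittered hexagonal lobular lattices, and bipolar
pericentral scar fields — so every module can be exercised and calibrated
without image data.  All generators are seed-deterministic.

The clumpy raster uses a blur-and-threshold construction (Gaussian smoothing
of iid noise, thresholded at class-weight quantiles) rather than the
modified-random-clusters algorithm: it is simpler, gives exact marginal
class proportions, and is monotone in the clumpiness parameter, which is all
the metric calibrations require.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .microarch import make_scar_field
from .points import PointPattern, Window
from .raster import CategoricalRaster

__all__ = [
    "gen_clumpy_raster",
    "gen_point_process",
    "gen_lobular_lattice",
    "gen_scar_field",
]


def gen_clumpy_raster(shape: tuple, n_classes: int, clumpiness: float,
                      class_weights: np.ndarray | None = None,
                      seed: int | None = None,
                      resolution: float = 1.0) -> CategoricalRaster:
    """Random categorical raster with controllable spatial aggregation.

    An iid Gaussian field is blurred with sigma proportional to
    ``clumpiness`` (0 gives iid labels) and thresholded at the cumulative
    class-weight quantiles, so marginal class proportions match
    ``class_weights`` (default equal) up to rounding.
    """
    if len(shape) != 2 or min(shape) < 8:
        raise ValueError("shape must be at least 8x8")
    if not 0.0 <= clumpiness <= 1.0:
        raise ValueError("clumpiness must be in [0, 1]")
    if class_weights is None:
        class_weights = np.full(n_classes, 1.0 / n_classes)
    class_weights = np.asarray(class_weights, float)
    if len(class_weights) != n_classes:
        raise ValueError("one weight per class required")
    if not np.isclose(class_weights.sum(), 1.0):
        raise ValueError("class weights must sum to 1")

    rng = np.random.default_rng(seed)
    field = rng.standard_normal(shape)
    sigma = clumpiness * min(shape) / 16.0
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma)
    # quantile thresholding gives exact marginal proportions up to ties
    thresholds = np.quantile(field, np.cumsum(class_weights)[:-1])
    values = np.searchsorted(thresholds, field, side="right")
    return CategoricalRaster(values=values.astype(np.int32),
                             resolution=resolution)


def gen_point_process(kind: str, window: Window, params: dict,
                      seed: int | None = None) -> PointPattern:
    """Generate a point pattern: CSR, clustered, or inhibited.

    * ``poisson``: homogeneous Poisson with ``intensity`` (points per unit
      area); N ~ Poisson(intensity * |W|), positions uniform.
    * ``matern_cluster``: Poisson parents (``kappa`` per unit area, simulated
      on the window dilated by ``radius`` to avoid edge effects), each with
      Poisson(``mu``) offspring uniform in a disc of ``radius``; offspring
      clipped to the window.
    * ``inhibition``: simple sequential inhibition with hard-core distance
      ``hardcore`` toward ``n`` points; if the target cannot be reached
      within ``max_attempts`` proposals a partial pattern is returned with a
      warning.
    """
    rng = np.random.default_rng(seed)
    w = window

    def uniform(n, x0=w.x_min, x1=w.x_max, y0=w.y_min, y1=w.y_max):
        return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])

    if kind == "poisson":
        lam = params["intensity"]
        if lam <= 0:
            raise ValueError("intensity must be > 0")
        n = rng.poisson(lam * w.area)
        return PointPattern(uniform(n), w)

    if kind == "matern_cluster":
        kappa, mu, radius = params["kappa"], params["mu"], params["radius"]
        if min(kappa, mu, radius) <= 0:
            raise ValueError("kappa, mu and radius must be > 0")
        n_par = rng.poisson(kappa * (w.width + 2 * radius) * (w.height + 2 * radius))
        parents = uniform(n_par, w.x_min - radius, w.x_max + radius,
                          w.y_min - radius, w.y_max + radius)
        pts = []
        for p in parents:
            n_off = rng.poisson(mu)
            rho = radius * np.sqrt(rng.uniform(size=n_off))
            theta = rng.uniform(0, 2 * np.pi, n_off)
            pts.append(p + np.column_stack([rho * np.cos(theta),
                                            rho * np.sin(theta)]))
        pts = np.vstack(pts) if pts else np.empty((0, 2))
        inside = Window(w.x_min, w.x_max, w.y_min, w.y_max).contains(pts) \
            if len(pts) else np.array([], bool)
        return PointPattern(pts[inside], w)

    if kind == "inhibition":
        h, n_target = params["hardcore"], params["n"]
        if h <= 0:
            raise ValueError("hard-core distance must be > 0")
        if h >= w.short_side:
            raise ValueError("hard-core distance exceeds window scale")
        max_attempts = params.get("max_attempts", 10000 * n_target)
        pts: list = []
        attempts = 0
        while len(pts) < n_target and attempts < max_attempts:
            cand = uniform(1)[0]
            attempts += 1
            if all(np.hypot(*(cand - q)) >= h for q in pts):
                pts.append(cand)
        if len(pts) < n_target:
            warnings.warn(f"inhibition target n={n_target} unreachable; "
                          f"returning {len(pts)} points")
        return PointPattern(np.array(pts).reshape(-1, 2), w)

    raise ValueError(f"unknown point process kind {kind!r}")


def gen_lobular_lattice(window: Window, lobule_spacing: float,
                        jitter_sd: float = 0.0,
                        seed: int | None = None) -> dict:
    """Hexagonal lobular lattice: central veins with portal tracts at vertices.

    Central veins sit on a triangular lattice with spacing ``lobule_spacing``
    (s); portal tracts at the vertices of the surrounding regular hexagon
    (circumradius s/sqrt(3)), shared between adjacent lobules and
    deduplicated.  iid Gaussian jitter of sd ``jitter_sd`` is applied to all
    points (clamped to the window).  Only central veins whose 6 vertices fall
    inside the window are kept, so at jitter 0 every central's 6 nearest
    portals are exactly its own vertices.

    Returns ``{'centrals', 'portals', 'true_area', 'true_r'}`` where
    true_area = (sqrt(3)/2) * s^2 is the exact lattice hexagon area.
    """
    s = lobule_spacing
    if s >= window.short_side / 2:
        raise ValueError("lobule spacing must be < half the short window side")
    if jitter_sd >= s / 2:
        warnings.warn("jitter comparable to spacing: lobule identity overlaps")
    rng = np.random.default_rng(seed)
    circum = s / np.sqrt(3.0)
    vertex_angles = np.radians(np.arange(30, 360, 60))
    offsets = circum * np.column_stack([np.cos(vertex_angles),
                                        np.sin(vertex_angles)])

    row_h = s * np.sqrt(3.0) / 2.0
    centrals, portals = [], []
    n_rows = int(window.height / row_h) + 1
    n_cols = int(window.width / s) + 1
    for j in range(n_rows):
        y = window.y_min + circum + j * row_h
        for i in range(n_cols):
            x = window.x_min + i * s + (s / 2.0 if j % 2 else 0.0)
            verts = np.array([x, y]) + offsets
            if (verts[:, 0].min() >= window.x_min
                    and verts[:, 0].max() <= window.x_max
                    and verts[:, 1].min() >= window.y_min
                    and verts[:, 1].max() <= window.y_max):
                centrals.append((x, y))
                portals.extend(map(tuple, verts))
    if not centrals:
        raise ValueError("window too small for any complete lobule")
    centrals = np.array(centrals)
    portals = np.unique(np.round(np.array(portals), 12), axis=0)

    if jitter_sd > 0:
        centrals = centrals + rng.normal(0, jitter_sd, centrals.shape)
        portals = portals + rng.normal(0, jitter_sd, portals.shape)
        for arr in (centrals, portals):
            arr[:, 0] = np.clip(arr[:, 0], window.x_min, window.x_max)
            arr[:, 1] = np.clip(arr[:, 1], window.y_min, window.y_max)

    return {
        "centrals": PointPattern(centrals, window),
        "portals": PointPattern(portals, window),
        "true_r": circum,
        "true_area": (np.sqrt(3.0) / 2.0) * s * s,
    }


def gen_scar_field(n_cells: int, vein_radius: float, axis_deg: float,
                   bipolar_concentration: float, radial_decay: float,
                   seed: int | None = None, dominant_weight: float = 0.7,
                   ring_vertices: int = 64) -> dict:
    """Synthetic pericentral scar field with a planted bipolar axis.

    Cell polar angles are drawn from an axial von Mises mixture with modes at
    ``axis_deg`` and ``axis_deg + 180`` (weights ``dominant_weight`` and its
    complement; concentration ``bipolar_concentration``, 0 = uniform) and
    radial distances from the vein ring from Exponential(scale =
    ``radial_decay``).  The vein ring is a circle polyline.  Points are in
    image coordinates (y down).

    Returns ``{'field': ScarField, 'theta': axis_deg, 'weight', 'tau'}``.
    """
    if n_cells < 10:
        raise ValueError("need at least 10 cells")
    if bipolar_concentration < 0:
        raise ValueError("concentration must be >= 0")
    if not 0.5 <= dominant_weight <= 1.0:
        raise ValueError("dominant mode weight must be in [0.5, 1]")
    rng = np.random.default_rng(seed)
    tau = radial_decay
    d = rng.exponential(scale=tau, size=n_cells)
    extent = vein_radius + max(d.max() * 1.5, 6 * tau)
    cx = cy = extent + vein_radius

    is_dominant = rng.uniform(size=n_cells) < dominant_weight
    modes = np.where(is_dominant, axis_deg, axis_deg + 180.0)
    if bipolar_concentration == 0:
        phi = rng.uniform(0.0, 360.0, n_cells)
    else:
        dev = rng.vonmises(0.0, bipolar_concentration, n_cells)
        phi = (modes + np.degrees(dev)) % 360.0

    rad = np.radians(phi)
    rho = vein_radius + d
    cells = np.column_stack([cx + rho * np.cos(rad), cy - rho * np.sin(rad)])

    t = np.linspace(0, 2 * np.pi, ring_vertices, endpoint=False)
    ring = np.column_stack([cx + vein_radius * np.cos(t),
                            cy - vein_radius * np.sin(t)])
    field = make_scar_field(cells, ring)
    return {"field": field, "theta": axis_deg % 360.0,
            "weight": dominant_weight, "tau": tau}
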