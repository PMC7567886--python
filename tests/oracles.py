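"""Naive enumeration oracles, independent of the package implementation.

Everything here is written with plain Python loops over pixels, pairs and
edges so that it can be trusted by inspection on small inputs; it shares no
code path with histoscape.
"""

import math

import numpy as np


def flood_label(values, nodata, connectivity):
    """BFS connected-component labelling per class; ids dense from 1.

    Classes are visited in ascending code order and seeds in scan order,
    matching the documented deterministic labelling.
    """
    nrow, ncol = values.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    labels = np.zeros_like(values, dtype=int)
    patch_class = {}
    next_id = 1
    codes = sorted({int(v) for v in values.ravel() if v != nodata})
    for code in codes:
        for r0 in range(nrow):
            for c0 in range(ncol):
                if values[r0, c0] != code or labels[r0, c0] != 0:
                    continue
                stack = [(r0, c0)]
                labels[r0, c0] = next_id
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < nrow and 0 <= cc < ncol
                                and labels[rr, cc] == 0
                                and values[rr, cc] == code):
                            labels[rr, cc] = next_id
                            stack.append((rr, cc))
                patch_class[next_id] = code
                next_id += 1
    return labels, patch_class


def adjacency_matrix(values, nodata):
    """Double-counted 4-neighbour class co-occurrence (dict of dicts)."""
    nrow, ncol = values.shape
    counts = {}
    for r in range(nrow):
        for c in range(ncol):
            a = values[r, c]
            if a == nodata:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol:
                    b = values[rr, cc]
                    if b == nodata:
                        continue
                    counts.setdefault(int(a), {}).setdefault(int(b), 0)
                    counts[int(a)][int(b)] += 1
    return counts


def patch_area_perimeter(values, labels, pid):
    """Pixel count and boundary edge count (vs anything else) of one patch."""
    nrow, ncol = values.shape
    area = 0
    perim = 0
    for r in range(nrow):
        for c in range(ncol):
            if labels[r, c] != pid:
                continue
            area += 1
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrow and 0 <= cc < ncol):
                    perim += 1
                elif labels[rr, cc] != pid:
                    perim += 1
    return area, perim


def patch_enn(labels, patch_class, pid):
    """Min pixel-centre distance to another same-class patch (nan if none)."""
    cls = patch_class[pid]
    others = [q for q, k in patch_class.items() if k == cls and q != pid]
    if not others:
        return float("nan")
    own = list(zip(*np.nonzero(labels == pid)))
    best = float("inf")
    for q in others:
        for r1, c1 in own:
            for r2, c2 in zip(*np.nonzero(labels == q)):
                best = min(best, math.hypot(r1 - r2, c1 - c2))
    return best


def max_like_adjacencies(a):
    n = int(math.floor(math.sqrt(a)))
    m = a - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def class_level(values, nodata, resolution, connectivity):
    """Per-class PLAND/NP/PD/LPI/TE/ED/AREA_MN/AI by enumeration."""
    labels, patch_class = flood_label(values, nodata, connectivity)
    adj = adjacency_matrix(values, nodata)
    total_px = sum(1 for v in values.ravel() if v != nodata)
    total_area = total_px * resolution ** 2
    out = {}
    for cls in sorted({k for k in patch_class.values()}):
        pids = [p for p, k in patch_class.items() if k == cls]
        areas, perims = [], []
        for p in pids:
            a, pe = patch_area_perimeter(values, labels, p)
            areas.append(a)
            perims.append(pe)
        area_px = sum(areas)
        te = sum(perims) * resolution
        g_ii = adj.get(cls, {}).get(cls, 0) // 2
        mg = max_like_adjacencies(area_px)
        out[cls] = {
            "pland": 100.0 * area_px / total_px,
            "np": len(pids),
            "pd": len(pids) / total_area,
            "lpi": 100.0 * max(areas) / total_px,
            "te": te,
            "ed": te / total_area,
            "area_mn": (area_px / len(pids)) * resolution ** 2,
            "ai": 100.0 * g_ii / mg if mg > 0 else float("nan"),
        }
    return out


def landscape_level(values, nodata, resolution, connectivity):
    labels, patch_class = flood_label(values, nodata, connectivity)
    nrow, ncol = values.shape
    total_px = sum(1 for v in values.ravel() if v != nodata)
    total_area = total_px * resolution ** 2
    counts = {}
    for v in values.ravel():
        if v != nodata:
            counts[int(v)] = counts.get(int(v), 0) + 1
    props = [c / total_px for c in counts.values()]
    m = len(props)

    # total edge: unlike interior edges once, plus valid/nodata edges
    te = 0
    for r in range(nrow):
        for c in range(ncol):
            for rr, cc in ((r, c + 1), (r + 1, c)):
                if not (0 <= rr < nrow and 0 <= cc < ncol):
                    continue
                a, b = values[r, c], values[rr, cc]
                a_ok, b_ok = a != nodata, b != nodata
                if a_ok and b_ok and a != b:
                    te += 1
                elif a_ok != b_ok:
                    te += 1
    te *= resolution

    sizes = {}
    for pid in patch_class:
        sizes[pid] = int((labels == pid).sum())
    shdi = -sum(p * math.log(p) for p in props)
    cls = class_level(values, nodata, resolution, connectivity)
    wsum = 0.0
    asum = 0.0
    for code, rec in cls.items():
        if not math.isnan(rec["ai"]):
            wsum += rec["pland"] / 100.0
            asum += rec["pland"] / 100.0 * rec["ai"]
    out = {
        "np": len(patch_class),
        "te": te,
        "ed": te / total_area,
        "area_mn": (sum(sizes.values()) / len(sizes)) * resolution ** 2,
        "lpi": 100.0 * max(sizes.values()) / total_px,
        "shdi": shdi,
        "shei": shdi / math.log(m) if m > 1 else float("nan"),
        "sidi": 1.0 - sum(p * p for p in props),
        "ai": asum / wsum if wsum > 0 else float("nan"),
        "contag": contagion(values, nodata) if m > 1 else float("nan"),
    }
    return out


def contagion(values, nodata):
    adj = adjacency_matrix(values, nodata)
    total_px = sum(1 for v in values.ravel() if v != nodata)
    codes = sorted(adj)
    m = len(codes)
    counts = {c: int((values == c).sum()) for c in codes}
    s = 0.0
    for i in codes:
        gsum = sum(adj[i].values())
        if gsum == 0:
            return float("nan")
        for k in codes:
            pik = (counts[i] / total_px) * adj[i].get(k, 0) / gsum
            if pik > 0:
                s += pik * math.log(pik)
    return (1.0 + s / (2.0 * math.log(m))) * 100.0


def complexity(values, nodata):
    """Entropies (bits) of the co-occurrence distribution, by enumeration."""
    adj = adjacency_matrix(values, nodata)
    total = sum(v for row in adj.values() for v in row.values())
    probs = {(i, j): v / total for i, row in adj.items() for j, v in row.items()}
    marg = {}
    for (i, _j), p in probs.items():
        marg[i] = marg.get(i, 0.0) + p
    hx = -sum(p * math.log2(p) for p in marg.values() if p > 0)
    hxy = -sum(p * math.log2(p) for p in probs.values() if p > 0)
    return {
        "marginal_entropy": hx,
        "conditional_entropy": hxy - hx,
        "joint_entropy": hxy,
        "mutual_information": hx - (hxy - hx),
        "relative_mutual_information":
            (2 * hx - hxy) / hx if hx > 0 else float("nan"),
    }


def k_uncorrected(points, area, r_values):
    """Ripley K without edge correction by explicit pair enumeration."""
    pts = np.asarray(points, float)
    n = len(pts)
    out = []
    for r in r_values:
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if math.hypot(*(pts[i] - pts[j])) <= r:
                    count += 1
        out.append(area / (n * (n - 1)) * count)
    return np.array(out)


def circle_fraction_numeric(cx, cy, r, x0, x1, y0, y1, n_angles=20000):
    """Fraction of a circle's circumference inside a rectangle, numerically."""
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    return inside.mean()
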