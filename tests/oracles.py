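"""Independent brute-force oracles used to check the fast implementations.

Each function here is written in the most literal way possible (explicit
loops, exhaustive enumeration) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_disk_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by an exact Euclidean disk, double loop.

    Out-of-image positions are ignored (min/max over the in-bounds part
    of the disk).
    """
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]

    def erode(a):
        out = np.empty_like(a)
        for r in range(rows):
            for c in range(cols):
                vals = [
                    a[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < rows and 0 <= c + dc < cols
                ]
                out[r, c] = min(vals)
        return out

    def dilate(a):
        out = np.empty_like(a)
        for r in range(rows):
            for c in range(cols):
                vals = [
                    a[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < rows and 0 <= c + dc < cols
                ]
                out[r, c] = max(vals)
        return out

    return dilate(erode(img))


def brute_otsu(pixels: np.ndarray) -> int:
    """Exhaustive argmax of between-class variance over all cut points."""
    flat = np.asarray(pixels).ravel().astype(float)
    n_levels = 256 if flat.max() <= 255 else 65536
    best_v, best_t = -1.0, -1
    for t in range(n_levels):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if hi.size == 0:
            continue
        v = 0.0 if lo.size == 0 else lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def brute_remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """8-connected component labeling by BFS + size filter, pure python."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = [(r0, c0)]
            seen[r0, c0] = True
            head = 0
            while head < len(comp):
                r, c = comp[head]
                head += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < rows
                            and 0 <= cc < cols
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            comp.append((rr, cc))
            if len(comp) >= min_area:
                for r, c in comp:
                    out[r, c] = True
    return out


def _neighbors8(r, c, mask):
    rows, cols = mask.shape
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                out.append((rr, cc))
    return out


def brute_path_length(skel: np.ndarray, pixel_size: float) -> float:
    """Neighbor-walk length of a union of simple 1-px paths.

    Walks each path from an endpoint, summing 1 or sqrt(2) per step.
    Only valid for masks whose components are simple open paths.
    """
    skel = np.asarray(skel, dtype=bool)
    visited = np.zeros_like(skel)
    total = 0.0
    coords = list(zip(*np.nonzero(skel)))
    endpoints = [p for p in coords if len(_neighbors8(*p, skel)) == 1]
    for start in endpoints:
        if visited[start]:
            continue
        visited[start] = True
        prev, cur = None, start
        while True:
            nxt = [
                q for q in _neighbors8(*cur, skel) if q != prev and not visited[q]
            ]
            if not nxt:
                break
            q = nxt[0]
            total += (
                math.sqrt(2.0) if (q[0] != cur[0] and q[1] != cur[1]) else 1.0
            ) * pixel_size
            visited[q] = True
            prev, cur = cur, q
    return total


def brute_prune(skel: np.ndarray, min_len_px: float) -> np.ndarray:
    """Repeated leaf-chain deletion to a fixpoint.

    From each endpoint, walk through degree-2 pixels until a junction
    pixel (degree >= 3) is met; if the chain's geometric length,
    including the final step onto the junction, is below the threshold,
    delete the chain (junction kept) and re-thin.  Independent of the
    package's segment-tracing machinery.
    """
    from skimage.morphology import skeletonize as _thin

    skel = np.asarray(skel, dtype=bool).copy()
    while True:
        removed = False
        deg = {
            p: len(_neighbors8(*p, skel)) for p in zip(*np.nonzero(skel))
        }
        endpoints = [p for p, d in deg.items() if d == 1]
        for start in endpoints:
            if not skel[start]:
                continue
            chain = [start]
            length = 0.0
            prev, cur = None, start
            hit_junction = False
            while True:
                nbrs = [q for q in _neighbors8(*cur, skel) if q != prev]
                junctions = [q for q in nbrs if deg.get(q, 0) >= 3]
                if junctions:
                    q = junctions[0]
                    length += (
                        math.sqrt(2.0) if (q[0] != cur[0] and q[1] != cur[1]) else 1.0
                    )
                    hit_junction = True
                    break
                if len(nbrs) != 1:
                    break  # isolated chain or dead end: not a spur
                q = nbrs[0]
                length += (
                    math.sqrt(2.0) if (q[0] != cur[0] and q[1] != cur[1]) else 1.0
                )
                chain.append(q)
                prev, cur = cur, q
            if hit_junction and length < min_len_px:
                for p in chain:
                    skel[p] = False
                removed = True
        if not removed:
            return skel
        skel = _thin(skel)


def brute_anova(groups):
    """One-way fixed-effects ANOVA by explicit sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return ssb / dfb, ssw / dfw, dfb, dfw


def t_sf_numeric(t: float, df: float) -> float:
    """Upper-tail t probability by numerical integration of the density."""
    from scipy.integrate import quad
    from math import gamma, sqrt, pi

    norm = gamma((df + 1) / 2) / (sqrt(df * pi) * gamma(df / 2))

    def pdf(x):
        return norm * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = quad(pdf, t, np.inf)
    return val


def gaussian_kernel_1d(sigma: float, order: int) -> np.ndarray:
    """The sampled Gaussian (or its derivative) as a correlation kernel."""
    r = int(4 * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    phi = np.exp(-(x**2) / (2 * sigma**2))
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return (x / sigma**2) * phi  # correlation form of the derivative
    raise ValueError(order)


def correlate_sym(img: np.ndarray, k1d: np.ndarray, axis: int) -> np.ndarray:
    """Plain 1D correlation with symmetric (reflect) padding, loops."""
    r = (len(k1d) - 1) // 2
    pad = [(0, 0), (0, 0)]
    pad[axis] = (r, r)
    p = np.pad(img, pad, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            if axis == 1:
                out[i, j] = (p[i, j : j + 2 * r + 1] * k1d).sum()
            else:
                out[i, j] = (p[i : i + 2 * r + 1, j] * k1d).sum()
    return out


def brute_structure_tensor(img: np.ndarray, sg: float, sw: float):
    """Structure tensor via explicit separable kernels (y-up convention)."""
    img = np.asarray(img, dtype=float)
    g = gaussian_kernel_1d(sg, 0)
    d = gaussian_kernel_1d(sg, 1)
    gx = correlate_sym(correlate_sym(img, d, 1), g, 0)
    gy = -correlate_sym(correlate_sym(img, d, 0), g, 1)
    w = gaussian_kernel_1d(sw, 0)

    def smooth(a):
        return correlate_sym(correlate_sym(a, w, 0), w, 1)

    return smooth(gx * gx), smooth(gx * gy), smooth(gy * gy)
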