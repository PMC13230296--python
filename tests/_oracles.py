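"""Independent brute-force re-implementations used as test oracles.

Everything here is written with explicit Python loops over enumerated
voxel sets, deliberately sharing no code with the package internals.
Only usable on small arrays.
"""

import math

import numpy as np

FACES = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def brute_ring(fg: np.ndarray, width: int) -> np.ndarray:
    """Voxels within `width` 6-connected dilation steps of fg, minus fg."""
    current = {tuple(v) for v in np.argwhere(fg)}
    grown = set(current)
    shape = fg.shape
    for _ in range(width):
        new = set()
        for (i, j, k) in grown:
            for di, dj, dk in FACES:
                w = (i + di, j + dj, k + dk)
                if 0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]:
                    new.add(w)
        grown |= new
    ring = np.zeros(shape, bool)
    for v in grown - current:
        ring[v] = True
    return ring


def brute_ace(values: np.ndarray, fg: np.ndarray, width: int) -> float:
    ring = brute_ring(fg, width)
    a = [float(values[tuple(v)]) for v in np.argwhere(fg)]
    r = [float(values[tuple(v)]) for v in np.argwhere(ring)]
    return sum(a) / len(a) - sum(r) / len(r)


def brute_cnr(values: np.ndarray, fg: np.ndarray, width: int) -> float:
    ring = brute_ring(fg, width)
    a = [float(values[tuple(v)]) for v in np.argwhere(fg)]
    r = [float(values[tuple(v)]) for v in np.argwhere(ring)]
    mr = sum(r) / len(r)
    sd = math.sqrt(sum((x - mr) ** 2 for x in r) / len(r))
    return (sum(a) / len(a) - mr) / sd


def brute_edge_sharpness(values: np.ndarray, fg: np.ndarray, spacing) -> float:
    values = values.astype(np.float64)
    shape = values.shape
    grads = []
    for (i, j, k) in np.argwhere(fg):
        if i in (0, shape[0] - 1) or j in (0, shape[1] - 1) or k in (0, shape[2] - 1):
            continue
        if not any(not fg[i + d[0], j + d[1], k + d[2]] for d in FACES):
            continue
        g = [
            (values[i + 1, j, k] - values[i - 1, j, k]) / (2 * spacing[0]),
            (values[i, j + 1, k] - values[i, j - 1, k]) / (2 * spacing[1]),
            (values[i, j, k + 1] - values[i, j, k - 1]) / (2 * spacing[2]),
        ]
        grads.append(math.sqrt(sum(x * x for x in g)))
    return sum(grads) / len(grads)


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(v) for v in np.argwhere(a)}
    sb = {tuple(v) for v in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def brute_branch_assignment(pred: np.ndarray, points_world, codes, spacing) -> dict:
    """Assign each predicted voxel the code of its nearest centreline point."""
    assigned = {}
    for v in np.argwhere(pred):
        w = (v[0] * spacing[0], v[1] * spacing[1], v[2] * spacing[2])
        best, best_d = None, None
        for p, c in zip(points_world, codes):
            d = (w[0] - p[0]) ** 2 + (w[1] - p[1]) ** 2 + (w[2] - p[2]) ** 2
            if best_d is None or d < best_d:
                best, best_d = c, d
        assigned[tuple(v)] = best
    return assigned


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_welch(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    t = (ma - mb) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
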