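"""Independent brute-force oracles used to check the package's algorithms.

These deliberately avoid the implementation's machinery (no sparse graphs,
no priority queues, no vectorised zonal math): plain loops and fixpoint
iteration only.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def edge_minutes(speed, a, b, cell_size, elev=None, walking=None):
    """Travel minutes for one move a -> b (center-to-center, mean of the two
    cells' time-per-metre, Tobler-corrected on walking cells)."""
    (r1, c1), (r2, c2) = a, b
    dist = cell_size * math.sqrt((r1 - r2) ** 2 + (c1 - c2) ** 2)
    tpms = []
    for (r, c) in (a, b):
        v = speed[r][c]  # km/h
        tpm = 0.06 / v  # minutes per metre
        if elev is not None and walking is not None and walking[r][c]:
            s = (elev[r2][c2] - elev[r1][c1]) / dist
            factor = math.exp(-3.5 * abs(s + 0.05)) / math.exp(-3.5 * 0.05)
            tpm /= factor
        tpms.append(tpm)
    return dist * (tpms[0] + tpms[1]) / 2.0


def value_iteration_times(speed, origins, cell_size, elev=None, walking=None):
    """Shortest time from every cell to the nearest origin by min-plus
    fixpoint iteration (Bellman-Ford style, no priority queue)."""
    nr, nc = len(speed), len(speed[0])
    t = [[math.inf] * nc for _ in range(nr)]
    for (r, c) in origins:
        t[r][c] = 0.0
    for _ in range(nr * nc):
        changed = False
        for r in range(nr):
            for c in range(nc):
                if speed[r][c] <= 0:
                    continue
                for dr, dc in OFFSETS:
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc and speed[r2][c2] > 0:
                        cand = edge_minutes(speed, (r, c), (r2, c2), cell_size, elev, walking) + t[r2][c2]
                        if cand < t[r][c] - 1e-15:
                            t[r][c] = cand
                            changed = True
        if not changed:
            break
    return np.array(t)


def enumerate_simple_path_times(speed, origin, cell_size):
    """Exact minimum over ALL simple paths to the origin (tiny grids only)."""
    nr, nc = len(speed), len(speed[0])
    best = [[math.inf] * nc for _ in range(nr)]
    orr, orc = origin
    best[orr][orc] = 0.0

    def walk(r, c, cost, seen):
        if cost < best[r][c]:
            best[r][c] = cost
        for dr, dc in OFFSETS:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and speed[r2][c2] > 0 and (r2, c2) not in seen:
                e = edge_minutes(speed, (r2, c2), (r, c), cell_size)
                walk(r2, c2, cost + e, seen | {(r2, c2)})

    if speed[orr][orc] > 0:
        walk(orr, orc, 0.0, {(orr, orc)})
    return np.array(best)


def naive_band_tally(tt, pop, zones, bands, zone_nodata):
    """Per-cell loop tally of persons per zone per travel-time band."""
    out: dict = {}
    nr, nc = tt.shape
    for r in range(nr):
        for c in range(nc):
            z = zones[r][c]
            if z == zone_nodata or pop[r][c] <= 0:
                continue
            t = tt[r][c]
            if not np.isfinite(t):
                b = len(bands)
            else:
                b = len(bands)
                for i, edge in enumerate(bands):
                    if t <= edge:
                        b = i
                        break
            key = (int(z), b)
            out[key] = out.get(key, 0.0) + pop[r][c]
    return out


def naive_membership(fac_tt, transfusing, threshold):
    """Per-pair loop recount of (n_low_level, k_competing)."""
    res = {}
    for j in fac_tt.columns:
        n = k = 0
        for i in fac_tt.index:
            if fac_tt.loc[i, j] <= threshold:
                if transfusing[i]:
                    if i != j:
                        k += 1
                else:
                    n += 1
        res[j] = (n, k)
    return res


def pearson_by_hand(x, y):
    """Covariance over product of standard deviations, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)
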