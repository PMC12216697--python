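"""Brute-force oracles, independent of the library code paths they check."""

import numpy as np


def oracle_line_length(lines, center, radius, n=10_000):
    """Dense point-sampling: fraction of each segment inside the disk."""
    total = 0.0
    for line in lines:
        coords = np.asarray(line.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            t = (np.arange(n) + 0.5) / n
            pts = a[None, :] + t[:, None] * (b - a)[None, :]
            inside = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) <= radius
            total += inside.mean() * np.hypot(*(b - a))
    return total


def oracle_point_count(points, center, radius):
    return sum(
        1 for p in points if np.hypot(p.x - center[0], p.y - center[1]) <= radius
    )


def oracle_raster_mean(grid, center, radius):
    vals = []
    for i in range(grid.ny):
        for j in range(grid.nx):
            x, y = grid.center_of(i, j)
            if (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2:
                vals.append(grid.values[i, j])
    return np.mean(vals) if vals else None


def oracle_distance(center, lines, spacing=1.0):
    """Brute-force min distance via densified vertices."""
    best = np.inf
    for line in lines:
        coords = np.asarray(line.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            seg_len = np.hypot(*(b - a))
            n = max(2, int(seg_len / spacing))
            t = np.linspace(0, 1, n)
            pts = a[None, :] + t[:, None] * (b - a)[None, :]
            d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]).min()
            best = min(best, d)
    return best
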