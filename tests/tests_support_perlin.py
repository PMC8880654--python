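"""Shared independent oracle: direct scalar evaluation of gradient noise.

Deliberately written with explicit corner weights (not the lerp chain used
by the package) so it constitutes a second, independent route to the same
mathematical definition.
"""

import math


def _ease(t: float) -> float:
    return 3.0 * t * t - 2.0 * t**3


def reference_perlin_value(angles, grid_cells, x_cm, y_cm, side_cm):
    cell = side_cm / grid_cells
    u, v = x_cm / cell, y_cm / cell
    i = min(int(math.floor(u)), grid_cells - 1)
    j = min(int(math.floor(v)), grid_cells - 1)
    fx, fy = u - i, v - j
    total = 0.0
    for dj in (0, 1):
        for di in (0, 1):
            a = angles[j + dj, i + di]
            dot = math.cos(a) * (fx - di) + math.sin(a) * (fy - dj)
            wx = _ease(fx) if di else 1.0 - _ease(fx)
            wy = _ease(fy) if dj else 1.0 - _ease(fy)
            total += wx * wy * dot
    return total
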