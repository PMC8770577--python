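"""Polygon helpers shared by the pipeline/training/acceptance tests."""

import math

import numpy as np


def rect_polygon(w: float, h: float, angle_deg: float = 0.0,
                 center=(40.0, 40.0)) -> np.ndarray:
    """Closed rectangle contour in (row, col) coordinates, rotated about its
    centre by ``angle_deg`` (positive = counter-clockwise in x-y)."""
    th = math.radians(angle_deg)
    pts = []
    for x, y in [(-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2),
                 (-w / 2, h / 2)]:
        xr = x * math.cos(th) - y * math.sin(th)
        yr = x * math.sin(th) + y * math.cos(th)
        pts.append((center[0] + yr, center[1] + xr))
    pts.append(pts[0])
    return np.array(pts)


def circle_polygon(r: float, n: int = 200, center=(40.0, 40.0)) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * math.pi, n + 1)
    return np.stack([center[0] + r * np.sin(ang),
                     center[1] + r * np.cos(ang)], axis=1)
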