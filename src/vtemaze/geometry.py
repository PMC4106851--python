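"""Low-level 2-D geometry for the T-maze: ray casting, segment tests.

All walls are axis-aligned line segments; everything here is vectorized
over rays and/or segments with plain numpy broadcasting.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "ray_segments_first_hit",
    "segment_disc_intersects",
    "wrap_angle",
]


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), 2.0 * np.pi)


def ray_segments_first_hit(origin, dirs, seg_a, seg_b):
    """First intersection of rays with a set of segments.

    Parameters
    ----------
    origin : (2,) array
        Common ray origin.
    dirs : (R, 2) array
        Unit (or any nonzero) ray directions.
    seg_a, seg_b : (S, 2) arrays
        Segment endpoints.

    Returns
    -------
    dist : (R,) array
        Distance along each ray to the closest segment hit (inf if none).
    index : (R,) int array
        Index of the segment hit (-1 if none).
    """
    origin = np.asarray(origin, dtype=float)
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)

    # Solve origin + t*d = a + s*(b-a), 0<=s<=1, t>0.
    e = b - a                                   # (S,2)
    ao = a[None, :, :] - origin[None, None, :]  # (1,S,2) broadcastable
    d = dirs[:, None, :]                        # (R,1,2)
    denom = d[..., 0] * (-e[None, :, 1]) - d[..., 1] * (-e[None, :, 0])  # (R,S)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[..., 0] * (-e[None, :, 1]) - ao[..., 1] * (-e[None, :, 0])) / denom
        s = (d[..., 0] * ao[..., 1] - d[..., 1] * ao[..., 0]) / denom
    valid = (np.abs(denom) > 1e-300) & (t > 1e-9) & (s >= -1e-12) & (s <= 1 + 1e-12)
    t = np.where(valid, t, np.inf)
    index = np.argmin(t, axis=1)
    dist = t[np.arange(t.shape[0]), index]
    index = np.where(np.isfinite(dist), index, -1)
    return dist, index


def segment_disc_intersects(p0, p1, center, radius):
    """True where segment [p0, p1] comes within `radius` of `center`.

    p0, p1 may be (N, 2) arrays of N segments; center is a single point.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    c = np.asarray(center, dtype=float)
    d = p1 - p0
    f = c[None, :] - p0
    dd = np.einsum("ij,ij->i", d, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.clip(np.einsum("ij,ij->i", f, d) / dd, 0.0, 1.0)
    t = np.where(dd > 0, t, 0.0)
    closest = p0 + t[:, None] * d
    dist2 = np.einsum("ij,ij->i", (closest - c[None, :]), (closest - c[None, :]))
    return dist2 <= radius * radius


def point_rect_distance(px, py, x0, x1, y0, y1):
    """Euclidean distance from a point to an axis-aligned rectangle (0 inside)."""
    dx = max(x0 - px, 0.0, px - x1)
    dy = max(y0 - py, 0.0, py - y1)
    return math.hypot(dx, dy)
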