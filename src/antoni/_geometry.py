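"""Exact circle/rectangle intersection areas (vectorised).

Used for the edge correction of the cross-pair correlation function: the
area of the annulus [r, r+dr) around each cell intersected with the
rectangular observation window, by closed-form geometry rather than Monte
Carlo, so results are deterministic and testable against numerical
integration.
"""

from __future__ import annotations

import numpy as np


def _half_plane_area(x, r):
    """Area of a radius-``r`` disc (centred at origin) with X <= x."""
    x = np.clip(x, -r, r)
    return x * np.sqrt(np.maximum(r * r - x * x, 0.0)) + r * r * np.arcsin(
        np.divide(x, r, out=np.zeros_like(x), where=r > 0)
    ) + np.pi * r * r / 2.0


def _corner_pos(x, y, r):
    """Area of disc with X >= x, Y >= y, valid for x, y >= 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = x * x + y * y < r * r
    x2 = np.sqrt(np.maximum(r * r - y * y, 0.0))

    def F(t):  # antiderivative of sqrt(r^2 - t^2)
        t = np.clip(t, -r, r)
        return 0.5 * (
            t * np.sqrt(np.maximum(r * r - t * t, 0.0))
            + r * r * np.arcsin(np.divide(t, r, out=np.zeros_like(t), where=r > 0))
        )

    area = F(x2) - F(np.minimum(x, x2)) - y * np.maximum(x2 - x, 0.0)
    return np.where(inside, area, 0.0)


def _corner(x, y, r):
    """Area of disc with X >= x, Y >= y, any signs (reflection recursion)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    disc = np.pi * r * r
    xp, yp = np.abs(x), np.abs(y)
    base_pp = _corner_pos(xp, yp, r)
    # x>=0, y>=0 -> base ; x<0,y>=0 -> (disc - C(y-halfplane)) - base(-x, y)
    a_np = (disc - _half_plane_area(y, r)) - base_pp  # for x < 0, y >= 0
    a_pn = (disc - _half_plane_area(x, r)) - base_pp  # for x >= 0, y < 0
    a_nn = _half_plane_area(-y, r) - _half_plane_area(x, r) + base_pp  # x<0, y<0
    out = np.where(
        x >= 0,
        np.where(y >= 0, base_pp, a_pn),
        np.where(y >= 0, a_np, a_nn),
    )
    return out


def circle_rectangle_area(cx, cy, r: float, width: float, height: float):
    """Area of the disc of radius ``r`` centred at (cx, cy) intersected
    with the rectangle [0, width] x [0, height].  Vectorised over centres.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    if r <= 0:
        return np.zeros(np.broadcast(cx, cy).shape)

    def G(x, y):  # disc area with X <= x, Y <= y (circle at origin)
        return (
            _half_plane_area(x, r)
            + _half_plane_area(y, r)
            - np.pi * r * r
            + _corner(x, y, r)
        )

    ax, bx = -cx, width - cx
    ay, by = -cy, height - cy
    return G(bx, by) - G(ax, by) - G(bx, ay) + G(ax, ay)


def annulus_rectangle_area(cx, cy, r_in: float, r_out: float, width: float, height: float):
    """Window-clipped annulus areas, vectorised over annulus centres."""
    return circle_rectangle_area(cx, cy, r_out, width, height) - circle_rectangle_area(
        cx, cy, r_in, width, height
    )
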