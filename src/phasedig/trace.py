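"""Boundary-curve reconstruction from user guide points.

The user marks a handful of points along one boundary curve of the cleaned
drawing (from a file, in order).  Each point snaps to the nearest ink pixel;
consecutive snapped points lying on the same 8-connected line component are
joined by a fewest-steps path through that component only (4-connected
moves, white pixels are walls), so the traced piece is always a subset of
the original curve.  Points that fall in different components are joined by
a straight rasterized segment instead.  The union of the pieces is the
reconstructed curve; overlaying all curves plus the frame rebuilds the
diagram.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .exceptions import RoutingError, SnapError
from .image import EIGHT_CONNECTED, add_frame, _as_mask

__all__ = ["Curve", "snap", "trace_curve", "overlay"]

#: BFS neighbor order: up, down, left, right.
_STEPS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class Curve:
    """One reconstructed boundary curve."""

    mask: np.ndarray
    endpoints: tuple[tuple[int, int], tuple[int, int]]


def snap(
    point: tuple[float, float],
    mask: np.ndarray,
    border_margin: int = 2,
) -> tuple[int, int]:
    """Snap a guide point to the nearest ink pixel (ties: raster order).

    If the snapped pixel sits within *border_margin* of the image border and
    has an 8-connected ink neighbor on the border itself, that border pixel
    is returned instead, so curves that run into the frame attach to it.
    """
    mask = _as_mask(mask)
    ink = np.argwhere(mask == 1)  # raster order
    if ink.size == 0:
        raise SnapError("cannot snap: the mask has no ink pixels")
    p = np.asarray(point, dtype=float)
    d2 = ((ink - p) ** 2).sum(axis=1)
    best = ink[int(np.argmin(d2))]  # argmin keeps the first (raster) minimum
    r, c = int(best[0]), int(best[1])
    h, w = mask.shape
    near_border = min(r, c, h - 1 - r, w - 1 - c) <= border_margin
    on_border = r in (0, h - 1) or c in (0, w - 1)
    if near_border and not on_border:
        candidates = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    if rr in (0, h - 1) or cc in (0, w - 1):
                        candidates.append((abs(dr) + abs(dc), rr, cc))
        if candidates:  # nearest on-frame neighbor, raster order on ties
            _, rr, cc = min(candidates)
            return rr, cc
    return r, c


def _bfs_path(
    start: tuple[int, int],
    goal: tuple[int, int],
    passable: np.ndarray,
) -> list[tuple[int, int]]:
    """Fewest-4-connected-steps path on *passable* pixels, or raise KeyError."""
    h, w = passable.shape
    parent: dict[tuple[int, int], tuple[int, int] | None] = {start: None}
    queue: deque[tuple[int, int]] = deque([start])
    while queue:
        cur = queue.popleft()
        if cur == goal:
            path = []
            node: tuple[int, int] | None = cur
            while node is not None:
                path.append(node)
                node = parent[node]
            return path[::-1]
        r, c = cur
        for dr, dc in _STEPS:
            nxt = (r + dr, c + dc)
            if (
                0 <= nxt[0] < h
                and 0 <= nxt[1] < w
                and passable[nxt]
                and nxt not in parent
            ):
                parent[nxt] = cur
                queue.append(nxt)
    raise KeyError(goal)


def trace_curve(
    points: Sequence[tuple[float, float]],
    mask: np.ndarray,
    labeled_lines: np.ndarray | None = None,
    border_margin: int = 2,
    snap_points: bool = True,
) -> Curve:
    """Reconstruct one curve from ordered guide points.

    *labeled_lines* labels the 8-connected ink components (computed from
    *mask* when omitted).  For each consecutive pair of snapped points: a
    fewest-steps path through their shared component when they share one, a
    straight segment otherwise.  Any fewest-steps path is acceptable; the
    one found by the fixed up/down/left/right neighbor order is kept.
    """
    if len(points) < 2:
        raise ValueError("a curve needs at least two guide points")
    mask = _as_mask(mask)
    if labeled_lines is None:
        labeled_lines, _ = ndimage.label(mask, structure=EIGHT_CONNECTED)
    snapped = [
        snap(p, mask, border_margin) if snap_points else (int(p[0]), int(p[1]))
        for p in points
    ]
    out = np.zeros_like(mask)
    for a, b in zip(snapped[:-1], snapped[1:]):
        lab_a, lab_b = labeled_lines[a], labeled_lines[b]
        if lab_a == lab_b and lab_a != 0:
            passable = labeled_lines == lab_a
            try:
                path = _bfs_path(a, b, passable)
            except KeyError:
                raise RoutingError(
                    f"no 4-connected path between {a} and {b}: their line "
                    "component is connected only diagonally there"
                ) from None
            for pix in path:
                out[pix] = 1
        else:
            rr, cc = skdraw.line(a[0], a[1], b[0], b[1])
            out[rr, cc] = 1
    return Curve(mask=out, endpoints=(snapped[0], snapped[-1]))


def overlay(curves: Sequence[Curve], height: int, width: int) -> np.ndarray:
    """Pixelwise union of curves plus the frame rectangle."""
    out = np.zeros((height, width), dtype=np.uint8)
    for curve in curves:
        if curve.mask.shape != (height, width):
            raise ValueError(
                f"curve shape {curve.mask.shape} does not match frame "
                f"({height}, {width})"
            )
        out |= curve.mask.astype(np.uint8)
    return add_frame(out)
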