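"""Raster processing: raw diagram image -> rectified, cleaned, labeled regions.

The processing convention throughout is that of a scanned line drawing: a
binary mask holds ``1`` (black ink) on phase-boundary lines and ``0`` (white
paper) inside phase domains.  Boundary lines are treated as 8-connected and
phase domains as 4-connected, which prevents a domain from "tunneling"
diagonally through a line that is only diagonally connected.

The stages mirror the digitization workflow: binarize the scan, locate the
enclosing plot frame (largest closed contour), rectify a skewed frame onto a
rectangle, discard nuisance ink (``keep_largest``), apply manual edit
primitives (isotherms, drawn/erased segments, open-boundary extension), thin
every line to one pixel without changing the number of enclosed areas, and
finally label the phase domains.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktransform

from .exceptions import (
    EditError,
    GeometryError,
    NoRegionsError,
    NotEnclosedError,
)

__all__ = [
    "FOUR_CONNECTED",
    "EIGHT_CONNECTED",
    "Quadrilateral",
    "LabeledRegions",
    "EditPrimitive",
    "load_image",
    "binarize",
    "find_plot_frame",
    "rectify",
    "keep_largest",
    "apply_edits",
    "thin",
    "label_regions",
    "add_frame",
]

#: 4-connectivity structuring element (phase domains).
FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)
#: 8-connectivity structuring element (boundary lines).
EIGHT_CONNECTED = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class Quadrilateral:
    """Four (row, col) corners in top-left, top-right, bottom-right,
    bottom-left winding order."""

    corners: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.corners) != 4:
            raise GeometryError("a quadrilateral needs exactly four corners")
        if len({tuple(c) for c in self.corners}) != 4:
            raise GeometryError("quadrilateral corners must be distinct")
        pts = np.asarray(self.corners, dtype=float)
        crosses = []
        for i in range(4):
            a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
            u, v = b - a, c - b
            crosses.append(float(u[0] * v[1] - u[1] * v[0]))
        nonzero = [x for x in crosses if abs(x) > 1e-9]
        if not nonzero:
            raise GeometryError("quadrilateral corners are collinear")
        if min(nonzero) < 0 < max(nonzero):
            raise GeometryError("quadrilateral must be convex")


@dataclass
class LabeledRegions:
    """Integer-labeled partition of a diagram: 0 = boundary ink, 1..n = phase
    domains."""

    labels: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.n != int(self.labels.max()):
            raise ValueError("n must equal the maximum label value")
        present = np.unique(self.labels)
        expected = np.arange(0, self.n + 1)
        if not np.array_equal(np.union1d(present, expected), expected):
            raise ValueError("labels must be exactly {0} U {1..n}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class EditPrimitive:
    """One manual rectification step.

    kind
        ``"segment"`` draws (or erases) a 1-px line between two endpoints;
        ``"isotherm"`` draws a horizontal line at a given temperature between
        two compositions (data coordinates; requires an axis calibration);
        ``"extend"`` continues an open boundary line through its endpoint
        along its local slope until it meets other ink or the frame.
    value
        1 to draw ink, 0 to erase it (ignored by ``extend``, which draws).
    """

    kind: Literal["segment", "isotherm", "extend"]
    value: int = 1
    start: tuple[float, float] | None = None
    end: tuple[float, float] | None = None
    coords: Literal["pixel", "data"] = "pixel"
    temperature: float | None = None
    composition_range: tuple[float, float] | None = None
    slope_window: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "EditPrimitive":
        d = dict(d)
        for key in ("start", "end", "composition_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# loading / binarization
# ---------------------------------------------------------------------------


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/BMP/JPEG image as a 2-D grayscale intensity array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def binarize(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a grayscale image on normalized darkness.

    A pixel becomes ink (1) iff ``1 - intensity/intensity_max >= threshold``
    where ``intensity_max`` is the dtype white level (255 for uint8, 1.0 for
    floats).  Deterministic; the default 0.5 suits clean scans and screen
    captures.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be a fraction in (0, 1)")
    if np.issubdtype(image.dtype, np.integer):
        white = float(np.iinfo(image.dtype).max)
    else:
        white = 1.0
    darkness = 1.0 - image.astype(float) / white
    return (darkness >= threshold).astype(np.uint8)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D binary mask, got shape {mask.shape}")
    return (mask != 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# frame detection / rectification
# ---------------------------------------------------------------------------


def find_plot_frame(mask: np.ndarray) -> Quadrilateral:
    """Locate the plot frame as the largest closed ink contour.

    Every 8-connected ink component is tested for an interior (hole); the
    component enclosing the largest interior wins and its four extreme convex
    hull corners are returned.  Raises :class:`NotEnclosedError` when no
    component encloses anything: the workflow requires the diagram to be
    fully enclosed on all four sides.
    """
    mask = _as_mask(mask)
    comps, ncomp = ndimage.label(mask, structure=EIGHT_CONNECTED)
    best_label, best_area = 0, 0
    for lab in range(1, ncomp + 1):
        comp = comps == lab
        filled = ndimage.binary_fill_holes(comp)
        interior = int(filled.sum() - comp.sum())
        if interior > best_area:
            best_label, best_area = lab, interior
    if best_label == 0:
        raise NotEnclosedError(
            "diagram not enclosed: no closed contour found "
            "(the plot frame must be closed on all four sides)"
        )
    rows, cols = np.nonzero(comps == best_label)
    pts = np.stack([rows, cols], axis=1).astype(float)
    tl = pts[np.argmin(pts[:, 0] + pts[:, 1])]
    tr = pts[np.argmax(pts[:, 1] - pts[:, 0])]
    br = pts[np.argmax(pts[:, 0] + pts[:, 1])]
    bl = pts[np.argmax(pts[:, 0] - pts[:, 1])]
    return Quadrilateral(tuple(map(tuple, (tl, tr, br, bl))))


def rectify(
    image: np.ndarray,
    quad: Quadrilateral,
    out_height: int,
    out_width: int,
) -> np.ndarray:
    """Projectively map *quad*'s corners onto the output rectangle corners.

    Binary inputs are resampled nearest-neighbor so the output stays binary;
    grayscale inputs are interpolated bilinearly.  An axis-aligned quad equal
    to the output rectangle is the identity.
    """
    image = np.asarray(image)
    if out_height < 3 or out_width < 3:
        raise ValueError("output dimensions must be at least 3x3")
    src_rc = np.asarray(quad.corners, dtype=float)
    # skimage transforms work in (x, y) = (col, row)
    src_xy = src_rc[:, ::-1]
    dst_xy = np.array(
        [
            [0.0, 0.0],
            [out_width - 1.0, 0.0],
            [out_width - 1.0, out_height - 1.0],
            [0.0, out_height - 1.0],
        ]
    )
    # inverse_map for warp: output (x, y) -> input (x, y)
    try:
        tform = sktransform.ProjectiveTransform.from_estimate(dst_xy, src_xy)
    except AttributeError:  # older scikit-image
        tform = sktransform.ProjectiveTransform()
        if not tform.estimate(dst_xy, src_xy):
            tform = None
    if not tform or not np.all(np.isfinite(tform.params)):
        raise GeometryError("degenerate quadrilateral: corners are collinear")
    binary = image.dtype == bool or set(np.unique(image)).issubset({0, 1})
    warped = sktransform.warp(
        image.astype(float),
        inverse_map=tform,
        output_shape=(out_height, out_width),
        order=0 if binary else 1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return warped.astype(image.dtype)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def keep_largest(mask: np.ndarray, n: int = 1) -> np.ndarray:
    """Keep only the *n* largest 8-connected ink components.

    Components are ranked by pixel count, ties broken by earliest first
    pixel in raster scan order.  Asking for more components than exist
    returns the mask unchanged with a warning.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    mask = _as_mask(mask)
    comps, ncomp = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if ncomp == 0:
        return mask.copy()
    if n >= ncomp:
        if n > ncomp:
            warnings.warn(
                f"asked to keep {n} components but the mask has only {ncomp}; "
                "returning the mask unchanged",
                stacklevel=2,
            )
        return mask.copy()
    flat = comps.ravel()
    sizes = np.bincount(flat, minlength=ncomp + 1)
    uniq, first = np.unique(flat, return_index=True)
    first_idx = dict(zip(uniq.tolist(), first.tolist()))
    order = sorted(range(1, ncomp + 1), key=lambda lab: (-sizes[lab], first_idx[lab]))
    keep = set(order[:n])
    out = np.isin(comps, list(keep)).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# edit primitives
# ---------------------------------------------------------------------------


def _draw_segment(mask: np.ndarray, p0, p1, value: int) -> None:
    rr, cc = skdraw.line(
        int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
    )
    ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    mask[rr[ok], cc[ok]] = value


def _local_direction(mask: np.ndarray, tip: tuple[int, int], k: int) -> np.ndarray:
    """Direction of a line at *tip*, estimated from the last *k* ink pixels
    walking back along the 8-connected line."""
    h, w = mask.shape
    visited = {tip}
    frontier = [tip]
    trail: list[tuple[int, int]] = []
    while frontier and len(trail) < k:
        nxt: list[tuple[int, int]] = []
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    q = (r + dr, c + dc)
                    if 0 <= q[0] < h and 0 <= q[1] < w and mask[q] and q not in visited:
                        visited.add(q)
                        trail.append(q)
                        nxt.append(q)
        frontier = nxt
    if not trail:
        raise EditError(f"cannot estimate slope: {tip} is an isolated pixel")
    centroid = np.mean(np.asarray(trail, dtype=float), axis=0)
    vec = np.asarray(tip, dtype=float) - centroid
    norm = np.hypot(*vec)
    if norm == 0:
        raise EditError(f"cannot estimate slope at {tip}: symmetric neighborhood")
    return vec / norm


def _extend(mask: np.ndarray, tip: tuple[int, int], k: int) -> None:
    """Continue the line through *tip* along its local slope until it meets
    existing ink or leaves the frame."""
    h, w = mask.shape
    tip = (int(round(tip[0])), int(round(tip[1])))
    if not (0 <= tip[0] < h and 0 <= tip[1] < w) or not mask[tip]:
        raise EditError(f"extend endpoint {tip} is not on a line")
    direction = _local_direction(mask, tip, k)
    original = mask.copy()
    pos = np.asarray(tip, dtype=float)
    prev = tip
    drawn = 0
    max_steps = 4 * (h + w)
    for _ in range(max_steps):
        pos = pos + 0.5 * direction
        pix = (int(round(pos[0])), int(round(pos[1])))
        if pix == prev:
            continue
        if not (0 <= pix[0] < h and 0 <= pix[1] < w):
            break  # ran off the image: the frame row/col was already drawn
        if original[pix] and drawn > 0:
            break  # met another boundary line (or the frame)
        if not original[pix]:
            mask[pix] = 1
            drawn += 1
        prev = pix


def apply_edits(
    mask: np.ndarray,
    edits: Sequence[EditPrimitive | dict],
    calibration=None,
) -> np.ndarray:
    """Apply manual rectification edits to a boundary mask.

    Isotherm edits and data-coordinate segments require an
    :class:`~phasedig.sampler.AxisCalibration` to place them on the raster.
    Returns a new mask; the input is never modified.
    """
    out = _as_mask(mask).copy()
    for edit in edits:
        if isinstance(edit, dict):
            edit = EditPrimitive.from_dict(edit)
        if edit.kind == "segment":
            if edit.start is None or edit.end is None:
                raise EditError("segment edit needs start and end points")
            p0, p1 = edit.start, edit.end
            if edit.coords == "data":
                if calibration is None:
                    raise EditError("data-coordinate segment requires a calibration")
                p0 = calibration.data_to_pixel(p0)
                p1 = calibration.data_to_pixel(p1)
            _draw_segment(out, p0, p1, int(bool(edit.value)))
        elif edit.kind == "isotherm":
            if edit.temperature is None:
                raise EditError("isotherm edit needs a temperature")
            if calibration is None:
                raise EditError("isotherm edits are in data coordinates and "
                                "require a calibration")
            w0, w1 = edit.composition_range or (
                calibration.composition.data_min,
                calibration.composition.data_max,
            )
            r0, c0 = calibration.data_to_pixel((edit.temperature, w0))
            _, c1 = calibration.data_to_pixel((edit.temperature, w1))
            _draw_segment(out, (r0, c0), (r0, c1), int(bool(edit.value)))
        elif edit.kind == "extend":
            if edit.start is None:
                raise EditError("extend edit needs the endpoint to extend from")
            p = edit.start
            if edit.coords == "data":
                if calibration is None:
                    raise EditError("data-coordinate extend requires a calibration")
                p = calibration.data_to_pixel(p)
            _extend(out, (int(round(p[0])), int(round(p[1]))), edit.slope_window)
        else:
            raise EditError(f"unknown edit kind {edit.kind!r}")
    return out


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, size: int) -> None:
        self.parent = list(range(size))

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin boundary lines to one pixel without changing the area count.

    Ink pixels are removed in order of decreasing white-8-neighbor count
    (raster order among ties), and a pixel is removed only when the removal
    leaves the number of white areas unchanged: it must have white
    4-neighbors, all already belonging to one region.  Area counting matches
    :func:`label_regions` exactly -- the image edge is a wall, not white --
    so a pixel whose removal would merge two domains (or open a new
    one-pixel area) is never touched.  White regions only ever grow during
    thinning, and two distinct regions can never merge, so an incremental
    union-find answers each candidate test in near-constant time.

    Pixels on the image border are never removed: after cropping and
    rectification the border carries the enclosing frame, which must stay
    boundary ink so that boundary lines keep their anchor points where they
    meet it (and outer domains stay closed by actual ink, not merely by the
    image edge).

    Idempotent, and ``label_regions(thin(m)).n == label_regions(m).n``.
    An interior separating line ends up one pixel wide; interior ink that
    separates nothing (blobs, spurs) erodes away entirely.
    """
    mask = _as_mask(mask).copy()
    h, w = mask.shape

    uf = _UnionFind(h * w)
    regions, _ = ndimage.label(mask == 0, structure=FOUR_CONNECTED)
    # union white pixels within each initial region
    reps: dict[int, int] = {}
    for r in range(h):
        base = r * w
        for c in range(w):
            lab = regions[r, c]
            if lab:
                idx = base + c
                if lab in reps:
                    uf.union(reps[lab], idx)
                else:
                    reps[lab] = idx

    def white8(r: int, c: int) -> int:
        count = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] == 0:
                    count += 1
        return count

    def neighbor_roots(r: int, c: int) -> set[int]:
        roots = set()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] == 0:
                roots.add(uf.find(rr * w + cc))
        return roots

    heap: list[tuple[int, int]] = []
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if mask[r, c]:
                wc = white8(r, c)
                if wc:
                    heapq.heappush(heap, (-wc, r * w + c))

    while heap:
        neg_wc, idx = heapq.heappop(heap)
        r, c = divmod(idx, w)
        if mask[r, c] == 0:
            continue
        wc = white8(r, c)
        if wc == 0:
            continue
        if -neg_wc != wc:
            heapq.heappush(heap, (-wc, idx))  # stale priority, re-queue
            continue
        roots = neighbor_roots(r, c)
        if len(roots) != 1:
            continue  # removal would merge regions (>=2) or open a new one (0)
        mask[r, c] = 0
        uf.union(roots.pop(), idx)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 < rr < h - 1 and 0 < cc < w - 1 and mask[rr, cc]:
                    heapq.heappush(heap, (-white8(rr, cc), rr * w + cc))
    return mask


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------


def label_regions(mask: np.ndarray) -> LabeledRegions:
    """Label each 4-connected white domain 1..n; ink keeps label 0.

    The phase count n is simply the maximum label value.
    """
    mask = _as_mask(mask)
    if not np.any(mask == 0):
        raise NoRegionsError("mask has no white pixels: no regions to label")
    labels, n = ndimage.label(mask == 0, structure=FOUR_CONNECTED)
    return LabeledRegions(labels=labels.astype(np.int32), n=int(n))


def add_frame(mask: np.ndarray) -> np.ndarray:
    """Draw the 1-px image-border frame rectangle onto a copy of *mask*."""
    out = _as_mask(mask).copy()
    out[0, :] = 1
    out[-1, :] = 1
    out[:, 0] = 1
    out[:, -1] = 1
    return out
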