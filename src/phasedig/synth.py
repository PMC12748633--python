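"""Synthetic phase-diagram images with known vector geometry.

The generator emulates the structures found in published binary
surfactant-water diagrams: polygonal single- and two-phase regions tiling
the temperature/composition rectangle, boundary curves drawn with a finite
line width, eutectic/peritectic horizontal isotherms, and nuisance ink
(dashed tie-line-like segments, text-like blobs, optional grid lines, and a
sheared plot frame as produced by skewed book scans).  Because the vector
geometry is known exactly, expected phase probabilities at any point follow
from exact point-to-polygon distances -- an oracle entirely independent of
the raster pipeline's code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import draw as skdraw
from skimage import transform as sktransform

from .image import LabeledRegions, add_frame
from .sampler import (
    DEFAULT_KERNEL_THRESHOLD,
    Axis,
    AxisCalibration,
)

__all__ = [
    "Region",
    "DiagramSpec",
    "GroundTruth",
    "generate",
    "oracle_probabilities",
    "probability_band",
    "region_state_map",
    "half_plane_spec",
    "random_spec",
]


@dataclass(frozen=True)
class Region:
    """One polygonal phase domain in data coordinates.

    The polygon vertices are (temperature, wt%) pairs.
    """

    polygon: tuple[tuple[float, float], ...]
    state: str

    def shapely(self) -> Polygon:
        # shapely works in (x, y); use x = wt%, y = temperature
        return Polygon([(w, t) for t, w in self.polygon])


@dataclass(frozen=True)
class DiagramSpec:
    """Recipe for one synthetic diagram.

    Regions must tile the axis rectangle (shared edges only); nuisance
    options add removable clutter the cleaning stage is expected to strip.
    Rasterization is deterministic given the seed.
    """

    regions: tuple[Region, ...]
    t_range: tuple[float, float] = (0.0, 100.0)
    w_range: tuple[float, float] = (0.0, 100.0)
    isotherms: tuple[tuple[float, float, float], ...] = ()  # (T, w0, w1)
    height: int = 401
    width: int = 401
    line_width: int = 3
    text_blobs: int = 0
    dashed_segments: int = 0
    grid_spacing: float | None = None
    shear_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("a diagram needs at least one region")
        rect_area = (self.t_range[1] - self.t_range[0]) * (
            self.w_range[1] - self.w_range[0]
        )
        polys = [r.shapely() for r in self.regions]
        total = sum(p.area for p in polys)
        if abs(total - rect_area) > 1e-6 * rect_area:
            raise ValueError(
                "region polygons must tile the axis rectangle "
                f"(polygon area {total:g} vs rectangle {rect_area:g})"
            )
        for i, a in enumerate(polys):
            for b in polys[i + 1 :]:
                inter = a.intersection(b)
                if inter.area > 1e-9 * rect_area:
                    raise ValueError("region polygons overlap beyond shared edges")


@dataclass
class GroundTruth:
    """Vector geometry behind a generated image."""

    spec: DiagramSpec
    calibration: AxisCalibration
    frame_quad: tuple[tuple[float, float], ...]
    polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.polygons:
            self.polygons = [r.shapely() for r in self.spec.regions]

    @property
    def states(self) -> list[str]:
        return [r.state for r in self.spec.regions]

    def state_distances(self, point: tuple[float, float]) -> dict[str, float]:
        """Exact distance (data units) from (T, wt%) to each state's domain."""
        t, w = point
        t0, t1 = self.spec.t_range
        w0, w1 = self.spec.w_range
        if not (t0 <= t <= t1 and w0 <= w <= w1):
            raise ValueError(f"point {point} outside the axis rectangle")
        pt = Point(w, t)
        out: dict[str, float] = {}
        for poly, state in zip(self.polygons, self.states):
            d = 0.0 if poly.covers(pt) else float(poly.distance(pt))
            out[state] = min(out.get(state, math.inf), d)
        return out


def _default_calibration(spec: DiagramSpec) -> AxisCalibration:
    h, w = spec.height, spec.width
    return AxisCalibration(
        temperature=Axis(
            pixel_min=h - 1, pixel_max=0,
            data_min=spec.t_range[0], data_max=spec.t_range[1],
        ),
        composition=Axis(
            pixel_min=0, pixel_max=w - 1,
            data_min=spec.w_range[0], data_max=spec.w_range[1],
        ),
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _draw_data_line(mask, cal, p0, p1) -> None:
    r0, c0 = cal.data_to_pixel(p0)
    r1, c1 = cal.data_to_pixel(p1)
    rr, cc = skdraw.line(r0, c0, r1, c1)
    mask[rr, cc] = 1


def _clear_zone(mask: np.ndarray, r: int, c: int, hh: int, ww: int, pad: int) -> bool:
    r0, c0 = max(0, r - pad), max(0, c - pad)
    r1, c1 = min(mask.shape[0], r + hh + pad), min(mask.shape[1], c + ww + pad)
    return not mask[r0:r1, c0:c1].any()


def generate(spec: DiagramSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a spec into a grayscale image plus its ground truth.

    Returns an 8-bit image (255 white paper, 0 black ink) and the
    :class:`GroundTruth` whose calibration refers to the *rectified*
    geometry -- for a sheared spec the pipeline is expected to rectify the
    frame back onto the (height, width) rectangle first.
    """
    rng = np.random.default_rng(spec.seed)
    cal = _default_calibration(spec)
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)

    for region in spec.regions:
        verts = list(region.polygon)
        for p0, p1 in zip(verts, verts[1:] + verts[:1]):
            _draw_data_line(mask, cal, p0, p1)
    for t_iso, w0, w1 in spec.isotherms:
        _draw_data_line(mask, cal, (t_iso, w0), (t_iso, w1))
    if spec.grid_spacing:
        t0, t1 = spec.t_range
        w0, w1 = spec.w_range
        t = t0 + spec.grid_spacing
        while t < t1:
            _draw_data_line(mask, cal, (t, w0), (t, w1))
            t += spec.grid_spacing
        w = w0 + spec.grid_spacing
        while w < w1:
            _draw_data_line(mask, cal, (t0, w), (t1, w))
            w += spec.grid_spacing
    mask = add_frame(mask)
    if spec.line_width > 1:
        r = spec.line_width // 2
        mask = ndimage.binary_dilation(
            mask, structure=np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        ).astype(np.uint8)

    # nuisance ink: kept clear of real lines so it forms separate components
    for _ in range(spec.text_blobs):
        for _attempt in range(50):
            hh = int(rng.integers(3, 8))
            ww = int(rng.integers(3, 10))
            r = int(rng.integers(1, spec.height - hh - 1))
            c = int(rng.integers(1, spec.width - ww - 1))
            if _clear_zone(mask, r, c, hh, ww, pad=3):
                mask[r : r + hh, c : c + ww] = 1
                break
    for _ in range(spec.dashed_segments):
        for _attempt in range(50):
            length = int(rng.integers(12, 40))
            r = int(rng.integers(2, spec.height - 3))
            c = int(rng.integers(2, spec.width - length - 3))
            if _clear_zone(mask, r, c, 1, length, pad=3):
                for start in range(0, length, 6):
                    mask[r, c + start : c + min(start + 3, length)] = 1
                break

    frame_quad = (
        (0.0, 0.0),
        (0.0, spec.width - 1.0),
        (spec.height - 1.0, spec.width - 1.0),
        (spec.height - 1.0, 0.0),
    )
    if spec.shear_deg:
        shear = math.tan(math.radians(spec.shear_deg))
        # (x, y) -> (x + shear * y, y): rows keep, columns slide with row
        matrix = np.array([[1.0, shear, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        tform = sktransform.AffineTransform(matrix=matrix)
        extra = int(math.ceil(abs(shear) * (spec.height - 1)))
        out_shape = (spec.height, spec.width + extra)
        shift = extra if shear < 0 else 0
        offset = sktransform.AffineTransform(translation=(shift, 0.0))
        combined = tform + offset
        mask = sktransform.warp(
            mask.astype(float),
            inverse_map=combined.inverse,
            output_shape=out_shape,
            order=0,
            cval=0.0,
            preserve_range=True,
        ).astype(np.uint8)
        quad = []
        for r, c in frame_quad:
            x, y = combined([[c, r]])[0]
            quad.append((float(y), float(x)))
        frame_quad = tuple(quad)

    image = ((1 - mask) * 255).astype(np.uint8)
    truth = GroundTruth(spec=spec, calibration=cal, frame_quad=frame_quad)
    return image, truth


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def oracle_probabilities(
    truth: GroundTruth,
    point: tuple[float, float],
    threshold: float = DEFAULT_KERNEL_THRESHOLD,
) -> dict[str, float]:
    """Expected phase probabilities at (T, wt%) from exact polygon distances.

    Same kernel, cutoff and normalization as the raster sampler, but the
    distances are exact vector geometry, not rasterized approximations.
    """
    dist = truth.state_distances(point)
    raw = {s: math.exp(-d / 2.0) for s, d in dist.items()}
    raw = {s: (0.0 if v < threshold else v) for s, v in raw.items()}
    total = sum(raw.values())
    if total == 0.0:
        raise ValueError("all phases below the probability cutoff")
    return {s: v / total for s, v in raw.items()}


def probability_band(
    truth: GroundTruth,
    point: tuple[float, float],
    delta: float,
    threshold: float = DEFAULT_KERNEL_THRESHOLD,
) -> dict[str, tuple[float, float]]:
    """Probability interval per state when every distance may err by *delta*.

    Used to bound the raster pipeline against the vector oracle: the
    rasterized boundary can displace each distance by about a pixel, so the
    pipeline's probability must fall inside the band obtained by sliding
    each distance through [d - delta, d + delta] through the full
    kernel/cutoff/normalization.
    """
    dist = truth.state_distances(point)
    states = list(dist)

    def kernel(d: float) -> float:
        v = math.exp(-max(d, 0.0) / 2.0)
        return 0.0 if v < threshold else v

    out: dict[str, tuple[float, float]] = {}
    for s in states:
        hi_num = kernel(dist[s] - delta)
        hi_den = hi_num + sum(kernel(dist[o] + delta) for o in states if o != s)
        lo_num = kernel(dist[s] + delta)
        lo_den = lo_num + sum(kernel(dist[o] - delta) for o in states if o != s)
        hi = hi_num / hi_den if hi_den > 0 else (1.0 if hi_num > 0 else 0.0)
        lo = lo_num / lo_den if lo_den > 0 else 0.0
        out[s] = (lo, hi)
    return out


def region_state_map(
    labeled: LabeledRegions,
    cal: AxisCalibration,
    truth: GroundTruth,
) -> dict[int, str]:
    """Recover the region-label -> phase-state mapping from the ground truth.

    For each raster region the most interior pixel (max distance transform)
    is mapped to data coordinates and located in the vector polygons.  In
    the real workflow this mapping is curated by hand; here the generator's
    geometry supplies it.
    """
    out: dict[int, str] = {}
    for lab in range(1, labeled.n + 1):
        inside = labeled.labels == lab
        depth = ndimage.distance_transform_edt(inside)
        r, c = np.unravel_index(int(np.argmax(depth)), depth.shape)
        t, w = cal.pixel_to_data((float(r), float(c)))
        pt = Point(w, t)
        best_state, best_d = None, math.inf
        for poly, state in zip(truth.polygons, truth.states):
            d = 0.0 if poly.covers(pt) else float(poly.distance(pt))
            if d < best_d:
                best_state, best_d = state, d
        assert best_state is not None
        out[lab] = best_state
    return out


# ---------------------------------------------------------------------------
# stock specs
# ---------------------------------------------------------------------------


def half_plane_spec(
    split_w: float = 50.0,
    states: tuple[str, str] = ("L1", "La"),
    **kwargs,
) -> DiagramSpec:
    """Two half-plane regions split by a vertical boundary at *split_w*."""
    t0, t1 = kwargs.pop("t_range", (0.0, 100.0))
    w0, w1 = kwargs.pop("w_range", (0.0, 100.0))
    left = Region(((t0, w0), (t0, split_w), (t1, split_w), (t1, w0)), states[0])
    right = Region(((t0, split_w), (t0, w1), (t1, w1), (t1, split_w)), states[1])
    return DiagramSpec(
        regions=(left, right), t_range=(t0, t1), w_range=(w0, w1), **kwargs
    )


_STOCK_STATES = ("W", "L1", "H1", "V1", "La", "X1", "L2", "H2")


def random_spec(
    seed: int,
    n_regions: int = 3,
    n_knots: int = 4,
    knot_quantum: float | None = None,
    **kwargs,
) -> DiagramSpec:
    """Random vertical-band partition with piecewise-linear boundaries.

    Boundaries are n_regions - 1 non-crossing polylines running bottom to
    top, the way composition-driven phase boundaries sweep through a
    temperature range; regions take distinct stock states left to right.
    *knot_quantum* quantizes boundary-vertex compositions (e.g. 0.25 wt%
    puts every vertex on an exact pixel of a 4-px-per-unit raster, which
    caps the rasterization error of every boundary segment at half a
    pixel).
    """
    if n_regions < 1 or n_regions > len(_STOCK_STATES):
        raise ValueError(f"n_regions must be in 1..{len(_STOCK_STATES)}")
    rng = np.random.default_rng(seed)
    t0, t1 = kwargs.pop("t_range", (0.0, 100.0))
    w0, w1 = kwargs.pop("w_range", (0.0, 100.0))
    knots = np.linspace(t0, t1, n_knots)
    span = w1 - w0
    # sorted interior offsets with a guaranteed margin between boundaries
    cuts = np.empty((n_knots, n_regions - 1))
    for k in range(n_knots):
        base = np.linspace(w0, w1, n_regions + 1)[1:-1]
        jitter = rng.uniform(-0.35, 0.35, size=n_regions - 1) * span / n_regions
        cuts[k] = np.clip(base + jitter, w0 + 0.05 * span, w1 - 0.05 * span)
        if knot_quantum:
            cuts[k] = np.round(cuts[k] / knot_quantum) * knot_quantum
        cuts[k].sort()
    regions = []
    for j in range(n_regions):
        left = [w0] * n_knots if j == 0 else cuts[:, j - 1]
        right = [w1] * n_knots if j == n_regions - 1 else cuts[:, j]
        verts: list[tuple[float, float]] = []
        for k in range(n_knots):  # up the left edge
            verts.append((float(knots[k]), float(left[k])))
        for k in reversed(range(n_knots)):  # down the right edge
            verts.append((float(knots[k]), float(right[k])))
        regions.append(Region(tuple(verts), _STOCK_STATES[j]))
    return DiagramSpec(
        regions=tuple(regions), t_range=(t0, t1), w_range=(w0, w1),
        seed=seed, **kwargs
    )
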