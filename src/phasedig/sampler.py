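"""Gridded probabilistic phase-state sampling of a labeled diagram.

The soft-labeling model: each (temperature, composition) grid point is mapped
to its test pixel; for every phase region *i* the minimum Euclidean distance
``d_i`` between the test pixel and the region is measured in *data units*,
treating a 1 degC step and a 1 wt% step as equal length.  The raw phase
weight is the exponential kernel ``P_i = exp(-d_i / 2)``; weights below the
cutoff (default 1e-3, i.e. phases further than ``-2 ln(1e-3) ~ 13.82`` data
units away) are set to exactly zero, and the remainder is normalized to one.
A point inside a region therefore gets probability 1 for that region when
every other region is far away; a point on a one-pixel boundary between two
regions is equidistant to both and gets 0.5 / 0.5.

Distances are measured in data units rather than raw pixels so that the
result does not depend on the scan resolution; the conversion lives in
:meth:`AxisCalibration.units_per_pixel` and can be swapped out in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import NoAssignablePhaseError, RangeError
from .image import LabeledRegions

__all__ = [
    "DEFAULT_KERNEL_THRESHOLD",
    "Axis",
    "AxisCalibration",
    "GridSpec",
    "data_to_pixel",
    "phase_distances",
    "distance_maps",
    "assign_probabilities",
    "sample_grid",
    "categorical_grid",
]

#: Raw-weight cutoff below which a phase probability is zeroed.
DEFAULT_KERNEL_THRESHOLD = 1e-3

#: Distance (data units) beyond which the kernel falls under the default
#: cutoff: -2 ln(1e-3).
CUTOFF_DISTANCE = -2.0 * math.log(DEFAULT_KERNEL_THRESHOLD)


@dataclass(frozen=True)
class Axis:
    """Invertible linear (or log-linear) map between one pixel coordinate and
    one data coordinate.

    ``pixel_min`` is the pixel coordinate of ``data_min``; for a temperature
    axis drawn the usual way up the page, ``pixel_min`` is the bottom row
    index and ``pixel_max`` is a smaller number (the top row).
    """

    pixel_min: float
    pixel_max: float
    data_min: float
    data_max: float
    log: bool = False

    def __post_init__(self) -> None:
        if self.pixel_min == self.pixel_max:
            raise ValueError("degenerate pixel range")
        if self.data_min == self.data_max:
            raise ValueError("degenerate data range")
        if self.log and (self.data_min <= 0 or self.data_max <= 0):
            raise ValueError("log axis requires strictly positive data range")

    def _t(self, value: float) -> float:
        return math.log10(value) if self.log else value

    def to_pixel(self, value: float) -> float:
        """Continuous pixel coordinate of *value* (no rounding)."""
        lo, hi = sorted((self.data_min, self.data_max))
        if not lo <= value <= hi:
            raise RangeError(f"value {value} outside axis range [{lo}, {hi}]")
        frac = (self._t(value) - self._t(self.data_min)) / (
            self._t(self.data_max) - self._t(self.data_min)
        )
        return self.pixel_min + frac * (self.pixel_max - self.pixel_min)

    def to_data(self, pixel: float) -> float:
        frac = (pixel - self.pixel_min) / (self.pixel_max - self.pixel_min)
        t = self._t(self.data_min) + frac * (self._t(self.data_max) - self._t(self.data_min))
        return 10.0**t if self.log else t

    @property
    def units_per_pixel(self) -> float:
        """Data units (log10 units for a log axis) spanned by one pixel."""
        span = abs(self._t(self.data_max) - self._t(self.data_min))
        return span / abs(self.pixel_max - self.pixel_min)


@dataclass(frozen=True)
class AxisCalibration:
    """Pixel <-> data mapping for both axes of a rectified diagram.

    Temperature runs along image rows, composition (wt% surfactant, bounded
    to [0, 100]: 0 is pure water, 100 pure surfactant) along columns.
    """

    temperature: Axis
    composition: Axis

    def __post_init__(self) -> None:
        lo, hi = sorted((self.composition.data_min, self.composition.data_max))
        if lo < 0.0 or hi > 100.0:
            raise ValueError("composition axis must stay within [0, 100] wt%")

    def data_to_pixel(self, point: tuple[float, float]) -> tuple[int, int]:
        """Nearest (row, col) test pixel of a (temperature, wt%) point.

        Half-way values round toward the larger pixel index.
        """
        t, w = point
        row = math.floor(self.temperature.to_pixel(t) + 0.5)
        col = math.floor(self.composition.to_pixel(w) + 0.5)
        return int(row), int(col)

    def pixel_to_data(self, pixel: tuple[float, float]) -> tuple[float, float]:
        r, c = pixel
        return self.temperature.to_data(r), self.composition.to_data(c)

    def units_per_pixel(self) -> tuple[float, float]:
        """(temperature units per row, composition units per column)."""
        return self.temperature.units_per_pixel, self.composition.units_per_pixel

    @classmethod
    def from_dict(cls, d: dict) -> "AxisCalibration":
        return cls(Axis(**d["temperature"]), Axis(**d["composition"]))

    def to_dict(self) -> dict:
        return {
            "temperature": vars(self.temperature).copy(),
            "composition": vars(self.composition).copy(),
        }


@dataclass(frozen=True)
class GridSpec:
    """Sampling lattice: ranges and spacings, default 1 degC x 1 wt%."""

    t_min: float
    t_max: float
    w_min: float
    w_max: float
    t_step: float = 1.0
    w_step: float = 1.0

    def __post_init__(self) -> None:
        if self.t_step <= 0 or self.w_step <= 0:
            raise ValueError("grid spacings must be positive")
        if self.t_max < self.t_min or self.w_max < self.w_min:
            raise ValueError("grid ranges must be non-decreasing")

    @staticmethod
    def _points(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    @property
    def temperatures(self) -> np.ndarray:
        return self._points(self.t_min, self.t_max, self.t_step)

    @property
    def compositions(self) -> np.ndarray:
        return self._points(self.w_min, self.w_max, self.w_step)


def data_to_pixel(point: tuple[float, float], cal: AxisCalibration) -> tuple[int, int]:
    """Functional alias for :meth:`AxisCalibration.data_to_pixel`."""
    return cal.data_to_pixel(point)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def distance_maps(labeled: LabeledRegions, cal: AxisCalibration) -> np.ndarray:
    """Per-phase minimum-distance fields in data units, shape (n, H, W).

    For each phase the Euclidean distance transform locates the nearest
    pixel of that phase; the distance is then recomputed from the row/column
    offsets as ``sqrt((drow * t_units)**2 + (dcol * w_units)**2)`` --
    bitwise the same arithmetic as a brute-force scan over phase pixels, so
    the fast path is exactly equal to exhaustive search, not merely close.
    """
    st, sw = cal.units_per_pixel()
    labels = labeled.labels
    h, w = labels.shape
    rows, cols = np.indices((h, w))
    out = np.empty((labeled.n, h, w), dtype=float)
    for i in range(1, labeled.n + 1):
        _, (nr, nc) = ndimage.distance_transform_edt(
            labels != i, sampling=(st, sw), return_indices=True
        )
        out[i - 1] = np.sqrt(((rows - nr) * st) ** 2 + ((cols - nc) * sw) ** 2)
    return out


def phase_distances(
    test_pixel: tuple[int, int],
    labeled: LabeledRegions,
    cal: AxisCalibration,
    maps: np.ndarray | None = None,
) -> np.ndarray:
    """Minimum distance (data units) from *test_pixel* to each phase 1..n.

    Zero exactly when the test pixel carries that phase's label; boundary
    (label 0) pixels are in no phase, so all their distances are positive.
    """
    r, c = test_pixel
    h, w = labeled.shape
    if not (0 <= r < h and 0 <= c < w):
        raise RangeError(f"test pixel {test_pixel} outside image {labeled.shape}")
    if maps is None:
        maps = distance_maps(labeled, cal)
    return maps[:, r, c].copy()


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------


def assign_probabilities(
    d: np.ndarray,
    threshold: float = DEFAULT_KERNEL_THRESHOLD,
) -> np.ndarray:
    """Exponential-kernel soft assignment with cutoff and normalization.

    ``raw_i = exp(-d_i / 2)``; raw weights strictly below *threshold* become
    exactly zero; the survivors are normalized to sum to one.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    raw = np.exp(-d / 2.0)
    raw[raw < threshold] = 0.0
    total = raw.sum()
    if total == 0.0:
        raise NoAssignablePhaseError(
            "every phase fell below the probability cutoff; the test point "
            "is outside the reach of all phases"
        )
    return raw / total


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------


def _state_distance_stack(
    maps: np.ndarray,
    region_states: dict[int, str] | None,
    n: int,
) -> tuple[list[str], np.ndarray]:
    """Collapse per-region distance maps onto per-state maps.

    Two disconnected regions carrying the same state (a split solid phase,
    say) contribute through the smaller of their distances.
    """
    if region_states is None:
        region_states = {i: f"phase_{i}" for i in range(1, n + 1)}
    missing = [i for i in range(1, n + 1) if i not in region_states]
    if missing:
        from .exceptions import MappingError

        raise MappingError(f"no state mapped for region label(s) {missing}")
    states: list[str] = []
    groups: dict[str, list[int]] = {}
    for i in range(1, n + 1):
        s = str(region_states[i])
        if s not in groups:
            groups[s] = []
            states.append(s)
        groups[s].append(i - 1)
    stack = np.stack([maps[groups[s]].min(axis=0) for s in states])
    return states, stack


def sample_grid(
    labeled: LabeledRegions,
    cal: AxisCalibration,
    grid: GridSpec,
    region_states: dict[int, str] | None = None,
    threshold: float = DEFAULT_KERNEL_THRESHOLD,
) -> pd.DataFrame:
    """Probability table over the full grid, endpoints inclusive.

    One row per (temperature, composition) lattice point; the default
    0-100 x 0-100 grid at unit spacing gives 101 x 101 = 10201 rows.
    Columns: ``temperature``, ``composition``, then one fractional
    probability column per phase state.
    """
    maps = distance_maps(labeled, cal)
    states, stack = _state_distance_stack(maps, region_states, labeled.n)
    ts = grid.temperatures
    ws = grid.compositions
    rr = np.array([cal.data_to_pixel((t, ws[0]))[0] for t in ts])
    cc = np.array([cal.data_to_pixel((ts[0], w))[1] for w in ws])
    h, w = labeled.shape
    if rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w:
        raise RangeError("grid maps outside the image; check the calibration")
    tt, wwv = np.meshgrid(ts, ws, indexing="ij")
    d = stack[:, rr[:, None], cc[None, :]]  # (n_states, nt, nw)
    raw = np.exp(-d / 2.0)
    raw[raw < threshold] = 0.0
    total = raw.sum(axis=0)
    if np.any(total == 0.0):
        raise NoAssignablePhaseError(
            "a grid point fell below the probability cutoff for every phase"
        )
    prob = raw / total
    data = {"temperature": tt.ravel(), "composition": wwv.ravel()}
    for k, s in enumerate(states):
        data[s] = prob[k].ravel()
    return pd.DataFrame(data)


def categorical_grid(
    labeled: LabeledRegions,
    cal: AxisCalibration,
    grid: GridSpec,
    region_states: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Single nearest-phase assignment per grid point (validation mode).

    Ties (e.g. a point exactly on a boundary) go to the lowest region label,
    which with the default identity mapping is also the first state column.
    """
    maps = distance_maps(labeled, cal)
    states, stack = _state_distance_stack(maps, region_states, labeled.n)
    ts = grid.temperatures
    ws = grid.compositions
    rr = np.array([cal.data_to_pixel((t, ws[0]))[0] for t in ts])
    cc = np.array([cal.data_to_pixel((ts[0], w))[1] for w in ws])
    h, w = labeled.shape
    if rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w:
        raise RangeError("grid maps outside the image; check the calibration")
    d = stack[:, rr[:, None], cc[None, :]]
    winner = np.argmin(d, axis=0)  # argmin returns the first (lowest) index on ties
    tt, wwv = np.meshgrid(ts, ws, indexing="ij")
    return pd.DataFrame(
        {
            "temperature": tt.ravel(),
            "composition": wwv.ravel(),
            "state": [states[k] for k in winner.ravel()],
        }
    )
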