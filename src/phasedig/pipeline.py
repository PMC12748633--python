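"""End-to-end digitization: image + config in, validated PhDat record out.

The stages are the ones a user runs one by one from the CLI -- binarize,
frame detection, rectification, cleaning, manual edits, thinning, labeling,
grid sampling, record assembly -- chained with logging of each stage's
region/row counts.  The region-number -> phase-state mapping is a required
user input: region numbering is an artifact of the labeling pass and only
the curator knows which numbered region is which phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import image as im
from .exceptions import MappingError
from .records import PhDatRecord, write_record
from .sampler import (
    DEFAULT_KERNEL_THRESHOLD,
    AxisCalibration,
    GridSpec,
    sample_grid,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("phasedig")


@dataclass
class RunConfig:
    """Everything one digitization run needs.

    Defaults follow the workflow's stated constants: 1 degC and 1 wt% grid
    spacing and a 1e-3 probability cutoff.
    """

    image: np.ndarray
    calibration: AxisCalibration
    region_states: dict[int, str]
    meta: dict
    grid: GridSpec | None = None
    edits: list = field(default_factory=list)
    binarize_threshold: float = 0.5
    keep_n: int | None = 1
    rectify_frame: bool = True
    kernel_threshold: float = DEFAULT_KERNEL_THRESHOLD


def run_pipeline(config: RunConfig) -> PhDatRecord:
    """Run segment -> edit -> thin -> label -> sample -> record.

    Deterministic for fixed inputs.  Raises :class:`MappingError` when the
    region-state map does not cover every labeled region.
    """
    gray = np.asarray(config.image)
    mask = im.binarize(gray, config.binarize_threshold)
    log.info("binarized: %d ink pixels", int(mask.sum()))

    if config.rectify_frame:
        quad = im.find_plot_frame(mask)
        h = config.calibration.temperature
        c = config.calibration.composition
        out_h = int(max(h.pixel_min, h.pixel_max)) + 1
        out_w = int(max(c.pixel_min, c.pixel_max)) + 1
        mask = im.rectify(mask, quad, out_h, out_w)
        mask = im.add_frame(mask)
        log.info("rectified frame %s -> %dx%d", quad.corners, out_h, out_w)

    if config.keep_n is not None:
        mask = im.keep_largest(mask, config.keep_n)
        log.info("kept %d largest component(s): %d ink pixels",
                 config.keep_n, int(mask.sum()))
    if config.edits:
        mask = im.apply_edits(mask, config.edits, config.calibration)
        log.info("applied %d edit(s)", len(config.edits))

    mask = im.thin(mask)
    labeled = im.label_regions(mask)
    log.info("thinned and labeled: %d regions", labeled.n)

    missing = [i for i in range(1, labeled.n + 1) if i not in config.region_states]
    if missing:
        raise MappingError(
            f"region-state mapping is missing label(s) {missing}; the "
            "labeling found {n} regions".format(n=labeled.n)
        )

    grid = config.grid
    if grid is None:
        t, w = config.calibration.temperature, config.calibration.composition
        grid = GridSpec(
            t_min=min(t.data_min, t.data_max), t_max=max(t.data_min, t.data_max),
            w_min=min(w.data_min, w.data_max), w_max=max(w.data_min, w.data_max),
        )
    table = sample_grid(
        labeled,
        config.calibration,
        grid,
        region_states=config.region_states,
        threshold=config.kernel_threshold,
    )
    log.info("sampled %d grid points x %d states", len(table), len(table.columns) - 2)
    return write_record(config.meta, table)
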