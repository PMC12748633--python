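"""Shared fixtures: vocabulary, worked-example dataset, synthetic diagrams."""

from __future__ import annotations

import numpy as np
import pytest

from phasedig import image as im
from phasedig import synth
from phasedig.records import PhDatDataset, PhDatRecord
from phasedig.vocab import load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


# A small hypothetical phase-diagram table: isotropic micellar solution (L1),
# cloud region (L1+W) and lamellar phase (La) probabilities on a coarse
# 3 x 3 grid, stored as percentages.  The (0 C, 50 wt%) point carries the
# worked 50 / 50 / 0 split between L1 and the cloud region.
TABLE6_ROWS = [
    (0.0, 0.0, 100.0, 0.0, 0.0),
    (0.0, 50.0, 50.0, 50.0, 0.0),
    (0.0, 100.0, 0.0, 100.0, 0.0),
    (20.0, 0.0, 33.0, 33.0, 33.0),
    (20.0, 50.0, 0.0, 50.0, 50.0),
    (20.0, 100.0, 0.0, 10.0, 90.0),
    (40.0, 0.0, 0.0, 50.0, 50.0),
    (40.0, 50.0, 0.0, 20.0, 80.0),
    (40.0, 100.0, 0.0, 0.0, 100.0),
]


def make_example_record(**overrides) -> PhDatRecord:
    cols = list(zip(*TABLE6_ROWS))
    fields = dict(
        smiles="CCCCOCCO",
        state="complete",
        name="butyl glycol ether (hypothetical diagram)",
        source="worked example",
        figure="5",
        method="F",
        type="nonionic",
        solvent="water",
        labels=(("L_1", "L1"), ("L_1 + W", "L1+W"), ("L_α", "La")),
        keys=("temperature", "composition", "L1", "L1+W", "La"),
        values=tuple(tuple(c) for c in cols),
    )
    fields.update(overrides)
    return PhDatRecord(**fields)


@pytest.fixture()
def example_record() -> PhDatRecord:
    return make_example_record()


@pytest.fixture()
def example_dataset(example_record) -> PhDatDataset:
    return PhDatDataset({"81": example_record})


@pytest.fixture(scope="session")
def half_plane():
    """Ideal two-region diagram (1-px lines), segmented once for the session."""
    spec = synth.half_plane_spec(height=401, width=401, line_width=1)
    image, truth = synth.generate(spec)
    labeled = im.label_regions(im.thin(im.binarize(image)))
    states = synth.region_state_map(labeled, truth.calibration, truth)
    return spec, image, truth, labeled, states


def random_line_mask(rng: np.random.Generator, h: int = 48, w: int = 48) -> np.ndarray:
    """Random clutter of lines, rings and blobs for topology tests."""
    from skimage.draw import line as skline

    mask = np.zeros((h, w), dtype=np.uint8)
    for _ in range(int(rng.integers(1, 5))):
        r0, c0 = int(rng.integers(0, h)), int(rng.integers(0, w))
        r1, c1 = int(rng.integers(0, h)), int(rng.integers(0, w))
        rr, cc = skline(r0, c0, r1, c1)
        mask[rr, cc] = 1
    if rng.random() < 0.5:  # thick bar
        r = int(rng.integers(0, h - 4))
        mask[r : r + 3, :] = 1
    if rng.random() < 0.5:  # filled blob
        r, c = int(rng.integers(0, h - 6)), int(rng.integers(0, w - 6))
        mask[r : r + 5, c : c + 5] = 1
    if rng.random() < 0.5:  # hollow rectangle ring
        r, c = int(rng.integers(0, h - 10)), int(rng.integers(0, w - 10))
        mask[r : r + 9, c] = 1
        mask[r : r + 9, c + 8] = 1
        mask[r, c : c + 9] = 1
        mask[r + 8, c : c + 9] = 1
    return mask


def random_labeling(
    rng: np.random.Generator, h: int = 100, w: int = 100, k: int = 4
) -> im.LabeledRegions:
    """Voronoi-style random region labeling with sprinkled boundary pixels."""
    seeds_r = rng.integers(0, h, size=k)
    seeds_c = rng.integers(0, w, size=k)
    rows, cols = np.indices((h, w))
    d2 = (rows[..., None] - seeds_r) ** 2 + (cols[..., None] - seeds_c) ** 2
    labels = np.argmin(d2, axis=-1) + 1
    # carve boundary pixels between differing neighbors
    boundary = np.zeros((h, w), dtype=bool)
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    labels = np.where(boundary, 0, labels)
    # relabel to contiguous 1..n in case a tiny region vanished
    present = np.unique(labels[labels > 0])
    remap = {old: new for new, old in enumerate(present, start=1)}
    out = np.zeros_like(labels)
    for old, new in remap.items():
        out[labels == old] = new
    return im.LabeledRegions(labels=out.astype(np.int32), n=len(present))
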