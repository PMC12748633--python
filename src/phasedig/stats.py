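"""Dataset-level phase-state frequency summaries.

For each phase state across a PhDat dataset: how many grid points carry a
non-zero probability of that state, and how many diagrams contain it at
all.  Soft boundaries mean one grid point can count toward several states,
so the point counts sum to at least the number of points.  States whose
point share falls under a reporting floor (default 1% of all points) are
flagged, not deleted, so the caller decides what to omit from a plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import PhDatDataset

__all__ = ["state_frequencies", "plot_frequencies"]


def state_frequencies(dataset: PhDatDataset, floor: float = 0.01) -> pd.DataFrame:
    """Tally non-zero-probability points and diagrams per phase state.

    A point counts toward a state iff its stored probability is strictly
    positive (the sampling cutoff has already zeroed noise-level weights,
    so no extra epsilon is applied); a diagram counts iff any of its points
    counts.  Returns a DataFrame indexed by state with ``points``,
    ``diagrams`` and ``below_floor`` columns, sorted by descending point
    count then state name.
    """
    if not 0.0 <= floor <= 1.0:
        raise ValueError("floor must be a fraction in [0, 1]")
    points: dict[str, int] = {}
    diagrams: dict[str, int] = {}
    total_points = 0
    for rec in dataset.values():
        if not rec.keys or not rec.values:
            continue
        n_rows = len(rec.values[0])
        total_points += n_rows
        for state, col in zip(rec.state_columns, rec.values[2:]):
            nonzero = int(np.count_nonzero(np.asarray(col, dtype=float) > 0.0))
            if nonzero:
                points[state] = points.get(state, 0) + nonzero
                diagrams[state] = diagrams.get(state, 0) + 1
    if not points:
        return pd.DataFrame(
            columns=["points", "diagrams", "below_floor"], index=pd.Index([], name="state")
        )
    df = pd.DataFrame(
        {
            "points": pd.Series(points),
            "diagrams": pd.Series(diagrams),
        }
    )
    df.index.name = "state"
    df["below_floor"] = df["points"] < floor * total_points
    # descending point count, alphabetical among ties
    df = df.sort_index().sort_values("points", ascending=False, kind="stable")
    return df


def plot_frequencies(freq: pd.DataFrame, log: bool = False, ax=None):
    """Bar plot of the frequency table (matplotlib optional extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.25 * len(freq)), 4))
    shown = freq[~freq["below_floor"]]
    ax.bar(shown.index, shown["points"], color="#4878d0")
    if log:
        ax.set_yscale("log")
    ax.set_ylabel("grid points with non-zero probability")
    ax.set_xlabel("phase state")
    ax.tick_params(axis="x", rotation=90)
    return ax
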