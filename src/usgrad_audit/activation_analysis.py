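"""Aggregate max-intensity-cell positions into 7x7 frequency maps.

For every image the grid cell with the highest Grad-CAM value is tallied
into a per-station two-dimensional frequency map, plus a combined map over
all stations. Degenerate (all-zero) grids carry no max cell; they are
excluded from the maps and counted separately so that each map's counts sum
to its number of contributing images.

Axis convention (documented on every rendering): columns follow the probe's
left-right orientation, rows run proximal (top) to distal (bottom) relative
to the transducer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from usgrad_audit.gradcam import GRID_SIZE, ActivationRegion


@dataclass
class FrequencyMap:
    scope: str                  # station id or "overall"
    counts: np.ndarray          # (7, 7) non-negative ints
    n_images: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError("counts must be 7x7")
        if int(self.counts.sum()) != self.n_images:
            raise ValueError("counts must sum to n_images")


@dataclass
class FrequencyMaps:
    by_station: dict[str, FrequencyMap]
    overall: FrequencyMap
    n_degenerate: int


def max_cell_frequency(regions: Iterable[tuple[str, ActivationRegion]]) -> FrequencyMaps:
    """Tally max-cell positions per station and overall.

    `regions` yields (station, region) pairs. Empty (degenerate) regions are
    skipped and reported via `n_degenerate`; the overall map is, by
    construction, the elementwise sum of the station maps.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions supplied")
    station_counts: dict[str, np.ndarray] = {}
    n_degenerate = 0
    for station, region in regions:
        if region.max_cell is None:
            n_degenerate += 1
            continue
        counts = station_counts.setdefault(station, np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.int64))
        r, c = region.max_cell
        counts[r, c] += 1
    by_station = {
        s: FrequencyMap(scope=s, counts=cnt, n_images=int(cnt.sum()))
        for s, cnt in sorted(station_counts.items())
    }
    total = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.int64)
    for fm in by_station.values():
        total += fm.counts
    overall = FrequencyMap(scope="overall", counts=total, n_images=int(total.sum()))
    return FrequencyMaps(by_station=by_station, overall=overall, n_degenerate=n_degenerate)


def frequency_table(maps: FrequencyMaps) -> pd.DataFrame:
    """Long-format export: scope,row,col,count (zero cells included)."""
    rows = []
    for fm in list(maps.by_station.values()) + [maps.overall]:
        for r in range(GRID_SIZE):
            for c in range(GRID_SIZE):
                rows.append({"scope": fm.scope, "row": r, "col": c,
                             "count": int(fm.counts[r, c])})
    return pd.DataFrame(rows)


def render_heatmaps(maps: FrequencyMaps):
    """One panel per station plus the overall panel; intensity ~ count.

    Returns a matplotlib Figure (Agg-safe).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    panels = list(maps.by_station.values()) + [maps.overall]
    ncols = min(3, len(panels))
    nrows = -(-len(panels) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.axis("off")
    vmax = max(1, int(maps.overall.counts.max()))
    for ax, fm in zip(axes.flat, panels):
        ax.axis("on")
        ax.imshow(fm.counts, cmap="Reds", vmin=0, vmax=vmax if fm.scope == "overall"
                  else max(1, int(fm.counts.max())))
        ax.set_title(f"{fm.scope} (n={fm.n_images})", fontsize=9)
        ax.set_xlabel("probe left-right")
        ax.set_ylabel("proximal-distal")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    return fig
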