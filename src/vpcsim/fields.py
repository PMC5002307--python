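"""Rate maps: rasterized firing activity over the arena.

A rate map grids the arena at a fixed resolution (row = y bin counted
from the south wall, col = x bin from the west wall). Per-cell maps hold
the mean firing rate over the trajectory points falling in each bin;
the population map holds the per-bin maximum across cells, visualizing
the overlap of all firing fields as the strongest responder. Bins the
trajectory never visits are NaN, never 0 — "not visited" and "not
firing" are different facts and conflating them corrupts field-area
metrics.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .agent import Trajectory
from .environment import Arena
from .perception import PlaceCode
from .placecell import FiringParams, PlaceCell, firing_rate

__all__ = [
    "RateMap",
    "FieldMetrics",
    "rasterize_cell",
    "population_map",
    "field_metrics",
    "write_rate_map_csv",
    "read_rate_map_csv",
    "plot_rate_map",
]


@dataclass
class RateMap:
    """Gridded firing rates with parallel per-bin visit counts.

    ``rates[i, j]`` is the rate in y-bin i, x-bin j; NaN where
    ``visits[i, j] == 0``. ``extent`` is (width, height) in metres.
    """

    rates: np.ndarray
    visits: np.ndarray
    resolution: float
    extent: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.rates.shape

    @property
    def visited(self) -> np.ndarray:
        return self.visits > 0

    def same_geometry(self, other: "RateMap") -> bool:
        return (
            self.shape == other.shape
            and self.resolution == other.resolution
            and self.extent == other.extent
        )


def _grid_shape(extent: tuple[float, float], resolution: float) -> tuple[int, int]:
    width, height = extent
    return (math.ceil(height / resolution), math.ceil(width / resolution))


def _bin_indices(
    x: np.ndarray, y: np.ndarray, resolution: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    # points exactly on the north/east arena boundary fall in the last bin
    rows = np.minimum((y / resolution).astype(np.int64), shape[0] - 1)
    cols = np.minimum((x / resolution).astype(np.int64), shape[1] - 1)
    return rows, cols


def rasterize_cell(
    cell: PlaceCell,
    trajectory: Trajectory,
    percepts: Sequence[PlaceCode],
    params: FiringParams,
    arena: Arena,
    resolution: float = 0.5,
    weight_normalization: str = "current",
) -> RateMap:
    """Rasterize one cell's firing along a trajectory.

    ``percepts`` must be aligned step-by-step with ``trajectory``. Each
    visited bin holds the mean of the cell's firing rates over the
    trajectory points that fall in it.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    if len(percepts) != len(trajectory):
        raise ValueError(
            f"trajectory ({len(trajectory)} steps) and percepts ({len(percepts)}) misaligned"
        )
    extent = (arena.width, arena.height)
    shape = _grid_shape(extent, resolution)
    rows, cols = _bin_indices(trajectory.x, trajectory.y, resolution, shape)
    sums = np.zeros(shape)
    visits = np.zeros(shape, dtype=np.int64)
    for k, code in enumerate(percepts):
        r = firing_rate(cell, code, params, weight_normalization)
        sums[rows[k], cols[k]] += r
        visits[rows[k], cols[k]] += 1
    rates = np.full(shape, np.nan)
    vis = visits > 0
    rates[vis] = sums[vis] / visits[vis]
    return RateMap(rates, visits, resolution, extent)


def population_map(rate_maps: Iterable[RateMap]) -> RateMap:
    """Per-bin maximum across cell maps (identical geometry required).

    A bin is visited in the result if it is visited in any input; its
    rate is the maximum over the inputs where it is visited.
    """
    maps = list(rate_maps)
    if not maps:
        raise ValueError("population_map needs at least one rate map")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_geometry(m):
            raise ValueError("rate maps have mismatched grid geometry")
    stack = np.stack([m.rates for m in maps])
    with warnings.catch_warnings():
        # bins unvisited in every map are legitimately all-NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        rates = np.nanmax(stack, axis=0)
    visits = np.maximum.reduce([m.visits for m in maps])
    return RateMap(rates, visits, first.resolution, first.extent)


@dataclass(frozen=True)
class FieldMetrics:
    field_area_m2: float
    coverage_fraction: float


def field_metrics(rate_map: RateMap, rate_threshold: float) -> FieldMetrics:
    """Firing-field area and visited-bin coverage at a rate threshold.

    field_area = (#visited bins with rate >= threshold) * resolution^2;
    coverage_fraction = that count / #visited bins (0 if nothing was
    visited).
    """
    if not 0.0 <= rate_threshold <= 1.0:
        raise ValueError(f"rate_threshold must be in [0, 1], got {rate_threshold}")
    vis = rate_map.visited
    n_visited = int(vis.sum())
    if n_visited == 0:
        return FieldMetrics(0.0, 0.0)
    above = int(np.sum(rate_map.rates[vis] >= rate_threshold))
    return FieldMetrics(above * rate_map.resolution**2, above / n_visited)


def write_rate_map_csv(rate_map: RateMap, path: str | Path) -> None:
    """Write a rate map as a CSV matrix with a 3-line metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# resolution_m={rate_map.resolution:.12g}\n")
        fh.write(f"# extent_m={rate_map.extent[0]:.12g},{rate_map.extent[1]:.12g}\n")
        fh.write("# unvisited=NA\n")
        for row in rate_map.rates:
            fh.write(",".join("NA" if np.isnan(v) else f"{v:.12g}" for v in row) + "\n")


def read_rate_map_csv(path: str | Path) -> RateMap:
    with open(path, encoding="utf-8") as fh:
        res_line = fh.readline()
        ext_line = fh.readline()
        fh.readline()  # unvisited marker line
        resolution = float(re.search(r"resolution_m=([\d.eE+-]+)", res_line).group(1))
        w, h = re.search(r"extent_m=([\d.eE+-]+),([\d.eE+-]+)", ext_line).groups()
        rows = [
            [np.nan if v == "NA" else float(v) for v in line.strip().split(",")]
            for line in fh
            if line.strip()
        ]
    rates = np.asarray(rows)
    visits = (~np.isnan(rates)).astype(np.int64)  # counts are not serialized
    return RateMap(rates, visits, resolution, (float(w), float(h)))


def plot_rate_map(rate_map: RateMap, trajectory: Trajectory | None = None, ax=None, **imshow_kw):
    """Render a rate map (optional trajectory overlay). Needs matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w, h = rate_map.extent
    im = ax.imshow(
        rate_map.rates,
        origin="lower",
        extent=(0, w, 0, h),
        vmin=0.0,
        vmax=1.0,
        cmap=imshow_kw.pop("cmap", "jet"),
        **imshow_kw,
    )
    if trajectory is not None:
        ax.plot(trajectory.x, trajectory.y, color="black", linewidth=0.3, alpha=0.7)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return im
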