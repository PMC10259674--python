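"""MAIA 10-2 stimulus grid geometry, region subsets and per-locus areas.

The standard 10-2 pattern places 68 Goldmann-III stimuli on a 2-degree
lattice over the central visual field.  The loci are the odd-integer
coordinate pairs (x, y) in degrees of visual angle with x^2 + y^2 <= 82;
that cutoff is the unique circular one reproducing the 68-point count and
the nested central-16 / central-36 subsets used for clustered endpoint
analyses.  Coordinates are device/field coordinates: no nasal-temporal
flip is applied for left versus right eyes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: lattice spacing of the 10-2 pattern, degrees
GRID_SPACING_DEG = 2.0
#: squared-radius cutoff selecting the 68 standard loci
_RADIUS2_CUTOFF = 82

REGION_CENTRAL16 = "central16"
REGION_CENTRAL36 = "central36"
REGION_PERIPHERAL = "peripheral"


@dataclass(frozen=True)
class Locus:
    """A single stimulus location on the grid."""

    locus_id: int
    x_deg: float
    y_deg: float

    @property
    def r_deg(self) -> float:
        """Eccentricity (distance from fixation) in degrees."""
        return float(np.hypot(self.x_deg, self.y_deg))


@dataclass(frozen=True)
class Grid:
    """An ordered set of stimulus loci with region labels and cell areas.

    ``region_labels`` gives the *innermost* region each locus belongs to
    (central16 < central36 < peripheral); the central-36 subset returned by
    :meth:`region_ids` includes the central-16 loci, mirroring how the
    clustered endpoint regions nest.
    """

    loci: tuple[Locus, ...]
    region_labels: Mapping[int, str]
    areas_deg2: Mapping[int, float]

    def __post_init__(self) -> None:
        for lid, a in self.areas_deg2.items():
            if a <= 0:
                raise ValueError(f"non-positive area {a} for locus {lid}")

    @property
    def locus_ids(self) -> tuple[int, ...]:
        return tuple(l.locus_id for l in self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def coords(self) -> np.ndarray:
        """(n, 2) array of locus coordinates in grid order."""
        return np.array([[l.x_deg, l.y_deg] for l in self.loci], dtype=float)

    def region_ids(self, region: str) -> tuple[int, ...]:
        """Locus ids in a (cumulative) region: central16, central36 or all68."""
        if region in ("all", "all68"):
            return self.locus_ids
        if region == REGION_CENTRAL16:
            keep = {REGION_CENTRAL16}
        elif region == REGION_CENTRAL36:
            keep = {REGION_CENTRAL16, REGION_CENTRAL36}
        else:
            raise ValueError(f"unknown region {region!r}")
        return tuple(lid for lid in self.locus_ids if self.region_labels[lid] in keep)

    def total_area_deg2(self) -> float:
        return float(sum(self.areas_deg2[lid] for lid in self.locus_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": list(self.locus_ids),
                "x_deg": [l.x_deg for l in self.loci],
                "y_deg": [l.y_deg for l in self.loci],
                "region": [self.region_labels[l.locus_id] for l in self.loci],
                "area_deg2": [self.areas_deg2[l.locus_id] for l in self.loci],
            }
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _innermost_region(x: float, y: float) -> str:
    if abs(x) <= 3 and abs(y) <= 3:
        return REGION_CENTRAL16
    if abs(x) <= 5 and abs(y) <= 5:
        return REGION_CENTRAL36
    return REGION_PERIPHERAL


def build_grid_10_2(area_method: str = "uniform") -> Grid:
    """Construct the standard 68-locus 10-2 grid.

    Loci are ordered row-major: y descending, then x ascending, so that
    locus ids align across follow-up examinations of the same eye.
    """
    pts = [
        (x, y)
        for y in range(9, -10, -2)
        for x in range(-9, 10, 2)
        if x * x + y * y <= _RADIUS2_CUTOFF
    ]
    loci = tuple(
        Locus(locus_id=i, x_deg=float(x), y_deg=float(y))
        for i, (x, y) in enumerate(pts)
    )
    regions = {l.locus_id: _innermost_region(l.x_deg, l.y_deg) for l in loci}
    grid = Grid(loci=loci, region_labels=regions,
                areas_deg2={l.locus_id: GRID_SPACING_DEG ** 2 for l in loci})
    if area_method != "uniform":
        grid = Grid(loci=loci, region_labels=regions,
                    areas_deg2=locus_areas(grid, area_method))
    return grid


def grid_from_frame(df: pd.DataFrame) -> Grid:
    """Build a (possibly non-standard) grid from a locus table.

    Expects columns locus_id, x_deg, y_deg and optionally region, area_deg2.
    """
    loci = tuple(
        Locus(int(r.locus_id), float(r.x_deg), float(r.y_deg))
        for r in df.itertuples()
    )
    if "region" in df.columns:
        regions = dict(zip(df["locus_id"].astype(int), df["region"]))
    else:
        regions = {l.locus_id: _innermost_region(l.x_deg, l.y_deg) for l in loci}
    if "area_deg2" in df.columns:
        areas = dict(zip(df["locus_id"].astype(int), df["area_deg2"].astype(float)))
    else:
        areas = {l.locus_id: GRID_SPACING_DEG ** 2 for l in loci}
    return Grid(loci=loci, region_labels=regions, areas_deg2=areas)


def load_grid_csv(path) -> Grid:
    return grid_from_frame(pd.read_csv(path))


def locus_areas(grid: Grid, method: str = "uniform") -> dict[int, float]:
    """Per-locus cell areas in deg^2 used by volume sensitivity.

    ``uniform``
        Every locus owns a spacing x spacing square: 4.0 deg^2 on the
        standard grid, totalling 272.0 deg^2.
    ``voronoi_clipped``
        Voronoi cell of each locus clipped to the square [-10, 10]^2
        intersected with the 10-degree disc; suits irregular custom grids.
        Cell areas sum to the area of the clipped region.
    """
    if method == "uniform":
        return {lid: GRID_SPACING_DEG ** 2 for lid in grid.locus_ids}
    if method == "voronoi_clipped":
        return _voronoi_clipped_areas(grid)
    raise ValueError(f"unknown area method {method!r}")


def _voronoi_clipped_areas(grid: Grid) -> dict[int, float]:
    from scipy.spatial import Voronoi
    from shapely.geometry import Point, Polygon, box

    pts = grid.coords()
    if len(pts) == 1:
        # degenerate: the single locus owns one lattice cell
        return {grid.locus_ids[0]: GRID_SPACING_DEG ** 2}
    # ghost points far outside the clip region close every finite cell
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ghosts = 60.0 * np.c_[np.cos(theta), np.sin(theta)]
    vor = Voronoi(np.vstack([pts, ghosts]))
    clip = box(-10, -10, 10, 10).intersection(
        Point(0, 0).buffer(10.0, quad_segs=512)
    )
    areas: dict[int, float] = {}
    for i, lid in enumerate(grid.locus_ids):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # pragma: no cover - ghosts prevent this
            raise RuntimeError(f"unbounded Voronoi cell for locus {lid}")
        cell = Polygon(vor.vertices[region]).intersection(clip)
        areas[lid] = float(cell.area)
    return areas
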