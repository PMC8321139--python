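"""Geometry of the nine-subfield ETDRS macular grid.

The ETDRS grid partitions the macula into a central subfield (CS) and two
rings of four sectors each (superior / temporal / inferior / nasal, inner and
outer).  Spatial kernels need a representative point per sector; each annulus
sector is represented by its ring's mid-radius at the sector's cardinal angle,
with CS at the fovea.  All coordinates and distances are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical sector labels: central, then inner ring, then outer ring.
SECTOR_IDS = ("CS", "SI", "TI", "II", "NI", "SO", "TO", "IO", "NO")

#: Default ordering used to define the lag of the discrete autoregressive
#: kernel: centre first, then the inner ring, then the outer ring.
DEFAULT_LAG_ORDER = ("CS", "SI", "NI", "II", "TI", "SO", "NO", "IO", "TO")

# Ring boundaries of the standard grid are 0.5 / 1.5 / 3.0 mm, so the ring
# mid-radii are 1.0 mm (inner) and 2.25 mm (outer).
DEFAULT_INNER_RADIUS_MM = 1.0
DEFAULT_OUTER_RADIUS_MM = 2.25


@dataclass(frozen=True)
class SectorGrid:
    """Sector labels, centroid coordinates and pairwise distances (mm)."""

    sector_ids: tuple[str, ...]
    centroids: np.ndarray  # (n, 2) x/y in mm
    distance_matrix: np.ndarray  # (n, n) mm
    lag_order: tuple[str, ...]
    laterality: str = "right"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.sector_ids)}
        )

    @property
    def n_sectors(self) -> int:
        return len(self.sector_ids)

    def position(self, sector: str) -> int:
        try:
            return self._index[sector]
        except KeyError:
            raise KeyError(f"unknown sector {sector!r}") from None

    def lag_positions(self) -> np.ndarray:
        """Integer position of each sector under ``lag_order``, aligned
        with ``sector_ids``."""
        order = {s: i for i, s in enumerate(self.lag_order)}
        return np.array([order[s] for s in self.sector_ids])

    def lag_matrix(self) -> np.ndarray:
        pos = self.lag_positions()
        return np.abs(pos[:, None] - pos[None, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sector_id": self.sector_ids,
                "x_mm": self.centroids[:, 0],
                "y_mm": self.centroids[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_sector_grid(
    laterality: str = "right",
    inner_radius_mm: float = DEFAULT_INNER_RADIUS_MM,
    outer_radius_mm: float = DEFAULT_OUTER_RADIUS_MM,
    lag_order: tuple[str, ...] = DEFAULT_LAG_ORDER,
) -> SectorGrid:
    """Place the nine ETDRS sector centroids and compute their distances.

    Superior is at 90 deg and inferior at 270 deg; for a right eye the nasal
    sectors sit at 0 deg (temporal at 180 deg), mirrored for a left eye.
    Distances between *named* sectors are identical for the two lateralities
    (mirroring is an isometry that permutes the labels consistently).
    """
    if laterality not in ("right", "left"):
        raise ValueError(f"unknown laterality {laterality!r}")
    if not (0 < inner_radius_mm < outer_radius_mm):
        raise ValueError("require 0 < inner_radius_mm < outer_radius_mm")
    if set(lag_order) != set(SECTOR_IDS):
        raise ValueError("lag_order must be a permutation of the sector ids")

    nasal_deg = 0.0 if laterality == "right" else 180.0
    temporal_deg = 180.0 - nasal_deg
    angles = {
        "S": 90.0,
        "I": 270.0,
        "N": nasal_deg,
        "T": temporal_deg,
    }
    pts = []
    for sid in SECTOR_IDS:
        if sid == "CS":
            pts.append((0.0, 0.0))
            continue
        direction, ring = sid[0], sid[1]
        r = inner_radius_mm if ring == "I" else outer_radius_mm
        a = np.deg2rad(angles[direction])
        pts.append((r * np.cos(a), r * np.sin(a)))
    centroids = np.asarray(pts)
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    return SectorGrid(SECTOR_IDS, centroids, dist, tuple(lag_order), laterality)


def grid_from_frame(df: pd.DataFrame, laterality: str = "right",
                    lag_order: tuple[str, ...] | None = None) -> SectorGrid:
    """Build a grid from a (sector_id, x_mm, y_mm) table (custom lattices)."""
    required = {"sector_id", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"grid table needs columns {sorted(required)}")
    ids = tuple(df["sector_id"].astype(str))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sector ids in grid table")
    centroids = df[["x_mm", "y_mm"]].to_numpy(float)
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    return SectorGrid(ids, centroids, dist, tuple(lag_order or ids), laterality)


def grid_from_csv(path, **kwargs) -> SectorGrid:
    return grid_from_frame(pd.read_csv(path), **kwargs)


def lag_between(grid: SectorGrid, sector_a: str, sector_b: str) -> int:
    """Absolute separation of two sectors under the grid's lag ordering."""
    order = {s: i for i, s in enumerate(grid.lag_order)}
    for s in (sector_a, sector_b):
        if s not in order:
            raise KeyError(f"unknown sector {s!r}")
    return abs(order[sector_a] - order[sector_b])
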