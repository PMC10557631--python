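"""Visium-style hexagonal spot lattice.

The 10x Visium array places capture spots on a triangular (hex-packed)
lattice with ~100 um center-to-center spacing.  Array coordinates follow the
Visium convention: integer (row, col) with row + col even; the six lattice
neighbors of (r, c) are (r±1, c±1) and (r, c±2).  Physical coordinates are
in micrometers; pixel coordinates follow image convention (row down, col
right).

Subspots are a purely geometric subdivision of each spot into six
sub-capture areas ~20 um apart, used for resolution-enhanced cell-type
inference.  No expression smoothing happens here: subspot expression is
either supplied externally or inherited from the parent spot.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: offsets generating the six hex neighbors in (row, col) array coordinates
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 1), (1, -1), (1, 1), (0, -2), (0, 2),
)

DEFAULT_SPACING_UM = 100.0
SUBSPOTS_PER_SPOT = 6


@dataclass
class HexSpotGrid:
    """A set of spots with array, physical, and pixel coordinates.

    ``positions`` is indexed by barcode with columns ``array_row``,
    ``array_col``, ``x_um``, ``y_um``, ``pixel_row``, ``pixel_col``.
    """

    positions: pd.DataFrame
    spacing_um: float = DEFAULT_SPACING_UM
    _coord_to_barcode: dict[tuple[int, int], str] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spot spacing must be positive")
        if self.positions.index.duplicated().any():
            raise ValueError("barcodes must be unique")
        rc = self.positions[["array_row", "array_col"]].to_numpy()
        odd = (rc.sum(axis=1) % 2) != 0
        if odd.any():
            bad = self.positions.index[odd][0]
            raise ValueError(
                f"array coordinate parity violated (row+col must be even), e.g. spot {bad!r}"
            )
        self._coord_to_barcode = {
            (int(r), int(c)): bc for bc, (r, c) in zip(self.positions.index, rc)
        }

    # -- basic queries -------------------------------------------------
    def __len__(self) -> int:
        return len(self.positions)

    @property
    def barcodes(self) -> pd.Index:
        return self.positions.index

    def contains(self, coord: tuple[int, int]) -> bool:
        return (int(coord[0]), int(coord[1])) in self._coord_to_barcode

    def barcode_at(self, coord: tuple[int, int]) -> str:
        return self._coord_to_barcode[(int(coord[0]), int(coord[1]))]

    def coord_of(self, barcode: str) -> tuple[int, int]:
        row = self.positions.loc[barcode]
        return int(row["array_row"]), int(row["array_col"])

    # -- neighbor relation ---------------------------------------------
    def neighbors(self, coord: tuple[int, int]) -> set[tuple[int, int]]:
        """On-grid subset of {(r±1, c±1), (r, c±2)} for an on-grid coord."""
        r, c = int(coord[0]), int(coord[1])
        if (r, c) not in self._coord_to_barcode:
            raise KeyError(f"coordinate {(r, c)} is not on the grid")
        return {
            (r + dr, c + dc)
            for dr, dc in NEIGHBOR_OFFSETS
            if (r + dr, c + dc) in self._coord_to_barcode
        }

    def neighbor_barcodes(self, barcode: str) -> set[str]:
        return {self.barcode_at(c) for c in self.neighbors(self.coord_of(barcode))}

    def bfs_distance(self, sources: set[tuple[int, int]], max_dist: int | None = None
                     ) -> dict[tuple[int, int], int]:
        """Multi-source breadth-first hex-graph distance from ``sources``.

        Returns distances for every reached coordinate (sources at 0).  When
        ``max_dist`` is given the search stops after that many rings.
        """
        sources = {(int(r), int(c)) for r, c in sources}
        for s in sources:
            if s not in self._coord_to_barcode:
                raise KeyError(f"source coordinate {s} is not on the grid")
        dist = {s: 0 for s in sources}
        queue = deque(sources)
        while queue:
            cur = queue.popleft()
            d = dist[cur]
            if max_dist is not None and d >= max_dist:
                continue
            for nb in self.neighbors(cur):
                if nb not in dist:
                    dist[nb] = d + 1
                    queue.append(nb)
        return dist


def build_lattice(n_rows: int, n_cols: int, spacing_um: float = DEFAULT_SPACING_UM,
                  pixel_scale_um: float = 1.0, pixel_margin: float = 0.0) -> HexSpotGrid:
    """Build a full parity-valid lattice of ``n_rows`` x ``n_cols`` array coords.

    Physical centers sit on a triangular lattice: x = col * spacing / 2,
    y = row * spacing * sqrt(3) / 2, which puts every neighbor pair exactly
    ``spacing_um`` apart.  Pixel coordinates are physical coordinates divided
    by ``pixel_scale_um`` (um per pixel) plus an optional margin.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    if spacing_um <= 0:
        raise ValueError("spot spacing must be positive")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    keep = (rows + cols) % 2 == 0
    r, c = rows[keep], cols[keep]
    x = c * spacing_um / 2.0
    y = r * spacing_um * np.sqrt(3.0) / 2.0
    positions = pd.DataFrame(
        {
            "array_row": r,
            "array_col": c,
            "x_um": x,
            "y_um": y,
            "pixel_row": y / pixel_scale_um + pixel_margin,
            "pixel_col": x / pixel_scale_um + pixel_margin,
        },
        index=pd.Index([f"spot_{rr:03d}_{cc:03d}" for rr, cc in zip(r, c)], name="barcode"),
    )
    return HexSpotGrid(positions, spacing_um=spacing_um)


def subdivide_spots(grid: HexSpotGrid, k: int = SUBSPOTS_PER_SPOT) -> pd.DataFrame:
    """Subdivide every spot into ``k`` subspots arranged hexagonally.

    Only k = 6 is supported: subspot centers sit on a circle of radius
    spacing/5 around the spot center at 60-degree steps, so adjacent
    subspots within a spot are spacing/5 apart (~20 um at 100 um spacing).

    Returns a frame indexed by subspot id with parent barcode, sub-index,
    center offsets, and absolute physical/pixel coordinates.
    """
    if k != SUBSPOTS_PER_SPOT:
        raise ValueError(f"unsupported subspot count {k}; only {SUBSPOTS_PER_SPOT} supported")
    radius = grid.spacing_um / 5.0
    angles = np.deg2rad(30.0 + 60.0 * np.arange(k))
    dx = radius * np.cos(angles)
    dy = radius * np.sin(angles)
    pos = grid.positions
    n = len(pos)
    parent = np.repeat(pos.index.to_numpy(), k)
    sub_idx = np.tile(np.arange(k), n)
    off_x = np.tile(dx, n)
    off_y = np.tile(dy, n)
    px_scale = _pixel_scale(grid)
    frame = pd.DataFrame(
        {
            "parent_barcode": parent,
            "sub_index": sub_idx,
            "offset_x_um": off_x,
            "offset_y_um": off_y,
            "x_um": np.repeat(pos["x_um"].to_numpy(), k) + off_x,
            "y_um": np.repeat(pos["y_um"].to_numpy(), k) + off_y,
        },
        index=pd.Index([f"{p}:{i}" for p, i in zip(parent, sub_idx)], name="subspot"),
    )
    if px_scale is not None:
        frame["pixel_row"] = np.repeat(pos["pixel_row"].to_numpy(), k) + off_y / px_scale
        frame["pixel_col"] = np.repeat(pos["pixel_col"].to_numpy(), k) + off_x / px_scale
    return frame


def _pixel_scale(grid: HexSpotGrid) -> float | None:
    """Infer um-per-pixel from one neighbor pair, if pixel coords are present."""
    pos = grid.positions
    if "pixel_row" not in pos.columns or len(pos) < 2:
        return None
    a = pos.iloc[0]
    coord = (int(a["array_row"]), int(a["array_col"]))
    nbs = grid.neighbors(coord)
    if not nbs:
        return None
    b = pos.loc[grid.barcode_at(next(iter(nbs)))]
    d_px = float(np.hypot(a["pixel_row"] - b["pixel_row"], a["pixel_col"] - b["pixel_col"]))
    return grid.spacing_um / d_px if d_px > 0 else None
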