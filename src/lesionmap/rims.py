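"""Lesion core definition, concentric rim assignment, and subregion labels.

The lesion core is the set of spots that are both demyelinated (SB-) and
lesion-module positive.  Outward rims +1..+n are concentric hex-graph shells
(breadth-first over the [r±1, c±1] / [r, c±2] neighbor rule) extending from
the core; centripetal rims -1, -2, ... count inward from the core boundary
(-1 is the outermost core ring).  Subregion labels follow the study's
categorical scheme: SB+WM_rim.k, SB-WM_-rim.k, SB+WM_NA.Ctrl, SB-notWM_rims,
SB-notWM_EAE for diseased tissue, SB+WM_He.Ctrl / SB-notWM_He for healthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hexgrid import HexSpotGrid

HEALTHY = "healthy"
EAE = "EAE"


@dataclass
class RimLabeling:
    """Signed rim index per spot (+k outward, -k inward, 0 unassigned)."""

    rim_index: pd.Series
    is_core: pd.Series
    n_out: int
    warnings: list[str] = field(default_factory=list)

    def outward_labels(self) -> list[int]:
        vals = sorted(set(self.rim_index[self.rim_index > 0]))
        return [int(v) for v in vals]

    def inward_labels(self) -> list[int]:
        vals = sorted(set(self.rim_index[self.rim_index < 0]), reverse=True)
        return [int(v) for v in vals]


def define_lesion_core(sb_status: pd.Series, lesion_mask: pd.Series) -> pd.Series:
    """Core = {SB-} intersect {Lesion+}."""
    if not sb_status.index.equals(lesion_mask.index):
        raise ValueError("sb_status and lesion_mask are misaligned")
    core = (~sb_status.astype(bool)) & lesion_mask.astype(bool)
    core.name = "core"
    return core


def assign_rims(grid: HexSpotGrid, core: pd.Series, n_out: int = 10) -> RimLabeling:
    """Assign outward rims +1..+n_out and centripetal rims -1..-m.

    Outward: multi-source BFS from the core over the hex neighbor relation;
    a non-core spot first reached at step k gets rim +k (k <= n_out).
    Inward: BFS from the set of non-core spots into the core; a core spot at
    distance k from the nearest non-core spot gets rim -k (so -1 is the
    outermost core ring, unbounded depth).  With multiple lesions the core
    union is used, giving min-distance semantics.
    """
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    core = core.reindex(grid.barcodes).fillna(False).astype(bool)
    rim = pd.Series(0, index=grid.barcodes, name="rim_index", dtype=int)
    notes: list[str] = []
    core_coords = {grid.coord_of(bc) for bc in core.index[core]}
    if not core_coords:
        notes.append("empty lesion core: no rims assigned")
        warnings.warn(notes[-1], stacklevel=2)
        return RimLabeling(rim, core, n_out, notes)

    dist_out = grid.bfs_distance(core_coords, max_dist=n_out)
    for coord, d in dist_out.items():
        if d > 0:
            rim[grid.barcode_at(coord)] = d

    non_core = {grid.coord_of(bc) for bc in core.index[~core]}
    if non_core:
        dist_in = grid.bfs_distance(non_core)
        for coord in core_coords:
            d = dist_in.get(coord)
            if d is not None:
                rim[grid.barcode_at(coord)] = -d
            # unreachable core spots (disconnected grid) stay 0
    else:
        notes.append("core covers the whole grid: inward rims undefined")
        warnings.warn(notes[-1], stacklevel=2)
    return RimLabeling(rim, core, n_out, notes)


def label_subregions(
    rims: RimLabeling,
    sb_status: pd.Series,
    gm_mask: pd.Series,
    condition: str,
) -> pd.Series:
    """Emit the categorical subregion label for every spot (total function).

    EAE condition:
      * core spots          -> "SB-WM_-rim.k" by their inward rim index
      * outward rim in GM   -> "SB-notWM_rims"
      * outward rim not GM  -> "SB+WM_rim.k"
      * SB+ beyond the rims -> "SB+WM_NA.Ctrl" (normal-appearing WM)
      * everything else     -> "SB-notWM_EAE"
    Healthy condition: SB+ -> "SB+WM_He.Ctrl", SB- -> "SB-notWM_He".
    """
    if condition not in (HEALTHY, EAE):
        raise ValueError(f"unknown condition {condition!r}")
    idx = rims.rim_index.index
    sb = sb_status.reindex(idx).astype(bool)
    if condition == HEALTHY:
        out = pd.Series(
            np.where(sb, "SB+WM_He.Ctrl", "SB-notWM_He"), index=idx, name="subregion"
        )
        return out
    gm = gm_mask.reindex(idx).fillna(False).astype(bool)
    labels = pd.Series("SB-notWM_EAE", index=idx, name="subregion", dtype=object)
    rim = rims.rim_index
    core = rims.is_core
    outward = rim > 0
    labels[sb & ~core & ~outward] = "SB+WM_NA.Ctrl"
    sel = outward & ~gm
    labels[sel] = [f"SB+WM_rim.{int(k)}" for k in rim[sel]]
    labels[outward & gm] = "SB-notWM_rims"
    labels[core] = [f"SB-WM_-rim.{int(-k)}" if k < 0 else "SB-WM_-rim.0" for k in rim[core]]
    return labels


def rim_profiles(values: pd.Series, rims: RimLabeling) -> pd.DataFrame:
    """Per-rim mean profile along the signed rim axis.

    One row per signed rim index from the deepest inward rim to +n_out, with
    the mean of ``values`` and the spot count.  Empty rims appear with count
    0 and a missing mean (never 0).  The core is indexed by its inward rims.
    """
    rim = rims.rim_index
    values = values.reindex(rim.index)
    lo = int(rim.min()) if (rim < 0).any() else -1
    index = [k for k in range(lo, rims.n_out + 1) if k != 0]
    rows = []
    for k in index:
        sel = rim == k
        n = int(sel.sum())
        rows.append({"rim": k, "mean": values[sel].mean() if n else np.nan, "count": n})
    return pd.DataFrame(rows).set_index("rim")
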