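"""Quantitative longitudinal-MRI lesion pipeline (M3Q).

Works on co-registered proton-density-weighted (PDw) and T1-map volumes with
an atlas label volume.  Stages: PDw normalization to the cortical-GM median;
longitudinal lesion masks from the terminal-minus-baseline normalized PD
difference; partition of lesion voxels by the 1250 ms T1 cutoff into core
(T1 > cutoff) and edge; 5 concentric in-plane voxel rims outward from the
core within WM; PD-T1 joint distributions; voxelwise PD/T1 ratio maps (the
early-warning readout for pre-demyelinating tissue); lesion-age bracketing
from scan gaps; and per-tract lesion load across animals.

Volumes are numpy arrays indexed (row, col, slice); atlas labels are integer
codes with a name map.  Registration is an input contract, not an operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

# canonical atlas label codes used by the synthetic generator and the CLI
BACKGROUND, CORTICAL_GM, SUBCORTICAL_GM = 0, 1, 2
FIRST_WM_LABEL = 3  # labels >= this are named WM tracts

RIM_OUTSIDE = -1
RIM_CORE = 0


def wm_mask_from_atlas(atlas: np.ndarray) -> np.ndarray:
    return np.asarray(atlas) >= FIRST_WM_LABEL


def normalize_pd(pd_volume: np.ndarray, atlas: np.ndarray,
                 cortical_gm_label: int = CORTICAL_GM) -> np.ndarray:
    """Divide the PDw volume by the median intensity over cortical-GM voxels.

    The output median over cortical GM is exactly 1; globally rescaling the
    input leaves the output unchanged.
    """
    pd_volume = np.asarray(pd_volume, dtype=float)
    gm = np.asarray(atlas) == cortical_gm_label
    if not gm.any():
        raise ValueError("no cortical-GM voxels in the atlas volume")
    med = float(np.median(pd_volume[gm]))
    if med == 0:
        raise ValueError("cortical-GM median intensity is zero")
    return pd_volume / med


def lesion_mask(baseline_norm: np.ndarray, terminal_norm: np.ndarray,
                delta: float | None = 0.2) -> np.ndarray:
    """Binary lesion mask = {terminal - baseline > delta} on normalized PDw.

    ``delta`` is in normalized PD units (default 0.2); pass ``None`` to pick
    the threshold by Otsu on the positive part of the difference image.
    Voxels where the terminal intensity decreased are never in the mask.
    """
    baseline_norm = np.asarray(baseline_norm, dtype=float)
    terminal_norm = np.asarray(terminal_norm, dtype=float)
    if baseline_norm.shape != terminal_norm.shape:
        raise ValueError("baseline and terminal volumes have different shapes")
    diff = terminal_norm - baseline_norm
    if delta is None:
        pos = diff[diff > 0]
        delta = float(threshold_otsu(pos)) if pos.size else np.inf
    return diff > delta


def partition_by_t1(lesion: np.ndarray, t1: np.ndarray,
                    cutoff: float = 1250.0) -> tuple[np.ndarray, np.ndarray]:
    """Split lesion voxels at the T1 cutoff: core = T1 > cutoff (strict),
    edge = the rest.  Core and edge are disjoint and cover the lesion."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lesion = np.asarray(lesion, dtype=bool)
    core = lesion & (np.asarray(t1) > cutoff)
    edge = lesion & ~core
    assert not (core & edge).any() and ((core | edge) == lesion).all()
    return core, edge


def voxel_rims(core: np.ndarray, wm_mask: np.ndarray, n: int = 5,
               connectivity: int = 8, in_plane: bool = True) -> np.ndarray:
    """Concentric voxel rims outward from the lesion core within WM.

    Rim k (1..n) = voxels first reached at the k-th dilation of the core,
    intersected with the WM mask.  Dilation is in-plane 8-connected per
    slice by default (slice thickness dominates the in-plane voxel size, so
    through-plane rims are physically inconsistent); set ``in_plane=False``
    for 3D 26/6-connectivity.  Returns an int field: RIM_CORE (0) for core
    voxels, 1..n for rims, RIM_OUTSIDE (-1) elsewhere.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    core = np.asarray(core, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if core.shape != wm_mask.shape:
        raise ValueError("core and WM masks have different shapes")
    field_arr = np.full(core.shape, RIM_OUTSIDE, dtype=int)
    field_arr[core] = RIM_CORE
    if not core.any():
        warnings.warn("empty lesion core: no rims assigned", stacklevel=2)
        return field_arr
    if in_plane:
        if core.ndim != 3:
            raise ValueError("in-plane rims expect a 3D volume (row, col, slice)")
        structure = (np.ones((3, 3), dtype=bool) if connectivity == 8
                     else ndimage.generate_binary_structure(2, 1))
        reached = core.copy()
        for k in range(1, n + 1):
            grown = np.stack(
                [ndimage.binary_dilation(reached[..., z], structure=structure)
                 for z in range(core.shape[-1])], axis=-1)
            new = grown & ~reached & wm_mask
            field_arr[new] = k
            reached = grown
    else:
        structure = (np.ones((3,) * core.ndim, dtype=bool) if connectivity == 8
                     else ndimage.generate_binary_structure(core.ndim, 1))
        reached = core.copy()
        for k in range(1, n + 1):
            grown = ndimage.binary_dilation(reached, structure=structure)
            new = grown & ~reached & wm_mask
            field_arr[new] = k
            reached = grown
    return field_arr


def rim_outer_distance_um(n_rims: int, in_plane_voxel_mm: float) -> float:
    """Distance from the core to the outer boundary of rim ``n_rims``:
    each one-voxel rim extends one in-plane voxel size further out."""
    return n_rims * in_plane_voxel_mm * 1000.0


def pdt1_summary(norm_pd: np.ndarray, t1: np.ndarray, region_mask: np.ndarray,
                 bins: int = 50, t1_cutoff: float = 1250.0) -> dict[str, object]:
    """Joint (normalized PD, T1) distribution summary over a region.

    Returns the 2D histogram with its edges, the marginal medians, and the
    fraction of region voxels with T1 above the cutoff.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    pdv = np.asarray(norm_pd, dtype=float)[region_mask]
    t1v = np.asarray(t1, dtype=float)[region_mask]
    hist, pd_edges, t1_edges = np.histogram2d(pdv, t1v, bins=bins)
    return {
        "hist": hist,
        "pd_edges": pd_edges,
        "t1_edges": t1_edges,
        "median_pd": float(np.median(pdv)),
        "median_t1": float(np.median(t1v)),
        "frac_t1_above_cutoff": float(np.mean(t1v > t1_cutoff)),
        "n_voxels": int(region_mask.sum()),
    }


def pd_over_t1_ratio(norm_pd: np.ndarray, t1: np.ndarray) -> np.ndarray:
    """Voxelwise normalized-PD / T1; voxels with T1 <= 0 are masked to NaN."""
    norm_pd = np.asarray(norm_pd, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    ratio = np.full(norm_pd.shape, np.nan)
    ok = t1 > 0
    ratio[ok] = norm_pd[ok] / t1[ok]
    return ratio


@dataclass
class LesionAge:
    """Age bracket of one detection episode: (0, max_age_days] after the
    last lesion-free scan, or left-censored when present at baseline."""

    lesion_id: str
    detected_day: int
    max_age_days: float  # inf when left-censored
    left_censored: bool
    episode: int = 0
    resurrected: bool = False


def lesion_age_intervals(detection_flags: dict[str, list[bool]],
                         scan_days: list[int]) -> list[LesionAge]:
    """Bracket lesion age from per-scan detection flags and scan-day gaps.

    A lesion first seen at day t whose previous scan at day s was clean has
    age in (0, t - s]: the inter-scan gap is the maximum age.  Lesions
    present at the first scan are left-censored (no upper bound).  A
    present -> absent -> present sequence yields one record per episode,
    flagged as resurrected.
    """
    scan_days = list(scan_days)
    if any(b >= a for b, a in zip(scan_days, scan_days[1:])):
        raise ValueError("scan days must be strictly increasing")
    records: list[LesionAge] = []
    for lesion_id, flags in detection_flags.items():
        if len(flags) != len(scan_days):
            raise ValueError(f"flags for {lesion_id!r} not aligned to scan days")
        episode = 0
        prev = False
        for i, present in enumerate(flags):
            if present and not prev:
                if i == 0:
                    records.append(LesionAge(lesion_id, scan_days[0], np.inf,
                                             True, episode, episode > 0))
                else:
                    gap = scan_days[i] - scan_days[i - 1]
                    records.append(LesionAge(lesion_id, scan_days[i], float(gap),
                                             False, episode, episode > 0))
                episode += 1
            prev = present
        if episode > 1:
            for rec in records:
                if rec.lesion_id == lesion_id:
                    rec.resurrected = True
    return records


def tract_lesion_load(lesion_masks: list[np.ndarray], atlas: np.ndarray,
                      tract_names: dict[int, str] | None = None
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Across-subject per-voxel lesion hit percentage and per-tract summary.

    Returns the voxelwise percentage volume (hits / subjects * 100) and a
    table with, per WM tract: mean and max voxel percentage and the fraction
    of tract voxels hit in at least one subject.
    """
    atlas = np.asarray(atlas)
    masks = [np.asarray(m, dtype=bool) for m in lesion_masks]
    for i, m in enumerate(masks):
        if m.shape != atlas.shape:
            raise ValueError(f"subject mask {i} shape {m.shape} != atlas {atlas.shape}")
    stack = np.stack(masks)
    hit_pct = stack.mean(axis=0) * 100.0
    labels = sorted(int(v) for v in np.unique(atlas) if v >= FIRST_WM_LABEL)
    rows = []
    for lab in labels:
        sel = atlas == lab
        name = (tract_names or {}).get(lab, f"tract_{lab}")
        rows.append({
            "tract": name,
            "label": lab,
            "n_voxels": int(sel.sum()),
            "mean_voxel_pct": float(hit_pct[sel].mean()),
            "max_voxel_pct": float(hit_pct[sel].max()),
            "lesioned_voxel_fraction": float(stack.any(axis=0)[sel].mean()),
        })
    return hit_pct, pd.DataFrame(rows).set_index("tract")
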