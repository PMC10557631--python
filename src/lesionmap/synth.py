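"""Synthetic spatial-transcriptomic bundles and longitudinal MRI series.

Every downstream stage is testable against planted ground truth without any
external data.  The spatial generator emulates a Visium hex lattice carrying
a white-matter region with one or more demyelinated lesion cores, a
gray-matter band, region-specific marker programs on negative-binomial
counts, a pixel-space myelin mask consistent with the spot-level ground
truth, and (optionally) subspot-level expression with per-subspot cell-type
ground truth.  The MRI generator emulates co-registered PDw / T1-map series
with an axis-aligned atlas, in which pre-lesional voxels raise PD one
configured lead interval before T1 crosses the 1250 ms partition.

Counts are negative-binomial (gamma-Poisson), parameterized by (mean,
dispersion) with marker effects applied multiplicatively to the mean — an
assumption standing in for real overdispersed UMI data.  One master seed;
submodule streams use fixed offsets so regenerating one layer does not
perturb the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hexgrid import HexSpotGrid, build_lattice, subdivide_spots
from .subspots import GeneSetHierarchy

# fixed seed offsets per generated layer
_SEED_COUNTS = 1_000
_SEED_SUBSPOTS = 2_000
_SEED_MRI = 3_000

REGION_CORE, REGION_WM, REGION_GM = "core", "WM", "GM"


# --------------------------------------------------------------------------
# spatial bundle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """One planted lesion: hex-disc of ``radius`` rings around ``center``."""

    center: tuple[int, int]
    radius: int

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("lesion radius must be >= 0")


@dataclass
class SpatialSimConfig:
    n_rows: int = 40
    n_cols: int = 40
    spacing_um: float = 100.0
    pixel_scale_um: float = 10.0     # um per pixel of the histology frame
    lesions: tuple[LesionSpec, ...] = (LesionSpec((20, 20), 3),)
    n_genes: int = 1200
    # per-region marker programs: name -> (n marker genes, fold change >= 1)
    region_markers: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"wm": (40, 6.0), "gm": (40, 6.0), "lesion": (40, 6.0)}
    )
    # hierarchical cell-type panel
    l1_classes: tuple[str, ...] = ("IMM", "OPC", "OLI", "NEU")
    l2_per_l1: int = 2
    markers_per_l2: int = 10
    celltype_fold: float = 4.0
    baseline_mean: float = 3.0
    dispersion: float = 8.0
    gm_col_frac: float = 0.3         # right-hand fraction of columns that are GM
    subspot_expression: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_um <= 0 or self.pixel_scale_um <= 0:
            raise ValueError("spacing and pixel scale must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline mean and dispersion must be positive")
        for name, (n, fold) in self.region_markers.items():
            if fold < 1:
                raise ValueError(f"fold change for program {name!r} must be >= 1")
        if self.celltype_fold < 1:
            raise ValueError("cell-type fold change must be >= 1")
        if len(self.l1_classes) * self.l2_per_l1 < 2:
            raise ValueError("need at least 2 cell types")

    @property
    def gm_start_col(self) -> int:
        return int(round(self.n_cols * (1.0 - self.gm_col_frac)))


# built-in ligand-receptor demo table; receptor/complex names on the left of
# the alias map resolve to gene symbols (one multi-subunit receptor included)
_LR_GENES = ("VEGFA", "FLT1", "KDR", "ANGPTL2", "ITGA5", "ITGB1", "TLR4", "IL16", "CD4")


def _lr_table() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pathway": "VEGF", "ligand": "VEGFA", "receptor_subunits": "VEGFR1",
             "cofactors": ""},
            {"pathway": "ANGPTL", "ligand": "ANGPTL2",
             "receptor_subunits": "ITGA5;ITGB1", "cofactors": "TLR4"},
            {"pathway": "IL16", "ligand": "IL16", "receptor_subunits": "CD4",
             "cofactors": ""},
        ]
    )


def _lr_aliases() -> dict[str, list[str]]:
    return {"VEGFR1": ["FLT1"], "VEGFR2": ["KDR"]}


@dataclass
class GenePanels:
    gene_names: list[str]
    program_sets: dict[str, list[str]]      # wm / gm / lesion marker programs
    hierarchy: GeneSetHierarchy
    lr_table: pd.DataFrame
    aliases: dict[str, list[str]]


def generate_gene_panels(config: SpatialSimConfig) -> GenePanels:
    """Allocate marker programs, the L1/L2 hierarchy, and the LR table.

    Marker sets are disjoint blocks of the gene list; every L2 set nests
    under its L1 class (the L1 set is the union of its L2 markers).  The LR
    table carries one multi-subunit receptor and alias entries.
    """
    n_region = sum(n for n, _ in config.region_markers.values())
    n_ct = len(config.l1_classes) * config.l2_per_l1 * config.markers_per_l2
    needed = n_region + n_ct + len(_LR_GENES)
    if needed > config.n_genes:
        raise ValueError(
            f"marker panel needs {needed} genes but config.n_genes = {config.n_genes}"
        )
    names = [f"G{i:04d}" for i in range(config.n_genes - len(_LR_GENES))]
    names += list(_LR_GENES)

    cursor = 0
    program_sets: dict[str, list[str]] = {}
    for prog, (n, _) in config.region_markers.items():
        program_sets[prog] = names[cursor:cursor + n]
        cursor += n

    l1_sets: dict[str, list[str]] = {}
    l2_sets: dict[str, list[str]] = {}
    l2_parent: dict[str, str] = {}
    for l1 in config.l1_classes:
        members: list[str] = []
        for j in range(config.l2_per_l1):
            l2 = f"{l1}.{j:02d}"
            genes = names[cursor:cursor + config.markers_per_l2]
            cursor += config.markers_per_l2
            l2_sets[l2] = genes
            l2_parent[l2] = l1
            members.extend(genes)
        l1_sets[l1] = members
    hierarchy = GeneSetHierarchy(l1_sets, l2_sets, l2_parent)
    return GenePanels(names, program_sets, hierarchy, _lr_table(), _lr_aliases())


@dataclass
class SpatialBundle:
    config: SpatialSimConfig
    grid: HexSpotGrid
    counts: pd.DataFrame                  # genes x spots, integer
    mask: np.ndarray                      # pixel-space myelin (SB+) mask
    pixel_scale_um: float
    truth: pd.DataFrame                   # per spot: region, sb, core, rim_truth
    panels: GenePanels
    subspot_positions: pd.DataFrame | None = None
    subspot_counts: pd.DataFrame | None = None
    subspot_truth: pd.DataFrame | None = None


# L1-class composition per region used for subspot ground truth
_COMPOSITION = {
    REGION_CORE: {"IMM": 0.55, "OPC": 0.25, "OLI": 0.10, "NEU": 0.10},
    REGION_WM: {"IMM": 0.05, "OPC": 0.15, "OLI": 0.70, "NEU": 0.10},
    REGION_GM: {"IMM": 0.10, "OPC": 0.10, "OLI": 0.05, "NEU": 0.75},
}


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _spot_regions(config: SpatialSimConfig, grid: HexSpotGrid) -> pd.DataFrame:
    pos = grid.positions
    gm = pos["array_col"] >= config.gm_start_col
    region = pd.Series(np.where(gm, REGION_GM, REGION_WM), index=pos.index)
    core_coords: set[tuple[int, int]] = set()
    for lesion in config.lesions:
        center = (int(lesion.center[0]), int(lesion.center[1]))
        if not grid.contains(center):
            raise ValueError(f"lesion center {center} is off-lattice")
        dist = grid.bfs_distance({center}, max_dist=lesion.radius)
        core_coords.update(dist)
    core = pd.Series(False, index=pos.index)
    for coord in core_coords:
        core[grid.barcode_at(coord)] = True
    region[core] = REGION_CORE
    sb = region == REGION_WM          # myelin retained only in non-lesion WM
    rim_truth = pd.Series(-1, index=pos.index, dtype=int)
    if core_coords:
        for coord, d in grid.bfs_distance(core_coords).items():
            rim_truth[grid.barcode_at(coord)] = d
    return pd.DataFrame({"region": region, "sb": sb, "core": core,
                         "rim_truth": rim_truth})


def _rasterize_sb_mask(grid: HexSpotGrid, sb: pd.Series,
                       pixel_scale_um: float) -> np.ndarray:
    """Pixel mask whose value at each pixel is the SB status of the nearest
    spot — so a 0-round center-pixel transfer reproduces the spot truth
    exactly, and WM coverage is contiguous."""
    pos = grid.positions
    h = int(np.ceil(pos["pixel_row"].max())) + 4
    w = int(np.ceil(pos["pixel_col"].max())) + 4
    tree = cKDTree(pos[["pixel_row", "pixel_col"]].to_numpy())
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    _, nearest = tree.query(pts)
    return sb.to_numpy()[nearest].reshape(h, w)


def generate_spatial_dataset(config: SpatialSimConfig) -> SpatialBundle:
    """Generate the full synthetic spatial bundle with ground truth.

    Identical seeds give byte-identical counts.  The returned truth frame
    carries per-spot region (core / WM / GM), SB status, core membership and
    the hex-graph distance to the core (``rim_truth``; -1 when no lesion).
    """
    grid = build_lattice(config.n_rows, config.n_cols, config.spacing_um,
                         pixel_scale_um=config.pixel_scale_um, pixel_margin=2.0)
    panels = generate_gene_panels(config)
    truth = _spot_regions(config, grid)
    mask = _rasterize_sb_mask(grid, truth["sb"], config.pixel_scale_um)

    mean = np.full((config.n_genes, len(grid)), config.baseline_mean)
    gene_index = pd.Index(panels.gene_names)
    region = truth["region"].to_numpy()
    program_region = {"wm": truth["sb"].to_numpy(),
                      "gm": region == REGION_GM,
                      "lesion": truth["core"].to_numpy()}
    for prog, (n, fold) in config.region_markers.items():
        rows = gene_index.get_indexer(panels.program_sets[prog])
        cols = program_region.get(prog)
        if cols is not None and cols.any():
            mean[np.ix_(rows, cols)] *= fold
    rng = np.random.default_rng(config.seed + _SEED_COUNTS)
    counts = pd.DataFrame(_nb_counts(mean, config.dispersion, rng),
                          index=gene_index, columns=grid.barcodes)

    sub_pos = sub_counts = sub_truth = None
    if config.subspot_expression:
        sub_pos, sub_counts, sub_truth = _generate_subspot_expression(
            config, grid, truth, panels)
    return SpatialBundle(config, grid, counts, mask, config.pixel_scale_um,
                         truth, panels, sub_pos, sub_counts, sub_truth)


def _generate_subspot_expression(
    config: SpatialSimConfig, grid: HexSpotGrid, truth: pd.DataFrame,
    panels: GenePanels,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-subspot cell-type ground truth and NB counts with marker effects."""
    rng = np.random.default_rng(config.seed + _SEED_SUBSPOTS)
    sub_pos = subdivide_spots(grid)
    parent_region = truth["region"].reindex(sub_pos["parent_barcode"]).to_numpy()
    hierarchy = panels.hierarchy
    l2_names = sorted(hierarchy.l2_sets)
    l2_by_l1 = {l1: hierarchy.l2_of_class(l1) for l1 in hierarchy.l1_sets}

    chosen = np.empty(len(sub_pos), dtype=object)
    for reg, comp in _COMPOSITION.items():
        sel = parent_region == reg
        if not sel.any():
            continue
        l1_classes = [l1 for l1 in comp if l1 in l2_by_l1 and l2_by_l1[l1]]
        probs = np.array([comp[l1] for l1 in l1_classes], dtype=float)
        probs /= probs.sum()
        l1_draw = rng.choice(len(l1_classes), size=int(sel.sum()), p=probs)
        picks = []
        for k in l1_draw:
            members = l2_by_l1[l1_classes[k]]
            picks.append(members[rng.integers(len(members))])
        chosen[sel] = picks
    gene_index = pd.Index(panels.gene_names)
    mean = np.full((config.n_genes, len(sub_pos)), config.baseline_mean)
    # inherit the parent region programs so rescaling sees realistic structure
    program_region = {"wm": truth["sb"].reindex(sub_pos["parent_barcode"]).to_numpy(),
                      "gm": parent_region == REGION_GM,
                      "lesion": parent_region == REGION_CORE}
    for prog, (n, fold) in config.region_markers.items():
        rows = gene_index.get_indexer(panels.program_sets[prog])
        cols = program_region[prog]
        if cols.any():
            mean[np.ix_(rows, cols)] *= fold
    for l2 in l2_names:
        rows = gene_index.get_indexer(hierarchy.l2_sets[l2])
        cols = chosen == l2
        if cols.any():
            mean[np.ix_(rows, cols)] *= config.celltype_fold
    counts = pd.DataFrame(_nb_counts(mean, config.dispersion, rng),
                          index=gene_index, columns=sub_pos.index)
    sub_truth = pd.DataFrame(
        {"l2": chosen, "l1": [hierarchy.l2_parent[c] for c in chosen],
         "region": parent_region},
        index=sub_pos.index,
    )
    return sub_pos, counts, sub_truth


# --------------------------------------------------------------------------
# longitudinal MRI series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueClass:
    pd_mean: float
    pd_sd: float
    t1_mean: float
    t1_sd: float


@dataclass(frozen=True)
class LesionEvent:
    """A lesion appearing at ``appear_day`` at ``center`` (voxel coords),
    with in-plane radius ``radius_vox`` growing ``growth_per_scan`` voxels
    per subsequent scan, and PD elevated ``lead_days`` before appearance."""

    appear_day: float
    center: tuple[int, int, int]
    radius_vox: float = 4.0
    growth_per_scan: float = 1.0
    lead_days: float = 7.0


@dataclass
class MRISimConfig:
    shape: tuple[int, int, int] = (48, 48, 3)
    voxel_size_mm: tuple[float, float, float] = (0.15, 0.15, 1.0)
    scan_days: tuple[int, ...] = (0, 23, 30, 37, 44)
    tissues: dict[str, TissueClass] = field(default_factory=lambda: {
        "background": TissueClass(10.0, 2.0, 200.0, 10.0),
        "cortical_gm": TissueClass(1000.0, 20.0, 1500.0, 60.0),
        "subcortical_gm": TissueClass(950.0, 20.0, 1400.0, 60.0),
        "wm": TissueClass(700.0, 15.0, 900.0, 40.0),
    })
    lesion_t1: TissueClass = TissueClass(0.0, 0.0, 2000.0, 80.0)
    lesion_pd_factor: float = 1.5
    lesions: tuple[LesionEvent, ...] = (LesionEvent(37.0, (30, 12, 1)),)
    seed: int = 0

    def __post_init__(self) -> None:
        days = list(self.scan_days)
        if any(b >= a for b, a in zip(days, days[1:])):
            raise ValueError("scan days must be strictly increasing")
        for name, tc in self.tissues.items():
            if tc.t1_mean <= 0:
                raise ValueError(f"T1 mean for {name!r} must be positive")
        if self.lesion_t1.t1_mean <= 1250.0:
            raise ValueError("lesion-core T1 mean must exceed 1250 ms by construction")
        if self.tissues["wm"].t1_mean >= 1250.0:
            raise ValueError("healthy-WM T1 mean must stay below 1250 ms")


#: atlas label codes emitted by the generator (matching lesionmap.m3q)
LABEL_NAMES = {0: "background", 1: "cortical_gm", 2: "subcortical_gm",
               3: "tract_a", 4: "tract_b"}
_LABEL_TISSUE = {0: "background", 1: "cortical_gm", 2: "subcortical_gm",
                 3: "wm", 4: "wm"}


def _build_atlas(shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned blocks: background border, a cortical-GM band, a
    subcortical-GM block, and two WM tracts splitting the remainder."""
    nr, nc, nz = shape
    atlas = np.zeros(shape, dtype=int)
    b = 2                                    # background border
    atlas[b:nr - b, b:nc - b, :] = 3          # default: WM tract A
    atlas[b:min(10, nr - b), b:nc - b, :] = 1  # cortical GM band at the top
    r0, r1 = 10, min(16, nr - b)
    c0 = max(b, int(nc * 0.58))
    atlas[r0:r1, c0:nc - b, :] = 2            # subcortical GM block
    wm = atlas == 3
    right = np.zeros(shape, dtype=bool)
    right[:, nc // 2:, :] = True
    atlas[wm & right] = 4                     # WM tract B (right half)
    return atlas


@dataclass
class MRISeries:
    config: MRISimConfig
    scan_days: tuple[int, ...]
    atlas: np.ndarray
    label_names: dict[int, str]
    pd_volumes: list[np.ndarray]
    t1_volumes: list[np.ndarray]
    lesion_masks: list[np.ndarray]        # ground truth: T1-elevated voxels
    pd_elevated_masks: list[np.ndarray]   # ground truth: PD-elevated voxels
    notes: list[str] = field(default_factory=list)


def _lesion_region(event: LesionEvent, shape: tuple[int, int, int],
                   radius: float) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disc = (rr - event.center[0]) ** 2 + (cc - event.center[1]) ** 2 <= radius**2
    region = np.zeros(shape, dtype=bool)
    region[:, :, event.center[2]] = disc
    return region


def generate_mri_series(config: MRISimConfig) -> MRISeries:
    """Generate the longitudinal PDw / T1 series with ground-truth masks.

    Per scan day: tissue-class means (per the atlas) plus lesion effects,
    with Gaussian voxel noise drawn fresh per scan.  A lesion's PD rises by
    ``lesion_pd_factor`` at scans within ``lead_days`` before its appearance
    day; from the appearance day on, T1 switches to the lesion-core
    distribution (above the 1250 ms partition) and PD stays elevated while
    the radius grows per scan.
    """
    atlas = _build_atlas(config.shape)
    gaps = np.diff(config.scan_days)
    notes: list[str] = []
    for event in config.lesions:
        if len(gaps) and event.lead_days >= gaps.min():
            notes.append(
                f"lesion at {event.center}: PD lead {event.lead_days} d >= "
                f"shortest scan gap {int(gaps.min())} d; may be flagged one scan early"
            )
            warnings.warn(notes[-1], stacklevel=2)

    pd_mean = np.zeros(config.shape)
    pd_sd = np.zeros(config.shape)
    t1_mean = np.zeros(config.shape)
    t1_sd = np.zeros(config.shape)
    for label, tissue in _LABEL_TISSUE.items():
        tc = config.tissues[tissue]
        sel = atlas == label
        pd_mean[sel], pd_sd[sel] = tc.pd_mean, tc.pd_sd
        t1_mean[sel], t1_sd[sel] = tc.t1_mean, tc.t1_sd

    pd_volumes, t1_volumes, lesion_masks, pd_masks = [], [], [], []
    for i, day in enumerate(config.scan_days):
        pm, ps = pd_mean.copy(), pd_sd.copy()
        tm, ts = t1_mean.copy(), t1_sd.copy()
        t1_region = np.zeros(config.shape, dtype=bool)
        pd_region = np.zeros(config.shape, dtype=bool)
        for event in config.lesions:
            def _radius_at(when: float) -> float | None:
                if when < event.appear_day:
                    return None
                n_growth = sum(1 for d in config.scan_days
                               if event.appear_day <= d <= when) - 1
                return event.radius_vox + event.growth_per_scan * max(n_growth, 0)

            r_t1 = _radius_at(day)
            if r_t1 is not None:
                t1_region |= _lesion_region(event, config.shape, r_t1)
            # PD rises in each voxel one lead interval before its T1 does,
            # so the PD extent at day d is the T1 extent at day d + lead
            r_pd = _radius_at(day + event.lead_days)
            if r_pd is not None:
                pd_region |= _lesion_region(event, config.shape, r_pd)
        pm[pd_region] *= config.lesion_pd_factor
        tm[t1_region] = config.lesion_t1.t1_mean
        ts[t1_region] = config.lesion_t1.t1_sd
        rng = np.random.default_rng(config.seed + _SEED_MRI + i)
        pd_volumes.append(np.maximum(rng.normal(pm, ps), 0.0))
        t1_volumes.append(np.maximum(rng.normal(tm, ts), 1.0))
        lesion_masks.append(t1_region)
        pd_masks.append(pd_region)
    return MRISeries(config, tuple(config.scan_days), atlas, dict(LABEL_NAMES),
                     pd_volumes, t1_volumes, lesion_masks, pd_masks, notes)
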