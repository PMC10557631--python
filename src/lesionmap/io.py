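"""Loaders and writers for the pipeline's external formats.

Spatial bundles use the Visium on-disk dialect: a genes x spots MTX matrix
with genes.tsv / barcodes.tsv sidecars and a tissue-positions CSV (barcode,
in_tissue, array_row, array_col, pixel_row, pixel_col).  Masks are
single-channel PNG/TIFF; MRI volumes are NIfTI with the voxel size on the
affine diagonal; tables are TSV.  Every CLI run emits a PipelineRunRecord
(config snapshot, seed registry, checksummed output manifest) sufficient to
re-run the stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .hexgrid import HexSpotGrid, DEFAULT_SPACING_UM

logger = logging.getLogger("lesionmap")

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "pixel_row", "pixel_col"]


# --------------------------------------------------------------------------
# spot positions
# --------------------------------------------------------------------------

def write_positions_csv(grid: HexSpotGrid, path: str | Path) -> None:
    pos = grid.positions
    out = pd.DataFrame({
        "barcode": pos.index,
        "in_tissue": 1,
        "array_row": pos["array_row"].astype(int),
        "array_col": pos["array_col"].astype(int),
        "pixel_row": pos["pixel_row"],
        "pixel_col": pos["pixel_col"],
    })
    out.to_csv(path, index=False)


def read_positions_csv(path: str | Path,
                       spacing_um: float = DEFAULT_SPACING_UM) -> HexSpotGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"positions file missing: {path}")
    table = pd.read_csv(path)
    missing = [c for c in POSITION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"positions CSV missing columns {missing}")
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            r, c = int(row.array_row), int(row.array_col)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed positions row {i}: {row}") from exc
        if (r + c) % 2 != 0:
            raise ValueError(
                f"positions row {i} (barcode {row.barcode!r}) violates "
                f"array-coordinate parity: ({r}, {c})"
            )
    table = table[table["in_tissue"] == 1]
    positions = table.set_index("barcode")[
        ["array_row", "array_col", "pixel_row", "pixel_col"]
    ].astype(float)
    positions[["array_row", "array_col"]] = positions[["array_row", "array_col"]].astype(int)
    # physical coordinates back-computed from the lattice convention
    positions["x_um"] = positions["array_col"] * spacing_um / 2.0
    positions["y_um"] = positions["array_row"] * spacing_um * np.sqrt(3.0) / 2.0
    positions = positions[["array_row", "array_col", "x_um", "y_um",
                           "pixel_row", "pixel_col"]]
    return HexSpotGrid(positions, spacing_um=spacing_um)


# --------------------------------------------------------------------------
# count matrices (MTX, genes x units on disk)
# --------------------------------------------------------------------------

def write_counts_mtx(counts: pd.DataFrame, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(directory / "genes.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(counts.columns).to_csv(directory / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_counts_mtx(directory: str | Path) -> pd.DataFrame:
    directory = Path(directory)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"count matrix file missing: {directory / name}")
    mat = spio.mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    return pd.DataFrame(dense, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(barcodes, name="barcode"))


def load_spatial_bundle(directory: str | Path,
                        spacing_um: float = DEFAULT_SPACING_UM
                        ) -> tuple[HexSpotGrid, pd.DataFrame, np.ndarray | None]:
    """Load (grid, counts, optional mask) from a bundle directory.

    Barcodes present in the matrix but absent from the positions table (or
    vice versa) are dropped to the intersection with a logged warning.
    """
    directory = Path(directory)
    grid = read_positions_csv(directory / "tissue_positions.csv", spacing_um)
    counts = read_counts_mtx(directory)
    shared = counts.columns.intersection(grid.barcodes)
    n_drop = (len(counts.columns) - len(shared)) + (len(grid.barcodes) - len(shared))
    if n_drop:
        warnings.warn(f"{n_drop} barcodes unmatched between matrix and positions; "
                      "reconciled to the intersection", stacklevel=2)
        logger.warning("dropped %d unmatched barcodes", n_drop)
        counts = counts[shared]
        grid = HexSpotGrid(grid.positions.loc[shared], spacing_um=grid.spacing_um)
    mask = None
    mask_path = directory / "mask.png"
    if mask_path.exists():
        mask = np.asarray(iio.imread(mask_path)) > 0
    return grid, counts, mask


def write_spatial_bundle(bundle, directory: str | Path) -> None:
    """Write a synthetic SpatialBundle in the loader's dialect plus truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(bundle.counts, directory)
    write_positions_csv(bundle.grid, directory / "tissue_positions.csv")
    write_mask(bundle.mask, directory / "mask.png")
    bundle.truth.to_csv(directory / "truth.tsv", sep="\t")
    gene_sets = pd.DataFrame(
        [(name, g) for name, genes in bundle.panels.program_sets.items() for g in genes],
        columns=["set_id", "gene"],
    )
    gene_sets.to_csv(directory / "gene_sets.tsv", sep="\t", index=False)
    bundle.panels.hierarchy.to_table().to_csv(directory / "hierarchy.tsv",
                                              sep="\t", index=False)
    bundle.panels.lr_table.to_csv(directory / "lr_pairs.tsv", sep="\t", index=False)
    if bundle.subspot_counts is not None:
        sub_dir = directory / "subspots"
        write_counts_mtx(bundle.subspot_counts, sub_dir)
        bundle.subspot_truth.to_csv(sub_dir / "truth.tsv", sep="\t")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def to_anndata(counts: pd.DataFrame, grid: HexSpotGrid):
    """Package counts + spot coordinates as an AnnData (units x genes)."""
    import anndata as ad

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.to_numpy().T),
        obs=grid.positions.loc[counts.columns, ["array_row", "array_col"]].copy(),
        var=pd.DataFrame(index=counts.index),
    )
    adata.obsm["spatial"] = grid.positions.loc[
        counts.columns, ["pixel_col", "pixel_row"]
    ].to_numpy()
    return adata


# --------------------------------------------------------------------------
# MRI volumes
# --------------------------------------------------------------------------

def write_nifti(volume: np.ndarray, path: str | Path,
                voxel_size_mm: tuple[float, float, float] = (0.15, 0.15, 1.0)) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file missing: {path}")
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), vox


def write_mri_series(series, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = series.config.voxel_size_mm
    for day, pdw, t1, les in zip(series.scan_days, series.pd_volumes,
                                 series.t1_volumes, series.lesion_masks):
        write_nifti(pdw, directory / f"pdw_day{day:04d}.nii", vox)
        write_nifti(t1, directory / f"t1_day{day:04d}.nii", vox)
        write_nifti(les.astype(float), directory / f"lesion_truth_day{day:04d}.nii", vox)
    write_nifti(series.atlas.astype(float), directory / "atlas.nii", vox)
    pd.Series(series.label_names).rename("name").to_csv(
        directory / "atlas_labels.tsv", sep="\t")
    with open(directory / "series.json", "w") as fh:
        json.dump({"scan_days": list(series.scan_days),
                   "voxel_size_mm": list(vox)}, fh, indent=2)


def load_mri_series(directory: str | Path):
    """Load (scan_days, pd_volumes, t1_volumes, atlas, label_names, voxel_size)."""
    directory = Path(directory)
    meta_path = directory / "series.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"series metadata missing: {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    days = meta["scan_days"]
    pd_volumes, t1_volumes = [], []
    for day in days:
        pd_volumes.append(read_nifti(directory / f"pdw_day{day:04d}.nii")[0])
        t1_volumes.append(read_nifti(directory / f"t1_day{day:04d}.nii")[0])
    atlas = read_nifti(directory / "atlas.nii")[0].round().astype(int)
    labels = pd.read_csv(directory / "atlas_labels.tsv", sep="\t", index_col=0)[
        "name"].to_dict()
    return days, pd_volumes, t1_volumes, atlas, labels, tuple(meta["voxel_size_mm"])


# --------------------------------------------------------------------------
# run records
# --------------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineRunRecord:
    """Config snapshot, seed registry, and checksummed output manifest."""

    stage: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def time_stage(self, name: str, started: float) -> None:
        self.timings_s[name] = round(time.perf_counter() - started, 4)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path: str | Path) -> "PipelineRunRecord":
        with open(path) as fh:
            return cls(**json.load(fh))
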