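"""Histology stain separation and mask transfer to the spot lattice.

The myelin (Sudan black, SB+) white-matter mask is extracted from an RGB
histology image by optical-density colour deconvolution, thresholded, dilated
with an 8-neighbor structuring element (5 rounds by default), and projected
onto the Visium lattice: a spot is SB+ when the dilated mask is foreground at
the pixel nearest the spot center (an any-pixel-in-footprint rule is
available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .hexgrid import HexSpotGrid

# Ruifrok-Johnston published stain OD vectors for the "H DAB" preset:
# hematoxylin, DAB; the third channel is the residual complement.
H_DAB_ROWS = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.268, 0.570, 0.776],
    ]
)


@dataclass
class StainMatrix:
    """3x3 matrix of unit-length stain optical-density row vectors."""

    rows: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.rows, dtype=float)
        if m.shape == (2, 3):
            m = np.vstack([m, np.cross(m[0], m[1])])
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3 (or 2x3 with residual computed)")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be nonzero")
        m = m / norms[:, None]
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain matrix is singular")
        self.rows = m

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.rows)

    @classmethod
    def h_dab(cls) -> "StainMatrix":
        return cls(H_DAB_ROWS.copy(), name="H DAB")


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density of an 8-bit RGB image: OD = -log10(I/255), I clipped to 1."""
    img = np.clip(np.asarray(image, dtype=float), 1.0, 255.0)
    return -np.log10(img / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(255.0 * np.power(10.0, -od), 0, 255)


def deconvolve_stains(image: np.ndarray, stains: StainMatrix | None = None) -> np.ndarray:
    """Unmix an RGB image into per-stain concentration channels.

    Each pixel's OD vector is projected through the inverse stain matrix:
    with stain rows S (stains x rgb), OD = C @ S, so C = OD @ inv(S).
    Returns an (..., 3) float array of stain concentrations; pure white maps
    to ~0 everywhere.
    """
    stains = stains or StainMatrix.h_dab()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = rgb_to_od(image)
    return od @ stains.inverse


def threshold_channel(channel: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binarize one concentration channel; Otsu when no threshold is given."""
    channel = np.asarray(channel, dtype=float)
    if threshold is None:
        threshold = float(threshold_otsu(channel))
    return channel > threshold


def dilate_mask(mask: np.ndarray, rounds: int, connectivity: int = 8) -> np.ndarray:
    """Morphological dilation, ``rounds`` applications of a 3x3 (8-conn) or
    cross (4-conn) structuring element.  Monotone: input is a subset of output."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if rounds == 0 or not mask.any() or mask.all():
        return mask.copy()
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    return ndimage.binary_dilation(mask, structure=structure, iterations=rounds)


def mask_to_spot_status(
    mask: np.ndarray,
    grid: HexSpotGrid,
    rounds: int = 5,
    connectivity: int = 8,
    rule: str = "center",
    footprint_radius_px: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Transfer a pixel mask to per-spot SB status.

    The mask is dilated ``rounds`` times, then each spot is SB+ iff the
    dilated mask is foreground at the pixel nearest the spot center
    (``rule="center"``) or anywhere within ``footprint_radius_px`` of it
    (``rule="footprint"``).  Spots whose center falls outside the mask bounds
    are flagged (returned in the second series) rather than dropped; their
    status is False.
    """
    if rule not in ("center", "footprint"):
        raise ValueError("rule must be 'center' or 'footprint'")
    dilated = dilate_mask(mask, rounds, connectivity=connectivity)
    pos = grid.positions
    rows = np.rint(pos["pixel_row"].to_numpy()).astype(int)
    cols = np.rint(pos["pixel_col"].to_numpy()).astype(int)
    h, w = dilated.shape
    oob = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    status = np.zeros(len(pos), dtype=bool)
    inb = ~oob
    if rule == "center":
        status[inb] = dilated[rows[inb], cols[inb]]
    else:
        radius = footprint_radius_px if footprint_radius_px is not None else 1.0
        rr = int(np.ceil(radius))
        dr, dc = np.meshgrid(np.arange(-rr, rr + 1), np.arange(-rr, rr + 1), indexing="ij")
        disk = (dr**2 + dc**2) <= radius**2
        offs = np.stack([dr[disk], dc[disk]], axis=1)
        for i in np.flatnonzero(inb):
            pts = offs + (rows[i], cols[i])
            ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
            status[i] = bool(dilated[pts[ok, 0], pts[ok, 1]].any())
    if oob.any():
        warnings.warn(
            f"{int(oob.sum())} spot centers fall outside the mask bounds; flagged SB-",
            stacklevel=2,
        )
    return (
        pd.Series(status, index=pos.index, name="sb_positive"),
        pd.Series(oob, index=pos.index, name="out_of_bounds"),
    )
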