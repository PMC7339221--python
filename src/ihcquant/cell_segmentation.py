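"""Nuclei detection, cytoplasm rings, and tissue-region assignment.

Nuclei are detected in the hematoxylin concentration channel with a
deterministic classical pipeline: Gaussian smoothing, global thresholding,
hole filling, size filtering, then a distance-transform watershed to split
touching nuclei.  Because no membrane stain is available, each cell's
cytoplasm is approximated by a ring of fixed width around its nucleus,
partitioned between neighbouring cells by nearest-nucleus distance.

Cells are assigned to an annotated tissue region (glandular epithelium vs
interstitial stroma) by majority vote of their nucleus pixels over a region
mask; ties and majority-unannotated nuclei are excluded from scoring.

Conventions: pixel coordinates are 0-based ``(row, col)``; connected
components use 4-connectivity, watershed basins 8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .exceptions import FormatError, ParameterError

GLANDULAR = "glandular"
INTERSTITIAL = "interstitial"
EXCLUDED = "excluded"

#: RegionMask raster codes.
REGION_CODES = {1: GLANDULAR, 2: INTERSTITIAL}

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the nuclei detector.

    Defaults are sized for TMA-core images at roughly 0.5 um/px where
    nuclei are ~10-20 px across.
    """

    smooth_sigma: float = 1.5          # px, Gaussian pre-smoothing
    threshold_method: str = "otsu"     # "otsu" | "fixed"
    fixed_threshold: float = 0.1       # OD-equivalent units (fixed method)
    min_area: int = 30                 # px^2
    max_area: int = 1500               # px^2
    seed_min_distance: int = 7         # px between watershed seeds
    ring_width: int = 4                # px, cytoplasm ring
    exclude_border: bool = True

    def __post_init__(self):
        if self.min_area >= self.max_area:
            raise ParameterError("min_area must be < max_area")
        if self.smooth_sigma < 0:
            raise ParameterError("smooth_sigma must be >= 0")
        if self.ring_width < 1:
            raise ParameterError("ring_width must be >= 1")
        if self.seed_min_distance < 1:
            raise ParameterError("seed_min_distance must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(f"unknown threshold_method {self.threshold_method!r}")


@dataclass
class Cell:
    """One detected cell: nucleus pixel set, cytoplasm ring, and region label."""

    id: int
    nucleus_rc: Tuple[np.ndarray, np.ndarray]
    cytoplasm_rc: Tuple[np.ndarray, np.ndarray]
    centroid: Tuple[float, float]
    region: str

    @property
    def nucleus_area(self) -> int:
        return int(self.nucleus_rc[0].size)

    @property
    def cytoplasm_area(self) -> int:
        return int(self.cytoplasm_rc[0].size)


def segment_nuclei(hema: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Detect nuclei in a hematoxylin concentration channel.

    Pipeline: Gaussian smooth -> threshold -> fill holes -> drop components
    outside [min_area, max_area] -> Euclidean distance transform -> local
    maxima seeds (>= seed_min_distance apart, per component) -> watershed
    split -> contiguous relabel.

    Returns an (H, W) int label image; 0 is background.  An all-background
    image yields a valid empty labeling.
    """
    hema = np.asarray(hema, dtype=float)
    if hema.ndim != 2:
        raise FormatError("hematoxylin channel must be 2-D")
    smoothed = ndi.gaussian_filter(hema, params.smooth_sigma) if params.smooth_sigma > 0 else hema

    if params.threshold_method == "otsu":
        if smoothed.max() - smoothed.min() < 1e-12:
            return np.zeros(hema.shape, dtype=np.int32)
        fg = smoothed > threshold_otsu(smoothed)
    else:
        fg = smoothed >= params.fixed_threshold
    fg = ndi.binary_fill_holes(fg)

    lbl, n = ndi.label(fg, structure=_STRUCT4)
    if n == 0:
        return np.zeros(hema.shape, dtype=np.int32)
    sizes = np.bincount(lbl.ravel())
    keep = (sizes >= params.min_area) & (sizes <= params.max_area)
    keep[0] = False
    fg = keep[lbl]
    if not fg.any():
        return np.zeros(hema.shape, dtype=np.int32)
    lbl, n = ndi.label(fg, structure=_STRUCT4)

    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(
        dist,
        min_distance=params.seed_min_distance,
        exclude_border=False,
        labels=lbl,
    )
    marker_mask = np.zeros(fg.shape, dtype=bool)
    marker_mask[tuple(coords.T)] = True
    markers, _ = ndi.label(marker_mask, structure=np.ones((3, 3), dtype=bool))
    ws = watershed(-dist, markers, mask=fg, connectivity=2)
    relabeled, _, _ = relabel_sequential(ws)
    return relabeled.astype(np.int32)


def make_cytoplasm_rings(labels: np.ndarray, ring_width: int) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Cytoplasm ring pixel sets for every nucleus label.

    Cell ``k`` owns the background pixels within ``ring_width`` (Euclidean)
    of its nucleus, excluding all nucleus pixels; pixels contested between
    nuclei go to the nearest one, exact distance ties to the lower label id.
    Rings are pairwise disjoint and clipped at the image border.
    """
    if ring_width < 1:
        raise ParameterError("ring_width must be >= 1")
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rings: Dict[int, Tuple[np.ndarray, np.ndarray]] = {
        int(k): (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)) for k in ids
    }
    if not ids.size:
        return rings

    nuc_mask = labels > 0
    dist = ndi.distance_transform_edt(~nuc_mask)
    cand = (~nuc_mask) & (dist <= ring_width)
    if not cand.any():
        return rings

    site_coords = np.argwhere(nuc_mask)
    site_labels = labels[nuc_mask]
    tree = cKDTree(site_coords)
    q = np.argwhere(cand)
    k = min(30, len(site_coords))  # tie candidates; >30 equidistant sites is negligible
    d, idx = tree.query(q, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    lab = site_labels[idx].astype(np.int64)
    tied = d <= d[:, :1] + 1e-9
    lab[~tied] = np.iinfo(np.int64).max
    owner = lab.min(axis=1)

    order = np.argsort(owner, kind="stable")
    owner_sorted = owner[order]
    q_sorted = q[order]
    starts = np.searchsorted(owner_sorted, ids)
    ends = np.searchsorted(owner_sorted, ids, side="right")
    for kid, s, e in zip(ids, starts, ends):
        pix = q_sorted[s:e]
        rings[int(kid)] = (pix[:, 0].copy(), pix[:, 1].copy())
    return rings


def assign_region(nucleus_rc: Tuple[np.ndarray, np.ndarray], mask: np.ndarray) -> str:
    """Majority vote of nucleus pixels over the region mask.

    Returns ``glandular`` or ``interstitial``; a strict plurality of
    unannotated pixels, or a glandular/interstitial tie, yields
    ``excluded``.
    """
    vals = mask[nucleus_rc]
    n1 = int(np.count_nonzero(vals == 1))
    n2 = int(np.count_nonzero(vals == 2))
    n0 = vals.size - n1 - n2
    if n0 > max(n1, n2):
        return EXCLUDED
    if n1 > n2:
        return GLANDULAR
    if n2 > n1:
        return INTERSTITIAL
    return EXCLUDED


def extract_cells(
    labels: np.ndarray,
    rings: Dict[int, Tuple[np.ndarray, np.ndarray]],
    mask: np.ndarray,
    params: SegmentationParams,
) -> List[Cell]:
    """Assemble the per-cell records from a labeling, its rings, and a mask.

    Cells whose nucleus touches the image border are dropped when
    ``exclude_border``; cells in unannotated/tied regions are kept but
    flagged ``excluded``.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask)
    if labels.shape != mask.shape:
        raise FormatError(f"label/mask shape mismatch: {labels.shape} vs {mask.shape}")
    h, w = labels.shape
    cells: List[Cell] = []
    objects = ndi.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == k
        rr, cc = np.nonzero(sub)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        if params.exclude_border and (
            rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1
        ):
            continue
        ring = rings.get(k, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))
        cells.append(
            Cell(
                id=k,
                nucleus_rc=(rr, cc),
                cytoplasm_rc=ring,
                centroid=(float(rr.mean()), float(cc.mean())),
                region=assign_region((rr, cc), mask),
            )
        )
    return cells


def cells_to_frame(cells: List[Cell]) -> pd.DataFrame:
    """Per-cell geometry table (one row per cell)."""
    return pd.DataFrame(
        {
            "cell_id": [c.id for c in cells],
            "centroid_row": [c.centroid[0] for c in cells],
            "centroid_col": [c.centroid[1] for c in cells],
            "nucleus_area": [c.nucleus_area for c in cells],
            "cytoplasm_area": [c.cytoplasm_area for c in cells],
            "region": [c.region for c in cells],
        }
    )
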