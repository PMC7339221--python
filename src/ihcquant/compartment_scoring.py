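"""Percent-positive scoring of DAB staining per compartment and region.

Each cell's nuclear and cytoplasmic DAB signal is the arithmetic mean of the
deconvolved DAB concentration over its pixel set.  A cell compartment is
positive when that mean reaches a single global cut-off applied unchanged to
every image of a run, which removes observer variation in calling positives.
A core's score is the percentage of positive cells per
{glandular, interstitial} x {nucleus, cytoplasm} cell stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cell_segmentation as seg
from . import stain_separation as stains
from .cell_segmentation import Cell, SegmentationParams
from .exceptions import FormatError, IntegrityError, ParameterError

REGIONS = (seg.GLANDULAR, seg.INTERSTITIAL)
COMPARTMENTS = ("nucleus", "cytoplasm")
MARKERS = ("CXCR3", "CXCR4", "CXCR7")


@dataclass(frozen=True)
class PositivityConfig:
    """Global positivity rule: mean compartment DAB vs one fixed cut-off."""

    marker: str = "CXCR3"
    dab_threshold: float = 0.15  # OD-equivalent units
    statistic: str = "mean"

    def __post_init__(self):
        if self.dab_threshold <= 0:
            raise ParameterError("dab_threshold must be > 0")
        if self.statistic != "mean":
            raise ParameterError("only the 'mean' statistic is supported")


@dataclass
class CellScore:
    cell_id: int
    nuc_dab: float
    cyt_dab: float  # NaN when the cytoplasm ring is empty
    nuc_positive: bool
    cyt_positive: bool
    region: str


@dataclass
class CoreScore:
    """Percent-positive per region x compartment for one marker on one core."""

    patient_id: str
    marker: str
    pct: Dict[Tuple[str, str], float] = field(default_factory=dict)
    n_cells: Dict[str, int] = field(default_factory=dict)

    def as_row(self) -> Dict[str, object]:
        return {
            "patient_id": self.patient_id,
            "marker": self.marker,
            "pct_gland_nuc": self.pct[(seg.GLANDULAR, "nucleus")],
            "pct_gland_cyt": self.pct[(seg.GLANDULAR, "cytoplasm")],
            "pct_inter_nuc": self.pct[(seg.INTERSTITIAL, "nucleus")],
            "pct_inter_cyt": self.pct[(seg.INTERSTITIAL, "cytoplasm")],
            "n_gland": self.n_cells[seg.GLANDULAR],
            "n_inter": self.n_cells[seg.INTERSTITIAL],
        }


def cell_compartment_intensity(cell: Cell, dab: np.ndarray) -> Tuple[float, float]:
    """Mean DAB concentration over the nucleus and the cytoplasm ring.

    An empty cytoplasm ring yields NaN for the cytoplasmic value; an empty
    nucleus is an integrity violation (cells are nucleus-defined).
    """
    if cell.nucleus_rc[0].size == 0:
        raise IntegrityError(f"cell {cell.id} has an empty nucleus")
    nuc = float(dab[cell.nucleus_rc].mean())
    cyt = float(dab[cell.cytoplasm_rc].mean()) if cell.cytoplasm_rc[0].size else math.nan
    return nuc, cyt


def score_cells(cells: Sequence[Cell], dab: np.ndarray, cfg: PositivityConfig) -> List[CellScore]:
    """Apply the global cut-off to every cell's compartment means."""
    out: List[CellScore] = []
    for cell in cells:
        nuc, cyt = cell_compartment_intensity(cell, dab)
        out.append(
            CellScore(
                cell_id=cell.id,
                nuc_dab=nuc,
                cyt_dab=cyt,
                nuc_positive=nuc >= cfg.dab_threshold,
                cyt_positive=(not math.isnan(cyt)) and cyt >= cfg.dab_threshold,
                region=cell.region,
            )
        )
    return out


def percent_positive(
    scores: Sequence[CellScore], region: str, compartment: str, cfg: PositivityConfig
) -> float:
    """100 x positive cells / cells in the region; NaN when the region is empty.

    Cells with a missing compartment value stay in the denominator as
    negatives, so denominators always equal the region's cell count.
    """
    if compartment not in COMPARTMENTS:
        raise ParameterError(f"unknown compartment {compartment!r}")
    in_region = [s for s in scores if s.region == region]
    if not in_region:
        return math.nan
    flag = "nuc_positive" if compartment == "nucleus" else "cyt_positive"
    n_pos = sum(1 for s in in_region if getattr(s, flag))
    return 100.0 * n_pos / len(in_region)


def score_core(
    img: np.ndarray,
    mask: np.ndarray,
    cfg: PositivityConfig,
    seg_params: SegmentationParams,
    stain_matrix: Optional[np.ndarray] = None,
    patient_id: str = "",
    i0=255.0,
    eps_intensity: float = 1.0,
) -> CoreScore:
    """Full scoring of one core image: deconvolve, segment, score.

    Deterministic given inputs.  A blank image scores zero cells and all
    four percentages missing.
    """
    img = np.asarray(img)
    mask = np.asarray(mask)
    if img.shape[:2] != mask.shape:
        raise FormatError(f"image {img.shape[:2]} and mask {mask.shape} dimensions differ")
    m = stains.build_stain_matrix() if stain_matrix is None else np.asarray(stain_matrix, float)
    od = stains.rgb_to_od(img, i0=i0, eps_intensity=eps_intensity)
    conc = stains.deconvolve(od, m)
    labels = seg.segment_nuclei(conc[..., 0], seg_params)
    rings = seg.make_cytoplasm_rings(labels, seg_params.ring_width)
    cells = seg.extract_cells(labels, rings, mask, seg_params)
    scores = score_cells(cells, conc[..., 1], cfg)
    return summarize_scores(scores, cfg, patient_id=patient_id, marker=cfg.marker)


def summarize_scores(
    scores: Sequence[CellScore], cfg: PositivityConfig, patient_id: str = "", marker: str = ""
) -> CoreScore:
    """Collapse per-cell scores into a CoreScore (excluded cells drop out)."""
    pct = {
        (r, c): percent_positive(scores, r, c, cfg) for r in REGIONS for c in COMPARTMENTS
    }
    n_cells = {r: sum(1 for s in scores if s.region == r) for r in REGIONS}
    return CoreScore(patient_id=patient_id, marker=marker, pct=pct, n_cells=n_cells)


def aggregate_patient(cores: Sequence[CoreScore]) -> CoreScore:
    """Cell-count-weighted mean of replicate cores for one patient + marker."""
    if not cores:
        raise IntegrityError("cannot aggregate an empty core list")
    pids = {c.patient_id for c in cores}
    marks = {c.marker for c in cores}
    if len(pids) > 1 or len(marks) > 1:
        raise IntegrityError("cores must share patient_id and marker")
    agg = CoreScore(patient_id=cores[0].patient_id, marker=cores[0].marker)
    for region in REGIONS:
        agg.n_cells[region] = sum(c.n_cells[region] for c in cores)
        for comp in COMPARTMENTS:
            num = den = 0.0
            for c in cores:
                w = c.n_cells[region]
                v = c.pct[(region, comp)]
                if w > 0 and not math.isnan(v):
                    num += w * v
                    den += w
            agg.pct[(region, comp)] = num / den if den > 0 else math.nan
    return agg


def cell_scores_to_frame(scores: Sequence[CellScore]) -> pd.DataFrame:
    """Per-cell score table (one row per CellScore)."""
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in scores],
            "nuc_dab": [s.nuc_dab for s in scores],
            "cyt_dab": [s.cyt_dab for s in scores],
            "nuc_positive": [s.nuc_positive for s in scores],
            "cyt_positive": [s.cyt_positive for s in scores],
            "region": [s.region for s in scores],
        }
    )
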