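"""Synthetic IHC cores and patient cohorts with known ground truth.

Real stained TMA cores with per-cell annotations are rarely shareable, so
validation here runs on simulated data where truth is known exactly:

* **Core images** — discs of hematoxylin-stained "nuclei" placed without
  overlap inside glandular / interstitial regions, each with independent
  Bernoulli nuclear and cytoplasmic DAB positivity, rendered through the
  same Beer-Lambert stain model the analysis inverts (plus Gaussian pixel
  noise and 8-bit quantization).
* **Cohort tables** — per-patient marker percentages drawn from correlated
  truncated normals around configurable means, clinicopathological
  categories drawn by prevalence, and exponential proportional-hazards
  survival with independent exponential censoring tuned to a target
  censoring rate.

Every generator is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from . import stain_separation as stains
from .cell_segmentation import GLANDULAR, INTERSTITIAL, make_cytoplasm_rings
from .cohort_statistics import MARKER_COLUMNS, survival_design
from .exceptions import FeasibilityError, ValidationError

REGION_VALUE = {GLANDULAR: 1, INTERSTITIAL: 2}


def _default_pos_frac() -> Dict[str, Dict[str, float]]:
    return {
        GLANDULAR: {"nucleus": 0.6, "cytoplasm": 0.3},
        INTERSTITIAL: {"nucleus": 0.4, "cytoplasm": 0.1},
    }


def _default_n_cells() -> Dict[str, int]:
    return {GLANDULAR: 150, INTERSTITIAL: 150}


@dataclass
class ImageSpec:
    """Geometry, staining levels, and noise of one synthetic core image.

    Default concentration levels (hematoxylin 0.6; DAB 0.8 positive /
    0.05 negative, OD-equivalent units) straddle the default scoring
    cut-off of 0.15 with a wide margin, so positivity calls are limited by
    segmentation, not by stain contrast.
    """

    height: int = 600
    width: int = 600
    n_cells: Dict[str, int] = field(default_factory=_default_n_cells)
    radius_mean: float = 8.0
    radius_sd: float = 1.0
    ring_width: int = 4
    layout: str = "split_halves"  # or "annotated_polygons"
    true_pos_frac: Dict[str, Dict[str, float]] = field(default_factory=_default_pos_frac)
    dab_pos_level: float = 0.8
    dab_neg_level: float = 0.05
    hema_level: float = 0.6
    noise_sd: float = 2.0  # 8-bit intensity units
    min_center_spacing: float = 21.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        for r, d in self.true_pos_frac.items():
            for c, f in d.items():
                if not 0.0 <= f <= 1.0:
                    raise ValidationError(f"true_pos_frac[{r}][{c}] must be in [0,1]")
        if min(self.dab_pos_level, self.dab_neg_level, self.hema_level) < 0:
            raise ValidationError("stain levels must be >= 0")
        rmax = self.radius_mean + 2 * self.radius_sd
        if not self.allow_overlap and self.min_center_spacing <= 2 * rmax:
            raise ValidationError(
                "min_center_spacing must exceed twice the maximum radius in non-overlapping mode"
            )

    @property
    def radius_bounds(self) -> Tuple[float, float]:
        return (max(2.0, self.radius_mean - 2 * self.radius_sd),
                self.radius_mean + 2 * self.radius_sd)


@dataclass
class GroundTruth:
    """Planted geometry and positivity flags for one rendered core."""

    cells: pd.DataFrame  # cell_id, center_row, center_col, radius, region, nuc_positive, cyt_positive
    planted_frac: Dict[str, Dict[str, float]]  # empirical mean of the drawn flags
    region_mask: np.ndarray
    concentration: Optional[np.ndarray] = None  # (H, W, 3) stain field, kept on request


def gen_region_mask(spec: ImageSpec) -> np.ndarray:
    """Region annotation raster: 0 unannotated, 1 glandular, 2 interstitial.

    ``split_halves`` marks the left half glandular and the right half
    interstitial; ``annotated_polygons`` drops seeded random polygons of
    each class onto an unannotated background.
    """
    h, w = spec.height, spec.width
    if spec.layout == "split_halves":
        mask = np.empty((h, w), dtype=np.uint8)
        mask[:, : w // 2] = 1
        mask[:, w // 2:] = 2
        return mask
    if spec.layout != "annotated_polygons":
        raise ValidationError(f"unknown layout {spec.layout!r}")
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((h, w), dtype=np.uint8)
    for value, col_range in ((1, (0.05, 0.45)), (2, (0.55, 0.95))):
        for _ in range(2):
            cy = rng.uniform(0.15 * h, 0.85 * h)
            cx = rng.uniform(col_range[0] * w, col_range[1] * w)
            n_vert = 8
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radii = rng.uniform(0.10, 0.22, n_vert) * min(h, w)
            rr, cc = draw_polygon(cy + radii * np.sin(angles), cx + radii * np.cos(angles),
                                  shape=mask.shape)
            mask[rr, cc] = value
    return mask


def _sample_centers(rng, mask, value, n, margin, spacing, radii, allow_overlap):
    """Rejection-sample disc centers wholly inside one region value."""
    h, w = mask.shape
    centers = np.empty((0, 2))
    placed = []
    max_attempts = 4000 * max(n, 1)
    attempts = 0
    k = 0
    while k < n:
        attempts += 1
        if attempts > max_attempts:
            raise FeasibilityError(
                f"could not place {n} nuclei in region {value} within {max_attempts} attempts"
            )
        r = float(radii[k])
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        rr, cc = draw_disk((cy, cx), r, shape=mask.shape)
        if not np.all(mask[rr, cc] == value):
            continue
        if placed and not allow_overlap:
            d2 = np.sum((np.array(placed)[:, :2] - (cy, cx)) ** 2, axis=1)
            if np.min(d2) < spacing ** 2:
                continue
        placed.append((cy, cx, r))
        k += 1
    return placed


def gen_core_image(spec: ImageSpec, stain_matrix: Optional[np.ndarray] = None,
                   keep_concentration: bool = False) -> Tuple[np.ndarray, GroundTruth]:
    """Render one synthetic core image with known per-cell ground truth.

    Nuclei carry hematoxylin at ``hema_level`` plus nuclear DAB; the
    cytoplasm rings (built with the same nearest-nucleus partition used in
    scoring) carry cytoplasmic DAB.  Positive compartments get
    ``dab_pos_level``, negative ones ``dab_neg_level``.  The RGB image is
    ``255 * 10**(-OD)`` per channel with additive Gaussian noise, clipped
    and quantized to 8 bits.
    """
    rng = np.random.default_rng(spec.seed)
    m = stains.build_stain_matrix() if stain_matrix is None else np.asarray(stain_matrix, float)
    mask = gen_region_mask(spec)
    rmax = spec.radius_bounds[1]
    margin = rmax + spec.ring_width + 2

    records = []
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    cell_id = 0
    for region in (GLANDULAR, INTERSTITIAL):
        n = int(spec.n_cells.get(region, 0))
        lo, hi = spec.radius_bounds
        radii = np.clip(rng.normal(spec.radius_mean, spec.radius_sd, n), lo, hi)
        placed = _sample_centers(rng, mask, REGION_VALUE[region], n, margin,
                                 spec.min_center_spacing, radii, spec.allow_overlap)
        fr = spec.true_pos_frac[region]
        nuc_flags = rng.random(n) < fr["nucleus"]
        cyt_flags = rng.random(n) < fr["cytoplasm"]
        for (cy, cx, r), npos, cpos in zip(placed, nuc_flags, cyt_flags):
            cell_id += 1
            rr, cc = draw_disk((cy, cx), r, shape=labels.shape)
            labels[rr, cc] = cell_id
            records.append({"cell_id": cell_id, "center_row": cy, "center_col": cx,
                            "radius": r, "region": region,
                            "nuc_positive": bool(npos), "cyt_positive": bool(cpos)})

    cells = pd.DataFrame(records, columns=["cell_id", "center_row", "center_col", "radius",
                                           "region", "nuc_positive", "cyt_positive"])
    rings = make_cytoplasm_rings(labels, spec.ring_width) if cell_id else {}

    conc = np.zeros((spec.height, spec.width, 3), dtype=float)
    for rec in records:
        cid = rec["cell_id"]
        nuc = labels == cid
        conc[..., 0][nuc] = spec.hema_level
        conc[..., 1][nuc] = spec.dab_pos_level if rec["nuc_positive"] else spec.dab_neg_level
        ring_rc = rings.get(cid)
        if ring_rc is not None and ring_rc[0].size:
            conc[..., 1][ring_rc] = spec.dab_pos_level if rec["cyt_positive"] else spec.dab_neg_level

    od = stains.compose(conc, m)
    rgb = 255.0 * np.power(10.0, -od)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    img = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    planted: Dict[str, Dict[str, float]] = {}
    for region in (GLANDULAR, INTERSTITIAL):
        sub = cells[cells["region"] == region]
        planted[region] = {
            "nucleus": float(sub["nuc_positive"].mean()) if len(sub) else float("nan"),
            "cytoplasm": float(sub["cyt_positive"].mean()) if len(sub) else float("nan"),
        }
    return img, GroundTruth(cells=cells, planted_frac=planted, region_mask=mask,
                            concentration=conc if keep_concentration else None)


# ---------------------------------------------------------------------------
# cohorts


def _default_marker_levels() -> Dict[str, Tuple[float, float]]:
    """Default (mean, sd) of each marker percentage, per patient.

    Means reflect typical glandular-dominant, nucleus-dominant chemokine
    receptor staining in gallbladder carcinoma cohorts; sds are scaled for
    a 55-patient cohort whose group means carry standard errors of a few
    points.
    """
    se = {
        "cxcr3_gland_nuc": (45.3, 4.0), "cxcr3_gland_cyt": (32.4, 3.4),
        "cxcr4_gland_nuc": (14.9, 2.0), "cxcr4_gland_cyt": (16.7, 2.3),
        "cxcr7_gland_nuc": (58.2, 3.9), "cxcr7_gland_cyt": (30.5, 3.0),
        "cxcr3_inter_nuc": (15.0, 2.0), "cxcr3_inter_cyt": (1.6, 0.3),
        "cxcr4_inter_nuc": (5.1, 1.0), "cxcr4_inter_cyt": (0.9, 0.3),
        "cxcr7_inter_nuc": (39.3, 4.0), "cxcr7_inter_cyt": (7.6, 1.6),
    }
    root_n = np.sqrt(55.0)
    return {k: (mu, s * root_n) for k, (mu, s) in se.items()}


@dataclass
class CohortSpec:
    """Distributional recipe for a synthetic patient cohort.

    ``group_effects`` maps an indicator column of :func:`survival_design`
    (e.g. ``t_stage_34``) to per-marker-column additive shifts applied when
    the indicator is 1.  ``survival_loghr`` maps design columns to log
    hazard ratios shared by the OS and DFS models.  Defaults encode the
    null (no group effects, no covariate hazards) so the generator doubles
    as a calibration tool.
    """

    n_patients: int = 55
    marker_levels: Dict[str, Tuple[float, float]] = field(default_factory=_default_marker_levels)
    nuc_cyt_corr: float = 0.6
    group_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    sex_male_prev: float = 0.4
    diff_probs: Tuple[float, ...] = (0.3, 0.4, 0.3)       # differentiation scores 1..3
    invasion_probs: Tuple[float, ...] = (0.35, 0.4, 0.25)  # invasion scores 1..3
    t_probs: Tuple[float, ...] = (0.15, 0.3, 0.35, 0.2)    # T 1..4
    n_probs: Tuple[float, ...] = (0.5, 0.3, 0.2)           # N 0..2
    tnm_probs: Tuple[float, ...] = (0.05, 0.15, 0.3, 0.3, 0.2)  # TNM 0..4
    os_median_months: float = 20.0
    dfs_median_months: float = 12.0
    survival_loghr: Dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3
    age_mean: float = 62.0
    age_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if not (0.0 < self.sex_male_prev < 1.0):
            raise ValidationError("sex_male_prev must be in (0,1)")
        for name in ("diff_probs", "invasion_probs", "t_probs", "n_probs", "tnm_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p <= 0) or np.any(p >= 1) or not np.isclose(p.sum(), 1.0):
                raise ValidationError(f"{name} must be in (0,1) and sum to 1")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValidationError("censor_rate must be in [0,1)")
        for k, (mu, sd) in self.marker_levels.items():
            if sd <= 0:
                raise ValidationError(f"marker sd for {k} must be > 0")


def _solve_censor_rate(rates: np.ndarray, target: float) -> float:
    """Censoring hazard mu with mean_i mu/(mu+lambda_i) equal to target."""
    def f(log_mu):
        mu = np.exp(log_mu)
        return float(np.mean(mu / (mu + rates))) - target

    return float(np.exp(brentq(f, -25.0, 25.0, xtol=1e-12)))


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic patient table with known effect sizes.

    Within each marker x region, the nuclear and cytoplasmic percentages
    are drawn jointly normal with correlation ``nuc_cyt_corr`` (staining of
    the two compartments co-varies within a patient), then shifted by any
    configured group effects and clipped to [0, 100].  Event times follow
    an exponential proportional-hazards model; censoring is independent
    exponential with its rate solved to meet ``censor_rate`` on average.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    df = pd.DataFrame({"patient_id": [f"P{i + 1:03d}" for i in range(n)]})
    df["sex"] = np.where(rng.random(n) < spec.sex_male_prev, "M", "F")
    df["age"] = np.round(np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 30, 90), 1)
    df["differentiation"] = rng.choice(np.arange(1, len(spec.diff_probs) + 1), n, p=spec.diff_probs)
    df["invasion"] = rng.choice(np.arange(1, len(spec.invasion_probs) + 1), n, p=spec.invasion_probs)
    df["t_score"] = rng.choice(np.arange(1, len(spec.t_probs) + 1), n, p=spec.t_probs)
    df["n_score"] = rng.choice(np.arange(len(spec.n_probs)), n, p=spec.n_probs)
    df["tnm"] = rng.choice(np.arange(len(spec.tnm_probs)), n, p=spec.tnm_probs)

    # markers: bivariate normal per marker x region (nuc, cyt), then shifts
    rho = spec.nuc_cyt_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    for marker in ("cxcr3", "cxcr4", "cxcr7"):
        for region in ("gland", "inter"):
            z = rng.standard_normal((n, 2)) @ chol.T
            for j, comp in enumerate(("nuc", "cyt")):
                col = f"{marker}_{region}_{comp}"
                mu, sd = spec.marker_levels[col]
                df[col] = mu + sd * z[:, j]

    if spec.group_effects:
        design = survival_design(df)
        for indicator, shifts in spec.group_effects.items():
            if indicator not in design.columns:
                raise ValidationError(f"unknown group-effect indicator {indicator!r}")
            on = design[indicator].to_numpy() > 0
            for col, shift in shifts.items():
                df.loc[on, col] = df.loc[on, col] + shift
    for col in MARKER_COLUMNS:
        df[col] = np.clip(df[col], 0.0, 100.0)

    design = survival_design(df)
    for endpoint, median in (("os", spec.os_median_months), ("dfs", spec.dfs_median_months)):
        base_rate = np.log(2.0) / median
        eta = np.zeros(n)
        for col, loghr in spec.survival_loghr.items():
            if col not in design.columns:
                raise ValidationError(f"unknown survival covariate {col!r}")
            eta = eta + loghr * design[col].to_numpy()
        rates = base_rate * np.exp(eta)
        event_t = rng.exponential(1.0 / rates)
        if spec.censor_rate > 0:
            mu = _solve_censor_rate(rates, spec.censor_rate)
            censor_t = rng.exponential(1.0 / mu, n)
        else:
            censor_t = np.full(n, np.inf)
        t = np.minimum(event_t, censor_t)
        df[f"{endpoint}_months"] = np.round(t, 3)
        df[f"{endpoint}_event"] = (event_t <= censor_t).astype(int)
    return df
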