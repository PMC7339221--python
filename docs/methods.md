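# Methods

## Stain model

Brightfield chromogens obey Beer–Lambert attenuation: transmitted intensity
`I_c = I0_c · 10^(−OD_c)` per channel, with optical densities additive across
co-localised stains. We work in base-10 OD with white reference `I0 = 255`
per channel and an intensity floor `ε = 1` (the smallest non-zero 8-bit
level), which caps OD at `log10(255) ≈ 2.41` and keeps saturated-dark pixels
finite. The stain basis is the Ruifrok–Johnston H-DAB pair — hematoxylin
(0.650, 0.704, 0.286), DAB (0.268, 0.570, 0.776), both unit length — with a
residual third vector from their normalized cross product, so unmixing is an
exact 3×3 solve rather than a least-squares projection. Stain vectors are
config-overridable per run; automatic stain estimation (Macenko-style) is
deliberately out of scope. Negative concentrations (out-of-gamut noise) are
clamped to zero after the solve; the `reconstruction_error` QC metric reports
the max per-pixel residual of the re-mixed image so silent clamping damage is
visible.

## Cell detection and compartments

Nuclei are detected in the hematoxylin concentration channel with a fully
deterministic classical pipeline: Gaussian smoothing (σ = 1.5 px), Otsu
global threshold (a fixed threshold is available for low-contrast material),
hole filling, size filter (30–1500 px², tuned for nuclei of roughly 6–20 px
radius at typical 20×–40× TMA scans), then a Euclidean-distance-transform
watershed: one seed per local distance maximum at least 7 px from its
neighbours within the same component, basins grown with 8-connectivity.
Choosing a transparent classical detector over a learned one trades some
robustness on real tissue for exact reproducibility and parameter-level
auditability — appropriate here because the scientific claims rest on the
scoring, not on detector novelty.

With no membrane stain, the cytoplasm of cell *k* is approximated by the
background pixels within `ring_width = 4` px (Euclidean) of its nucleus,
excluding all nucleus pixels. Pixels contested between cells belong to the
nearest nucleus; exact distance ties go to the lower label id, implemented
with a k-nearest-site search (k = 30) over nucleus pixels, which makes the
tie-break explicit rather than dependent on scan order. Rings are therefore
pairwise disjoint by construction and clipped at the image border.

Cells are assigned to the glandular or interstitial region by majority vote
of their nucleus pixels over the annotation mask; a strict plurality of
unannotated pixels, or a glandular/interstitial tie, excludes the cell from
scoring — conservative, matching the practice of scoring only outlined ROIs.
Cells whose nuclei touch the image border are dropped by default
(`exclude_border`), since their compartments are truncated.

## Positivity scoring

A compartment's signal is the arithmetic mean DAB concentration over its
pixel set; a compartment is positive when that mean reaches a single global
cut-off (default 0.15 OD-equivalent) applied unchanged to every image of a
run. "Percent positive" is the fraction of positive *cells* (not positive
pixel area) per region × compartment — the per-cell reading follows from the
single-cell framing of the measurement; an area-fraction variant would need
no new machinery but is not implemented. Cells with an empty cytoplasm ring
count as cytoplasm-negative and stay in the denominator, so denominators
always equal the region's cell count. Replicate cores of one patient are
combined by cell-count-weighted means.

## Cohort statistics

The analysis table carries 12 marker measurements per patient (3 markers ×
2 compartments × 2 regions) plus sex, age, differentiation and invasion
scores, T/N/TNM staging, and OS/DFS times and events. Staging dichotomies
are fixed: T1-2 vs T3-4, N = 0 vs N > 0, TNM 0–2 vs 3–4. Differentiation and
invasion are split at the cohort median (value > median = high); a median
split is the least arbitrary choice when the ordinal scale and its clinical
cut are not fixed in advance.

Test choices, given percent-scale, often skewed measurements at n ≈ 55:
paired contrasts use the Wilcoxon signed-rank test and group contrasts the
Mann–Whitney U, both two-sided, with exact null distributions up to n = 25
(when the data are tie-free; ties and larger n fall back to the tie-corrected
normal approximation) and Student/Welch t alternatives by config. Raw
p-values are reported by default; Benjamini–Hochberg adjustment is a flag.
The paired report covers 12 contrasts: nucleus vs cytoplasm within each
marker × region, and glandular vs interstitial within each marker ×
compartment.

Logistic models predict each clinicopathological dichotomy from the six
glandular marker measurements jointly (interstitial markers are withheld to
keep the predictor count sensible at this cohort size); the reported AUC is
apparent (in-sample), computed by the rank identity
`AUC = (#concordant + 0.5·#ties) / (n₊ n₋)`. Complete separation is detected
and flagged rather than silently diverging. Cox proportional-hazards models
(Efron tie handling, Wald CIs on the log hazard ratio, via lifelines) regress
OS and DFS on sex, the T and N dichotomies and the six glandular markers;
fits with fewer than 10 events are refused by default. Every per-analysis
failure (too few patients, single-class outcomes, zero events) is recorded as
a flag in the report tables without aborting the remaining analyses.

## Synthetic data

**Core images.** Nuclei are discs (radius ~ N(8, 1) px truncated to ±2 sd;
discs keep area and ring oracles analytic — an elliptical option was
considered and rejected for that reason) placed by rejection sampling wholly
inside one region with ≥ 21 px centre spacing (non-overlapping by
construction) and a border margin. Region layouts: vertical split halves, or
seeded random polygons with an unannotated margin. Each cell draws
independent Bernoulli nuclear and cytoplasmic positivity; concentration
fields use hematoxylin 0.6 in nuclei and DAB 0.8 (positive) / 0.05
(negative) in the flagged compartments, levels chosen to straddle the 0.15
cut-off with a wide margin so recovery tests measure segmentation, not stain
contrast. Rings are rendered with the same nearest-nucleus partition used in
scoring. Rendering inverts the stain model exactly, then adds Gaussian pixel
noise (sd 2 intensity units) and quantizes to 8 bits. What this emulates —
and what it does not: uniform compartment staining, clean backgrounds, disc
geometry, and exact mask registration are all idealisations; passing
recovery tests demonstrates the pipeline's correctness and calibration, not
robustness to folds, edge artefacts, intensity gradients or dense nuclear
crowding in real sections.

**Cohorts.** Default n = 55. Marker percentages are drawn per marker ×
region from a bivariate normal over (nucleus, cytoplasm) with correlation
0.6 — compartment staining co-varies within a patient — then shifted by any
configured per-category effects and clipped to [0, 100]. Default means/sds
encode the nucleus-dominant, gland-dominant staining pattern typical of
these receptors (e.g. glandular CXCR3 nucleus 45.3, cytoplasm 32.4; CXCR4
the exception with near-equal compartments), with per-patient sds set as
cohort-scale standard errors of a few points times √55. Group effects and
survival log hazard ratios default to zero, so the default generator is also
the null-calibration tool. Survival is exponential proportional hazards
(baseline medians: OS 20, DFS 12 months) over indicator/marker design
columns; censoring is independent exponential with its rate solved
numerically so the expected censored fraction equals the target (default
0.3).

## Numerical and validation choices

Problem sizes used in the validation suite: 50 cores of 100–300 nuclei for
detection recall, 20 seeded cores at 150 cells/region for percent-positive
recovery (mean absolute error ≤ 2 points), 100 replicates of n = 500 for Cox
recovery (log-HR 0.7, 30% censoring), 2000 null cohorts of n = 55 for test
calibration (rejection within 3–7% at the 5% level), and full-pipeline
byte-identity across reruns. Exact-test p-values are verified against
complete enumeration of the permutation null at n ≤ 12; unmixing against
independent per-pixel linear solves (agreement ≤ 1e-9) and closed-form
round trips.

Degenerate inputs have defined behaviour throughout: all-background images
yield an empty labeling, empty regions yield missing percentages (never
0/0), all-zero paired differences yield a flagged p = 1, zero-variance
paired-t is flagged rather than divided by zero, and collinear stain vectors
or singular matrices are rejected up front.

## Known limitations

No stain normalisation between slides; a single global cut-off presumes
comparable staining batches. The ring cytoplasm model is geometric, not
biological. Logistic and Cox results at n ≈ 55 with six marker covariates
are fragile by nature; the package reports them with flags but cannot make
them well-powered. The synthetic renderer does not model chromogen
saturation, scanner colour response, or spatially correlated expression.
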