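# ihcquant

Quantitative, observer-independent scoring of chromogenic immunohistochemistry
(IHC) on tissue-microarray (TMA) cores, built for studies that relate the
*subcellular localisation* of a marker — nuclear vs cytoplasmic, in tumour
glands vs stroma — to clinical outcome. The motivating use case is chemokine
receptor profiling (CXCR3, CXCR4, CXCR7) in gallbladder carcinoma, where the
fraction of positive cells per compartment carries prognostic information that
manual eyeballing scores too coarsely and too variably.

## What it computes

Given an RGB brightfield image of an H-DAB-stained core and a region mask
outlining glandular and interstitial areas, the pipeline:

1. **Unmixes the stains.** Pixels are converted to optical density,
   `OD_c = -log10(max(I_c, ε)/I0_c)`, where stains add linearly
   (Beer–Lambert), and unmixed with a 3×3 stain matrix
   (Ruifrok–Johnston H-DAB vectors by default) into hematoxylin, DAB and
   residual concentration maps.
2. **Finds cells.** Nuclei are detected in the hematoxylin channel
   (Gaussian smooth → Otsu threshold → size filter → distance-transform
   watershed to split touching nuclei); each cell's cytoplasm is a ring of
   width *w* around its nucleus, partitioned between neighbours by
   nearest-nucleus distance.
3. **Scores positivity.** A cell compartment is positive when its mean DAB
   concentration reaches one global cut-off (default 0.15 OD) applied
   unchanged to every image — the core output is the percent of positive
   cells per {glandular, interstitial} × {nucleus, cytoplasm}.
4. **Runs the cohort statistics.** Paired Wilcoxon tests of nuclear vs
   cytoplasmic (and glandular vs interstitial) expression, Mann–Whitney
   comparisons across clinicopathological strata (differentiation, invasion,
   T1-2 vs T3-4, N0 vs N>0, TNM early vs advanced), multivariable logistic
   regression with apparent ROC AUC, and Cox proportional-hazards models of
   overall and disease-free survival.

Because annotated clinical cores are rarely shareable, the package ships a
first-class synthetic-data module: rendered core images with per-cell ground
truth, and cohort tables with known effect sizes, so every stage is testable
end to end.

## Worked example

```python
from ihcquant import synthetic_data as sd, compartment_scoring as cs, cell_segmentation as seg

spec = sd.ImageSpec(seed=1)                       # 150 cells per region, 600x600 px
img, truth = sd.gen_core_image(spec)
core = cs.score_core(img, truth.region_mask, cs.PositivityConfig(), seg.SegmentationParams())
print(core.n_cells)
print({k: round(v, 1) for k, v in core.pct.items()})
print(truth.planted_frac)
```

prints

```
{'glandular': 150, 'interstitial': 150}
{('glandular', 'nucleus'): 60.7, ('glandular', 'cytoplasm'): 29.3,
 ('interstitial', 'nucleus'): 39.3, ('interstitial', 'cytoplasm'): 11.3}
{'glandular': {'nucleus': 0.6066..., 'cytoplasm': 0.2933...},
 'interstitial': {'nucleus': 0.3933..., 'cytoplasm': 0.1133...}}
```

— all 300 planted nuclei are recovered and each percent-positive estimate
matches the planted per-cell positivity exactly (91 of 150 glandular nuclei
were drawn positive, 60.7%). The same run is available from the shell:

```bash
ihcquant simulate --config cfg.yaml --out run/
ihcquant score    --config cfg.yaml --images run/images --masks run/masks --out run/scores
ihcquant stats    --config cfg.yaml --cohort run/cohort.csv --out run/stats
```

All outputs are CSV with a provenance header (version, seed, config hash)
and are byte-identical across reruns at a fixed seed.

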