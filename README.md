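# exurban

Forest and forest-edge birds respond to *how* low-density housing is arranged
in the landscape, not just how much of it there is.  `exurban` is a tested,
reusable pipeline for that question: it classifies binary land-cover rasters
into morphological spatial pattern (MSPA) classes, summarises the spatial
arrangement of exurban development around roadside survey stops as a
**compactness index**, adjusts Breeding-Bird-Survey-style counts for observer
nuisance with a hierarchical Bayesian model, detects threshold responses along
the compactness gradient with **Threshold Indicator Taxa Analysis (TITAN)**,
and compares compactness against forest loss and fragmentation predictors with
GCV-smoothed additive models (GAMs).  A synthetic-data generator produces
landscapes and bird counts with known ground truth, so every stage — and the
end-to-end run — is verifiable.

## The statistics at the core

**MSPA.** Every foreground pixel of a binary map is assigned to one of seven
mutually exclusive morphological classes (Core, Islet, Edge, Perforation,
Bridge, Loop, Branch) by iterated erosion (8-neighbour structural element,
edge width 1 by default), geodesic dilation and connectivity analysis.
Isolated single-pixel *Islets* are the footprint of scattered houses.

**Compactness.** Within a circular zone of influence (radius 400 m or 1 km)
around each survey stop,

```
compactness = 100 × (1 − islet exurban pixels / all exurban pixels)
```

ranges from 0 % (fully dispersed development) to 100 % (fully clumped);
it is undefined where the buffer holds no development (such stops are
excluded).

**Count adjustment.** Counts C_it at stop *i* in year *t* follow an
over-dispersed Poisson model on the log scale,

```
C_it ~ Poisson(μ_it)
log μ_it = β0_stop + β1_stop·Year_t + β2·FirstYear_it
           + Route_it + Observer_it + Error_it
```

fitted by an adaptive Metropolis-within-Gibbs sampler (2 chains, split
Gelman–Rubin convergence check, R̂ < 1.1).  *Adjusted counts* are posterior
expectations with observer, first-year and over-dispersion effects removed.

**TITAN.** For each species, every candidate split of the compactness
gradient is scored by the permutation-standardised Dufrêne–Legendre indicator
value (IndVal = 100 × specificity × fidelity); the change point maximises the
z score, the direction is z− (declines past the threshold) or z+ (increases),
and bootstrap resampling yields purity, reliability and 5–95 % change-point
quantiles.

**GAMs.** Adjusted counts are modelled as additive smooths (Gaussian errors,
identity link, GCV-selected penalties, year as a factor) of compactness,
proportion exurban, proportion forest, forest patches > 0.45 ha and forest
edge, with stepwise backward selection and ΔAIC ranking of the full versus
best-fitted model.

## Worked example

```python
import numpy as np, pandas as pd
from exurban import (BinaryLandscape, MSPAConfig, classify_mspa, class_summary,
                     compactness_index, SurveyStop, BufferSpec, extract_buffer)
from exurban.titan import Titan, TitanConfig

# one 9x9 housing block plus 30 scattered single-pixel houses (30 m pixels)
rng = np.random.default_rng(0)
grid = np.zeros((120, 120), bool)
grid[50:59, 50:59] = True
placed = 0
while placed < 30:
    r, c = rng.integers(1, 119, 2)
    if not grid[r-1:r+2, c-1:c+2].any():
        grid[r, c] = True; placed += 1

scene = BinaryLandscape(grid, pixel_size=30.0)
classes = classify_mspa(scene, MSPAConfig(connectivity=8, edge_width=1))
print(class_summary(classes).query("count > 0"))
```

```
     class  count  area_ha
BACKGROUND  14289  1286.01
      CORE     49     4.41
     ISLET     30     2.70
      EDGE     32     2.88
```

The block contributes 81 non-islet pixels (49 core + 32 edge), the scattered
houses 30 islets.  Within a 1-km buffer centred on the block:

```python
stop = SurveyStop("S001", x=55*30.0, y=scene.origin[1] - 55*30.0)
buf = extract_buffer(scene, stop, BufferSpec(radius=1000.0))
print(compactness_index(classes, buf))   # 93.1
```

93.1 % — development near this stop is strongly clumped.  TITAN then locates
species thresholds along such a gradient:

```python
env = np.sort(rng.uniform(0, 100, 60))
abund = pd.DataFrame({
    "steps_up":    np.where(env >= 42, 6.0, 0.0) * rng.lognormal(0, 0.2, 60),
    "steps_down":  np.where(env < 65, 5.0, 0.5) * rng.lognormal(0, 0.2, 60),
    "indifferent": rng.poisson(4.0, 60).astype(float),
})
results = Titan(env, abund, TitanConfig(n_perm=250, n_boot=250)).fit(seed=7)
print(results.summary())
```

```
    species direction      z     cp  cp_5pct  cp_95pct  purity  reliability     p
   steps_up        z+ 11.822 40.960   40.491    43.250    1.00        1.000 0.004
 steps_down        z-  8.691 65.055   64.610    71.839    1.00        1.000 0.004
indifferent        z-  1.581 23.501   20.116    90.860    0.58        0.032 0.669
```

Both planted thresholds (42 and 65) are recovered with the right direction,
tight bootstrap quantiles and purity/reliability 1.0; the indifferent species
is correctly flagged as unreliable (purity 0.58, p = 0.67).

The full pipeline — synthetic scenario, MSPA, landscape metrics, count
adjustment, TITAN, GAM comparison, report tables — runs as

```bash
exurban pipeline --out run/ --seed 3         # or: from a YAML config
```

and writes `table1.csv` (landscape composition), `table2.csv` (TITAN),
`table3.csv` (GAM comparison), `screen.csv`, convergence and provenance
records into the run directory.

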