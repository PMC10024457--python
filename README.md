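# leafpol

Leaf-surface phenotyping from microscopy and Brewster-angle polarized
reflectance.

Leaf surfaces carry phenotypes — glossy epicuticular wax, glaucous wax bloom,
dense trichomes (hairs), or a glabrous (bare) epidermis — that change how a
leaf scatters light and therefore confound spectral estimates of leaf
biochemistry. `leafpol` implements a desk-scale version of the measurement
and analysis chain used to characterize these phenotypes:

1. **Shape-from-focus microscopy.** A stack of 10–50 images taken at stage
   heights 0.005 mm apart (100×) or 0.001 mm apart (500×) is fused by
   selecting, per pixel, the slice with the highest intensity gradient. The
   selected stage height is the pixel's depth; a 10×10 median and a 15×15
   Gaussian filter smooth the depth map, and the composite image can be
   draped over the 3-D surface.
2. **Cell morphology.** From a manually traced cell polygon and the depth
   map: cell size (µm²), margin undulation `A1/A2` (traced area over
   convex-hull area, 1 for a convex cell), and the cell cap aspect ratio

   ```
   CAR = 2 c sqrt((x_peak - x_valley)^2 + (y_peak - y_valley)^2) / (z_peak - z_valley)
   ```

   with `c = 9.8e-5` mm/pixel at 500×. Pubescence coverage is the percent of
   the field covered by traced hairs, with a count × mean-hair-area
   approximation for dense uniform pubescence.
3. **Polarized spectral features.** A polarizer between sample and sensor is
   rotated 0°–90° in 5° steps at the ~55° Brewster geometry (arctan 1.45).
   After dark-reference removal and transmittance normalization, the lowest
   and highest scans over 500–900 nm give the polarized (specular) BRF
   `R_Q = (R_max − R_min)/2` and the total `R = R_Q + R_min`. Two features
   summarize a sample: `R_Qav`, the mean of `R_Q` over 500–900 nm, and
   `DIFF_R = R_min(765 nm)/R_min(680 nm)` across the red edge.
4. **Phenotype classification.** Equal-prior quadratic discriminant analysis
   on (`R_Qav`, `DIFF_R`), evaluated by repeatedly re-splitting the data
   into 150 training / 199 testing samples (10,000 runs in the full
   protocol) and aggregating per-run classification rates.

Every stage is exercised on synthetic data with retained ground truth:
surfaces with known height fields, defocus stacks with known best-focus
slices, polarizer sweeps with a known diffuse/specular decomposition, and
labeled feature clouds calibrated to the published per-phenotype ranges.

## Worked example

```python
import numpy as np
from leafpol.synthetic import ScanSetSpec, generate_polarized_scanset, \
    generate_study_sized_dataset
from leafpol.spectral import features_from_scanset
from leafpol.classify import PhenotypeQDA, monte_carlo_evaluation

# one synthetic polarizer sweep, 5 deg surface tilt
scanset, truth = generate_polarized_scanset(
    ScanSetSpec(specular_level=6e-4, tilt_offset_deg=5.0, noise_sd=1e-5), seed=42)
f = features_from_scanset(scanset)
print(f"R_Qav = {f.R_Qav:.3e}   DIFF_R = {f.DIFF_R:.2f}   "
      f"min @ {f.min_orientation_deg:.0f} deg, max @ {f.max_orientation_deg:.0f} deg")

# classify a synthetic dataset with the study's class composition
df = generate_study_sized_dataset(seed=7)
res = PhenotypeQDA.from_dataframe(df).fit()
print(res.summary())
mc = monte_carlo_evaluation(df, n_train=150, n_runs=2000, seed=7)
print(mc.summary())
```

prints

```
R_Qav = 2.971e-04   DIFF_R = 5.96   min @ 5 deg, max @ 90 deg
Quadratic Discriminant Analysis (equal priors)
features: (R_Qav, DIFF_R)   classes: 4
------------------------------------------------------------------
class          n   prior    mean R_Qav  mean DIFF_R    |cov|^1/2
glossy       104   0.250     7.001e-04        8.659    2.350e-02
glaucous     110   0.250     1.513e-04        4.765    9.631e-03
hairy         39   0.250     1.062e-04        5.322    5.851e-03
glabrous      96   0.250     1.939e-04        7.994    1.149e-02
Monte-Carlo QDA evaluation: 2000 runs, 150/199 train/test split
overall correct-classification rate: mean 70.3%  sd 2.2%  min 62.3%  max 78.4%
------------------------------------------------------------
glossy     mean  85.0%   sd  3.8%
glaucous   mean  50.5%   sd  5.8%
hairy      mean  74.8%   sd 10.7%
glabrous   mean  75.4%   sd  4.9%
```

The tilted sample's minimum is found at the 5° column rather than the
nominal 0° parallel orientation — the reason extrema are searched over all
19 scans. `R_Qav` recovers half the configured specular level, and the
Monte-Carlo summary shows which phenotypes the two features separate well
(glossy) and which overlap (glaucous vs hairy, both with low `R_Qav` and a
depressed red-edge ratio).

The same chain is available from the shell:

```
leafpol simulate features --seed 4 --out features.csv
leafpol classify --features features.csv --model model.json
leafpol evaluate --features features.csv --n-train 150 --runs 10000 --seed 17 --out eval.json
leafpol simulate stack --seed 2 --out sim/
leafpol stack --stack sim/stack.tiff --manifest sim/manifest.json --out recon/
```

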