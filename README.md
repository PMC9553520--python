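# octspeckle

Speckle-statistics texture analysis for optical coherence tomography (OCT),
aimed at detecting and telling apart semi-transparent structures — the kind
of problem posed by label-free lymphography and neurography, where lymph
fluid, vessel walls and nerves are all nearly transparent and conventional
negative-contrast OCT struggles.

The package implements the full analysis chain on synthetic, ground-truthed
data:

1. **Phantom simulator** — 4-D OCT-like volumes (depth × fast × slow ×
   repeat) of a tissue-mimicking phantom: a dyed-water lumen inside a
   semi-transparent micro-tube (305/762 µm), a 400 µm transparent rod, an
   attenuating Intralipid-like scattering background, air above the surface
   and a deep noise band — with voxel-exact labels.
2. **Rayleigh speckle statistics** — pool all pixels of a
   6 × 10 × 6-voxel ROI across 24 repeat frames (8640 pixels), histogram
   them, and fit the three-parameter Rayleigh probability density

   $$P(x; a, b, c) = \frac{a\,(x-c)}{b^2}\, e^{-\frac{(x-c)^2}{2 b^2}},\qquad x \ge c$$

   where *a* is the amplitude normalization, *b* the scale and *c* the
   shift. The goodness of fit R² separates scattering tissue-like material
   (poor single-Rayleigh fit) from transparent inclusions and noise
   (near-perfect fit); *a* and *c* further differentiate the
   low-scattering materials.
3. **Comparators** — the depth-resolved attenuation coefficient
   µ[i] = I[i] / (2 Δz Σ₍ⱼ₎ I[j]) and GLCM Haralick texture metrics
   (contrast, correlation, energy, homogeneity).
4. **Classification** — a "fine Gaussian" RBF-kernel SVM (kernel scale
   √d/4, box constraint 1) trained on 30 pixels per region with five-fold
   cross-validation over repeated dataset randomizations, reported as a
   row-normalized confusion matrix, per-class ROC with Youden-optimal
   operating points, and overall accuracy (mean of the six per-class true
   positive rates) ± sd.

## Worked example

Generate the default phantom and fit one ROI per region:

```python
import numpy as np
from octspeckle import (default_phantom_config, generate_phantom, pool_roi,
                        ROISpec, fit_sample, Region, REGION_SHORT_NAMES)
from octspeckle.pipeline import place_rois

cfg = default_phantom_config()
vol, labels = generate_phantom(cfg, seed=0)
rng = np.random.default_rng(0)
for region in Region:
    origin = place_rois(labels, region, (6, 6, 10), 1, rng)[0]
    fit = fit_sample(pool_roi(vol, ROISpec(origin, (6, 6, 10))))
    print(f"{REGION_SHORT_NAMES[region]:>6s} {fit.r_squared:7.4f} "
          f"{fit.a:7.3f} {fit.b:7.3f} {fit.c:8.3f}")
```

prints (columns: R², a, b, c):

```
    Ar  0.9951   0.999   0.892   -0.225
    No  0.9929   1.003   1.088   -0.189
    dW  0.9919   0.983   1.425   -0.382
    tS  0.9815   1.049   2.193   -1.051
   stS  0.9571   1.060   3.598    0.085
    IL  0.9106   1.091  13.435   -5.839
```

Air (Ar) and noise (No) pool pure detector speckle and fit almost
perfectly (R² > 0.99); dyed water (dW) and the transparent solid (tS) sit
just below; the semi-transparent tube wall (stS) drops to ≈ 0.96; the
scattering Intralipid background (IL) is visibly non-Rayleigh (R² ≈ 0.91)
and carries a strongly negative shift coefficient — exactly the contrast
the classifier exploits.

The same pipeline is scriptable from the shell:

```bash
octspeckle simulate --seed 0 --out scratch/vol
octspeckle fit-roi --volume scratch/vol --roi 40,20,5 --out fit.json
octspeckle roi-study --out scratch/roi      # per-region fit statistics
octspeckle classify --out scratch/clf       # SVM vs comparator features
octspeckle flow-study --out scratch/flow    # flow/dye insensitivity check
```

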