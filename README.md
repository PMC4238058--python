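# slbphase

Quantitative image analysis of **two-dimensional phase separation on
supported lipid bilayers (SLBs)** — the experimental system in which a
membrane-anchored receptor tail (e.g. phosphorylated Nephrin) is crosslinked
by multivalent cytoplasmic partners (Nck, N-WASP) into micrometre-scale
protein clusters visible by TIRF microscopy.

The package is aimed at membrane biophysicists analysing titration series,
FRAP experiments and calibration standards from SLB reconstitutions. It
covers the full measurement chain:

- **Image correction** — per-pixel background subtraction, flat-field
  division by normalized correction factors from a homogeneous reference
  bilayer, rolling-ball local-background flattening.
- **Cluster detection** — triangle, maximum-entropy (Kapur) and iterative
  3-sd histogram thresholds; 8-connected component labelling with
  per-cluster area, integrated intensity, centroid and edge flags.
- **Phase-transition order parameters** — fractional intensity in clusters,
  `φ = Σ_clusters I / Σ_image I`, and the pixel-intensity variance
  `Var(I)`; segmented ("hockey-stick") and baseline + 3 sd estimators of
  the clustering (critical) concentration where both begin to rise.
- **Cluster statistics** — size distributions with exponential
  `N(s) ∝ e^(−s/s̄)` vs power-law `N(s) ∝ s^(−k)` discrimination, and
  quadrat (box) counts with the edge-cluster overcounting correction and a
  Gaussian fit testing spatial randomness.
- **Kinetics** — FRAP normalization and fitting to
  `f(t) = plateau − Σᵢ Aᵢ e^(−t/τᵢ)` (1 or 2 components) with nested-model
  selection by the F-test
  `F = [(SS₁−SS₂)/(df₁−df₂)] / (SS₂/df₂)`; membrane-dissociation decays
  `A e^(−t/τ) + C`; per-cluster actin-assembly half-times `t_1/2` with
  Spearman correlations against cluster size and receptor intensity.
- **Density calibration** — standard curves, the brightness correction
  factor `F = I_protein / I_dye`, lipid mole-percent → molecules/µm²
  conversion through the headgroup area (69 Å², both leaflets), and
  intensity → absolute receptor density.
- **Synthetic data** (`slbphase.synth`) — TIRF-like scenes with nucleated
  or spinodal morphologies, titration series with a sharp onset, FRAP and
  dissociation traces, calibration standards, and actin time courses; every
  generator is seeded and ships its ground truth, so the whole pipeline is
  testable without microscope data.

## Worked example

```python
import numpy as np
from slbphase import (SceneParams, TitrationParams, gen_titration,
                      titration_statistics, clustering_concentration)

scene = SceneParams(width=128, height=128, morphology="nucleated",
                    noise_sd=10.0, mean_intensity=1000.0,
                    camera_offset=0.0, seed=0)
titration = TitrationParams(concentrations=tuple(np.geomspace(25, 1000, 12)),
                            critical_concentration=200.0, scene=scene)
curve = titration_statistics(gen_titration(titration))
for p in curve.points[5:9]:
    print(f"{p.concentration:7.1f} nM  phi = {p.fractional_intensity:.3f}  "
          f"var = {p.variance:10.1f}")
est = clustering_concentration(curve, statistic="fractional_intensity")
print(f"clustering concentration ~ {est.concentration:.0f} nM "
      f"(detected = {est.detected})")
```

prints

```
  133.7 nM  phi = 0.000  var =      101.7
  187.0 nM  phi = 0.000  var =      101.5
  261.5 nM  phi = 0.284  var =   741621.6
  365.7 nM  phi = 0.412  var =  1146162.3
clustering concentration ~ 187 nM (detected = True)
```

Below the 200 nM onset the bilayer is homogeneous (fractional intensity 0,
variance at the camera-noise floor); above it both order parameters jump,
and the segmented fit places the breakpoint at the last pre-onset grid
concentration — within one titration step of the true 200 nM.

A command-line interface exposes the same stages
(`slbphase simulate | correct | segment | titrate | sizes | spatial |
frap | dissociation | actin | calibrate | density | run`).

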