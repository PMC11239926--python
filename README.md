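# aneumorph

Computerized sizing of saccular intracranial aneurysms (IAs) from binary
vascular segmentations, plus the rater-agreement and growth-monitoring
statistics needed to evaluate such measurements.

Aneurysm growth — a size increase of **≥ 1 mm** between scans — flags an
elevated rupture risk, but manual dome-diameter measurements on a 2D
viewing plane carry rater variability of the same order as that
threshold. `aneumorph` provides:

* a mesh-based **3D measurement pipeline**: binary mask (NIfTI) →
  marching-cubes surface → non-shrinking (Taubin) smoothing → geodesic-ball
  region of interest around the annotated IA centre (5000 closest mesh
  points by edge-graph geodesic distance) → dome isolation by a closed
  neck curve → **MaxLen**, the maximum pairwise distance between dome-mesh
  vertices;
* **agreement statistics**: Bland-Altman systematic/random error and
  limits of agreement (mean ± 1.96 SD of paired differences), two-way
  ICC from ANOVA mean squares (absolute-agreement ICC(2,1) and
  consistency ICC(3,1)), Cohen's d with pooled SD, and stratified
  pairwise reports;
* **growth monitoring**: interval classification
  (growing / stable / shrinking), concordance against a reference rater,
  and the closed-form probability `P(|Δ| ≥ t) = 2Φ(−t/(σ√2))` that a
  truly stable aneurysm is misclassified under measurement noise σ;
* a **synthetic-data module**: sphere-on-tube vascular phantoms with
  analytic ground truth, and simulated rater panels with per-rater bias,
  noise, and rupture-dependent variance inflation.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from aneumorph import (
    make_vessel_phantom, measure_phantom,
    false_growth_probability, icc, bland_altman,
)

# A phantom: 1.5 mm-radius vessel with a 3 mm-radius dome, 0.3 mm voxels.
volume, truth = make_vessel_phantom(dome_radius_mm=3.0, spacing=0.3,
                                    tube_length_mm=50.0)
size = measure_phantom(volume, truth)   # full pipeline, auto neck curve
print(f"MaxLen {size.value_mm:.3f} mm (truth {truth.true_max_diameter_mm} mm)")
# -> MaxLen 6.169 mm (truth 6.0 mm)      # within 2 voxels of the truth

# How often would a rater with senior-level precision (sigma = 1.23 mm)
# falsely call a stable aneurysm changed under the 1 mm rule?
print(f"{false_growth_probability(1.23):.4f}")
# -> 0.5653                              # more likely wrong than right
```

The phantom's measured MaxLen (6.169 mm) recovers the analytic dome
diameter within the voxel tolerance; the false-change probability shows
that even expert-level variability (SD 1.23 mm) exceeds what the 1 mm
growth rule can tolerate on a single comparison — the quantitative
motivation for low-variability computerized measurement.

A command-line interface mirrors the library:

```bash
aneumorph simulate phantom mask.nii.gz truth.json
aneumorph mesh extract mask.nii.gz surface.ply
aneumorph mesh roi surface.ply roi.ply --center 0,0,3.5
aneumorph isolate --roi roi.ply --curve curve.json --center 0,0,3.5 --out-mesh dome.ply
aneumorph measure --dome dome.ply
aneumorph agreement --table measurements.csv --mode inter
aneumorph growth prob --sd 1.23
```

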