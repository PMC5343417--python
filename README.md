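# radshape

Statistical shape modelling and standardized cross-section morphometrics of
the distal radius.

## The problem

Morphometric knowledge of the distal radius — how wide, deep and large its
cross-section is, and how that varies across a population — underpins
fracture-plate design, surgical planning and forensic gender estimation.
Classical studies measure single radiograph or CT slices, which confounds
anatomy with the (arbitrary) measurement location.  A 3-D statistical shape
model removes that confounder: after aligning every bone surface into one
standardized frame and establishing dense point correspondence, the
population becomes a matrix of landmark coordinates whose principal
components ("modes") describe the anatomy's variation, and cut planes
defined by *anatomical landmarks* — not scanner coordinates — make
cross-sections comparable between specimens.

`radshape` implements that pipeline end to end for researchers in skeletal
morphometry and medical image analysis, together with a calibrated synthetic
bone generator so that every stage is testable without clinical data.

## What it computes

* **Point Distribution Model (PDM).**  Each corresponded specimen is a
  vector `x_i ∈ R^{3n}` of `n` surface landmarks.  With mean
  `x̄ = (1/N) Σ x_i` and sample covariance
  `S = (1/(N−1)) Σ (x_i − x̄)(x_i − x̄)^T`, the model is the eigensystem
  `S φ_j = λ_j φ_j`; any shape is `x ≈ x̄ + Σ_j b_j φ_j` with mode
  coefficients `b = Φ^T (x − x̄)`.  The number of modes is the smallest `m`
  with `Σ_{j≤m} λ_j / Σ_j λ_j ≥ 0.95`.
* **Standardized cut planes.**  From the styloid process tip (axial
  coordinate `z_s`) and the most dorsal point of the dorsal tubercle
  (`z_t`): the distal plane at `z_t`, the proximal plane at
  `z_t − (z_s − z_t)/2`, the middle plane halfway between — all
  perpendicular to the main axis.  Each section contour yields maximum
  width (medio-lateral extent), maximum depth (dorso-volar extent),
  perimeter and shoelace area.
* **Group statistics.**  Table-style descriptives per gender/side/plane,
  Lilliefors-corrected Kolmogorov–Smirnov normality checks, pooled
  two-sample t-tests at the Bonferroni-corrected threshold
  `α = 0.05/4 = 0.0125` (printed 0.013), and across-plane ANOVA with
  Bonferroni post-hoc comparisons.
* **Classification.**  Repeated leave-one-out cross-validation with a
  50-tree random forest on the mode coefficients — side, gender, and the
  step-wise side→gender scheme in which the gender forest is trained only on
  specimens of the *predicted* side.

## Worked example

```python
import numpy as np
from radshape import (PipelineConfig, PopulationConfig, run_pipeline)

config = PipelineConfig(
    population=PopulationConfig(n_per_group=10, seed=42,
                                mesh_resolution=1.5, side_variance_ratio=3.0),
    n_landmarks=300, icp_sample=1200, icp_max_iter=25,
    run_classification=False,
)
bundle = run_pipeline(config)
print(bundle.mode_counts.to_string(index=False))
print(bundle.morphometrics.groupby("plane", observed=True)["width"].mean())
```

prints (40 synthetic specimens, higher left-side latent variance):

```
  model  n_specimens  num_modes  first_mode_fraction
overall           40          6             0.747958
 female           20          4             0.814681
   male           20          6             0.670714
   left           20          4             0.807239
  right           20          3             0.795269
plane
distal      31.041340
middle      30.238149
proximal    28.334750
```

The left model needs more modes than the right one (the planted higher
left-side variance), and mean maximum width shrinks from the distal to the
proximal plane — the taper the cut-plane construction is designed to
resolve.  `bundle.tests["gender"]["width"].pvalue` is 1.8e-08 (males
larger), while `bundle.tests["side"]["width"].pvalue` is 0.64 (no side
difference in size): the planted gender-size/side-variance structure,
recovered through the full mesh pipeline.

A command-line interface wraps the same stages:

```bash
radshape generate --out pop/ --seed 3 --n-per-group 5
radshape validate pop/FR000.ply
radshape run results/ --config pipeline.yaml
```

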