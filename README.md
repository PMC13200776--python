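# dfigrade

Grading of unilateral facial palsy from 3D facial-landmark kinematics.

Clinicians grade facial-nerve palsy with ordinal scales — the Stennert Index
(SI, 0–10, lower is better), the House-Brackmann Scale (HBS, grades I–VI),
and the Sunnybrook Facial Grading System (SFGS, 0–100) — which are quick but
coarse and rater-dependent. Smartphone depth cameras can instead track facial
landmarks in 3D during standardized movements and quantify hemiface symmetry
objectively. `dfigrade` implements such an instrumented grading method — the
**Digital Facial Index (DFI)** — together with the conversion scheme linking
it to the clinical scales, the patient-reported outcome instruments used
alongside it (FDI, SUS), the rater-agreement statistics needed to validate it
(ICC, Cronbach α, Bland–Altman, Spearman), and a synthetic-data simulator
with planted ground truth so the whole pipeline is testable without a device.

## The index

For each facial region *g* ∈ {forehead, eye, mouth}, a movement task yields a
movement amplitude per hemiface: the mean over that region's landmarks of the
maximum Euclidean displacement (mm) from the resting face, after rigid
(Kabsch) alignment of every frame to the neutral frame on the midline
landmarks. With *A*ᵍ_aff the affected-side and *A*ᵍ_con the contralateral
amplitude, the regional symmetry ratio is

    r_g = min(A_aff / A_con, 1)            (clipped to [0, 1])

and the composite is the fixed convex combination

    DFI = 100 × (0.10 · r_forehead + 0.40 · r_eye + 0.50 · r_mouth)  [%]

where 100 % is intact function and 0 % complete paresis. The scales are
aligned on a common standardized axis (100 % = intact): SI → (10 − SI)·10,
HBS → (6 − grade)·20, SFGS and DFI map identically; hence DFI 60 % ↔ SI 4 ↔
HBS III ↔ SFGS 60.

## Worked example

```python
from dfigrade import (SimulationConfig, simulate_battery, compute_dfi,
                      ClinicalScore, Scale, convert)

# a synthetic patient: forehead intact, eye and mouth at half amplitude
cfg = SimulationConfig(severity=(1.0, 0.5, 0.5), affected_side="left")
result = compute_dfi(simulate_battery(cfg), affected_side="left")
print(f"DFI = {result.dfi_percent:.1f}%")          # DFI = 55.0%
print(convert(ClinicalScore(Scale.DFI, 55.0), Scale.HBS).render())  # IV
```

The composite is exactly 100 × (0.1·1.0 + 0.4·0.5 + 0.5·0.5) = 55.0 %: the
simulator plants the regional ratios, the grading pipeline recovers them from
the landmark trajectories, and the conversion maps 55 % to the nearest
House-Brackmann grade (IV, ties rounding toward worse function).

The same operations are available from a shell:

```
dfigrade simulate recording --severity 1.0 0.5 0.5 --out sim/
dfigrade dfi --recordings sim/ --affected-side left --out dfi.json
dfigrade convert --from DFI --value 60 --to SI
dfigrade agree --table ratings.csv --type absolute --unit average
```

Rater agreement, questionnaire scoring, and Bland–Altman comparisons work on
plain CSV tables; see `dfigrade --help`.

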