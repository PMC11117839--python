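# tetherdic

Desk-scale analysis pipeline for **posterior scleral deformation under
optic-nerve (ON) adduction tethering and intraocular-pressure (IOP)
loading**. In large adduction the ON exhausts its slack and pulls on the
globe; the sclera next to the nasal edge of the ON sheath is locally
compressed. This package re-creates the full measurement and analysis
chain used to quantify that effect on the bench — entirely on synthetic
data with exact ground truth, so every stage is testable without any
cadaver data:

* **synthgen** — speckle-patterned spherical surfaces viewed by two
  pinhole cameras under rigid motion, inflation, or a tether-like nasal
  compression (calibrated so the nasal 0–1 mm annulus area ratio equals
  0.977); cylinder calibration targets; planar translation standards;
  power-law tensile curves with an optional log-log slope break.
* **calib** — 11-parameter direct linear transformation (DLT) per camera,
  two-view triangulation, √2 displacement-error propagation, and the
  translation-standard validation.
* **dic** — subset image correlation: ZNCC integer search plus subpixel
  refinement (~0.005 px mean error on the default speckle).
* **surface** — triangulated surfaces from matched points; per-face
  **surface area ratio** (loaded/reference) instead of surface strain;
  30° nasal/superior/temporal sectors × 0–1/1–2 mm annuli from the sheath
  margin; strip profiles; mean absolute difference from unity; heat maps.
* **kinematics** — ON length by the law of cosines
  √(r² + R² − 2rR·cos(χ+ψ)), eye-rotation/gripper-rotation equivalence,
  virtual orbital apex (41 mm, 22°), apex–junction extension proportion,
  and sinuosity-corrected ON strain (elongation% − sinuosity%).
* **tensile** — engineering stress–strain from force–elongation records,
  tangent moduli dσ/dε from polynomial fits (order 3–5 by adjusted R²),
  and toe-region detection by bilinear regression of log σ vs log ε
  (transition = intersection of the two least-squares lines).
* **materials** — incompressible reduced-polynomial hyperelasticity
  W = Σᵢ C_i0 (Ī₁−3)ⁱ fitted to uniaxial data, the 5% pre-stretch
  strain-axis translation, and the lamina-cribrosa curve as the
  ON/peripapillary-sclera average.

Intended users: ocular-biomechanics researchers who want a transparent,
fully testable 3D-DIC / area-ratio / tensile-analysis reference
implementation, or a harness for validating their own pipelines against
known deformations.

## Worked example

Render the tether scene, measure it end-to-end (stereo DIC → DLT
triangulation → meshing → regional statistics):

```python
from tetherdic import pipeline, synthgen
from tetherdic.surface import regionalize

spec = synthgen.SceneSpec(deformation=synthgen.Tether(), seed=42)
meas = pipeline.measure_speckle_scene(spec, grid_step=9)
print(regionalize(meas.field, meas.region_spec)
      [["region", "n_faces", "mean", "sd", "mad_from_unity"]])
```

prints (about a minute on one core):

```
        region  n_faces     mean       sd  mad_from_unity
   nasal_0-1mm       43 0.976759 0.013611        0.023363
   nasal_1-2mm       53 0.996877 0.002595        0.003131
superior_0-1mm       50 0.999609 0.000766        0.000699
superior_1-2mm       53 1.000238 0.000873        0.000735
temporal_0-1mm       56 0.999950 0.000464        0.000376
temporal_1-2mm       56 1.000000 0.000868        0.000677
```

Read: the sclera within 1 mm of the nasal sheath margin is compressed
(mean area ratio 0.977 — the generator's calibrated ground truth was
0.9770, so the imaging pipeline recovered it to 0.0002), the effect has
decayed by 1–2 mm, and the superior/temporal sectors are undeformed. The
`mad_from_unity` column is the scalar used to compare loading modes
(≈0.023 nasally here, <0.001 in unloaded regions).

The numbered drivers under `analysis/` run the complete studies and write
tables under `results/`:

```
01_validate_calibration.py   cylinder DLT errors, √2 propagation, 0.5–2 mm stage sweep
02_scene_deformation.py      tether + inflation scenes end-to-end, regions/strips/heat maps
03_kinematics_report.py      per-specimen ON lengths, extension proportions, strains
04_tensile_analysis.py       tangent moduli per region, sheath bilinear log-log fit
05_material_models.py        hyperelastic fits, 5% pre-stretch, lamina-cribrosa curve
```

For instance `04_tensile_analysis.py` reports the sheath toe-region
transition at 3.41% strain (generator breakpoint 3.4%), with slopes
1.20 → 2.50 and recovery across 100 noisy curves of 3.40% ± 0.017%.

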