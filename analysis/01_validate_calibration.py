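#!/usr/bin/env python
"""Calibration and measurement-validation study.

Calibrates the two-camera rig against a 25.4 mm cylinder target (DLT),
reports reprojection and 3D reconstruction errors, propagates the
per-point error to displacement error, and runs the planar vernier
translation standard in normal and tangential directions up to 2 mm.
Writes results/calibration_validation.csv and results/calibration.json.
"""

import json
from pathlib import Path

import numpy as np

from tetherdic import pipeline, synthgen
from tetherdic.calib import propagate_displacement_error

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rig = synthgen.default_stereo_rig()
    pair, report = pipeline.calibrate_rig(rig, seed=1)
    rms_um = report["rms_3d_mm"] * 1e3
    disp_um = propagate_displacement_error(report["rms_3d_mm"]) * 1e3
    print(f"cylinder target: {report['n_points']} features, "
          f"reprojection RMS {max(report['rms_reprojection_px'].values()):.3f} px")
    print(f"3D reconstruction RMS error: {rms_um:.1f} um "
          f"-> displacement RMS error {disp_um:.1f} um (x sqrt 2)")

    df = pipeline.run_translation_standard(rig, pair=pair,
                                           magnitudes=(0.5, 1.0, 1.5, 2.0),
                                           grid_step=16, seed=2)
    df.to_csv(OUT / "calibration_validation.csv", index=False)
    print("\ntranslation standard (ideal: measured == magnitude, ratio == 1):")
    print(df.to_string(index=False))
    worst = np.abs(df["area_ratio_mean"] - 1.0).max()
    print(f"\nworst mean area-ratio deviation from unity: {worst:.5f}; "
          f"worst displacement error {df['error_mm'].max() * 1e3:.2f} um "
          "-> displacements up to 2 mm are measured without appreciable bias")

    (OUT / "calibration.json").write_text(json.dumps(
        {"rms_3d_um": rms_um, "displacement_rms_um": disp_um,
         "reprojection_px": report["rms_reprojection_px"]}, indent=2))


if __name__ == "__main__":
    main()
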