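"""Build the phantom cohort and export images, masks and ground-truth DVFs.

The cohort spans six weekly-anatomy trajectories (static control, weight
loss, tumor growth, tumor shrink, combined change, FOV-truncated tertiary
CTV).  For each phantom this writes the planning CT, structure masks, the
week-N deformed CT, ground-truth DVF and simulated CBCT as NIfTI, plus the
spec as YAML — the raw material the two study drivers consume on the fly.
"""

import argparse
import os

import numpy as np

from apteval import (
    Grid,
    build_planning_phantom,
    default_cohort,
    sample_weekly_anatomy,
    simulate_cbct,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0, help="master seed")
    ap.add_argument("--grid-mm", type=float, default=4.0,
                    help="isotropic voxel size (4 mm keeps this desk-scale)")
    ap.add_argument("--weeks", type=int, default=3)
    ap.add_argument("--out", default="results/phantoms")
    args = ap.parse_args()

    n = (48, 48, 32)
    sp = args.grid_mm
    grid = Grid(tuple(-(d - 1) * sp / 2 for d in n), (sp, sp, sp), n)
    cohort = default_cohort(args.seed, grid=grid)
    names = ["static", "weight_loss", "tumor_growth", "tumor_shrink",
             "combined", "fov_truncated"]
    for name, spec in zip(names, cohort):
        d = os.path.join(args.out, name)
        os.makedirs(d, exist_ok=True)
        spec.to_yaml(os.path.join(d, "spec.yaml"))
        pct, structures = build_planning_phantom(spec)
        pct.to_nifti(os.path.join(d, "pct.nii.gz"))
        structures.save(os.path.join(d, "masks"))
        for week in range(1, args.weeks + 1):
            dvf, deformed, gt = sample_weekly_anatomy(spec, week)
            cbct, fov = simulate_cbct(deformed, spec, week)
            dvf.to_nifti(os.path.join(d, f"gt_dvf_week{week}.nii.gz"))
            deformed.to_nifti(os.path.join(d, f"deformed_week{week}.nii.gz"))
            cbct.to_nifti(os.path.join(d, f"cbct_week{week}.nii.gz"))
            body0 = structures.volume_mm3("body")
            bodyw = gt.volume_mm3("body")
            print(f"{name} week {week}: body {bodyw / body0 * 100:.1f}% of planning, "
                  f"CTV_primary {gt.volume_mm3('ctv_primary') / 1000:.1f} cm^3, "
                  f"max |DVF| {dvf.max_magnitude_mm:.1f} mm")
    print(f"cohort written to {args.out}")


if __name__ == "__main__":
    main()
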