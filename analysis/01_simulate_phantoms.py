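#!/usr/bin/env python
"""Simulate an 18-patient imaging cohort of multi-lesion PET phantoms.

Each patient gets a baseline SUV volume with 2-5 spherical lesions; a
latent high-risk half of the cohort receives more heterogeneous fills
(checkerboard / noisy, larger amplitude), the low-risk half more uniform
ones.  16/18 patients also get a follow-up volume with shrunken, less
intense lesions.  Volumes and masks go to scratch/phantoms (NIfTI is
binary); the extraction manifest is written alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from petstrat.synthetic import LesionPattern, LesionSpec, PhantomSpec, generate_phantom
from petstrat.volume_io import write_mask, write_volume

OUT = Path(__file__).resolve().parents[1] / "scratch" / "phantoms"
SEED = 20180911
N_PATIENTS = 18
GRID = (48, 48, 36)
SPACING = (2.0, 2.0, 2.0)


def _patient_spec(rng: np.random.Generator, high_risk: bool, followup: bool, seed: int) -> PhantomSpec:
    n_lesions = int(rng.integers(2, 6))
    lesions = []
    occupied: list[tuple[np.ndarray, float]] = []
    for _ in range(n_lesions):
        for _attempt in range(50):
            radius = float(rng.uniform(8.0, 14.0))
            r_vox = radius / SPACING[0] + 1
            center = np.array(
                [int(rng.integers(int(r_vox), g - int(r_vox))) for g in GRID]
            )
            if all(
                np.linalg.norm((center - c) * SPACING[0]) > radius + r0 + 2
                for c, r0 in occupied
            ):
                break
        occupied.append((center, radius))
        if high_risk:
            choices = (LesionPattern.CHECKERBOARD, LesionPattern.GAUSSIAN_NOISE)
            amplitude = float(rng.uniform(1.5, 3.0))
        else:
            choices = (LesionPattern.UNIFORM, LesionPattern.RADIAL_GRADIENT)
            amplitude = float(rng.uniform(0.3, 1.0))
        pattern = choices[int(rng.integers(len(choices)))]
        mean_suv = float(rng.uniform(4.0, 8.0))
        if followup:  # therapy response: lower uptake, smaller lesions
            mean_suv = max(2.0, mean_suv * 0.7)
            radius = max(4.5, radius * 0.8)
        lesions.append(
            LesionSpec(
                center=tuple(int(c) for c in center),
                radius_mm=radius,
                pattern=pattern,
                mean_suv=mean_suv,
                amplitude=amplitude,
            )
        )
    return PhantomSpec(
        grid_shape=GRID, spacing=SPACING, background_suv=0.8,
        lesions=tuple(lesions), noise_sd=0.1, seed=seed,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    manifest = {"units": "suv", "gray_levels": 64, "patients": []}
    no_followup = set(rng.choice(N_PATIENTS, size=2, replace=False).tolist())
    for i in range(N_PATIENTS):
        pid = f"P{i + 1:03d}"
        high_risk = i < N_PATIENTS // 2
        entry = {"patient_id": pid}
        for tp in ("baseline", "followup"):
            if tp == "followup" and i in no_followup:
                continue
            seed = int(rng.integers(2**31 - 1))
            spec = _patient_spec(rng, high_risk, tp == "followup", seed)
            vol, masks = generate_phantom(spec)
            vp = OUT / f"{pid}_{tp}_suv.nii.gz"
            write_volume(vol, vp)
            mask_paths = []
            for k, m in enumerate(masks):
                mp = OUT / f"{pid}_{tp}_mask{k}.nii.gz"
                write_mask(m, mp)
                mask_paths.append(str(mp))
            entry[f"{tp}_volume"] = str(vp)
            entry[f"{tp}_masks"] = mask_paths
        manifest["patients"].append(entry)
    (OUT / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    n_fup = N_PATIENTS - len(no_followup)
    print(f"wrote {N_PATIENTS} baseline and {n_fup} follow-up phantoms to {OUT}")
    print(f"manifest: {OUT / 'manifest.yaml'}")


if __name__ == "__main__":
    main()
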