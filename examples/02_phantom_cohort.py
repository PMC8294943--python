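"""Generate a phantom cohort and verify its planted structure.

Creates a small two-site cohort of shell phantoms, standardizes it,
and shows (a) the covariate table layout, (b) that off-mask voxels are
exactly zero, and (c) that the mean intensity in the planted dose
sphere is linear in the dose covariate — the ground truth every
downstream analysis tries to recover.
"""

import numpy as np

import braincae as bc

cfg = bc.PhantomConfig(grid_shape=(20, 24, 20), voxel_size_mm=8.0,
                       n_subjects=24, seed=42)
volumes, cov = bc.generate_cohort(cfg)
print("cohort:", len(volumes), "subjects on a", cfg.grid_shape, "grid,",
      f"{volumes[0].mask.sum()} GM voxels (site_0)")
print("\ncovariates (patient-only fields are NaN for healthy subjects):")
print(cov.head(6).round(1).to_string(index=False))

std = [bc.standardize(v) for v in volumes]
v = std[0]
print("\nafter standardization: in-mask mean %.2e, SD %.6f, off-mask max |x| = %g"
      % (v.data[v.mask].mean(), v.data[v.mask].std(),
         np.abs(v.data[~v.mask]).max()))

def sphere_fit(volumes, cov, cfg):
    region = next(r for r in cfg.effects if r.covariate == "dose")
    sphere = region.sphere_mask(cfg.grid_shape)
    patients = cov["dose"].notna().to_numpy()
    dose = cov.loc[patients, "dose"].to_numpy()
    means = np.array([volumes[i].data[sphere].mean()
                      for i in np.flatnonzero(patients)])
    slope, _ = np.polyfit(dose, means, 1)
    return slope, np.corrcoef(dose, means)[0, 1], region.slope


slope, r, planted = sphere_fit(volumes, cov, cfg)
print(f"\nplanted dose sphere, default noise: fitted slope {slope:.2e} "
      f"intensity/mg (planted {planted:.2e}), r = {r:.3f}")

quiet = bc.PhantomConfig(grid_shape=cfg.grid_shape, voxel_size_mm=8.0,
                         n_subjects=24, noise_sd=0.0, smoothing_fwhm_mm=0.0,
                         n_sites=1, seed=42)
qvols, qcov = bc.generate_cohort(quiet)
slope, r, planted = sphere_fit(qvols, qcov, quiet)
print(f"noise-free, unsmoothed:       fitted slope {slope:.2e} "
      f"intensity/mg (planted {planted:.2e}), r = {r:.6f}")
print("with noise off the sphere mean is an exact linear function of dose; "
      "noise and smoothing attenuate but never bias the relation.")
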