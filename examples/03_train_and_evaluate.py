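"""End-to-end miniature run: train, extract, regress, map saliency.

A deliberately small configuration (10x12x10 grid, 800 iterations) so
the whole pipeline finishes in a few minutes on one core:

1. simulate a two-site phantom cohort and standardize it;
2. train a 2-block/8-channel autoencoder on site_0 (site_1 is the
   held-out transfer site) and compare against the average-brain
   reference;
3. extract flattened latent features and ROI-baseline features;
4. evaluate both with repeated-CV ridge regression on the planted dose
   covariate;
5. compute the group saliency map of the dose regression.

Numbers vary slightly with the seed; the qualitative picture (training
below the average-brain level, latent features beating the permuted
null) is the point.
"""

import numpy as np

import braincae as bc

cfg = bc.PhantomConfig(grid_shape=(10, 12, 10), voxel_size_mm=14.0,
                       n_subjects=40, seed=3)
volumes, cov = bc.generate_cohort(cfg)
std = [bc.standardize(v) for v in volumes]
primary = [v for v, s in zip(std, cov["site"]) if s == "site_0"]
external = [v for v, s in zip(std, cov["site"]) if s == "site_1"]

split = bc.SplitSpec(n_train=len(primary) - 8, n_val=4, n_test=4, seed=0)
train, val, test = bc.split_cohort(primary, split)

model = bc.build_cae(bc.ArchitectureSpec(n_blocks=2, extraction_channels=8),
                     cfg.grid_shape, seed=0)
tcfg = bc.TrainConfig(max_iterations=800, eval_interval=200, seed=0)
model, curve = bc.train_cae(model, train, val, test, external, tcfg)
print("validation MAE %.4f vs average-brain %.4f"
      % (curve.best("val"), curve.reference("val")))
print("transfer-site MAE %.4f vs its average-brain %.4f"
      % (curve.final("external"), curve.reference("external")))

# regression within one site, mirroring the single-dataset design that
# avoids scanning-site effects contaminating the features
patients = cov["dose"].notna() & (cov["site"] == "site_0")
ids = list(cov.loc[patients, "id"])
dose = cov.loc[patients, "dose"].to_numpy(float)
by_id = {v.subject_id: v for v in std}
subjects = [by_id[i] for i in ids]

latent = bc.extract_features(model, subjects)
atlas = bc.synthetic_parcellation(np.logical_or.reduce([v.mask for v in std]),
                                  n_parcels=30, seed=0)
roi = bc.roi_features(subjects, atlas)

# ridge penalty re-selected inside every training fold (inner CV); with
# ~20 patients and hundreds of ReLU features a fixed small penalty is
# fragile against units that are silent in training and fire on a held-out
# subject
GRID = (1e-2, 1.0, 1e2, 1e4)
rep_latent = bc.ridge_cv(latent, dose, seed=0, target_name="dose",
                         penalty_grid=GRID)
rep_roi = bc.ridge_cv(roi, dose, seed=0, target_name="dose",
                      penalty_grid=GRID)
rep_null = bc.ridge_cv(latent, np.random.default_rng(1).permutation(dose),
                       seed=0, target_name="dose", penalty_grid=GRID)
print("\ndose RMSE (mean over 10 CV repeats):")
print(f"  latent features ({latent.n_features}): {rep_latent.mean:7.1f}"
      f"  (SD {rep_latent.sd:.2f})")
print(f"  ROI features    ({roi.n_features}): {rep_roi.mean:7.1f}"
      f"  (SD {rep_roi.sd:.2f})")
print(f"  permuted null            : {rep_null.mean:7.1f}")
t, p, sig = bc.compare_to_roi_ttest(rep_latent, rep_roi)
print(f"  latent vs ROI t-test: t = {t:.2f}, p = {p:.3g}")

ridge = bc.fit_ridge(latent, dose, penalty=1.0, target="dose")
maps = [bc.subject_gradient(model, ridge, v, n_noise=10, seed=50 + i)
        for i, v in enumerate(subjects)]
smap = bc.group_saliency(maps, target="dose")
region = next(r for r in cfg.effects if r.covariate == "dose")
sphere = region.sphere_mask(cfg.grid_shape)
mask = np.logical_or.reduce([v.mask for v in std])
sphere_m = sphere & mask
thr = np.quantile(smap.data[mask], 0.95)
top = (smap.data >= thr) & mask
enrichment = ((top & sphere_m).sum() / top.sum()) / (sphere_m.sum() / mask.sum())
print("\nsaliency |t| inside planted dose sphere: %.3f vs elsewhere: %.3f"
      % (smap.data[sphere_m].mean(), smap.data[mask & ~sphere_m].mean()))
print("top-5%% saliency voxels are %.1fx enriched inside the sphere"
      % enrichment)
print("elevated saliency in the sphere localizes the dose signal; at this "
      "miniature scale the contrast is modest — the test suite shows >2x "
      "top-percentile enrichment at the full desk-scale conditions.")
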