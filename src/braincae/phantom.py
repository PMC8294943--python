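"""Synthetic brain-phantom cohorts.

Generates cohorts of smoothed gray-matter-like 3D volumes with a fully
known generative model, so that every downstream stage (standardization,
autoencoder training, feature extraction, regression, saliency) can be
tested without real MRI.  Each subject's volume is an ellipsoidal
cortical *shell*:

    field = baseline * shell
          + subject_intercept * shell
          + sum_r slope_r * covariate_r * sphere_r
          + voxel noise,

smoothed with a separable Gaussian (sigma = FWHM / 2.355, converted
from mm to voxels) and set exactly to zero outside the shell mask.
Sites differ by a configured global intensity factor and a shell
thickness delta — a crude stand-in for scanner/site differences, with
no attempt at scanner physics.

Two structured components make the phantom a meaningful reconstruction
benchmark rather than a bare noise field:

* a fixed smooth *anatomy pattern* inside the shell, shared by every
  subject — the analogue of common cortical anatomy, and the part of
  the signal a trivial average-brain predictor can represent;
* a smooth per-subject *random field* — the analogue of individual
  anatomical variability, spatially coherent and therefore encodable by
  a convolutional autoencoder but invisible to the average brain.

Covariates mirror a clinical-cohort table: age, binary diagnosis, and
patient-only clinical scores (antipsychotic dose in chlorpromazine
equivalents and positive/negative symptom scores) driven by a shared
latent severity.  All stochastic subject components (intercept, random
field, voxel noise) scale with ``noise_sd``, so ``noise_sd=0`` silences
every source of subject variability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import GreyMatterVolume, VolumeGrid, write_cohort

__all__ = [
    "EffectRegion",
    "PhantomConfig",
    "InvalidConfigError",
    "default_effect_map",
    "generate_cohort",
    "simulate_to_dir",
    "FWHM_TO_SIGMA",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma ~= 2.355 * sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EffectRegion:
    """A spherical region whose intensity is linear in one covariate."""

    center: tuple[float, float, float]  # voxel coordinates
    radius: float                       # voxels
    covariate: str
    slope: float                        # intensity units per covariate unit

    def sphere_mask(self, shape) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        r2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return r2 <= self.radius ** 2


def default_effect_map(grid_shape) -> tuple[EffectRegion, ...]:
    """Two planted spheres on the shell: a dose effect and an age effect.

    The dose slope (2e-3 intensity per CPZE-mg; dose SD ~100 mg) gives a
    ~0.2 intensity swing against a 0.6 shell baseline — a deliberately
    unambiguous planted signal.  The age effect is weaker (GM-decline
    flavored).  Sphere radius scales with the grid but never drops
    below 2 voxels.
    """
    shape = tuple(int(s) for s in grid_shape)
    ext = tuple(s - 1 for s in shape)
    radius = max(2.0, 0.09 * min(shape))
    return (
        EffectRegion(
            center=(0.5 * ext[0], 0.85 * ext[1], 0.5 * ext[2]),
            radius=radius, covariate="dose", slope=2e-3),
        EffectRegion(
            center=(0.5 * ext[0], 0.15 * ext[1], 0.5 * ext[2]),
            radius=radius, covariate="age", slope=-4e-3),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generative settings.

    ``grid_shape`` defaults to the small 40x48x40 mode; the full-scale
    standard-space mode is 121x145x121 at 1.5 mm.  ``noise_sd`` scales
    both voxel noise and (through ``subject_sd_scale``) the per-subject
    global intercept, so a zero value makes the cohort deterministic
    apart from planted covariate effects.
    """

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    n_subjects: int = 60
    n_sites: int = 2
    smoothing_fwhm_mm: float = 8.0
    noise_sd: float = 0.05
    subject_sd_scale: float = 2.0
    subject_field_scale: float = 1.5
    subject_field_fwhm_mm: float = 48.0
    anatomy_amplitude: float = 0.15
    anatomy_fwhm_mm: float = 32.0
    baseline: float = 0.6
    shell_outer_frac: float = 0.44
    shell_thickness_frac: float = 0.35
    site_intensity_factors: tuple[float, ...] | None = None
    site_thickness_deltas: tuple[float, ...] | None = None  # voxels
    site_proportions: tuple[float, ...] | None = None
    effect_map: tuple[EffectRegion, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "grid_shape",
                           tuple(int(s) for s in self.grid_shape))
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise InvalidConfigError(
                f"grid_shape must be three axes all >= 8, got {self.grid_shape}")
        if self.n_subjects < 2:
            raise InvalidConfigError("n_subjects must be >= 2")
        if self.n_sites < 1:
            raise InvalidConfigError("n_sites must be >= 1")
        if self.smoothing_fwhm_mm < 0:
            raise InvalidConfigError("smoothing_fwhm_mm must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.effect_map is not None:
            object.__setattr__(self, "effect_map", tuple(self.effect_map))
            for reg in self.effect_map:
                for c, s in zip(reg.center, self.grid_shape):
                    if not (0 <= c < s):
                        raise InvalidConfigError(
                            f"effect region centre {reg.center} outside grid "
                            f"{self.grid_shape}")

    # -- resolved defaults --------------------------------------------

    @property
    def effects(self) -> tuple[EffectRegion, ...]:
        if self.effect_map is not None:
            return self.effect_map
        return default_effect_map(self.grid_shape)

    @property
    def intensity_factors(self) -> tuple[float, ...]:
        if self.site_intensity_factors is not None:
            return tuple(self.site_intensity_factors)
        return tuple(1.0 + 0.12 * i for i in range(self.n_sites))

    @property
    def thickness_deltas(self) -> tuple[float, ...]:
        if self.site_thickness_deltas is not None:
            return tuple(self.site_thickness_deltas)
        return tuple(1.0 * i for i in range(self.n_sites))

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.site_proportions is not None:
            return tuple(self.site_proportions)
        if self.n_sites == 1:
            return (1.0,)
        if self.n_sites == 2:
            return (0.7, 0.3)
        return (1.0 / self.n_sites,) * self.n_sites

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.grid_shape, self.voxel_size_mm)

    def shell_mask(self, site_index: int = 0) -> np.ndarray:
        """Binary GM shell for a site's geometry."""
        outer = np.array(self.grid_shape) * self.shell_outer_frac
        thick_frac = self.shell_thickness_frac
        delta = self.thickness_deltas[site_index]
        inner = outer * (1.0 - thick_frac) - delta
        inner = np.maximum(inner, 1.0)
        center = (np.array(self.grid_shape) - 1) / 2.0
        grids = np.ogrid[tuple(slice(0, s) for s in self.grid_shape)]
        r_out = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, outer))
        r_in = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, inner))
        return (r_out <= 1.0) & (r_in > 1.0)


def _site_labels(cfg: PhantomConfig) -> list[int]:
    """Deterministic contiguous site assignment following the proportions."""
    props = np.asarray(cfg.proportions, dtype=float)
    props = props / props.sum()
    bounds = np.floor(np.cumsum(props) * cfg.n_subjects + 0.5).astype(int)
    bounds[-1] = cfg.n_subjects
    labels, start = [], 0
    for site, stop in enumerate(bounds):
        labels += [site] * (stop - start)
        start = stop
    return labels


def _covariates(cfg: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    sites = _site_labels(cfg)
    age = rng.uniform(20.0, 65.0, size=n)
    diagnosis = rng.integers(0, 2, size=n)
    severity = rng.standard_normal(n)
    dose = np.clip(300.0 + 100.0 * severity + rng.normal(0, 30.0, n), 25.0, None)
    positive = np.clip(15.0 + 4.0 * severity + rng.normal(0, 2.0, n), 7.0, None)
    negative = np.clip(14.0 + 3.5 * severity + rng.normal(0, 2.0, n), 7.0, None)
    duration = np.minimum(rng.uniform(1.0, 20.0, n), np.maximum(age - 18.0, 1.0))
    onset = age - duration
    patient = diagnosis == 1
    df = pd.DataFrame(
        {
            "id": [f"sub-{i:03d}" for i in range(n)],
            "site": [f"site_{s}" for s in sites],
            "diagnosis": diagnosis.astype(int),
            "age": age,
            "dose": np.where(patient, dose, np.nan),
            "positive_score": np.where(patient, positive, np.nan),
            "negative_score": np.where(patient, negative, np.nan),
            "onset_age": np.where(patient, onset, np.nan),
            "duration": np.where(patient, duration, np.nan),
        }
    )
    return df


def _smooth_unit_field(rng: np.random.Generator, shape,
                       fwhm_mm: float, voxel_mm: float) -> np.ndarray:
    """White noise smoothed to ``fwhm_mm`` and rescaled to unit SD."""
    field = rng.standard_normal(shape)
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    if sigma > 0:
        field = gaussian_filter(field, sigma=sigma)
    sd = field.std()
    return (field / sd).astype(np.float32) if sd > 0 else field.astype(np.float32)


def generate_cohort(cfg: PhantomConfig) -> tuple[list[GreyMatterVolume], pd.DataFrame]:
    """Generate the cohort; bit-for-bit reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    cov = _covariates(cfg, rng)
    shape = cfg.grid_shape
    grid = cfg.grid
    sigma_vox = cfg.smoothing_fwhm_mm * FWHM_TO_SIGMA / cfg.voxel_size_mm

    site_masks = {s: cfg.shell_mask(s) for s in range(cfg.n_sites)}
    # shared smooth anatomy inside the shell (same for every subject)
    anatomy = cfg.anatomy_amplitude * _smooth_unit_field(
        rng, shape, cfg.anatomy_fwhm_mm, cfg.voxel_size_mm)
    effect_fields = []
    for reg in cfg.effects:
        effect_fields.append((reg.covariate, reg.slope,
                              reg.sphere_mask(shape).astype(np.float32)))

    subject_sd = cfg.subject_sd_scale * cfg.noise_sd
    field_sd = cfg.subject_field_scale * cfg.noise_sd
    volumes = []
    for _, row in cov.iterrows():
        site = int(row["site"].split("_")[1])
        mask = site_masks[site]
        fmask = mask.astype(np.float32)
        field = (cfg.baseline + anatomy) * fmask
        if subject_sd > 0:
            field = field + np.float32(rng.normal(0.0, subject_sd)) * fmask
        if field_sd > 0:
            field = field + field_sd * _smooth_unit_field(
                rng, shape, cfg.subject_field_fwhm_mm, cfg.voxel_size_mm) * fmask
        for name, slope, sphere in effect_fields:
            value = row[name]
            if pd.notna(value):
                field = field + np.float32(slope * value) * sphere
        field = field * np.float32(cfg.intensity_factors[site])
        if cfg.noise_sd > 0:
            field = field + rng.normal(
                0.0, cfg.noise_sd, size=shape).astype(np.float32)
        if sigma_vox > 0:
            field = gaussian_filter(field, sigma=sigma_vox)
        field = field.astype(np.float32)
        field[~mask] = 0.0
        volumes.append(GreyMatterVolume(data=field, mask=mask, grid=grid,
                                        subject_id=row["id"]))
    return volumes, cov


def simulate_to_dir(cfg: PhantomConfig, outdir, compress: bool = True) -> dict:
    """Write the cohort (NIfTI per subject + covariates.csv + manifest.json)."""
    outdir = Path(outdir)
    volumes, cov = generate_cohort(cfg)
    paths = write_cohort(outdir, volumes, cov, compress=compress)
    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_dict(cfg: PhantomConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d["effect_map"] is not None:
        d["effect_map"] = [dataclasses.asdict(r) for r in cfg.effect_map]
    return d
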