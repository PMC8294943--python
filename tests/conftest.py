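"""Shared fixtures.

The expensive fixture is ``trained_system``: one phantom cohort with a
planted dose effect, and one 2-block/16-channel autoencoder trained for
2000 iterations on the primary site.  It is session-scoped and shared
by the reconstruction, regression and saliency acceptance tests, so the
training cost is paid once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import braincae as bc

# Desk-scale study conditions for the trained-model checks: a 12x16x12
# grid keeps a 2000-iteration training run on one core in the minutes
# range while the shell, the planted dose sphere and the two-site shift
# all stay resolvable.
DESK_GRID = (12, 16, 12)
DESK_VOXEL_MM = 12.0
DESK_N_SUBJECTS = 60
DESK_SEED = 7
TRAIN_ITERATIONS = 2000


def desk_config(**overrides) -> bc.PhantomConfig:
    kw = dict(grid_shape=DESK_GRID, voxel_size_mm=DESK_VOXEL_MM,
              n_subjects=DESK_N_SUBJECTS, seed=DESK_SEED)
    kw.update(overrides)
    return bc.PhantomConfig(**kw)


@dataclass
class TrainedSystem:
    config: bc.PhantomConfig
    covariates: object
    volumes: list            # standardized, cohort order
    train: list
    val: list
    test: list
    external: list
    model: bc.CAE
    curve: bc.LearningCurve


@pytest.fixture(scope="session")
def phantom_cohort():
    cfg = desk_config()
    vols, cov = bc.generate_cohort(cfg)
    std = [bc.standardize(v) for v in vols]
    return cfg, std, cov


@pytest.fixture(scope="session")
def trained_system(phantom_cohort) -> TrainedSystem:
    cfg, std, cov = phantom_cohort
    primary = [v for v, s in zip(std, cov["site"]) if s == "site_0"]
    external = [v for v, s in zip(std, cov["site"]) if s == "site_1"]
    n = len(primary)
    split = bc.SplitSpec(n_train=n - 12, n_val=6, n_test=6, seed=1)
    tr, va, te = bc.split_cohort(primary, split)
    model = bc.build_cae(bc.ArchitectureSpec(n_blocks=2, extraction_channels=16),
                         cfg.grid_shape, seed=0)
    tcfg = bc.TrainConfig(max_iterations=TRAIN_ITERATIONS, eval_interval=250,
                          seed=0)
    model, curve = bc.train_cae(model, tr, va, te, external, tcfg)
    return TrainedSystem(config=cfg, covariates=cov, volumes=std,
                         train=tr, val=va, test=te, external=external,
                         model=model, curve=curve)
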