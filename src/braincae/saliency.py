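"""Gradient saliency of the regression-through-encoder composite.

For a subject volume ``x`` the saliency is the gradient of the
prediction ``R(S(x))`` with respect to ``x``, where ``S`` is the frozen
encoder and ``R`` a linear (ridge) regressor on the flattened latent
features.  ``R`` being linear, its latent-space gradient is its
coefficient vector (rescaled by the column standardization); that
vector is backpropagated through the encoder to the input grid.

To temper single-point gradients the computation is repeated with
Gaussian noise added to the input and averaged — the SmoothGrad
recipe.  Per-subject maps are aggregated into a group map of voxelwise
|mean / SD| across subjects (population SD, as a t-like statistic);
voxels with zero SD are set to 0 and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import CAE
from .regression import FittedRidge
from .volume import GreyMatterVolume

__all__ = [
    "SaliencyMap",
    "UnsupportedRegressorError",
    "subject_gradient",
    "group_saliency",
    "DEFAULT_NOISE_FRACTION",
    "DEFAULT_N_NOISE",
]

#: Noise SD as a fraction of the subject's in-mask intensity SD.
DEFAULT_NOISE_FRACTION = 0.1
DEFAULT_N_NOISE = 25


class UnsupportedRegressorError(TypeError):
    """The regressor exposes no analytic feature-space gradient."""


@dataclass
class SaliencyMap:
    data: np.ndarray            # |t| per voxel, >= 0
    target: str
    n_subjects: int
    noise_sd: float | None
    n_noise: int
    seed: int | None
    zero_sd_voxels: int = 0

    def __post_init__(self):
        if (self.data < 0).any():
            raise ValueError("saliency values must be non-negative")


def _latent_gradient(model: CAE, regressor: FittedRidge) -> np.ndarray:
    if not hasattr(regressor, "feature_gradient"):
        raise UnsupportedRegressorError(
            "regressor must expose feature_gradient(); only linear models "
            "have a closed-form saliency gradient")
    g = np.asarray(regressor.feature_gradient(), dtype=np.float32)
    ls = model.latent
    if g.size != ls.flattened_length:
        raise ValueError(
            f"regressor has {g.size} coefficients but the latent space has "
            f"{ls.flattened_length} dimensions")
    # inverse of the channel-major flattening used by extract_features:
    # (C, d, h, w) per subject -> encoder layout (C, B, d, h, w)
    return g.reshape(ls.channels, *ls.dims)


def subject_gradient(model: CAE, regressor: FittedRidge, volume,
                     noise_sd: float | None = None,
                     n_noise: int = DEFAULT_N_NOISE,
                     seed: int | None = 0) -> np.ndarray:
    """Noise-averaged input gradient of R(S(x)) for one subject.

    ``noise_sd=None`` uses 0.1x the subject's in-mask intensity SD;
    ``noise_sd=0`` with ``n_noise=1`` is the plain single-point
    gradient.  Deterministic given ``seed``.
    """
    if n_noise < 1:
        raise ValueError("n_noise must be >= 1")
    if isinstance(volume, GreyMatterVolume):
        x = volume.data
        in_mask_sd = float(x[volume.mask].std()) if volume.mask.any() else float(x.std())
    else:
        x = np.asarray(volume, dtype=np.float32)
        in_mask_sd = float(x.std())
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_FRACTION * in_mask_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    glat = _latent_gradient(model, regressor)[:, None]  # add batch axis
    rng = np.random.default_rng(seed)
    acc = np.zeros(x.shape, dtype=np.float64)
    for _ in range(n_noise):
        xi = x if noise_sd == 0 else x + rng.normal(
            0.0, noise_sd, size=x.shape).astype(np.float32)
        model.encode(xi[None], keep=True)
        acc += model.encoder_input_gradient(glat)[0].astype(np.float64)
    return (acc / n_noise).astype(np.float32)


def group_saliency(maps, target: str = "", noise_sd: float | None = None,
                   n_noise: int = DEFAULT_N_NOISE,
                   seed: int | None = None) -> SaliencyMap:
    """Voxelwise |mean / SD| of per-subject gradient maps.

    SD is the population SD across subjects, taken before the absolute
    value; zero-SD voxels map to 0 and their count is recorded.
    """
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    if stack.shape[0] < 2:
        raise ValueError("group saliency needs at least 2 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    # SD that is zero up to float rounding (identical maps leave residuals
    # of ~1e-17 through the mean) counts as degenerate, not as evidence
    zero = sd <= 1e-9 * np.abs(mean)
    out = np.zeros_like(mean)
    np.divide(mean, sd, out=out, where=~zero)
    return SaliencyMap(data=np.abs(out).astype(np.float32), target=target,
                       n_subjects=stack.shape[0], noise_sd=noise_sd,
                       n_noise=n_noise, seed=seed,
                       zero_sd_voxels=int(zero.sum()))
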