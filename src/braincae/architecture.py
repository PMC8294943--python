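"""Parametric 3D convolutional autoencoder architectures.

The architecture family is a grid over two hyperparameters: the number
of convolution/pooling *blocks* (1-4) and the channel count of the
*extraction layer* (1, 4, 16 or 32), with every other convolution fixed
at 32 channels.  A block is two 3x3x3 stride-1 convolutions (ReLU)
followed by one 2x2x2 stride-2 average pooling; after the blocks an
extraction pair (one 32-channel conv and one conv down to the
extraction channel count, both ReLU) produces the latent feature map.
The decoder mirrors the encoder with nearest-neighbour unpooling, and
its final convolution maps back to a single channel with a *linear*
output so that standardized (zero-mean) targets are representable.

For the 3-block member this composition gives an encoder of exactly
eight convolutional layers and an effective receptive field of
68x68x68 voxels per latent unit; both quantities are available in
closed form (:func:`receptive_field`) and by an autodiff probe
(:func:`gradient_support_side`).
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import yaml

from .nn import AvgPool3d, Conv3d, Sequential, Unpool3d

__all__ = [
    "ArchitectureSpec",
    "LayerDescriptor",
    "LatentShape",
    "CAE",
    "build_cae",
    "default_grid",
    "encoder_layer_descriptors",
    "receptive_field",
    "latent_shape",
    "gradient_support_side",
    "save_checkpoint",
    "load_checkpoint",
]

VALID_BLOCKS = (1, 2, 3, 4)
VALID_EXTRACTION_CHANNELS = (1, 4, 16, 32)


@dataclass(frozen=True)
class ArchitectureSpec:
    """One point of the block x channel architecture grid.

    Parameters
    ----------
    n_blocks:
        Number of conv-conv-pool blocks in the encoder (1-4).  Each
        block halves the spatial extent and widens the receptive field.
    extraction_channels:
        Channel count of the latent (extraction) layer: 1, 4, 16 or 32.
        Together with the pooled spatial dims it sets the latent
        dimensionality, from hundreds to millions of scalars.
    base_channels:
        Width of every non-extraction convolution.  Fixed at 32 in the
        reference grid; exposed so probes and tiny tests can shrink it
        (it does not affect shapes or receptive fields).
    """

    n_blocks: int
    extraction_channels: int
    base_channels: int = 32

    def __post_init__(self):
        if self.n_blocks not in VALID_BLOCKS:
            raise ValueError(f"n_blocks must be in {VALID_BLOCKS}, got {self.n_blocks}")
        if self.extraction_channels < 1:
            raise ValueError("extraction_channels must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls(**yaml.safe_load(text))


def default_grid() -> list[ArchitectureSpec]:
    """The 16 reference configurations (4 block levels x 4 channel levels)."""
    return [
        ArchitectureSpec(n_blocks=b, extraction_channels=c)
        for b in VALID_BLOCKS
        for c in VALID_EXTRACTION_CHANNELS
    ]


@dataclass(frozen=True)
class LayerDescriptor:
    kind: str            # conv | pool | unpool
    kernel: int
    stride: int
    in_channels: int
    out_channels: int


@dataclass(frozen=True)
class LatentShape:
    channels: int
    dims: tuple[int, int, int]

    @property
    def flattened_length(self) -> int:
        return self.channels * int(np.prod(self.dims))


def encoder_layer_descriptors(spec: ArchitectureSpec) -> list[LayerDescriptor]:
    """Layer-by-layer description of the encoder path (input to latent)."""
    layers: list[LayerDescriptor] = []
    cin = 1
    for _ in range(spec.n_blocks):
        layers.append(LayerDescriptor("conv", 3, 1, cin, spec.base_channels))
        layers.append(LayerDescriptor("conv", 3, 1, spec.base_channels, spec.base_channels))
        layers.append(LayerDescriptor("pool", 2, 2, spec.base_channels, spec.base_channels))
        cin = spec.base_channels
    layers.append(LayerDescriptor("conv", 3, 1, cin, spec.base_channels))
    layers.append(LayerDescriptor("conv", 3, 1, spec.base_channels, spec.extraction_channels))
    return layers


def receptive_field(spec: ArchitectureSpec) -> int:
    """Effective receptive-field side (voxels) of one latent unit.

    Standard receptive-field recursion over the encoder path: starting
    from rf=1 and jump=1, each layer grows rf by (kernel-1)*jump and
    multiplies jump by its stride.
    """
    rf, jump = 1, 1
    for layer in encoder_layer_descriptors(spec):
        rf += (layer.kernel - 1) * jump
        jump *= layer.stride
    return rf


def latent_shape(spec: ArchitectureSpec, input_shape) -> LatentShape:
    """Latent feature-map shape for a given input grid (ceil division)."""
    dims = tuple(ceil(d / 2 ** spec.n_blocks) for d in input_shape)
    return LatentShape(channels=spec.extraction_channels, dims=dims)


class CAE:
    """A built autoencoder: encoder, decoder and the joint forward pass.

    ``forward`` center-crops the decoded volume back to the input grid
    (odd extents round up through ceil-mode pooling, so the decoder
    output can overshoot by up to ``2**n_blocks - 1`` voxels per axis).
    """

    def __init__(self, spec: ArchitectureSpec, input_shape, seed: int = 0):
        input_shape = tuple(int(d) for d in input_shape)
        if len(input_shape) != 3:
            raise ValueError("input_shape must have three axes")
        if min(input_shape) < 2 ** spec.n_blocks:
            raise ValueError(
                f"input shape {input_shape} too small for {spec.n_blocks} poolings")
        self.spec = spec
        self.input_shape = input_shape
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        bc, ec = spec.base_channels, spec.extraction_channels

        enc: list = []
        cin = 1
        for _ in range(spec.n_blocks):
            enc.append(Conv3d(cin, bc, rng=rng))
            enc.append(Conv3d(bc, bc, rng=rng))
            enc.append(AvgPool3d())
            cin = bc
        enc.append(Conv3d(cin, bc, rng=rng))
        enc.append(Conv3d(bc, ec, rng=rng))
        self.encoder = Sequential(enc)

        dec: list = [Conv3d(ec, bc, rng=rng), Conv3d(bc, bc, rng=rng)]
        for b in range(spec.n_blocks):
            last_block = b == spec.n_blocks - 1
            dec.append(Unpool3d())
            dec.append(Conv3d(bc, bc, rng=rng))
            if last_block:
                dec.append(Conv3d(bc, 1, relu=False, rng=rng))
            else:
                dec.append(Conv3d(bc, bc, rng=rng))
        self.decoder = Sequential(dec)
        self._crop = None  # offsets of the final center crop

    # -- shapes -------------------------------------------------------

    @property
    def latent(self) -> LatentShape:
        return latent_shape(self.spec, self.input_shape)

    def encoder_conv_count(self) -> int:
        return len(self.encoder.conv_layers())

    # -- forward / backward -------------------------------------------

    def encode(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """x: (B, D, H, W) -> latent (C, B, d, h, w)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"volume grid {x.shape[1:]} incompatible with model grid {self.input_shape}")
        return self.encoder.forward(x[np.newaxis], keep=keep)

    def decode(self, z: np.ndarray, keep: bool = True) -> np.ndarray:
        """latent (C, B, d, h, w) -> reconstruction (B, D, H, W)."""
        y = self.decoder.forward(z, keep=keep)
        D, H, W = self.input_shape
        _, B, Dd, Hd, Wd = y.shape
        o = ((Dd - D) // 2, (Hd - H) // 2, (Wd - W) // 2)
        self._crop = (o, (Dd, Hd, Wd))
        return y[0, :, o[0] : o[0] + D, o[1] : o[1] + H, o[2] : o[2] + W]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        return self.decode(self.encode(x, keep=keep), keep=keep)

    def backward(self, grad_recon: np.ndarray) -> None:
        """Backprop from d(loss)/d(reconstruction); fills conv gradients."""
        (o, (Dd, Hd, Wd)) = self._crop
        D, H, W = self.input_shape
        B = grad_recon.shape[0]
        g = np.zeros((1, B, Dd, Hd, Wd), dtype=np.float32)
        g[0, :, o[0] : o[0] + D, o[1] : o[1] + H, o[2] : o[2] + W] = grad_recon
        gz = self.decoder.backward(g, need_input_grad=True)
        self.encoder.backward(gz, need_input_grad=False)

    def encoder_input_gradient(self, grad_latent: np.ndarray) -> np.ndarray:
        """Backprop a latent-space gradient to the input volume(s).

        Requires a preceding ``encode(..., keep=True)``.  Returns
        (B, D, H, W).
        """
        gx = self.encoder.backward(
            np.asarray(grad_latent, dtype=np.float32), need_input_grad=True)
        return gx[0]

    def calibrate_init(self, sample_batch: np.ndarray,
                       hidden_bias: float = 0.05,
                       head_scale: float | None = None) -> None:
        """Stabilizing initialization pass before mean-absolute-error training.

        Three measures, all standard remedies for deep ReLU stacks:

        * LSUV-style variance scaling — average pooling attenuates weakly
          correlated activations by up to sqrt(8) per block, which fan-in
          initialization alone does not compensate, so each hidden
          convolution's weights are rescaled for unit pre-activation SD
          on a sample batch;
        * a small positive bias on every hidden (ReLU) convolution, so
          no layer starts, or is easily pushed, into the all-dead regime
          from which no gradient returns;
        * a zero-initialized final reconstruction layer.  The output then
          starts exactly at 0, where the background voxels of the
          absolute-error loss contribute no gradient (sign 0); the last
          layer first grows like a linear probe on live decoder features
          and upstream layers only move once that output path exists,
          which avoids the uniform shrink transient that otherwise kills
          decoder ReLUs.

        With ``head_scale`` set, the final layer is instead rescaled so
        the initial output SD is ``head_scale`` times the sample batch
        SD — a live head descends from the first iteration (useful for
        short smoke runs) at the cost of an initial shrink phase.

        Deterministic given the batch; call once before training.
        """
        x = np.asarray(sample_batch, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        h = x[np.newaxis]
        layers = self.encoder.layers + self.decoder.layers
        for layer in layers:
            if isinstance(layer, Conv3d):
                relu, layer.relu = layer.relu, False
                pre = layer.forward(h, keep=False)
                layer.relu = relu
                sd = float(pre.std())
                if layer.relu:
                    if sd > 1e-8:
                        layer.W /= sd
                    layer.b[:] = hidden_bias
                elif head_scale is not None and sd > 1e-8:
                    layer.W *= head_scale * float(x.std()) / sd
            h = layer.forward(h, keep=False)
        if head_scale is None:
            final = layers[-1]
            final.W[:] = 0.0
            final.b[:] = 0.0

    # -- weights ------------------------------------------------------

    def conv_layers(self) -> list[Conv3d]:
        return self.encoder.conv_layers() + self.decoder.conv_layers()

    def parameter_count(self) -> int:
        return sum(c.W.size + c.b.size for c in self.conv_layers())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for c in self.conv_layers():
            out.append(c.W.copy())
            out.append(c.b.copy())
        return out

    def set_weights(self, weights) -> None:
        it = iter(weights)
        for c in self.conv_layers():
            c.W = next(it).astype(np.float32).copy()
            c.b = next(it).astype(np.float32).copy()


def build_cae(spec: ArchitectureSpec, input_shape, seed: int = 0) -> CAE:
    """Instantiate a CAE for ``input_shape`` with seeded He-uniform weights."""
    return CAE(spec, input_shape, seed=seed)


def gradient_support_side(spec: ArchitectureSpec, margin: int = 4) -> int:
    """Measure the receptive field empirically via gradient support.

    Builds the encoder with all-positive constant weights and biases
    (so every ReLU is active and no gradient path is masked), runs a
    zero input large enough to contain the field, backpropagates a
    one-hot gradient from a central latent unit and returns the side of
    the bounding box of nonzero input gradients.  ``base_channels`` and
    ``extraction_channels`` are collapsed to 1 — they do not affect the
    geometry of the field — which keeps the probe cheap even for the
    4-block model.
    """
    probe_spec = ArchitectureSpec(
        n_blocks=spec.n_blocks, extraction_channels=1, base_channels=1)
    rf = receptive_field(probe_spec)
    stride = 2 ** probe_spec.n_blocks
    side = rf + margin * stride
    model = CAE(probe_spec, (side, side, side), seed=0)
    for conv in model.conv_layers():
        conv.W.fill(0.05)
        conv.b.fill(0.1)
    x = np.zeros((1, side, side, side), dtype=np.float32)
    z = model.encode(x, keep=True)
    g = np.zeros_like(z)
    c = tuple(d // 2 for d in z.shape[2:])
    g[0, 0, c[0], c[1], c[2]] = 1.0
    gx = model.encoder_input_gradient(g)[0]
    nz = np.nonzero(np.abs(gx) > 0)
    sides = [int(n.max() - n.min() + 1) for n in nz]
    if len(set(sides)) != 1:
        raise RuntimeError(f"anisotropic gradient support {sides}")
    return sides[0]


# -- checkpoints ------------------------------------------------------


def save_checkpoint(path, model: CAE) -> None:
    """Single-file checkpoint: architecture spec + input grid + weights."""
    meta = json.dumps(
        {
            "spec": dataclasses.asdict(model.spec),
            "input_shape": list(model.input_shape),
            "seed": model.seed,
        }
    )
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez_compressed(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **weights)


def load_checkpoint(path) -> CAE:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        n = len([k for k in f.files if k.startswith("w")])
        weights = [f[f"w{i}"] for i in range(n)]
    model = CAE(ArchitectureSpec(**meta["spec"]), tuple(meta["input_shape"]),
                seed=meta["seed"])
    model.set_weights(weights)
    return model
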