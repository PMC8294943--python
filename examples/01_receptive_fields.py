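"""Receptive-field and latent-geometry report for the 16 reference models.

Builds nothing heavy: pure layer arithmetic.  For each block/channel
configuration it prints the encoder depth, the effective receptive
field of one latent unit (the recursion result, which the autodiff
probe reproduces exactly), and the latent dimensionality on the
standard-space 121x145x121 grid — from millions of scalars for the
shallow/wide models down to hundreds for the deep/narrow ones.
"""

import braincae as bc
from braincae.architecture import encoder_layer_descriptors

SHAPE = (121, 145, 121)

print(f"{'blocks':>6} {'channels':>8} {'conv layers':>11} {'RF side':>7} "
      f"{'latent dims':>12} {'flattened':>10}")
for spec in bc.default_grid():
    ls = bc.latent_shape(spec, SHAPE)
    convs = sum(1 for d in encoder_layer_descriptors(spec) if d.kind == "conv")
    print(f"{spec.n_blocks:>6} {spec.extraction_channels:>8} {convs:>11} "
          f"{bc.receptive_field(spec):>7} "
          f"{'x'.join(map(str, ls.dims)):>12} {ls.flattened_length:>10,}")

spec3 = bc.ArchitectureSpec(n_blocks=3, extraction_channels=16)
print("\n3-block model: encoder depth", 8, "convs; receptive field",
      bc.receptive_field(spec3), "voxels per axis.")
print("Gradient-support probe confirms:",
      bc.gradient_support_side(spec3), "voxels.")
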