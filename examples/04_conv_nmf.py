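"""Convolutional NMF: patch-wise parts coding over an image.

Applies a CNMF layer to a synthetic parts image.  At every output position
the receptive-field patch is encoded as a distribution over the layer's
components, so each output channel map shows where one additive part is
detected.
"""

import numpy as np

from nmfnet import ConvGeometry, LayerConfig, LayerWeights, cnmf_forward
from nmfnet.synthetic_data import make_parts_images

data = make_parts_images(n_classes=3, n_per_class=2, size=12, noise_sd=0.05, seed=4)
image = data.images[:1]  # (1, 1, 12, 12)

geom = ConvGeometry(kernel_h=3, kernel_w=3, in_channels=1, out_channels=8,
                    stride_h=2, stride_w=2, pad=1)
rng = np.random.default_rng(0)
weights = [LayerWeights(U=rng.normal(size=(geom.patch_size, geom.out_channels)))]

out = cnmf_forward(image, weights, geom, LayerConfig(n_iters=25))

print(f"input image:   {image.shape[1:]}, min {image.min():.3f} (non-negative)")
print(f"output map:    {out.shape[1:]}  (8 components x 6 x 6 positions)")
print(f"output min:    {out.min():.4f} (non-negative by construction)")
sums = out.sum(axis=1)
print(f"channel sums per position: {sums.min():.6f} .. {sums.max():.6f} (= 1)")
# each spatial position carries a distribution over 8 parts: the layer
# explains every local patch as an additive mixture of shared components
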