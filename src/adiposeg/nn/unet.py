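"""Encoder–decoder U-Net for 3-class fat segmentation, pure numpy.

The contracting path has three down-sampling steps with feature widths
16/32/64 by default (halved grids via 2×2 max-pooling), a dropout-
regularised bottleneck, and an expanding path of 2×2-stride transposed
convolutions with skip concatenations; a final 1×1 convolution and
per-pixel softmax produce the class probabilities.  'Same' padding keeps
the output at the input resolution.
"""

from __future__ import annotations

import numpy as np

from .layers import Adam, Conv2D, ConvTranspose2x2, Dropout, MaxPool2x2, ReLU, \
    softmax_cross_entropy

__all__ = ["UNet"]


class _Block:
    """convs_per_block × (Conv 3×3 → ReLU)."""

    def __init__(self, in_ch, out_ch, n_convs, rng):
        self.layers = []
        c = in_ch
        for _ in range(n_convs):
            self.layers += [Conv2D(c, out_ch, 3, rng), ReLU()]
            c = out_ch

    def forward(self, x, training):
        for ly in self.layers:
            x = ly.forward(x, training)
        return x

    def backward(self, dy):
        for ly in reversed(self.layers):
            dy = ly.backward(dy)
        return dy


class UNet:
    """The bare network: parameters, forward, backward, train step."""

    def __init__(self, input_size=(384, 384), encoder_channels=(16, 32, 64),
                 bottleneck_channels=128, n_classes=3, dropout_rate=0.5,
                 convs_per_block=2, seed=0):
        H, W = input_size
        depth = len(encoder_channels)
        if H % (2 ** depth) or W % (2 ** depth):
            raise ValueError(
                f"input size {input_size} must be divisible by 2^{depth} "
                f"(= {2 ** depth}) for {depth} down-sampling steps")
        if n_classes != 3:
            raise ValueError("the segmentation head is 3-class (bg/SAT/VAT)")
        self.input_size = (H, W)
        self.n_classes = n_classes
        self.encoder_channels = tuple(encoder_channels)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)

        self.enc_blocks, self.pools = [], []
        c = 1
        for ch in encoder_channels:
            self.enc_blocks.append(_Block(c, ch, convs_per_block, rng))
            self.pools.append(MaxPool2x2())
            c = ch
        self.bottleneck = _Block(c, bottleneck_channels, convs_per_block, rng)
        self.dropout = Dropout(dropout_rate, self._dropout_rng)
        self.upconvs, self.dec_blocks = [], []
        c = bottleneck_channels
        for ch in reversed(encoder_channels):
            self.upconvs.append(ConvTranspose2x2(c, ch, rng))
            self.dec_blocks.append(_Block(2 * ch, ch, convs_per_block, rng))
            c = ch
        self.head = Conv2D(c, n_classes, 1, rng)

    # ------------------------------------------------------------------

    def _all_layers(self):
        out = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            out += blk.layers + [pool]
        out += self.bottleneck.layers + [self.dropout]
        for up, blk in zip(self.upconvs, self.dec_blocks):
            out += [up] + blk.layers
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) in [0, 1] → logits (N, 3, H, W)."""
        skips = []
        h = np.asarray(x)
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        h = self.dropout.forward(h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, blk, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        # decoder stages in reverse: the last stage consumed the shallowest skip
        dskips = []  # gradients w.r.t. skips, shallowest first
        for up, blk, ch in zip(reversed(self.upconvs), reversed(self.dec_blocks),
                               self._skip_channels):
            dy = blk.backward(dy)
            dskips.append(dy[:, :ch])
            dy = up.backward(dy[:, ch:])
        dy = self.dropout.backward(dy)
        dy = self.bottleneck.backward(dy)
        for blk, pool, dskip in zip(reversed(self.enc_blocks),
                                    reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = blk.backward(dy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self._all_layers(), lr=lr)

    def train_step(self, optimizer: Adam, xb: np.ndarray, yb: np.ndarray,
                   class_weights=None) -> float:
        optimizer.zero_grad()
        logits = self.forward(xb, training=True)
        loss, _, grad = softmax_cross_entropy(logits, yb, class_weights)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss ({loss}); last batch stats: "
                f"x∈[{xb.min():.3g},{xb.max():.3g}]")
        self.backward(grad)
        optimizer.step()
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size=16,
                      class_weights=None) -> float:
        losses, counts = [], []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            loss, _, _ = softmax_cross_entropy(logits, y[i:i + batch_size],
                                               class_weights)
            losses.append(loss)
            counts.append(len(x[i:i + batch_size]))
        return float(np.average(losses, weights=counts))

    # ------------------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for ly in self._all_layers():
            for k in sorted(ly.params):
                out.append(ly.params[k].copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for ly in self._all_layers():
            for k in sorted(ly.params):
                w = next(it)
                if w.shape != ly.params[k].shape:
                    raise ValueError("weight shape mismatch")
                ly.params[k] = w.astype(ly.params[k].dtype).copy()
                ly.grads[k] = np.zeros_like(ly.params[k])
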