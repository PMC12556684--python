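"""Configurable 3D U-Net assembled from the numpy layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv3d, ConvBlock, MaxPool2, Upsample2

__all__ = ["NetConfig", "UNet3D", "softmax"]


@dataclass
class NetConfig:
    """Network topology and patch geometry.

    The full-scale preset is 6 stages with
    ``(32, 64, 128, 256, 320, 320)`` features, kernel 3, patch
    ``(192, 192, 160)``, batch 2; desk-scale runs use 3 stages and 24^3
    patches.
    """

    n_stages: int = 3
    features_per_stage: tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    leaky_slope: float = 0.01
    patch_size: tuple[int, int, int] = (24, 24, 24)
    batch_size: int = 2
    n_classes: int = 2
    in_channels: int = 1
    #: auxiliary loss heads on the coarser decoder outputs;
    #: speeds convergence, costs almost nothing at these sizes
    deep_supervision: bool = False
    #: feed normalized world-coordinate features (linear + quadratic, 9
    #: channels) straight into the classification head, bypassing the
    #: normalized conv trunk.  The full-scale configuration's patches cover
    #: the whole brain, so patch position is implicit there; small
    #: desk-scale patches lose it, and instance normalization inside the
    #: trunk would strip it again (the per-patch mean of a coordinate ramp
    #: *is* the position) — hence the direct skip to the head.
    coord_channels: bool = False

    N_COORD_FEATURES = 9

    def __post_init__(self) -> None:
        self.features_per_stage = tuple(int(f) for f in self.features_per_stage)
        self.patch_size = tuple(int(p) for p in np.broadcast_to(self.patch_size, (3,)))
        if len(self.features_per_stage) != self.n_stages:
            raise ValueError("features_per_stage length must equal n_stages")
        div = 2 ** (self.n_stages - 1)
        if any(p % div for p in self.patch_size):
            raise ValueError(f"patch size must be divisible by {div}")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")

    @property
    def total_in_channels(self) -> int:
        return self.in_channels + (self.N_COORD_FEATURES if self.coord_channels else 0)


def full_scale_preset(n_classes: int) -> NetConfig:
    """Full-scale configuration (GPU territory; not used in tests)."""
    return NetConfig(
        n_stages=6,
        features_per_stage=(32, 64, 128, 256, 320, 320),
        kernel=3,
        patch_size=(192, 192, 160),
        batch_size=2,
        n_classes=n_classes,
    )


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class UNet3D:
    """Encoder-decoder with skip connections; fully convolutional, so any
    input whose sides are divisible by ``2**(n_stages-1)`` is accepted."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.features_per_stage
        self.enc = []
        c_in = cfg.in_channels
        for i in range(cfg.n_stages):
            self.enc.append(ConvBlock(c_in, f[i], cfg.kernel, cfg.leaky_slope, rng))
            c_in = f[i]
        self.pools = [MaxPool2() for _ in range(cfg.n_stages - 1)]
        self.ups = []
        self.upconvs = []
        self.dec = []
        for i in range(cfg.n_stages - 2, -1, -1):
            self.ups.append(Upsample2())
            self.upconvs.append(Conv3d(f[i + 1], f[i], cfg.kernel, rng))
            self.dec.append(ConvBlock(2 * f[i], f[i], cfg.kernel, cfg.leaky_slope, rng))
        head_in = f[0] + (cfg.N_COORD_FEATURES if cfg.coord_channels else 0)
        self.head = Conv3d(head_in, cfg.n_classes, 1, rng)
        # aux head k sits on decoder stage k's output (all but the final,
        # full-resolution stage, which the main head covers)
        self.aux_heads = [Conv3d(f[i], cfg.n_classes, 1, rng)
                          for i in range(cfg.n_stages - 2, 0, -1)] \
            if cfg.deep_supervision else []
        self._skip_channels = list(f[:-1])

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods = []
        for blk in self.enc + self.dec:
            mods.extend(blk.layers)
        mods.extend(self.upconvs)
        mods.append(self.head)
        mods.extend(self.aux_heads)
        return mods

    def parameters(self) -> list[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.params.values())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.grads.values())
        return out

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p[...] = state[f"p{i}"]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, C_in, X, Y, Z) float32 -> (N, n_classes, X, Y, Z) logits.

        With ``coord_channels`` the trailing N_COORD_FEATURES input channels
        skip the trunk and enter the head directly."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        div = 2 ** (self.cfg.n_stages - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial sides must be divisible by {div}, got {x.shape[2:]}")
        self._coords = None
        if self.cfg.coord_channels:
            if x.shape[1] != self.cfg.total_in_channels:
                raise ValueError(
                    f"expected {self.cfg.total_in_channels} input channels, got {x.shape[1]}")
            self._coords = x[:, self.cfg.in_channels:]
            x = np.ascontiguousarray(x[:, : self.cfg.in_channels])
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x)
            if i < self.cfg.n_stages - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._concat_splits = []
        self._dec_outputs = []
        for j, (up, upconv, dec) in enumerate(zip(self.ups, self.upconvs, self.dec)):
            x = upconv.forward(up.forward(x))
            skip = skips[-(j + 1)]
            self._concat_splits.append(skip.shape[1])
            x = dec.forward(np.concatenate([skip, x], axis=1))
            self._dec_outputs.append(x)
        if self._coords is not None:
            x = np.concatenate([x, self._coords], axis=1)
        return self.head.forward(x)

    def forward_deep(self, x: np.ndarray) -> list[np.ndarray]:
        """Main logits plus aux logits; ``aux[k]`` sits on decoder stage k
        (k=0 is the coarsest, at 1/2^(n_stages-2-k) of full resolution)."""
        main = self.forward(x)
        aux = [h.forward(self._dec_outputs[k]) for k, h in enumerate(self.aux_heads)]
        return [main] + aux

    def backward(self, glogits: np.ndarray,
                 gaux: list[np.ndarray] | None = None) -> None:
        g = self.head.backward(glogits)
        if self._coords is not None:
            g = np.ascontiguousarray(g[:, : self.cfg.features_per_stage[0]])
        # decoder stage j consumed skips[S-2-j]; walk decoder in reverse so
        # gskips[m] ends up holding the gradient for skips[m]
        gskips: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            if gaux is not None and j < len(self.aux_heads):
                g = g + self.aux_heads[j].backward(gaux[j])
            g = self.dec[j].backward(g)
            c = self._concat_splits[j]
            gskip, g = g[:, :c], g[:, c:]
            gskips[self.cfg.n_stages - 2 - j] = np.ascontiguousarray(gskip)
            g = self.ups[j].backward(self.upconvs[j].backward(np.ascontiguousarray(g)))
        for i in range(self.cfg.n_stages - 1, -1, -1):
            if i < self.cfg.n_stages - 1:
                g = self.pools[i].backward(g)
                g = g + gskips[i]
            g = self.enc[i].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))
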