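"""Simplified encoder-decoder U-Net for epidermal segmentation.

The network is a compact variant of the classic U-Net: a configurable
number of encoder blocks (default two), a bottleneck, and a mirrored
decoder whose upsampling uses small 2x2 learned transposed-convolution
filters instead of the conventional 3x3, with skip connections
concatenating each encoder output onto the matching decoder level.
All convolutions use zero ("same") padding, so the output probability map
has exactly the spatial size of the input B-scan.

Channel widths start at ``base_filters`` and double per level
(16, 32, bottleneck 64 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "UNet",
    "build_model",
    "predict",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a model or run configuration violates its invariants."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    input_height, input_width : pixels; must be divisible by 2**encoder_depth
        so that pooling and upsampling round-trip to the original raster.
    encoder_depth : number of encoder blocks (and decoder blocks).
    base_filters : channels in the first encoder block; doubles per level.
    upsample_kernel : spatial size of the learned upsampling filter.
    padding_mode : only "same" is supported — the shape-preserving contract.
    output_channels : 1 (epidermis-probability map).
    """

    input_height: int = 256
    input_width: int = 256
    encoder_depth: int = 2
    base_filters: int = 16
    upsample_kernel: int = 2
    padding_mode: str = "same"
    output_channels: int = 1

    def validate(self) -> None:
        if self.encoder_depth < 1:
            raise ConfigError("encoder_depth must be >= 1")
        if self.base_filters < 1:
            raise ConfigError("base_filters must be >= 1")
        if self.padding_mode != "same":
            raise ConfigError("only padding_mode='same' is supported")
        if self.upsample_kernel != 2:
            raise ConfigError("upsample_kernel must be 2 (2x2 learned filters)")
        div = 2 ** self.encoder_depth
        for name, size in (("input_height", self.input_height),
                           ("input_width", self.input_width)):
            if size < div or size % div:
                raise ConfigError(
                    f"{name}={size} must be divisible by 2**encoder_depth={div} "
                    f"so downsample/upsample round-trips restore the raster; "
                    f"pad the input to a multiple of {div}")


class UNet:
    """A built network: layers, parameters, and forward/backward passes."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        d = config.encoder_depth
        f = config.base_filters

        def block(cin, cout):
            return [nn.Conv3x3(cin, cout, rng, dtype), nn.ReLU(),
                    nn.Conv3x3(cout, cout, rng, dtype), nn.ReLU()]

        self.enc_blocks = []
        self.pools = []
        cin = 1
        for i in range(d):
            cout = f * 2 ** i
            self.enc_blocks.append(block(cin, cout))
            self.pools.append(nn.MaxPool2x2())
            cin = cout
        self.bottleneck = block(cin, f * 2 ** d)
        cin = f * 2 ** d
        self.ups = []
        self.dec_blocks = []
        for i in reversed(range(d)):
            cout = f * 2 ** i
            self.ups.append(nn.ConvTranspose2x2(cin, cout, rng, dtype))
            self.dec_blocks.append(block(2 * cout, cout))  # concat doubles ch
            cin = cout
        self.head = nn.Conv1x1(cin, config.output_channels, rng, dtype)

    # -- parameter plumbing ------------------------------------------------

    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        for up, blk in zip(self.ups, self.dec_blocks):
            yield up
            yield from blk
        yield self.head

    @property
    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, ablate_skip: int | None = None) -> np.ndarray:
        """Forward pass to logits. x: (N, 1, H, W).

        ablate_skip zeroes the skip connection from encoder level i
        (diagnostic only, used to verify the connections are live).
        """
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        self._concat_ch = []
        for j, (up, blk) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h)
            skip = skips[len(skips) - 1 - j]
            if ablate_skip == len(skips) - 1 - j:
                skip = np.zeros_like(skip)
            self._concat_ch.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for layer in blk:
                h = layer.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dskips = {}
        for j in reversed(range(len(self.ups))):
            blk = self.dec_blocks[j]
            for layer in reversed(blk):
                dh = layer.backward(dh)
            nskip = self._concat_ch[j]
            dskips[len(self.enc_blocks) - 1 - j] = dh[:, :nskip]
            dh = self.ups[j].backward(np.ascontiguousarray(dh[:, nskip:]))
        for layer in reversed(self.bottleneck):
            dh = layer.backward(dh)
        for i in reversed(range(len(self.enc_blocks))):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            for layer in reversed(self.enc_blocks[i]):
                dh = layer.backward(dh)

    # -- state -------------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_state(self, state) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> UNet:
    """Build a trainable U-Net; raises ConfigError on invalid configs."""
    return UNet(config, seed=seed, dtype=dtype)


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel epidermis probabilities for one B-scan.

    image: (H, W) float array with intensities scaled to [0, 1]; H, W must
    equal the model's configured input size. Returns an (H, W) map in [0, 1].
    """
    cfg = model.config
    if image.ndim != 2 or image.shape != (cfg.input_height, cfg.input_width):
        raise ValueError(
            f"expected image of shape ({cfg.input_height}, {cfg.input_width}), "
            f"got {image.shape}")
    x = image.astype(model.dtype)[None, None]
    logits = model.forward(x)
    return nn.sigmoid(logits)[0, 0].astype(np.float64)


def count_parameters(model: UNet) -> int:
    """Total trainable parameter count."""
    return sum(p.size for p in model.params)


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Save weights as .npz with a sidecar JSON describing the config."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> UNet:
    """Rebuild a model from a checkpoint and its config sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = UNet(cfg)
    with np.load(path) as data:
        state = [data[f"p{i}"] for i in range(len(model.params))]
    model.set_state(state)
    return model
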