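"""Image/mask I/O, overlay rendering, configuration and provenance.

B-scans are read from 8- or 16-bit grayscale PNG/TIFF files and scaled to
floating intensities in [0, 1] by the dtype maximum; masks are binarized
at the midpoint of the 8-bit range (value >= 128 is foreground). Overlay
figures follow the usual agreement color code: manual-only red,
predicted-only blue, overlap purple, on top of the grayscale B-scan.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import yaml
from PIL import Image

from .model import ModelConfig
from .phantom import PhantomSpec
from .sweep import SweepConfig
from .trainer import TrainConfig

__all__ = ["load_image_mask_pair", "load_manifest_dataset", "render_overlay",
           "RunConfig", "load_config", "default_config_text",
           "write_provenance"]


def _load_gray(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise ValueError(f"{path}: color image; expected grayscale")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    return arr


def load_image_mask_pair(image_path: str | Path,
                         mask_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load one B-scan and its mask.

    Returns (image, mask): image float64 in [0, 1] scaled by the input
    dtype's maximum; mask uint8 {0, 1}, binarized at >= 128 for 8-bit
    input (>= half range in general).
    """
    image = _load_gray(image_path)
    mask = _load_gray(mask_path)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask "
                         f"{mask.shape}")
    if np.issubdtype(image.dtype, np.integer):
        scale = float(np.iinfo(image.dtype).max)
    else:
        scale = max(float(image.max()), 1.0)
    image = image.astype(np.float64) / scale
    if np.issubdtype(mask.dtype, np.integer):
        mid = (np.iinfo(mask.dtype).max + 1) // 2
    else:
        mid = 0.5
    mask = (mask >= mid).astype(np.uint8)
    return image, mask


def load_manifest_dataset(manifest_path: str | Path) -> list[tuple]:
    """Load every (image, mask) pair listed in a phantom manifest CSV."""
    import pandas as pd
    df = pd.read_csv(manifest_path)
    root = Path(manifest_path).parent
    pairs = []
    for _, row in df.iterrows():
        ip, mp = Path(row["image_path"]), Path(row["mask_path"])
        if not ip.is_absolute():
            ip, mp = root / ip, root / mp
        pairs.append(load_image_mask_pair(ip, mp))
    return pairs


def render_overlay(image: np.ndarray, manual_mask: np.ndarray,
                   predicted_mask: np.ndarray, out_path: str | Path) -> Path:
    """Write an RGB overlay: manual-only red, predicted-only blue,
    intersection purple, over the grayscale B-scan."""
    image = np.asarray(image, dtype=np.float64)
    manual = np.asarray(manual_mask) > 0
    pred = np.asarray(predicted_mask) > 0
    if not (image.shape == manual.shape == pred.shape):
        raise ValueError("image and masks must share one shape")
    base = np.clip(image / max(image.max(), 1e-9), 0, 1)
    rgb = np.stack([base] * 3, axis=-1)
    alpha = 0.55
    colors = {"manual": (1.0, 0.1, 0.1), "pred": (0.15, 0.25, 1.0),
              "both": (0.7, 0.1, 0.9)}
    regions = {"manual": manual & ~pred, "pred": pred & ~manual,
               "both": manual & pred}
    for key, region in regions.items():
        for ch, cval in enumerate(colors[key]):
            rgb[..., ch][region] = (1 - alpha) * rgb[..., ch][region] + alpha * cval
    out_path = Path(out_path)
    Image.fromarray(np.rint(rgb * 255).astype(np.uint8), "RGB").save(out_path)
    return out_path


@dataclasses.dataclass
class RunConfig:
    """Merged configuration for a full pipeline run."""

    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    sweep: SweepConfig = dataclasses.field(default_factory=SweepConfig)

    def validate(self) -> None:
        self.phantom.validate()
        self.model.validate()
        self.train.validate()


_SECTIONS = {"phantom": PhantomSpec, "model": ModelConfig,
             "train": TrainConfig, "sweep": SweepConfig}


def _coerce(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v
               for k, v in data.items()}
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config with optional phantom/model/train/sweep sections;
    every section is validated before any compute starts."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {name: _coerce(cls, raw.get(name, {}) or {})
              for name, cls in _SECTIONS.items()}
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def default_config_text() -> str:
    """All defaults, as YAML — makes every implementer default visible."""
    cfg = RunConfig()
    data = {name: dataclasses.asdict(getattr(cfg, name))
            for name in _SECTIONS}
    return yaml.safe_dump(data, sort_keys=False)


def write_provenance(out_dir: str | Path, record: dict) -> Path:
    """Write a JSON provenance record (config, seeds, versions, hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = dict(record)
    record.setdefault("python", platform.python_version())
    record.setdefault("numpy", np.__version__)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path


def file_sha1(path: str | Path) -> str:
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()
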