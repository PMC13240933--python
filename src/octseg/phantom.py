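"""Synthetic OCT skin phantoms with known epidermis masks.

Clinical OCT B-scans of actinic keratosis are not publicly deposited, so
every downstream stage (training, evaluation, thickness analysis) is
exercised on synthetic phantoms that emulate the salient structure of a
dermatological B-scan:

* an air region of near-zero signal above the skin,
* a bright entrance-surface line where the beam first hits tissue,
* an epidermis band of spatially varying thickness, bounded below by a
  smooth dermal-epidermal junction (DEJ),
* a dermis with stronger scattering that attenuates exponentially with
  depth,
* fully developed multiplicative speckle (unit-mean gamma multiplier),
* optional hyperkeratosis (a localized bright, thickened surface region),
* optional vertical hair-shadow artifacts darkening narrow column spans.

Boundaries (surface and DEJ) are sums of low-frequency sinusoids with
random phases, so they are smooth, band-limited and exactly reproducible
from the seed. The generator records the per-column epidermis thickness it
drew, which downstream thickness measurements must reproduce exactly.

Default geometry follows a 464x1356-pixel B-scan (6 mm lateral field at
4.4 um fast-axis sampling, 5.5 um axial pixel pitch); ``quick_spec`` gives
a 256x256 preset with the same morphology for fast experiments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom",
           "generate_dataset", "quick_spec", "PhantomSpecError"]


class PhantomSpecError(ValueError):
    """A phantom specification violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic B-scan; all spatial units are pixels."""

    height: int = 464
    width: int = 1356
    surface_depth_mean: float = 70.0
    surface_roughness_amplitude: float = 10.0
    epidermis_thickness_mean: float = 45.0
    epidermis_thickness_amplitude: float = 15.0
    speckle_contrast: float = 0.3
    attenuation_rate: float = 0.004
    hyperkeratosis_probability: float = 0.3
    hyperkeratosis_extra_thickness: float = 25.0
    shadow_count_mean: float = 1.5
    axial_pitch_um: float = 5.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("height", "width", "surface_depth_mean",
                     "epidermis_thickness_mean", "axial_pitch_um"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be strictly positive")
        for name in ("surface_roughness_amplitude",
                     "epidermis_thickness_amplitude", "attenuation_rate",
                     "hyperkeratosis_extra_thickness", "shadow_count_mean"):
            if getattr(self, name) < 0:
                raise PhantomSpecError(f"{name} must be non-negative")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise PhantomSpecError(
                "speckle_contrast must lie in [0, 1] (0 disables speckle)")
        if not 0.0 <= self.hyperkeratosis_probability <= 1.0:
            raise PhantomSpecError(
                "hyperkeratosis_probability must lie in [0, 1]")
        budget = (self.surface_depth_mean + self.surface_roughness_amplitude
                  + self.epidermis_thickness_mean
                  + self.epidermis_thickness_amplitude
                  + self.hyperkeratosis_extra_thickness)
        if budget >= self.height:
            raise PhantomSpecError(
                "surface_depth_mean + amplitudes + epidermis_thickness_mean "
                f"must leave dermis below them (budget {budget} >= height "
                f"{self.height})")


def quick_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """256x256 preset scaled from the native geometry, for fast runs."""
    base = PhantomSpec(height=256, width=256, surface_depth_mean=40.0,
                       surface_roughness_amplitude=6.0,
                       epidermis_thickness_mean=25.0,
                       epidermis_thickness_amplitude=8.0,
                       hyperkeratosis_extra_thickness=14.0,
                       seed=seed)
    return replace(base, **overrides) if overrides else base


@dataclass
class PhantomPair:
    """One generated B-scan with its ground truth."""

    image: np.ndarray                    # (H, W) float32 in [0, 1]
    mask: np.ndarray                     # (H, W) uint8 in {0, 1}
    true_thickness_profile: np.ndarray   # (W,) int per-column band thickness
    spec: PhantomSpec = field(repr=False, default=None)


# layer reflectivities in the noise-free limit
_AIR = 0.03
_SURFACE = 0.95
_EPIDERMIS = 0.45
_DERMIS = 0.75
_SURFACE_LINE_PX = 2


def _smooth_profile(rng: np.random.Generator, width: int,
                    n_components: int = 4) -> np.ndarray:
    """Band-limited random profile normalized to peak amplitude 1."""
    cols = np.arange(width)
    out = np.zeros(width)
    for k in range(1, n_components + 1):
        phase = rng.uniform(0, 2 * np.pi)
        weight = rng.uniform(0.3, 1.0) / k
        out += weight * np.sin(2 * np.pi * k * cols / width + phase)
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Generate one phantom B-scan. Deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    surface = spec.surface_depth_mean + \
        spec.surface_roughness_amplitude * _smooth_profile(rng, w)
    thickness = spec.epidermis_thickness_mean + \
        spec.epidermis_thickness_amplitude * _smooth_profile(rng, w)

    # hyperkeratosis: raised-cosine thickening + brighter surface patch
    hk_boost = np.zeros(w)
    has_hk = rng.random() < spec.hyperkeratosis_probability
    if has_hk and spec.hyperkeratosis_extra_thickness > 0:
        center = rng.integers(w // 4, 3 * w // 4)
        half = max(4, int(rng.integers(w // 12, w // 5)))
        cols = np.arange(max(0, center - half), min(w, center + half))
        hk_boost[cols] = spec.hyperkeratosis_extra_thickness * 0.5 * (
            1 + np.cos(np.pi * (cols - center) / half))
        thickness = thickness + hk_boost

    surf_rows = np.clip(np.rint(surface).astype(int), 0, h - 2)
    thick_px = np.clip(np.rint(thickness).astype(int), 1, None)
    dej_rows = np.minimum(surf_rows + thick_px, h - 1)
    thick_px = dej_rows - surf_rows

    rows = np.arange(h)[:, None]
    image = np.full((h, w), _AIR, dtype=np.float64)
    in_epi = (rows >= surf_rows[None, :]) & (rows < dej_rows[None, :])
    image[in_epi] = _EPIDERMIS
    in_derm = rows >= dej_rows[None, :]
    depth_in_derm = (rows - dej_rows[None, :]).clip(min=0)
    dermis_val = _DERMIS * np.exp(-spec.attenuation_rate * depth_in_derm)
    image[in_derm] = dermis_val[in_derm]
    # bright entrance line occupies the top pixels of the band
    in_surf = (rows >= surf_rows[None, :]) & \
              (rows < (surf_rows + _SURFACE_LINE_PX)[None, :]) & in_epi
    surf_gain = np.ones(w)
    if has_hk:
        surf_gain += 0.05 * (hk_boost / max(spec.hyperkeratosis_extra_thickness, 1e-9))
    image[in_surf] = np.minimum(_SURFACE * np.broadcast_to(surf_gain, (h, w))[in_surf], 1.0)

    # vertical hair shadows darken everything below the surface
    n_shadows = rng.poisson(spec.shadow_count_mean) if spec.shadow_count_mean > 0 else 0
    for _ in range(n_shadows):
        c0 = int(rng.integers(0, max(1, w - 3)))
        width_cols = int(rng.integers(3, 11))
        factor = float(rng.uniform(0.1, 0.3))
        cols = slice(c0, min(w, c0 + width_cols))
        below = rows >= surf_rows[None, cols]
        block = image[:, cols]
        block[below] *= factor
        image[:, cols] = block

    if spec.speckle_contrast > 0:
        k = 1.0 / spec.speckle_contrast ** 2
        mult = rng.gamma(shape=k, scale=1.0 / k, size=(h, w))
        image = image * mult

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    mask = in_epi.astype(np.uint8)
    return PhantomPair(image=image, mask=mask,
                       true_thickness_profile=thick_px.astype(np.int64),
                       spec=spec)


def _write_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def generate_dataset(n: int, spec: PhantomSpec, seed: int,
                     out_dir: str | Path) -> list[dict]:
    """Write ``n`` phantom image/mask PNG pairs plus a CSV manifest.

    Item seeds are drawn once from ``seed`` so the whole dataset is
    reproducible from (n, spec, seed). Images are quantized to 8-bit
    grayscale; masks use {0, 255}. Returns the manifest rows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable") from exc

    item_seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)
    rows = []
    for i in range(n):
        item_seed = int(item_seeds[i])
        pair = generate_phantom(replace(spec, seed=item_seed))
        img_path = out_dir / f"phantom_{i:04d}_image.png"
        mask_path = out_dir / f"phantom_{i:04d}_mask.png"
        _write_png(np.rint(pair.image * 255).astype(np.uint8), img_path)
        _write_png(pair.mask * 255, mask_path)
        rows.append({
            "image_path": str(img_path),
            "mask_path": str(mask_path),
            "item_seed": item_seed,
            "mean_thickness_px": float(pair.true_thickness_profile.mean()),
        })
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return rows
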