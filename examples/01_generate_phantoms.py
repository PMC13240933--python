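"""Generate a small synthetic OCT dataset and inspect its ground truth.

Builds six speckled skin phantoms at the 256x256 quick preset, writes
them as PNG image/mask pairs with a CSV manifest, and prints the mean
epidermal thickness the generator drew for each — the ground truth that
segmentation and thickness measurements are judged against.
"""

from pathlib import Path

import octseg as o

out = Path("scratch/example_phantoms")
rows = o.generate_dataset(6, o.quick_spec(), seed=42, out_dir=out)

print(f"wrote {len(rows)} image/mask pairs to {out}/")
for row in rows:
    print(f"  {Path(row['image_path']).name}: "
          f"mean thickness {row['mean_thickness_px']:.1f} px "
          f"({row['mean_thickness_px'] * 5.5:.0f} um at 5.5 um/px)")
# Thickness varies around the preset's 25-px mean; each phantom's mask
# reproduces exactly the per-column profile the generator drew.
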