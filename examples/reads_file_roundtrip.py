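"""Write, reload and filter a reads file.

Simulates a small study, writes the long-format reads table (one row per
image x arm x reader x round x finding), reloads it, and applies the quality
exclusion rule: an image is dropped when a majority of its arm-1 panel flag
it uninterpretable.
"""

import tempfile
from pathlib import Path

from panelgt import SimulationConfig, apply_exclusions, load_reads, simulate_study, write_reads

config = SimulationConfig(n_images=200, seed=42, image_poor_quality_rate=0.03)
labelset, _, _ = simulate_study(config)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "reads.csv"
    write_reads(labelset, path)
    reloaded = load_reads(path)
    assert reloaded == labelset
    print(f"wrote and reloaded {len(reloaded.reads)} reads for "
          f"{len(reloaded.images())} images (round-trip exact)")

filtered = apply_exclusions(reloaded, quality_arm=1)
print(f"quality exclusions: {len(filtered.excluded_images)} image(s) removed "
      f"-> {len(filtered.images())} analyzable images")
for img, reason in sorted(filtered.excluded_images.items()):
    print(f"  {img}: {reason}")
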