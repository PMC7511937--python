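"""Generate a synthetic thermal cohort and inspect its manifest.

Ten mice (5 control, 5 on the disease signature), imaged weekly from
week 2 to week 5. Each image is a 64×64 temperature map in °C written
as a headerless CSV matrix, listed in manifest.csv.
"""

import tempfile
from pathlib import Path

from thermoliver import SyntheticCohortSpec, generate_cohort, read_map

out = Path(tempfile.mkdtemp(prefix="thermoliver_cohort_"))
spec = SyntheticCohortSpec(seed=7)
manifest = generate_cohort(spec, out)

print(f"wrote {len(manifest)} maps to {out}")
print(manifest.head(6).to_string(index=False))

T = read_map(out / manifest["image_path"].iloc[0])
print(f"\nfirst map: shape {T.shape}, range {T.min():.2f}..{T.max():.2f} °C")
# The diseased group carries a larger, shorter-range heterogeneity field,
# so its maps are visibly "patchier" at the same mean temperature.
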