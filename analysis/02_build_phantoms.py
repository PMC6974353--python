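"""Build the desk-scale ONL phantom: ~40 packed rod nuclei painted with the
two chromatin architectures (inverted vs multi-chromocenter) on identical
geometry.

Volumes (tens of MB) go to scratch/phantoms/; a small per-nucleus summary
table goes to results/phantom_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from onloptics import io as onlio
from onloptics.phantom import (
    ChromatinParams,
    assign_chromocenters,
    assign_inverted,
    generate_packed_nuclei,
    smooth_and_embed,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "phantoms"
SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 11
params = ChromatinParams()
labels = generate_packed_nuclei(
    40, (128, 256, 256), voxel_size_um=0.166, radius_um=(2.8, 0.3), seed=SEED
)
inv_raw = assign_inverted(labels, params)
cc_raw = assign_chromocenters(labels, params, seed=SEED + 1)
inv = smooth_and_embed(inv_raw, params)
cc = smooth_and_embed(cc_raw, params)

onlio.write_labeled_volume(labels, SCRATCH / "labels.tif")
onlio.write_ri_volume(inv, SCRATCH / "ri_inverted.tif")
onlio.write_ri_volume(cc, SCRATCH / "ri_chromocenter.tif")

rows = []
for k in range(1, labels.n_nuclei + 1):
    mask = labels.labels == k
    rows.append(
        dict(
            nucleus=k,
            voxels=int(mask.sum()),
            volume_um3=float(mask.sum()) * labels.voxel_size_um**3,
            n_chromocenters=cc_raw.chromocenter_counts.get(k, 0),
            mean_ri_inverted=float(inv_raw.ri[mask].mean()),
            mean_ri_chromocenter=float(cc_raw.ri[mask].mean()),
        )
    )
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "phantom_summary.csv", index=False, float_format="%.8g")

print(f"packed {labels.n_nuclei} nuclei, volume fraction {labels.volume_fraction():.3f}")
print(f"chromocenter counts drawn: {sorted(set(cc_raw.chromocenter_counts.values()))}")
print("paired-model check: per-nucleus mean RI identical to "
      f"{np.abs(df.mean_ri_inverted - df.mean_ri_chromocenter).max():.2e} "
      "(same optical material, different arrangement)")
print(f"volumes in {SCRATCH}, summary in {RESULTS / 'phantom_summary.csv'}")
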