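"""Clean and label a raw bioactivity table.

Generates a small synthetic assay CSV with deliberately planted defects
(missing IC50 values, duplicate rows, salt forms, intermediate-potency
compounds), then runs the preparation pipeline: salt stripping, missing-value
removal, deduplication, IC50 -> class labeling (active <= 1000 nM, inactive
>= 10000 nM), pIC50 conversion, and the 80/20 train/test split.
"""

import tempfile
import os

from mathqsar import FixtureSpec, generate_bioactivity_csv, prepare

tmp = tempfile.mkdtemp()
raw = os.path.join(tmp, "raw.csv")
spec = FixtureSpec(
    n_molecules=40, seed=11, n_missing=3, n_duplicates=2, n_salts=2, n_intermediates=3
)
df = generate_bioactivity_csv(spec, raw)
print(f"raw table: {len(df)} rows (40 clean + 3 missing-IC50 + 2 duplicates "
      "+ 2 salts + 3 intermediates)")

prepared = prepare(raw, os.path.join(tmp, "prepared.csv"), test_fraction=0.2, seed=42)
print(f"prepared table: {len(prepared)} unique compounds")
print(prepared["label"].value_counts().to_string())
print(prepared["split"].value_counts().to_string())
print("Intermediate-potency compounds are kept in the table but excluded "
      "from the train/test split ('excluded').")
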