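"""Feature engineering: truncate codes, prune, and screen by entropy gain.

Raw ICD9-CM and ATC codes collapse to their category level, duplicate
diagnoses collapse to binary presence, all-zero columns are discarded, and
the k most class-informative features survive an entropy-gain ranking.
"""

import tempfile
from pathlib import Path

from sctree import (default_paper_like_spec, generate_cohort, load_cohort,
                    prune_zero_count_features, select_top_k_features,
                    truncate_atc_code, truncate_icd9_code)
from sctree.cohort import feature_gains

print("truncation:", truncate_icd9_code("250.01"), truncate_atc_code("A10BA02"))

# round-trip the cohort through the wide CSV layout, as a file-based run would
cohort = generate_cohort(default_paper_like_spec(), seed=0)
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "cohort.csv"
    cohort.to_csv(path)
    loaded = load_cohort(path)

pruned = prune_zero_count_features(loaded)
screened = select_top_k_features(pruned, k=8)
gains = feature_gains(pruned).sort_values(ascending=False)

print(f"{loaded.schema.n} features -> {pruned.schema.n} after pruning "
      f"-> {screened.schema.n} after gain screening")
print("top gains (bits):")
print(gains.head(8).round(3).to_string())
# The diabetes code '250' and the antidiabetic drug class 'A10BA' carry the
# most information about the health status, as expected clinically.
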