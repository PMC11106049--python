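"""Compare LC/MS metabolite profiles across cultivation conditions.

Synthetic peak tables emulate a five-condition OSMAC experiment (a control
and four metal-salt additions) where the iron condition both gains
condition-specific features and shows a ~5x global intensity boost.  The
script applies the 1% noise rule, summarizes polarity zones, builds the
log relative-area matrix behind a heat map, and runs PCA and k-means.
"""

import numpy as np

from osmactools.lcms_profiles import (
    ZoneConfig,
    build_profile_matrix,
    filter_noise,
    kmeans_profiles,
    pca_profiles,
    zone_summary,
)
from osmactools.synthetic_data import ConditionSpec, gen_peak_tables

tables = gen_peak_tables(ConditionSpec(seed=17))

print("total ion areas (the iron condition is boosted ~5x):")
for t in tables:
    print(f"  {t.sample_id:<5} {t.total_area:>12.0f}  ({len(t.peaks)} peaks)")

# LC/UV-style bookkeeping: drop <1% peaks, then count peaks per polarity zone
zones = ZoneConfig(boundaries=(9.0, 21.0, 39.0))
print("\npeaks per polarity zone after the 1% noise filter:")
for t in tables:
    df = zone_summary(filter_noise(t), zones)
    counts = " ".join(f"{z}={int(n)}" for z, n in df["n_peaks"].items())
    print(f"  {t.sample_id:<5} {counts}")

# LC/MS profile matrix on all features (relative areas, log10 for display)
pm = build_profile_matrix(tables)
heat = pm.log10()
print(f"\nlog10 relative-area matrix: {heat.shape[0]} samples x "
      f"{heat.shape[1]} features; floor for absent features = -6")

scores, evr = pca_profiles(pm, n_components=2)
print(f"\nPCA: PC1+PC2 explain {100 * evr.sum():.2f}% of the variance")
print(scores.round(2))

labels = kmeans_profiles(pm, k=2, seed=17)
groups = {int(lbl): [s for s, c in zip(pm.samples, labels) if c == lbl]
          for lbl in set(labels)}
print("\nk-means (k=2) groups:", groups)
print("\nThe boosted, feature-distinct condition separates from the other "
      "four along PC1 and forms its own cluster, mirroring how an outlier "
      "extract stands apart in an OSMAC comparison.")
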