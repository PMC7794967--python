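"""Bivariate spatial association between urbanization and ecosystem health.

Computes the per-cell urbanization composite (population, GDP per capita,
construction-land proportion), then the global bivariate Moran's I against
the health index with a 999-run Monte-Carlo test, and the local (LISA)
cluster map for the final epoch.
"""

import numpy as np

from karsthealth import coupled_preset, generate_scene, run_assessment
from karsthealth.spatial import LISA_CLASSES

scene = generate_scene(coupled_preset(seed=42))
result = run_assessment(scene, n_perm=999, alpha=0.05, seed=7)

print(result.moran_table().round(3).to_string(index=False))
lisa = result.lisa[-1]
counts = np.bincount(lisa.cluster, minlength=5)
print("\nLISA clusters, final epoch:")
for name, c in zip(LISA_CLASSES, counts):
    print(f"  {name:16s} {c:4d} cells")
# Negative Moran's I with p at the 0.001 floor says high-urbanization cells
# sit next to low-health neighbourhoods; High-Low cells mark the urban
# cores where that coupling is locally significant.
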