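"""Quantify trade-offs and synergies between services.

Service rasters are aggregated to square sample units; the Spearman
matrix gives the overall (sign-based) relationships, and geographically
weighted regression maps where a pair is locally synergistic (positive
slope) or a trade-off (negative slope).
"""

import numpy as np

from luces.pipeline import compute_es_stack
from luces.synth import SyntheticConfig, generate_landscape
from luces.tradeoff import (
    CATEGORY_CODES, aggregate_grid, classify_relationship, gwr_fit, spearman_matrix,
)

cfg = SyntheticConfig(shape=(120, 120), seed=13)
scene = generate_landscape(cfg)
stack = compute_es_stack(scene["lulc_t1"], scene["drivers"])

table = aggregate_grid(stack, unit_size_m=300.0)   # 10x10-cell units
m = spearman_matrix(table)
print(f"Spearman matrix over {m.n} sample units:")
print(m.rho.round(3).to_string(), "\n")
print("sign classification:")
print(m.classification.to_string(), "\n")

g = gwr_fit(table["SR"].to_numpy(), table["HQ"].to_numpy(),
            table[["U", "V"]].to_numpy(), bandwidth="auto")
codes = classify_relationship(g)
print(f"GWR HQ->SR: bandwidth {g.bandwidth:.0f} neighbours, local R2 {g.r2:.3f}")
for code, name in CATEGORY_CODES.items():
    print(f"  {name:>16}: {(codes == code).mean():.1%} of units")
# A positive local slope means HQ and SR rise together there (synergy);
# the strong/weak split is at the median absolute slope.
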