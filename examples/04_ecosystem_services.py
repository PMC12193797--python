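"""Compute the four ecosystem services on a synthetic landscape.

Water yield (mm) from the water balance, carbon stock (t/hm^2) by
land-cover lookup, habitat quality (0-1) with cropland/built-up threat
degradation, and RUSLE soil retention (t/hm^2).
"""

from luces.pipeline import compute_es_stack
from luces.synth import SyntheticConfig, generate_landscape

cfg = SyntheticConfig(shape=(100, 100), seed=9)
scene = generate_landscape(cfg)
stack = compute_es_stack(scene["lulc_t1"], scene["drivers"])

units = {"WY": "mm", "CS": "t/hm2", "HQ": "-", "SR": "t/hm2"}
for name, grid in stack.items():
    v = grid.values[grid.mask()]
    print(f"{name}: mean {v.mean():9.3f} {units[name]:>6}  "
          f"range [{v.min():.3f}, {v.max():.3f}]")

# HQ is bounded in [0,1] by construction; WY/CS/SR are non-negative.
# Carbon and habitat parameters here are synthetic placeholder tables
# (see luces.es); swap in calibrated biophysical tables for real studies.
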