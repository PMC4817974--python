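"""Classify diagonal contacts (RaL / LaR / Cross) and tabulate them.

Generates tubes with known junction configurations, calls each ring pair
from the mesh geometry alone, and prints a per-ring contact table in the
standard category layout (RaL+RaL ... C+C, plus n).
"""

from gutmorph import (
    PackingSpec,
    classify_pair,
    generate_tube,
    hatching_configs,
    tabulate_calls,
)

spec = PackingSpec(cells_per_ring={1: 4})
frame = generate_tube(spec, configs=hatching_configs(spec))

print("per-ring calls on the hatching fixture:")
calls = []
for ring in range(2, 10):
    call = classify_pair(None, frame, ring)
    calls.append(call)
    print(f"  int{ring} vs int{ring - 1}: {call.category:8s} "
          f"(areas: {', '.join(f'{a:.1f}' for a in call.areas)} um^2)")

print("\ncontact table (percent per category):")
print(tabulate_calls(calls).table.to_string())
# The posterior rings are purely hexagonal (RaL+RaL: the R cell touches
# two faces of the anterior L cell) while int2 makes the invariant equal
# RaL and LaR contacts with the 4-cell int1 ring (2R-1LD and 2L-1RV).
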