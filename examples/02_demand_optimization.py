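"""Solve the 2030 land-use demand programs.

Two linear programs over per-class areas x1..x6 (ha) and population P:
the ecological-protection program maximises total ecological benefit,
the economic-development program maximises total economic benefit, both
under the same policy constraint set (fixed total area, food security,
planning brackets per class, ecological land >= 75% of the region).
"""

from luces.demand import demand_table, optimize_demand

print(demand_table().to_string(), "\n")

for sc in ("eps", "eds"):
    res = optimize_demand(sc)
    print(f"{sc.upper()}: objective {res.objective_value:,.1f} million CNY, "
          f"P = {res.areas.population:.0f} x10^4 persons")
    print(f"  binding: {', '.join(res.binding)}")

# Reading the table: under ecological protection, woodland/grassland/water
# sit at their upper planning bounds and built-up at its lower bound, with
# cropland absorbing the residual area; economic development reverses this,
# pushing built-up (the highest-value class) to its ceiling.
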