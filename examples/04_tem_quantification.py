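"""TEM read-outs: immunogold callose density and interface PD counts.

Immunogold labeling puts one gold particle per bound callose epitope; the
level is reported as particles per standard 0.025 µm² window delineated
around each plasmodesma. Manually counted PD per cell–cell interface are
aggregated per cell and can be drawn as an interface color map.
"""

from pdquant.quantify import gold_density, interface_table

# particle counts in the standard window, one PD each
for label, count in [("dormant bud", 9), ("after constant cold", 3)]:
    gd = gold_density(count)   # window defaults to 0.025 µm²
    print(f"{label}: {count} particles -> "
          f"{gd.density_per_um2:.0f} particles/µm²")

# manual PD counts at interfaces of a small cell patch
counts = [("c1", "c2", 4), ("c1", "c3", 2), ("c2", "c3", 5), ("c2", "c4", 1)]
interfaces, per_cell = interface_table(counts)
print("\nper interface:")
print(interfaces.to_string(index=False))
print("\nper cell (sum over touching interfaces):")
print(per_cell.to_string(index=False))
# c2 touches three interfaces (4 + 5 + 1 = 10 PD): the best-connected cell.
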