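"""Stage lookups and age binning on the packaged geologic timescale.

Loads the pinned chart, prints the midpoints used throughout the analysis
and shows the half-open binning convention for ages on a boundary.
"""

import echidrill as ed

table = ed.load_timescale()
print(f"chart {table.chart_version}: {len(table)} stages, "
      f"{table.names[0]} -> {table.names[-1]}")

for stage in ("Selandian", "Ypresian", "Lutetian", "Rupelian", "Chattian"):
    s = table.stage(stage)
    print(f"  {s.name:10s} {s.older_bound:6.2f}-{s.younger_bound:5.2f} Ma "
          f"midpoint {s.midpoint} Ma")

# ages exactly on a boundary belong to the younger stage
print("age 45.0 Ma ->", table.assign_bin(45.0).name)
print("age 47.8 Ma ->", table.assign_bin(47.8).name,
      "(boundary age goes to the younger stage)")
print("'Recent'    ->", table.assign_bin("Recent").name, "(alias resolution)")
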