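"""Whole-structure cell-count estimates and co-expression classes.

Scales section counts to whole-structure totals (counted cells divided by
the sampled percentage, times 100), compares marker abundances, classifies
transporter co-expression in somatostatin-positive cells, and summarizes a
rostro-caudal density profile.
"""

import vtasst as v
from vtasst.anatomy import CountRecord

# nine sections covering 40% of the structure
sst = v.scale_section_counts(counted=324, sampled_percent=40)
th = v.scale_section_counts(counted=2720, sampled_percent=40)
print(f"whole-structure estimates: Sst {sst.total_rounded} cells, "
      f"Th {th.total_rounded} cells")
print(f"Sst/Th ratio: {v.marker_ratio(sst.total, th.total):.1f}%")

calls = (
    [(1, 0, 0)] * 75 + [(0, 1, 0)] * 18 + [(1, 1, 0)] * 5
    + [(0, 0, 1)] * 1 + [(1, 1, 1)] * 1
)
_, props = v.classify_coexpression(calls)
print("co-expression classes (% of Sst+ cells):")
print(props[props > 0].to_string())

records = [
    CountRecord("s1", -2.9, {"Sst": 4, "Th": 95}),
    CountRecord("s2", -3.2, {"Sst": 9, "Th": 90}),
    CountRecord("s3", -3.5, {"Sst": 18, "Th": 70}),
    CountRecord("s4", -3.8, {"Sst": 31, "Th": 48}),
]
for marker in ("Sst", "Th"):
    series, trend = v.rostrocaudal_profile(records, marker)
    word = {1: "increases", -1: "decreases", 0: "is flat"}[trend]
    print(f"{marker} density {word} in the rostro-caudal direction: "
          f"{series.to_dict()}")
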