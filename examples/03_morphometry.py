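"""Per-file morphometric statistics for a generated neuron."""

from swcqc import GeneratorParams, generate_morphology, summarize
from swcqc.validation import STRUCTURE_NAMES

cell = generate_morphology(GeneratorParams(seed=11))
s = summarize(cell)

print(f"nodes: {s.node_count}")
for t, count in s.counts_by_type.items():
    print(f"  {STRUCTURE_NAMES.get(t, t)}: {count}")
print(f"tips: {s.tip_count}   branch points: {s.branch_point_count}"
      f"   max branch order: {s.max_branch_order}")
print(f"total cable length: {s.total_length:.1f} um")
print(f"longest root-to-tip path: {s.max_path_distance:.1f} um")
print(f"radius (um) min/mean/max: {s.radius_min:.3f}/{s.radius_mean:.3f}/{s.radius_max:.3f}")
(xmin, xmax), (ymin, ymax), (zmin, zmax) = s.bounding_box
print(f"extent (um): x {xmax - xmin:.0f}, y {ymax - ymin:.0f}, z {zmax - zmin:.0f}")

# Total cable length sums the Euclidean parent-child distances over the
# whole arbor; the path distance is the longest cumulative route from the
# soma root to any terminal tip.
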