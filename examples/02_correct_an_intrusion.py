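"""Repair a basal-typed intrusion inside an apical dendrite.

Generates a synthetic pyramidal cell, retypes a flanked 2-node run on the
apical trunk to basal (the classic mis-typing defect), then corrects it
with the basal+apic repair and shows every recorded change.
"""

from swcqc import (
    APICAL,
    BASAL,
    CorrectionConfig,
    DefectKind,
    DefectSpec,
    GeneratorParams,
    apply_corrections,
    generate_morphology,
    inject_defects,
)

cell = generate_morphology(GeneratorParams(seed=5))
corrupted, truth = inject_defects(cell, [DefectSpec(
    DefectKind.TYPE_SANDWICH, count=1, run_length=2,
    host_structure=APICAL, intruder_type=BASAL, seed=2)])
print("injected basal-typed nodes on the apical trunk:",
      [edit.node_id for edit in truth])

fixed, changes, unresolved = apply_corrections(
    corrupted, CorrectionConfig(fix_basal=True, fix_apic=True))
for c in changes:
    print(f"  node {c.node_id}: type {c.old_value} -> {c.new_value}  ({c.rule})")
print("unresolved:", len(unresolved))

restored = all(fixed.node(e.node_id).type_code == e.original_value for e in truth)
print("every intruded node restored to apical:", restored)
# The run is flanked by apical compartments on both sides, which is what
# makes the correction unambiguous; an unflanked subtree would be reported
# as UNCORRECTABLE_STRUCTURE instead of retyped.
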