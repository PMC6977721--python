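"""Rule-based repair of SWC defects.

Three families of correction, all recorded as :class:`ChangeRecord` entries:

* **Structure-type repair** (:func:`repair_structure`) enforces the membership
  rule that a compartment of a given structure may only connect to the same
  structure or to the soma.  It restores "sandwich" intrusions — a run of
  wrongly typed compartments embedded inside a path of a single host
  structure, flanked by correctly typed compartments — and retypes stray
  nodes whose surroundings unambiguously indicate the correct type.  Nodes
  whose neighbourhood is ambiguous are never touched; they are reported as
  UNCORRECTABLE_STRUCTURE instead.
* **Zero-radius repair** (:func:`repair_zero_radius`) replaces each zero
  radius with the parent's current radius, so chains of zeros inherit the
  nearest positive ancestor's value.
* **Reindexing** (:func:`reindex`) renumbers nodes 1..N with every parent
  preceding its children, preserving topology exactly.

The repair procedure runs two phases to a fixed point:

R2 (sandwich absorption): a maximal connected run of non-soma nodes typed
differently from ``structure``, attached below a ``structure`` parent and
whose every exit edge leads back into ``structure`` (at least one exit
required), is retyped to ``structure``.  The flanking requirement is what
distinguishes an intrusion from a genuine subtree of another structure,
which has no exit and is left alone.

R1 (membership): a node of type ``structure`` whose parent has some other
type P (not soma) is retyped to P provided the subsequent nodes are
correctly connected: it has no children, or all children already have type
P, or all children continue the same-type chain and that chain provably
terminates in type-P nodes.  Each pass retypes the head of such a chain, so
iterating to a fixed point absorbs whole runs.  Both phases only ever shrink
the set of violations, so the iteration terminates in at most N passes.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from .swc_io import Morphology, NodeRecord
from .validation import (
    SOMA,
    UNDEFINED,
    IssueCode,
    Severity,
    ValidationIssue,
    find_cycle_members,
)

__all__ = [
    "CorrectionConfig",
    "ChangeRecord",
    "repair_structure",
    "repair_zero_radius",
    "reindex",
    "apply_corrections",
]


@dataclass
class CorrectionConfig:
    """Which corrections to apply; all default off (validation-only run)."""

    fix_soma: bool = False
    fix_axon: bool = False
    fix_basal: bool = False
    fix_apic: bool = False
    fix_radius: bool = False
    reindex: bool = False

    @property
    def any_enabled(self) -> bool:
        return any((self.fix_soma, self.fix_axon, self.fix_basal,
                    self.fix_apic, self.fix_radius, self.reindex))


@dataclass
class ChangeRecord:
    """One applied correction: which field of which node changed, and why."""

    file: str
    node_id: int
    field: str  # type_code | radius | id | parent_id
    old_value: object
    new_value: object
    rule: str  # SANDWICH_RETYPE | MEMBERSHIP_RETYPE | RADIUS_FROM_PARENT | REINDEX

    def __post_init__(self) -> None:
        if self.old_value == self.new_value:
            raise ValueError("ChangeRecord with no actual change")


def _require_acyclic(morph: Morphology) -> None:
    if find_cycle_members(morph):
        raise ValueError("morphology contains parent-chain cycles; validate and reject first")


def _retype(morph: Morphology, node: NodeRecord, new_type: int, rule: str,
            changes: list[ChangeRecord]) -> None:
    changes.append(ChangeRecord(morph.source_path, node.id, "type_code",
                                node.type_code, new_type, rule))
    node.type_code = new_type


def _intruder_components(morph: Morphology, structure: int):
    """Maximal connected components of non-``structure``, non-soma nodes whose
    attachment parent has type ``structure``.

    Yields (members, flanked): ``flanked`` is True when every path out of the
    component ends at a ``structure``-typed child — i.e. the component is a
    sandwich intrusion.  A leaf inside the component (no children) or an exit
    to soma means the component dangles and is not flanked below.
    """
    seen: set[int] = set()
    for n in morph.nodes:
        if n.id in seen or n.type_code in (structure, SOMA):
            continue
        parent = morph.parent_of(n)
        if parent is None or parent.type_code != structure:
            continue
        members: list[NodeRecord] = []
        flanked = True
        stack = [n]
        seen.add(n.id)
        while stack:
            cur = stack.pop()
            members.append(cur)
            kids = morph.child_nodes(cur)
            if not kids:
                flanked = False
            for child in kids:
                if child.type_code == structure:
                    continue  # a flanking exit
                if child.type_code == SOMA:
                    flanked = False
                elif child.id not in seen:
                    seen.add(child.id)
                    stack.append(child)
        yield members, flanked


def _chain_terminates_in(morph: Morphology, start: NodeRecord, structure: int, target: int) -> bool:
    """True if every path from *start* through same-``structure`` nodes ends at
    children all of type *target* (i.e. the run is flanked below)."""
    stack = [start]
    while stack:
        cur = stack.pop()
        kids = morph.child_nodes(cur)
        if not kids:
            return False  # dangles: cannot confirm flanking
        if all(k.type_code == target for k in kids):
            continue
        if all(k.type_code == structure for k in kids):
            stack.extend(kids)
        else:
            return False
    return True


def repair_structure(morph: Morphology, structure: int) -> tuple[Morphology, list[ChangeRecord], list[ValidationIssue]]:
    """Repair connectivity violations involving *structure* (1=soma, 2=axon,
    3=basal, 4=apical).  Returns (corrected copy, changes, issues)."""
    if structure not in (1, 2, 3, 4):
        raise ValueError(f"structure must be a canonical type code 1-4, got {structure}")
    _require_acyclic(morph)
    m = morph.copy()
    changes: list[ChangeRecord] = []
    issues: list[ValidationIssue] = []

    # R2: absorb flanked intruder runs into the host structure.
    changed = True
    while changed:
        changed = False
        for members, flanked in _intruder_components(m, structure):
            if flanked:
                for node in sorted(members, key=lambda x: m.id_index[x.id]):
                    _retype(m, node, structure, "SANDWICH_RETYPE", changes)
                changed = True

    # R1: retype stray `structure` nodes to their parent's type when the
    # subsequent nodes are correctly connected.
    changed = True
    while changed:
        changed = False
        for n in m.nodes:
            if n.type_code != structure:
                continue
            parent = m.parent_of(n)
            if parent is None or parent.type_code in (structure, SOMA):
                continue
            target = parent.type_code
            if target == UNDEFINED:
                continue  # never retype to undefined; reported below
            kids = m.child_nodes(n)
            if (not kids
                    or all(k.type_code == target for k in kids)
                    or (all(k.type_code == structure for k in kids)
                        and _chain_terminates_in(m, n, structure, target))):
                _retype(m, n, target, "MEMBERSHIP_RETYPE", changes)
                changed = True

    # Anything still violating the membership rule is ambiguous: report, don't guess.
    for n in m.nodes:
        if n.type_code != structure:
            continue
        parent = m.parent_of(n)
        if parent is not None and parent.type_code not in (structure, SOMA):
            issues.append(ValidationIssue(
                code=IssueCode.UNCORRECTABLE_STRUCTURE,
                severity=Severity.WARNING,
                file=m.source_path,
                node_id=n.id,
                message=(f"node {n.id} (type {n.type_code}) connects to type "
                         f"{parent.type_code} parent but its children do not "
                         f"indicate an unambiguous correction"),
            ))
    return m, changes, issues


def repair_zero_radius(morph: Morphology) -> tuple[Morphology, list[ChangeRecord], list[ValidationIssue]]:
    """Replace zero radii by the parent's current radius, in topological order,
    so chains of zeros inherit the nearest positive ancestor's radius.

    Roots (and dangling-parent nodes) with zero radius have no parent to copy
    from; they are left unchanged and reported.
    """
    _require_acyclic(morph)
    m = morph.copy()
    changes: list[ChangeRecord] = []
    issues: list[ValidationIssue] = []

    order: list[NodeRecord] = []
    ids = set(m.id_index)
    stack = [n for n in reversed(m.nodes) if n.parent_id == -1 or n.parent_id not in ids]
    while stack:
        cur = stack.pop()
        order.append(cur)
        stack.extend(reversed(m.child_nodes(cur)))

    def report(node: NodeRecord, why: str) -> None:
        issues.append(ValidationIssue(
            code=IssueCode.ZERO_RADIUS, severity=Severity.WARNING, file=m.source_path,
            node_id=node.id, message=f"node {node.id} radius left at 0: {why}"))

    for n in order:
        if n.radius != 0.0:
            continue
        parent = m.parent_of(n)
        if parent is None:
            report(n, "root has no parent to copy the radius from")
        elif parent.radius == 0.0:
            report(n, "parent radius is also 0 (no positive ancestor)")
        else:
            changes.append(ChangeRecord(m.source_path, n.id, "radius", 0.0, parent.radius,
                                        "RADIUS_FROM_PARENT"))
            n.radius = parent.radius
    return m, changes, issues


def reindex(morph: Morphology) -> tuple[Morphology, list[ChangeRecord]]:
    """Renumber nodes 1..N with parents before children, preserving topology.

    The order is stable: among nodes whose parents are already placed, the
    original file order decides.  Raises on dangling parent references (the
    remap would be unsafe).
    """
    _require_acyclic(morph)
    ids = set(morph.id_index)
    for n in morph.nodes:
        if n.parent_id != -1 and n.parent_id not in ids:
            raise ValueError(f"cannot reindex: node {n.id} has dangling parent {n.parent_id}")

    position = {n.id: i for i, n in enumerate(morph.nodes)}
    ready = [position[n.id] for n in morph.nodes if n.parent_id == -1]
    heapq.heapify(ready)
    new_order: list[NodeRecord] = []
    while ready:
        node = morph.nodes[heapq.heappop(ready)]
        new_order.append(node)
        for child in morph.children[node.id]:
            heapq.heappush(ready, position[child])

    id_map = {n.id: i + 1 for i, n in enumerate(new_order)}
    changes: list[ChangeRecord] = []
    out_nodes = []
    for n in new_order:
        new_id = id_map[n.id]
        new_parent = -1 if n.parent_id == -1 else id_map[n.parent_id]
        if new_id != n.id:
            changes.append(ChangeRecord(morph.source_path, n.id, "id", n.id, new_id, "REINDEX"))
        out_nodes.append(NodeRecord(new_id, n.type_code, n.x, n.y, n.z, n.radius, new_parent))
    out = Morphology.from_nodes(out_nodes, morph.header_lines, morph.source_path)
    return out, changes


# Order matters for determinism when flags interact; soma first, then outward.
_STRUCTURE_FLAG_ORDER = (("fix_soma", 1), ("fix_axon", 2), ("fix_basal", 3), ("fix_apic", 4))


def apply_corrections(morph: Morphology, config: CorrectionConfig) -> tuple[Morphology, list[ChangeRecord], list[ValidationIssue]]:
    """Apply the enabled corrections in fixed order: structure repairs
    (soma, axon, basal, apical), then zero-radius repair, then reindexing.

    Idempotent: a second application with the same config yields no changes.
    UNCORRECTABLE_STRUCTURE reports from early phases are dropped when a later
    phase resolved the violation.
    """
    m = morph
    changes: list[ChangeRecord] = []
    issues: list[ValidationIssue] = []
    uncorrectable: list[ValidationIssue] = []
    for flag, structure in _STRUCTURE_FLAG_ORDER:
        if getattr(config, flag):
            m, ch, iss = repair_structure(m, structure)
            changes += ch
            uncorrectable += iss
    # keep only reports whose violation still stands after all structure passes
    for iss in uncorrectable:
        node = m.node(iss.node_id)
        parent = m.parent_of(node)
        if parent is not None and parent.type_code not in (node.type_code, SOMA):
            issues.append(iss)
    if config.fix_radius:
        m, ch, iss = repair_zero_radius(m)
        changes += ch
        issues += iss
    if config.reindex:
        m, ch = reindex(m)
        changes += ch
    return m, changes, issues
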