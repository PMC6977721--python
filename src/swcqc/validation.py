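"""Structural validation of SWC morphologies.

Detects the defect classes that occur in real reconstruction corpora:
indexing problems (duplicate, dangling, out-of-order or non-sequential ids,
cycles), missing or non-soma roots, zero radii, and compartments connected to
the wrong structure (e.g. a basal dendrite hanging off an apical branch —
basal dendrites may only connect to more basal dendrite or the soma, and
likewise for every other structure).

Each finding is a :class:`ValidationIssue` carrying the file, line and raw
text needed to locate it, suitable for a machine-readable error log.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .swc_io import Morphology, RawRecord

__all__ = [
    "IssueCode",
    "Severity",
    "ValidationIssue",
    "SOMA",
    "AXON",
    "BASAL",
    "APICAL",
    "STRUCTURE_NAMES",
    "check_indexing",
    "check_root",
    "check_soma_start",
    "check_structure_connectivity",
    "check_zero_radius",
    "validate_file",
    "validate_text",
    "has_blocking_errors",
]

# Canonical SWC structure type codes.
UNDEFINED, SOMA, AXON, BASAL, APICAL = 0, 1, 2, 3, 4
STRUCTURE_NAMES = {
    UNDEFINED: "undefined",
    SOMA: "soma",
    AXON: "axon",
    BASAL: "basal dendrite",
    APICAL: "apical dendrite",
}


class IssueCode(str, Enum):
    MISSING_FIELDS = "MISSING_FIELDS"
    EXTRA_FIELDS = "EXTRA_FIELDS"
    BAD_NUMBER = "BAD_NUMBER"
    DUPLICATE_ID = "DUPLICATE_ID"
    NO_ROOT = "NO_ROOT"
    MULTIPLE_ROOTS = "MULTIPLE_ROOTS"
    NOT_SOMA_START = "NOT_SOMA_START"
    BAD_PARENT_REF = "BAD_PARENT_REF"
    SELF_PARENT = "SELF_PARENT"
    CHILD_BEFORE_PARENT = "CHILD_BEFORE_PARENT"
    NON_SEQUENTIAL_IDS = "NON_SEQUENTIAL_IDS"
    CYCLE = "CYCLE"
    ZERO_RADIUS = "ZERO_RADIUS"
    STRUCTURE_MISCONNECTED = "STRUCTURE_MISCONNECTED"
    UNCORRECTABLE_STRUCTURE = "UNCORRECTABLE_STRUCTURE"


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass
class ValidationIssue:
    """One detected defect, with enough context to locate the offending line."""

    code: IssueCode
    severity: Severity
    file: str
    line_number: Optional[int] = None
    node_id: Optional[int] = None
    message: str = ""
    raw_line: Optional[str] = None


def _line_of(morph: "Morphology", node_id: int):
    cache = getattr(morph, "_line_map", None)
    if cache is None:
        cache = {r.parsed.id: (r.line_number, r.raw_text)
                 for r in morph.raw_records if r.parsed is not None}
        morph._line_map = cache
    return cache.get(node_id, (None, None))


def _mk(morph, code, severity, node_id=None, message="", line_number=None, raw_line=None):
    if node_id is not None and line_number is None:
        line_number, raw_line = _line_of(morph, node_id)
    return ValidationIssue(
        code=code,
        severity=severity,
        file=morph.source_path,
        line_number=line_number,
        node_id=node_id,
        message=message,
        raw_line=raw_line,
    )


def find_cycle_members(morph: "Morphology") -> set[int]:
    """Ids of nodes lying on a parent-chain cycle, in O(N) via visitation marking."""
    WHITE, GREY, BLACK = 0, 1, 2
    state: dict[int, int] = {n.id: WHITE for n in morph.nodes}
    cyclic: set[int] = set()
    for start in morph.nodes:
        if state[start.id] != WHITE:
            continue
        chain: list[int] = []
        nid = start.id
        while nid != -1 and nid in state and state[nid] == WHITE:
            state[nid] = GREY
            chain.append(nid)
            nid = morph.node(nid).parent_id
        if nid != -1 and nid in state and state[nid] == GREY:
            # revisited a node on the current chain: the tail from there is a cycle
            cyclic.update(chain[chain.index(nid):])
        for cid in chain:
            state[cid] = BLACK
    return cyclic


def check_indexing(morph: "Morphology", raw: Optional[list["RawRecord"]] = None) -> list[ValidationIssue]:
    """Indexing defects: dangling/self parents, children before parents, cycles,
    and ids that are not sequential 1..N in file order (WARNING)."""
    issues: list[ValidationIssue] = []
    ids = set(morph.id_index)
    position = {n.id: i for i, n in enumerate(morph.nodes)}

    for n in morph.nodes:
        if n.parent_id == n.id:
            issues.append(_mk(morph, IssueCode.SELF_PARENT, Severity.ERROR, n.id,
                              f"node {n.id} is its own parent"))
        elif n.parent_id != -1 and n.parent_id not in ids:
            issues.append(_mk(morph, IssueCode.BAD_PARENT_REF, Severity.ERROR, n.id,
                              f"node {n.id} references missing parent {n.parent_id}"))
        elif n.parent_id != -1 and position[n.parent_id] > position[n.id]:
            issues.append(_mk(morph, IssueCode.CHILD_BEFORE_PARENT, Severity.WARNING, n.id,
                              f"node {n.id} appears before its parent {n.parent_id}"))

    cyclic = find_cycle_members(morph)
    cyclic -= {n.id for n in morph.nodes if n.parent_id == n.id}  # SELF_PARENT covers these
    reported: set[int] = set()
    for n in morph.nodes:  # one issue per cycle, anchored at its first member in file order
        if n.id in cyclic and n.id not in reported:
            component = _cycle_component(morph, n.id, cyclic)
            reported |= component
            issues.append(_mk(morph, IssueCode.CYCLE, Severity.ERROR, n.id,
                              f"parent chain revisits node {n.id} (cycle of {len(component)} nodes)"))

    if [n.id for n in morph.nodes] != list(range(1, len(morph.nodes) + 1)):
        if morph.nodes:
            issues.append(_mk(morph, IssueCode.NON_SEQUENTIAL_IDS, Severity.WARNING,
                              message="node ids are not sequential 1..N in file order"))
    return issues


def _cycle_component(morph: "Morphology", start: int, cyclic: set[int]) -> set[int]:
    comp = {start}
    nid = morph.node(start).parent_id
    while nid in cyclic and nid not in comp:
        comp.add(nid)
        nid = morph.node(nid).parent_id
    return comp


def check_root(morph: "Morphology") -> list[ValidationIssue]:
    """NO_ROOT (ERROR) when no node has parent -1; MULTIPLE_ROOTS (WARNING) otherwise."""
    roots = morph.roots
    if not morph.nodes:
        return []
    if not roots:
        return [_mk(morph, IssueCode.NO_ROOT, Severity.ERROR,
                    message="no node has parent -1; the file has no root")]
    if len(roots) > 1:
        ids = ", ".join(str(r.id) for r in roots)
        return [_mk(morph, IssueCode.MULTIPLE_ROOTS, Severity.WARNING, roots[0].id,
                    message=f"multiple root nodes: {ids}")]
    return []


def check_soma_start(morph: "Morphology") -> list[ValidationIssue]:
    """The first record should be a soma (type 1) root."""
    if not morph.nodes:
        return []
    first = morph.nodes[0]
    if first.type_code != SOMA or not first.is_root():
        what = ("first record is not a soma"
                if first.type_code != SOMA
                else "first record is a soma but not a root")
        return [_mk(morph, IssueCode.NOT_SOMA_START, Severity.WARNING, first.id,
                    message=f"{what} (type {first.type_code}, parent {first.parent_id})")]
    return []


def check_structure_connectivity(morph: "Morphology", structure: int) -> list[ValidationIssue]:
    """Nodes of *structure* whose parent is neither the same structure nor soma.

    The soma is a universally legal parent; soma nodes themselves may only
    attach to other soma nodes.  Roots and dangling parents are exempt.
    """
    legal = {structure} if structure == SOMA else {structure, SOMA}
    issues = []
    for n in morph.nodes:
        if n.type_code != structure:
            continue
        parent = morph.parent_of(n)
        if parent is None or parent.type_code in legal:
            continue
        issues.append(_mk(
            morph, IssueCode.STRUCTURE_MISCONNECTED, Severity.WARNING, n.id,
            f"{STRUCTURE_NAMES.get(structure, structure)} node {n.id} connects to "
            f"{STRUCTURE_NAMES.get(parent.type_code, parent.type_code)} parent {parent.id}",
        ))
    return issues


def check_zero_radius(morph: "Morphology") -> list[ValidationIssue]:
    """One WARNING per node whose radius is exactly zero."""
    return [
        _mk(morph, IssueCode.ZERO_RADIUS, Severity.WARNING, n.id,
            f"node {n.id} has radius 0")
        for n in morph.nodes
        if n.radius == 0.0
    ]


def validate_file(
    morph: "Morphology",
    parse_issues: Optional[list[ValidationIssue]] = None,
) -> list[ValidationIssue]:
    """All checks, deterministically ordered by line number then code.

    ``parse_issues`` (from :func:`swcqc.swc_io.parse_swc`) are merged in so the
    result covers line-level and tree-level defects alike.
    """
    issues = list(parse_issues or [])
    issues += check_indexing(morph)
    issues += check_root(morph)
    issues += check_soma_start(morph)
    for structure in (SOMA, AXON, BASAL, APICAL):
        issues += check_structure_connectivity(morph, structure)
    issues += check_zero_radius(morph)
    issues.sort(key=lambda i: (i.line_number if i.line_number is not None else 10 ** 9, i.code.value))
    return issues


def validate_text(text: str, source_path: str = "<string>"):
    """Parse and validate in one step; returns (morphology, all issues)."""
    from .swc_io import parse_swc

    morph, parse_issues = parse_swc(text, source_path)
    return morph, validate_file(morph, parse_issues)


def has_blocking_errors(issues: list[ValidationIssue]) -> bool:
    """True when ERROR-severity tree defects make corrections unsafe."""
    return any(i.severity is Severity.ERROR for i in issues)
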