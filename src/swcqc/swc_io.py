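"""Tolerant reading and deterministic writing of SWC morphology files.

The SWC format stores one neuron compartment per line as seven
whitespace-separated fields::

    index  type  x  y  z  radius  parent

with ``#`` comment/header lines and ``parent = -1`` marking a root.  Files in
the wild are frequently malformed (missing fields, duplicate indices, stray
columns), so the parser here never raises on content: every defective line is
converted into a :class:`~swcqc.validation.ValidationIssue` and parsing
continues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .validation import IssueCode, Severity, ValidationIssue

__all__ = [
    "NodeRecord",
    "RawRecord",
    "Morphology",
    "parse_swc",
    "parse_swc_file",
    "write_swc",
    "read_directory",
]


@dataclass
class NodeRecord:
    """One SWC compartment: id, structure type, position (um), radius (um), parent id."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def is_root(self) -> bool:
        return self.parent_id == -1


@dataclass
class RawRecord:
    """A single non-header, non-blank input line, parsed or not.

    ``parsed`` is present exactly when the line yielded seven interpretable
    leading tokens.
    """

    line_number: int
    raw_text: str
    fields: list[str]
    parsed: Optional[NodeRecord] = None


@dataclass
class Morphology:
    """A parsed SWC file: verbatim headers plus nodes in original file order.

    ``id_index`` maps node id to position in ``nodes``; ``children`` maps node
    id to the ordered list of child ids.  Both are derived and kept consistent
    by :meth:`rebuild_index`.
    """

    header_lines: list[str] = field(default_factory=list)
    nodes: list[NodeRecord] = field(default_factory=list)
    id_index: dict[int, int] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    source_path: str = "<memory>"
    raw_records: list[RawRecord] = field(default_factory=list)

    @classmethod
    def from_nodes(
        cls,
        nodes: Iterable[NodeRecord],
        header_lines: Iterable[str] = (),
        source_path: str = "<memory>",
    ) -> "Morphology":
        m = cls(header_lines=list(header_lines), nodes=list(nodes), source_path=source_path)
        m.rebuild_index()
        return m

    def rebuild_index(self) -> None:
        self.id_index = {n.id: i for i, n in enumerate(self.nodes)}
        if len(self.id_index) != len(self.nodes):
            raise ValueError("duplicate node ids in Morphology")
        self.children = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id in self.children:
                self.children[n.parent_id].append(n.id)

    def node(self, node_id: int) -> NodeRecord:
        return self.nodes[self.id_index[node_id]]

    def parent_of(self, node: NodeRecord) -> Optional[NodeRecord]:
        """Parent record, or None for roots and dangling parent references."""
        if node.parent_id == -1:
            return None
        pos = self.id_index.get(node.parent_id)
        return None if pos is None else self.nodes[pos]

    def child_nodes(self, node: NodeRecord) -> list[NodeRecord]:
        return [self.node(c) for c in self.children.get(node.id, [])]

    @property
    def roots(self) -> list[NodeRecord]:
        return [n for n in self.nodes if n.is_root()]

    def copy(self) -> "Morphology":
        m = Morphology(
            header_lines=list(self.header_lines),
            nodes=[replace(n) for n in self.nodes],
            source_path=self.source_path,
            raw_records=list(self.raw_records),
        )
        m.rebuild_index()
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Morphology):
            return NotImplemented
        return self.header_lines == other.header_lines and self.nodes == other.nodes


def _coerce_int(token: str) -> tuple[int, bool]:
    """Parse an integer token; integer-valued floats ("3.0") coerce with a flag.

    Raises ValueError for non-numeric or genuinely fractional tokens.
    """
    try:
        return int(token), False
    except ValueError:
        value = float(token)  # may raise ValueError -> caller reports BAD_NUMBER
        if math.isfinite(value) and value.is_integer():
            return int(value), True
        raise ValueError(f"not an integer: {token!r}")


def parse_swc(text: str, source_path: str = "<string>") -> tuple[Morphology, list[ValidationIssue]]:
    """Parse SWC text, classifying every line and never raising on content.

    Lines are headers (first non-blank char ``#``), blank (skipped), or data.
    Data lines with exactly 7 numeric tokens become nodes.  Lines with extra
    tokens keep the first 7 and warn (EXTRA_FIELDS); lines with fewer than 7
    or uninterpretable tokens are excluded and reported (MISSING_FIELDS /
    BAD_NUMBER).  Later occurrences of a duplicate id are dropped
    (DUPLICATE_ID); the first is kept.

    Returns the morphology plus the list of parse-level issues.
    """
    headers: list[str] = []
    nodes: list[NodeRecord] = []
    raws: list[RawRecord] = []
    issues: list[ValidationIssue] = []
    seen_ids: set[int] = set()

    def issue(code: IssueCode, severity: Severity, lineno: int, msg: str, raw: str, node_id=None):
        issues.append(
            ValidationIssue(
                code=code,
                severity=severity,
                file=source_path,
                line_number=lineno,
                node_id=node_id,
                message=msg,
                raw_line=raw,
            )
        )

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            headers.append(line.rstrip("\r"))
            continue
        tokens = stripped.split()
        raw = RawRecord(line_number=lineno, raw_text=line.rstrip("\r"), fields=tokens)
        raws.append(raw)
        if len(tokens) < 7:
            issue(
                IssueCode.MISSING_FIELDS,
                Severity.ERROR,
                lineno,
                f"expected 7 fields, found {len(tokens)}",
                raw.raw_text,
            )
            continue
        if len(tokens) > 7:
            issue(
                IssueCode.EXTRA_FIELDS,
                Severity.WARNING,
                lineno,
                f"expected 7 fields, found {len(tokens)}; extra fields ignored",
                raw.raw_text,
            )
        try:
            node_id, id_coerced = _coerce_int(tokens[0])
            type_code, type_coerced = _coerce_int(tokens[1])
            parent_id, parent_coerced = _coerce_int(tokens[6])
            coords = [float(t) for t in tokens[2:6]]
        except ValueError as exc:
            issue(IssueCode.BAD_NUMBER, Severity.ERROR, lineno, str(exc), raw.raw_text)
            continue
        x, y, z, radius = coords
        if not all(math.isfinite(v) for v in coords):
            issue(IssueCode.BAD_NUMBER, Severity.ERROR, lineno, "non-finite coordinate or radius", raw.raw_text)
            continue
        if node_id < 1 or type_code < 0 or radius < 0 or (parent_id != -1 and parent_id < 1):
            issue(
                IssueCode.BAD_NUMBER,
                Severity.ERROR,
                lineno,
                "field out of range (id>=1, type>=0, radius>=0, parent=-1 or >=1)",
                raw.raw_text,
            )
            continue
        if id_coerced or type_coerced or parent_coerced:
            issue(
                IssueCode.BAD_NUMBER,
                Severity.WARNING,
                lineno,
                "integer field written as float; coerced",
                raw.raw_text,
                node_id=node_id,
            )
        if node_id in seen_ids:
            issue(
                IssueCode.DUPLICATE_ID,
                Severity.WARNING,
                lineno,
                f"duplicate id {node_id}; first occurrence kept",
                raw.raw_text,
                node_id=node_id,
            )
            continue
        seen_ids.add(node_id)
        node = NodeRecord(node_id, type_code, x, y, z, radius, parent_id)
        raw.parsed = node
        nodes.append(node)

    morph = Morphology.from_nodes(nodes, headers, source_path)
    morph.raw_records = raws
    return morph, issues


def parse_swc_file(path: str | Path) -> tuple[Morphology, list[ValidationIssue]]:
    p = Path(path)
    return parse_swc(p.read_text(), source_path=str(p))


def _fmt(value: float) -> str:
    # repr() gives the shortest decimal string that round-trips the float.
    return repr(float(value))


def write_swc(morph: Morphology) -> str:
    """Serialize a morphology: headers verbatim, then one node per line.

    Fields are single-space separated; ids and type codes print as integers;
    coordinates and radii use the shortest decimal representation that
    round-trips (``repr``), so parse -> write -> parse is the identity.
    Raises ValueError if the morphology's id/children indices are stale.
    """
    ids = {n.id for n in morph.nodes}
    if len(ids) != len(morph.nodes):
        raise ValueError("cannot write morphology with duplicate ids")
    if morph.id_index != {n.id: i for i, n in enumerate(morph.nodes)}:
        raise ValueError("stale id_index; call rebuild_index() first")
    lines = list(morph.header_lines)
    for n in morph.nodes:
        lines.append(
            f"{n.id} {n.type_code} {_fmt(n.x)} {_fmt(n.y)} {_fmt(n.z)} {_fmt(n.radius)} {n.parent_id}"
        )
    return "\n".join(lines) + "\n"


def read_directory(path: str | Path, extension: str = ".swc") -> list[tuple[Path, str]]:
    """All files in *path* with the given extension (case-insensitive), read as
    text, sorted lexicographically by filename for deterministic batch order.

    Raises FileNotFoundError if *path* is missing or not a directory.
    """
    p = Path(path)
    if not p.is_dir():
        raise FileNotFoundError(f"DIRECTORY_NOT_FOUND: {p}")
    ext = extension.lower()
    files = sorted(
        (f for f in p.iterdir() if f.is_file() and f.suffix.lower() == ext),
        key=lambda f: f.name,
    )
    return [(f, f.read_text()) for f in files]
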