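"""Synthetic morphologies and seeded defect injection.

The generator grows structurally valid single-root SWC trees: a short soma
chain at the root, an axon with a long initial segment, several basal
dendrite trees and an apical dendrite with a prominent trunk (the pyramidal
cell layout in which mis-typed intrusion defects are commonly observed).
Subtrees grow by a seeded branching process: per-compartment bifurcation
probability, step lengths jittered around a mean inter-node spacing, 3-D
random-walk directions with momentum, and radii tapering per branch order.
Coordinates are rounded to nm-scale decimals as real reconstruction tools
emit, so serialized files are compact and round-trip exactly.

The injector corrupts a valid morphology with any of the defect classes the
validator and corrector handle, and returns the exact ground-truth edits so
detection and recovery can be scored.  Each defect spec draws from its own
seeded random stream, so adding one spec never perturbs another's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .swc_io import Morphology, NodeRecord, write_swc
from .validation import APICAL, AXON, BASAL, SOMA, IssueCode

__all__ = [
    "GeneratorParams",
    "DefectKind",
    "DefectSpec",
    "EXPECTED_ISSUE",
    "generate_morphology",
    "inject_defects",
    "corrupted_to_text",
    "generate_fixture_directory",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the branching process; defaults yield a ~1000-node pyramidal
    cell of roughly the size of a typical single-neuron SWC file (~60 KB)."""

    seed: int = 0
    n_soma: int = 3
    n_basal_trees: int = 2
    has_apical: bool = True
    has_axon: bool = True
    branch_prob: float = 0.05     # per-compartment bifurcation probability
    max_depth: int = 8            # maximum branch order per subtree
    segment_length_mean: float = 5.0   # um between consecutive compartments
    radius_root: float = 1.2      # um, neurite radius at branch order 0
    radius_taper: float = 0.8     # multiplicative radius factor per branch order


class DefectKind(str, Enum):
    TYPE_SANDWICH = "TYPE_SANDWICH"
    ZERO_RADIUS = "ZERO_RADIUS"
    SHUFFLE_INDEX = "SHUFFLE_INDEX"
    CHILD_BEFORE_PARENT = "CHILD_BEFORE_PARENT"
    DROP_FIELD = "DROP_FIELD"
    REMOVE_ROOT = "REMOVE_ROOT"
    NONSOMA_START = "NONSOMA_START"


#: Issue code the validator is expected to raise for each injected defect class.
EXPECTED_ISSUE = {
    DefectKind.TYPE_SANDWICH: IssueCode.STRUCTURE_MISCONNECTED,
    DefectKind.ZERO_RADIUS: IssueCode.ZERO_RADIUS,
    DefectKind.SHUFFLE_INDEX: IssueCode.NON_SEQUENTIAL_IDS,
    DefectKind.CHILD_BEFORE_PARENT: IssueCode.CHILD_BEFORE_PARENT,
    DefectKind.DROP_FIELD: IssueCode.MISSING_FIELDS,
    DefectKind.REMOVE_ROOT: IssueCode.NO_ROOT,
    DefectKind.NONSOMA_START: IssueCode.NOT_SOMA_START,
}


@dataclass(frozen=True)
class DefectSpec:
    """One class of defect to inject, with its own random stream."""

    kind: DefectKind
    count: int = 1
    run_length: int = 1            # TYPE_SANDWICH only
    host_structure: int = APICAL   # TYPE_SANDWICH only
    intruder_type: int = BASAL     # TYPE_SANDWICH only
    seed: int = 0


@dataclass
class GroundTruthEdit:
    """One injected corruption: node (or line) touched, field, original value."""

    node_id: Optional[int]
    field: str
    original_value: object
    line_number: Optional[int] = None


def _unit(vec: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(vec))
    return vec / norm if norm > 0 else np.array([0.0, 0.0, 1.0])


def _round3(v: float) -> float:
    return float(round(v, 3))


class _Builder:
    def __init__(self, rng: np.random.Generator, params: GeneratorParams):
        self.rng = rng
        self.p = params
        self.nodes: list[NodeRecord] = []

    def add(self, type_code: int, pos: np.ndarray, radius: float, parent_id: int) -> int:
        nid = len(self.nodes) + 1
        self.nodes.append(NodeRecord(
            nid, type_code, _round3(pos[0]), _round3(pos[1]), _round3(pos[2]),
            float(round(max(radius, 0.05), 4)), parent_id))
        return nid

    def grow_subtree(self, parent_id: int, type_code: int, direction: np.ndarray,
                     trunk_length: int) -> None:
        """Grow one neurite: an unbranched trunk, then a branching process."""
        p, rng = self.p, self.rng
        pos = np.array(self.position(parent_id))
        cur = parent_id
        radius = p.radius_root
        for _ in range(trunk_length):
            pos = pos + self.step(direction)
            cur = self.add(type_code, pos, radius, cur)
        # branching phase: stack of (parent id, position, direction, depth, radius)
        stack = [(cur, pos, direction, 0, radius)]
        while stack:
            cur, pos, direction, depth, radius = stack.pop()
            length = 4 + int(rng.geometric(1.0 / 8.0))  # compartments until forced branch/stop
            branched = False
            for _ in range(length):
                direction = _unit(direction + 0.35 * rng.standard_normal(3))
                pos = pos + self.step(direction)
                cur = self.add(type_code, pos, radius, cur)
                if depth < p.max_depth and rng.random() < p.branch_prob:
                    branched = True
                    break
            # proximal orders always bifurcate (real arbors rarely end that close
            # to the soma); distal termination is governed by branch_prob alone
            if branched or depth < min(3, p.max_depth):
                r_child = radius * p.radius_taper
                for _ in range(2):
                    d_child = _unit(direction + 0.8 * rng.standard_normal(3))
                    stack.append((cur, pos, d_child, depth + 1, r_child))

    def step(self, direction: np.ndarray) -> np.ndarray:
        jitter = self.rng.uniform(0.6, 1.4)
        return direction * self.p.segment_length_mean * jitter

    def position(self, node_id: int) -> tuple[float, float, float]:
        n = self.nodes[node_id - 1]
        return (n.x, n.y, n.z)


def generate_morphology(params: GeneratorParams = GeneratorParams()) -> Morphology:
    """A valid single-root morphology; same params always give identical output."""
    rng = np.random.default_rng(params.seed)
    b = _Builder(rng, params)
    soma_radius = max(3.0 * params.radius_root, 2.0)
    root = b.add(SOMA, np.zeros(3), soma_radius, -1)
    cur = root
    for _ in range(params.n_soma - 1):
        offset = rng.standard_normal(3) * soma_radius * 0.4
        cur = b.add(SOMA, np.array(b.position(cur)) + offset, soma_radius, cur)

    if params.has_axon:
        b.grow_subtree(root, AXON, _unit(np.array([0.2, -1.0, 0.0]) + 0.1 * rng.standard_normal(3)),
                       trunk_length=12)
    for i in range(params.n_basal_trees):
        angle = 2 * math.pi * (i + 1) / (params.n_basal_trees + 1)
        direction = _unit(np.array([math.cos(angle), -0.4, math.sin(angle)]))
        b.grow_subtree(root, BASAL, direction, trunk_length=4)
    if params.has_apical:
        b.grow_subtree(root, APICAL, _unit(np.array([0.05, 1.0, 0.05])), trunk_length=14)

    header = [f"# synthetic morphology (seed={params.seed})",
              "# index type x y z radius parent"]
    return Morphology.from_nodes(b.nodes, header, source_path=f"<synthetic:{params.seed}>")


def _sandwich_candidates(morph: Morphology, host: int, run_length: int) -> list[list[int]]:
    """Windows of `run_length` host-type chain nodes flanked by host type on
    both sides: parent of the head is host, every window node has exactly one
    child, and the exit child is host."""
    windows: list[list[int]] = []
    for n in morph.nodes:
        parent = morph.parent_of(n)
        if n.type_code != host or parent is None or parent.type_code != host:
            continue
        window = []
        cur = n
        ok = True
        for _ in range(run_length):
            kids = morph.children.get(cur.id, [])
            if cur.type_code != host or len(kids) != 1:
                ok = False
                break
            window.append(cur.id)
            cur = morph.node(kids[0])
        if ok and cur.type_code == host:
            windows.append(window)
    return windows


def _pick_disjoint(windows: list[list[int]], count: int, rng: np.random.Generator,
                   morph: Morphology) -> list[list[int]]:
    """Choose `count` windows whose members and flanks never touch, so each
    injected run stays individually flanked by correctly typed nodes."""
    order = rng.permutation(len(windows))
    chosen: list[list[int]] = []
    blocked: set[int] = set()
    for i in order:
        w = windows[int(i)]
        flank_parent = morph.node(w[0]).parent_id
        flank_child = morph.children[w[-1]][0]
        footprint = set(w) | {flank_parent, flank_child}
        if footprint & blocked:
            continue
        chosen.append(w)
        blocked |= footprint
        if len(chosen) == count:
            return chosen
    raise ValueError(f"only {len(chosen)} disjoint flanked runs available, need {count}")


def inject_defects(
    morph: Morphology, specs: list[DefectSpec]
) -> tuple[Union[Morphology, str], list[GroundTruthEdit]]:
    """Corrupt a valid morphology per *specs*; return it with ground truth.

    The result is a Morphology unless a spec (DROP_FIELD) produces lines the
    data model cannot hold, in which case raw SWC text is returned.  Raises
    ValueError when a spec is unsatisfiable on this morphology.
    """
    m = morph.copy()
    truth: list[GroundTruthEdit] = []
    drop_specs = [s for s in specs if s.kind is DefectKind.DROP_FIELD]

    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        if spec.kind is DefectKind.TYPE_SANDWICH:
            windows = _sandwich_candidates(m, spec.host_structure, spec.run_length)
            if not windows:
                raise ValueError(
                    f"no flanked run of length {spec.run_length} in structure "
                    f"{spec.host_structure}")
            for window in _pick_disjoint(windows, spec.count, rng, m):
                for nid in window:
                    node = m.node(nid)
                    truth.append(GroundTruthEdit(nid, "type_code", node.type_code))
                    node.type_code = spec.intruder_type
        elif spec.kind is DefectKind.ZERO_RADIUS:
            non_roots = [n.id for n in m.nodes if not n.is_root() and n.radius != 0.0]
            if len(non_roots) < spec.count:
                raise ValueError("not enough non-root nodes to zero")
            for nid in rng.choice(non_roots, size=spec.count, replace=False):
                node = m.node(int(nid))
                truth.append(GroundTruthEdit(node.id, "radius", node.radius))
                node.radius = 0.0
        elif spec.kind is DefectKind.SHUFFLE_INDEX:
            old_ids = [n.id for n in m.nodes]
            perm = list(rng.permutation(old_ids))
            if perm == old_ids:
                perm = perm[1:] + perm[:1]
            id_map = dict(zip(old_ids, (int(v) for v in perm)))
            for n in m.nodes:
                if id_map[n.id] != n.id:
                    truth.append(GroundTruthEdit(n.id, "id", n.id))
                n.parent_id = id_map[n.parent_id] if n.parent_id != -1 else -1
            for n in m.nodes:
                n.id = id_map[n.id]
            m.rebuild_index()
        elif spec.kind is DefectKind.CHILD_BEFORE_PARENT:
            movable = [n.id for n in m.nodes if not n.is_root()]
            if len(movable) < spec.count:
                raise ValueError("not enough non-root nodes to reorder")
            # pick children whose parents are not themselves picked, so one
            # move can never undo another's out-of-order pair
            chosen: list[int] = []
            blocked: set[int] = set()
            for nid in rng.permutation(movable):
                nid = int(nid)
                parent_id = m.node(nid).parent_id
                if nid in blocked or parent_id in chosen:
                    continue
                chosen.append(nid)
                blocked.add(parent_id)
                if len(chosen) == spec.count:
                    break
            if len(chosen) < spec.count:
                raise ValueError("not enough independent child/parent pairs to reorder")
            for nid in chosen:
                node = m.node(nid)
                m.nodes.remove(node)
                m.nodes.insert(m.nodes.index(m.node(node.parent_id)), node)
                m.rebuild_index()
                truth.append(GroundTruthEdit(node.id, "order", int(nid)))
        elif spec.kind is DefectKind.REMOVE_ROOT:
            roots = m.roots
            if not roots:
                raise ValueError("morphology already has no root")
            root = roots[0]
            new_parent = m.nodes[-1].id if m.nodes[-1].id != root.id else m.nodes[0].id
            truth.append(GroundTruthEdit(root.id, "parent_id", -1))
            root.parent_id = new_parent
            m.rebuild_index()
        elif spec.kind is DefectKind.NONSOMA_START:
            first = m.nodes[0]
            truth.append(GroundTruthEdit(first.id, "type_code", first.type_code))
            first.type_code = AXON
        elif spec.kind is DefectKind.DROP_FIELD:
            pass  # applied on the serialized text below
        else:  # pragma: no cover
            raise ValueError(f"unknown defect kind {spec.kind}")

    if not drop_specs:
        return m, truth

    lines = write_swc(m).splitlines()
    data_idx = [i for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("#")]
    for spec in drop_specs:
        rng = np.random.default_rng(spec.seed)
        if len(data_idx) < spec.count:
            raise ValueError("not enough data lines to truncate")
        for i in rng.choice(data_idx, size=spec.count, replace=False):
            i = int(i)
            tokens = lines[i].split()
            truth.append(GroundTruthEdit(None, "line", lines[i], line_number=i + 1))
            lines[i] = " ".join(tokens[:6])
    return "\n".join(lines) + "\n", truth


def corrupted_to_text(result: Union[Morphology, str]) -> str:
    """Serialize an injection result regardless of its return mode."""
    return result if isinstance(result, str) else write_swc(result)


def generate_fixture_directory(
    out_dir: str | Path,
    n_files: int,
    seed: int = 0,
    specs: Optional[list[DefectSpec]] = None,
    params: GeneratorParams = GeneratorParams(),
) -> list[Path]:
    """Write *n_files* seeded SWC files (optionally corrupted) into *out_dir*.

    File k uses generator seed ``seed + k`` and per-spec seeds derived the
    same way, so the directory contents are fully reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for k in range(n_files):
        p = replace(params, seed=(seed + k) % (2 ** 31))
        morph = generate_morphology(p)
        if specs:
            adjusted = [replace(s, seed=(s.seed + 7919 * k + 1) % (2 ** 31)) for s in specs]
            result, _ = inject_defects(morph, adjusted)
            text = corrupted_to_text(result)
        else:
            text = write_swc(morph)
        path = out / f"neuron_{k:04d}.swc"
        path.write_text(text)
        written.append(path)
    return written
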