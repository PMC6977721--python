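"""Per-file morphometric statistics.

A single traversal computes compartment counts, total cable length, tree
topology measures (tips, branch points, branch order), radius statistics and
the bounding box.  Distances are Euclidean on the raw coordinates, in the
micrometre units of the SWC convention; no rescaling is applied.

Nodes with dangling parent references are treated as extra roots for the
path-based statistics.  Nodes unreachable from any root (only possible when
the parent relation is cyclic) contribute to counts, radii and the bounding
box but not to path statistics; such files should be fixed before their
morphometry is trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .swc_io import Morphology

__all__ = ["MorphometrySummary", "summarize"]


@dataclass
class MorphometrySummary:
    node_count: int = 0
    counts_by_type: dict[int, int] = field(default_factory=dict)
    root_count: int = 0
    tip_count: int = 0
    branch_point_count: int = 0
    max_branch_order: int = 0
    total_length: float = 0.0  # um of cable
    bounding_box: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))  # (min,max) per axis
    radius_min: float = 0.0
    radius_mean: float = 0.0
    radius_max: float = 0.0
    max_path_distance: float = 0.0  # um, greatest root-to-tip cable distance


def summarize(morph: Morphology) -> MorphometrySummary:
    """Compute all statistics in one O(N) pass; empty input gives all zeros."""
    nodes = morph.nodes
    if not nodes:
        return MorphometrySummary()

    counts: dict[int, int] = {}
    for n in nodes:
        counts[n.type_code] = counts.get(n.type_code, 0) + 1

    ids = set(morph.id_index)
    roots = [n for n in nodes if n.parent_id == -1 or n.parent_id not in ids]
    tips = sum(1 for n in nodes if not morph.children.get(n.id))
    branch_points = sum(1 for n in nodes if len(morph.children.get(n.id, ())) >= 2)

    total_length = 0.0
    max_order = 0
    max_path = 0.0
    # depth-first from each root, carrying cumulative cable distance and branch order
    stack: list[tuple[int, float, int]] = [(r.id, 0.0, 0) for r in reversed(roots)]
    while stack:
        nid, dist, order = stack.pop()
        node = morph.node(nid)
        max_path = max(max_path, dist)
        max_order = max(max_order, order)
        kids = morph.children.get(nid, ())
        bump = 1 if len(kids) >= 2 else 0
        for cid in reversed(kids):
            child = morph.node(cid)
            step = math.dist((node.x, node.y, node.z), (child.x, child.y, child.z))
            total_length += step
            stack.append((cid, dist + step, order + bump))

    radii = [n.radius for n in nodes]
    xs = [n.x for n in nodes]
    ys = [n.y for n in nodes]
    zs = [n.z for n in nodes]
    return MorphometrySummary(
        node_count=len(nodes),
        counts_by_type=dict(sorted(counts.items())),
        root_count=len(roots),
        tip_count=tips,
        branch_point_count=branch_points,
        max_branch_order=max_order,
        total_length=total_length,
        bounding_box=((min(xs), max(xs)), (min(ys), max(ys)), (min(zs), max(zs))),
        radius_min=min(radii),
        radius_mean=sum(radii) / len(radii),
        radius_max=max(radii),
        max_path_distance=max_path,
    )
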