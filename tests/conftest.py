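"""Shared fixtures and small morphology builders."""

from __future__ import annotations

import pytest

from swcqc import Morphology, NodeRecord


def build(rows) -> Morphology:
    """Morphology from (id, type, x, y, z, radius, parent) tuples."""
    return Morphology.from_nodes([NodeRecord(*row) for row in rows])


def chain(*type_codes, radii=None) -> Morphology:
    """A straight chain along x: node i has type type_codes[i]; first is root."""
    radii = radii or [1.0] * len(type_codes)
    rows = [
        (i + 1, t, float(i), 0.0, 0.0, radii[i], i if i > 0 else -1)
        for i, t in enumerate(type_codes)
    ]
    return build(rows)


@pytest.fixture
def soma_only():
    return chain(1)


@pytest.fixture
def small_tree():
    # soma root with two branches: 1 -> 2 -> {3, 4}; 4 -> 5
    return build([
        (1, 1, 0.0, 0.0, 0.0, 2.0, -1),
        (2, 3, 1.0, 0.0, 0.0, 1.0, 1),
        (3, 3, 2.0, 0.0, 0.0, 0.8, 2),
        (4, 3, 1.0, 1.0, 0.0, 0.8, 2),
        (5, 3, 1.0, 2.0, 0.0, 0.6, 4),
    ])
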