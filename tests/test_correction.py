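"""Structure retyping, zero-radius repair, reindexing, and their invariants."""

import itertools

import networkx as nx
import numpy as np
import pytest

from swcqc import (
    APICAL,
    AXON,
    BASAL,
    SOMA,
    ChangeRecord,
    CorrectionConfig,
    DefectKind,
    DefectSpec,
    GeneratorParams,
    IssueCode,
    apply_corrections,
    generate_morphology,
    inject_defects,
    reindex,
    repair_structure,
    repair_zero_radius,
)

from conftest import build, chain


ALL_FLAGS = CorrectionConfig(fix_soma=True, fix_axon=True, fix_basal=True,
                             fix_apic=True, fix_radius=True, reindex=True)


def three_chain_oracle(types, structure):
    """Independent rule evaluator for a 3-node chain root->mid->leaf.

    Implements the membership and sandwich rules directly on the chain,
    iterating to a fixed point in file order, without any tree machinery.
    """
    a, b, c = list(types)
    changed = True
    while changed:
        changed = False
        # sandwich: mid absorbed into the host structure when flanked
        if b not in (structure, SOMA) and a == structure and c == structure:
            b, changed = structure, True
            continue
        # membership for mid: retype to parent's type if the leaf agrees
        if (b == structure and a not in (structure, SOMA) and a != 0 and c == a):
            b, changed = a, True
            continue
        # membership for leaf: no children, so always correctable
        if c == structure and b not in (structure, SOMA) and b != 0:
            c, changed = b, True
            continue
    return (a, b, c)


class TestRepairStructure:
    def test_basal_between_apicals_retyped_to_apical(self):
        # the archetypal apical-to-basal inconsistency
        m = chain(SOMA, APICAL, BASAL, APICAL)
        fixed, changes, issues = repair_structure(m, BASAL)
        assert [n.type_code for n in fixed.nodes] == [SOMA, APICAL, APICAL, APICAL]
        assert [(c.node_id, c.old_value, c.new_value) for c in changes] == [(3, BASAL, APICAL)]
        assert issues == []

    def test_apical_inside_axon_absorbed_under_axon_flag(self):
        m = chain(SOMA, AXON, APICAL, AXON)
        fixed, changes, issues = repair_structure(m, AXON)
        assert [n.type_code for n in fixed.nodes] == [SOMA, AXON, AXON, AXON]
        assert changes[0].rule == "SANDWICH_RETYPE"

    def test_genuine_hanging_subtree_left_alone(self):
        # basal subtree rooted under apical with all-basal children: ambiguous
        m = chain(SOMA, APICAL, BASAL, BASAL)
        fixed, changes, issues = repair_structure(m, BASAL)
        assert [n.type_code for n in fixed.nodes] == [SOMA, APICAL, BASAL, BASAL]
        assert changes == []
        assert [i.code for i in issues] == [IssueCode.UNCORRECTABLE_STRUCTURE]
        assert issues[0].node_id == 3

    @pytest.mark.parametrize("structure", [SOMA, AXON, BASAL, APICAL])
    def test_all_three_node_chains_match_brute_force_oracle(self, structure):
        for a, b, c in itertools.product((1, 2, 3, 4), (0, 1, 2, 3, 4), (0, 1, 2, 3, 4)):
            m = chain(a, b, c)
            fixed, _, _ = repair_structure(m, structure)
            got = tuple(n.type_code for n in fixed.nodes)
            assert got == three_chain_oracle((a, b, c), structure), (a, b, c, structure)

    @pytest.mark.parametrize("run_length", [1, 2, 3])
    def test_flanked_runs_fully_restored(self, run_length):
        for seed in range(5):
            m = generate_morphology(GeneratorParams(seed=seed))
            corrupted, truth = inject_defects(
                m, [DefectSpec(DefectKind.TYPE_SANDWICH, count=2, run_length=run_length,
                               host_structure=APICAL, intruder_type=BASAL, seed=seed)])
            fixed, changes, _ = apply_corrections(
                corrupted, CorrectionConfig(fix_basal=True, fix_apic=True))
            # every node back to its pristine type, not just the injected ones
            assert [n.type_code for n in fixed.nodes] == [n.type_code for n in m.nodes]

    @pytest.mark.parametrize("run_length", [1, 2, 3])
    def test_single_run_repair_touches_only_the_intruded_nodes(self, run_length):
        m = generate_morphology(GeneratorParams(seed=9))
        corrupted, truth = inject_defects(
            m, [DefectSpec(DefectKind.TYPE_SANDWICH, count=1, run_length=run_length,
                           host_structure=APICAL, intruder_type=BASAL, seed=4)])
        fixed, changes, _ = apply_corrections(
            corrupted, CorrectionConfig(fix_basal=True, fix_apic=True))
        assert sorted(c.node_id for c in changes) == sorted(e.node_id for e in truth)
        assert all(c.new_value == APICAL and c.old_value == BASAL for c in changes)

    def test_never_retypes_to_undefined(self):
        m = chain(SOMA, 0, BASAL)  # basal under an undefined-type parent
        fixed, changes, issues = repair_structure(m, BASAL)
        assert [n.type_code for n in fixed.nodes] == [SOMA, 0, BASAL]
        assert changes == []

    def test_raises_on_cycles(self):
        m = build([(1, 1, 0, 0, 0, 1, -1), (2, 3, 1, 0, 0, 1, 3), (3, 3, 2, 0, 0, 1, 2)])
        with pytest.raises(ValueError):
            repair_structure(m, BASAL)


def nearest_positive_ancestor_oracle(morph, node):
    """Brute-force ancestor walk used to check zero-radius repair."""
    cur = morph.parent_of(node)
    while cur is not None:
        if cur.radius > 0:
            return cur.radius
        cur = morph.parent_of(cur)
    return None


class TestRepairZeroRadius:
    def test_copies_parent_radius(self):
        m = chain(1, 3, radii=[1.2, 0.0])
        fixed, changes, issues = repair_zero_radius(m)
        assert fixed.nodes[1].radius == 1.2
        assert changes[0].rule == "RADIUS_FROM_PARENT"
        assert issues == []

    def test_chain_of_zeros_inherits_nearest_positive_ancestor(self):
        m = chain(1, 3, 3, radii=[0.8, 0.0, 0.0])
        fixed, _, _ = repair_zero_radius(m)
        assert [n.radius for n in fixed.nodes] == [0.8, 0.8, 0.8]

    def test_zero_root_left_unchanged_and_reported(self):
        m = chain(1, 3, radii=[0.0, 1.0])
        fixed, changes, issues = repair_zero_radius(m)
        assert fixed.nodes[0].radius == 0.0
        assert changes == []
        assert [i.code for i in issues] == [IssueCode.ZERO_RADIUS]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_ancestor_walk_oracle_on_random_trees(self, seed):
        m = generate_morphology(GeneratorParams(seed=seed))
        corrupted, truth = inject_defects(
            m, [DefectSpec(DefectKind.ZERO_RADIUS, count=8, seed=seed)])
        expected = {e.node_id: nearest_positive_ancestor_oracle(corrupted, corrupted.node(e.node_id))
                    for e in truth}
        fixed, changes, issues = repair_zero_radius(corrupted)
        assert all(n.radius > 0 for n in fixed.nodes)
        for nid, want in expected.items():
            assert fixed.node(nid).radius == want


class TestReindex:
    def test_order_preserving_renumbering(self):
        m = build([(5, 1, 0, 0, 0, 1, -1), (9, 3, 1, 0, 0, 1, 5), (12, 3, 2, 0, 0, 1, 9)])
        fixed, changes = reindex(m)
        assert [(n.id, n.parent_id) for n in fixed.nodes] == [(1, -1), (2, 1), (3, 2)]
        assert len(changes) == 3

    def test_already_sequential_is_identity(self, small_tree):
        fixed, changes = reindex(small_tree)
        assert changes == []
        assert fixed.nodes == small_tree.nodes

    @pytest.mark.parametrize("seed", range(10))
    def test_topology_isomorphic_after_shuffle(self, seed):
        m = generate_morphology(GeneratorParams(seed=seed, branch_prob=0.1, max_depth=3))
        corrupted, _ = inject_defects(m, [
            DefectSpec(DefectKind.SHUFFLE_INDEX, seed=seed),
            DefectSpec(DefectKind.CHILD_BEFORE_PARENT, count=3, seed=seed + 1),
        ])
        fixed, _ = reindex(corrupted)
        # parents precede children and ids are 1..N
        assert [n.id for n in fixed.nodes] == list(range(1, len(fixed.nodes) + 1))
        pos = {n.id: i for i, n in enumerate(fixed.nodes)}
        assert all(n.parent_id == -1 or pos[n.parent_id] < pos[n.id] for n in fixed.nodes)
        # topology is graph-isomorphic to the input (networkx as the oracle)
        def graph(mm):
            g = nx.Graph()
            g.add_nodes_from(n.id for n in mm.nodes)
            g.add_edges_from((n.id, n.parent_id) for n in mm.nodes if n.parent_id != -1)
            return g
        assert nx.is_isomorphic(graph(corrupted), graph(fixed))

    def test_raises_on_dangling_parent(self):
        m = build([(1, 1, 0, 0, 0, 1, -1), (2, 3, 1, 0, 0, 1, 7)])
        with pytest.raises(ValueError):
            reindex(m)


class TestApplyCorrections:
    def test_clean_file_unchanged_under_all_flags(self):
        m = generate_morphology(GeneratorParams(seed=4))
        fixed, changes, issues = apply_corrections(m, ALL_FLAGS)
        assert changes == []
        assert issues == []
        assert fixed.nodes == m.nodes

    @pytest.mark.parametrize("seed", range(8))
    def test_idempotent_on_corrupted_fixtures(self, seed):
        m = generate_morphology(GeneratorParams(seed=seed))
        corrupted, _ = inject_defects(m, [
            DefectSpec(DefectKind.TYPE_SANDWICH, count=1, run_length=2, seed=seed),
            DefectSpec(DefectKind.ZERO_RADIUS, count=4, seed=seed + 1),
            DefectSpec(DefectKind.SHUFFLE_INDEX, seed=seed + 2),
        ])
        once, changes1, _ = apply_corrections(corrupted, ALL_FLAGS)
        twice, changes2, _ = apply_corrections(once, ALL_FLAGS)
        assert changes2 == []
        assert twice.nodes == once.nodes

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_of_nodes_and_geometry(self, seed):
        m = generate_morphology(GeneratorParams(seed=seed))
        corrupted, _ = inject_defects(
            m, [DefectSpec(DefectKind.TYPE_SANDWICH, count=2, run_length=3, seed=seed)])
        fixed, changes, _ = apply_corrections(
            corrupted, CorrectionConfig(fix_basal=True, fix_apic=True))
        assert len(fixed.nodes) == len(corrupted.nodes)
        assert [(n.id, n.x, n.y, n.z) for n in fixed.nodes] == \
               [(n.id, n.x, n.y, n.z) for n in corrupted.nodes]
        changed_ids = {c.node_id for c in changes}
        untouched = [n.id for n in fixed.nodes if n.id not in changed_ids]
        for nid in untouched:
            assert fixed.node(nid).type_code == corrupted.node(nid).type_code

    def test_change_record_requires_actual_change(self):
        with pytest.raises(ValueError):
            ChangeRecord("f", 1, "radius", 1.0, 1.0, "RADIUS_FROM_PARENT")
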