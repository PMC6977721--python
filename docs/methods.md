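# Methods

## The problem

Digitally reconstructed neurons are exchanged as SWC files: one compartment
per line with an integer index, a structure type code (0 undefined, 1 soma,
2 axon, 3 basal dendrite, 4 apical dendrite, ≥5 custom), x/y/z coordinates
and a radius in micrometres, and a parent index (−1 for the root). The format
has no schema enforcement, so corpora accumulate structural defects —
duplicate or non-sequential indices, dangling or cyclic parent references,
missing roots, files that do not start at the soma, zero radii, and
compartments typed as the wrong structure (e.g. a run of basal-typed nodes
embedded in an apical branch). `swcqc` detects all of these, applies
conservative rule-based corrections for user-selected structures, and
reports per-file morphometry, at directory scale.

## Parsing and serialization

The parser never raises on content. Every line is classified as header
(`#`), blank, or data; data lines with exactly seven numeric tokens become
nodes; lines with extra tokens keep the first seven with a warning; lines
with fewer tokens or uninterpretable values are excluded and reported with
their line number and raw text. Integer fields written as integer-valued
floats ("3.0") are coerced with a warning, a common exporter quirk;
fractional values reject the line. Duplicate ids keep the first occurrence.
Input accepts any run of spaces/tabs and LF or CRLF endings; output is
single-space separated with LF. Coordinates and radii serialize with
`repr`, the shortest decimal string that round-trips the double exactly, so
parse → write → parse is the identity field-for-field and outputs are
byte-stable across runs.

## Validation checks and severity

Issue codes: MISSING_FIELDS, EXTRA_FIELDS, BAD_NUMBER, DUPLICATE_ID,
NO_ROOT, MULTIPLE_ROOTS, NOT_SOMA_START, BAD_PARENT_REF, SELF_PARENT,
CHILD_BEFORE_PARENT, NON_SEQUENTIAL_IDS, CYCLE, ZERO_RADIUS,
STRUCTURE_MISCONNECTED, UNCORRECTABLE_STRUCTURE. Defects that break tree
semantics (no root, dangling/self parents, cycles, unparseable lines) are
ERROR; everything else is WARNING. "Incorrect indexing" is interpreted as
the union of duplicate ids, dangling parents, child-before-parent ordering,
cycles, and ids that are not 1..N in file order. Cycle detection uses
visitation marking along parent chains and is O(N) even on fully cyclic
input. The zero-radius test is exact equality with 0 — the defect in the
wild is a literal zero written by an editor, not a small number. Structure
membership: a node of structure S may attach to S or to the soma; soma
nodes may attach only to soma; roots, dangling parents and custom type
codes (≥5) are exempt. Multiple roots are tolerated with a warning and each
tree is processed.

## Correction rules

Corrections are type and radius edits only; nodes are never added, deleted
or moved, and every edit is logged as a ChangeRecord.

**Structure repair** for a selected structure S runs two phases to a fixed
point:

* *R2, sandwich absorption.* A maximal connected component of non-S,
  non-soma nodes whose attachment parent has type S and whose every path
  out of the component exits to an S-typed child (at least one exit; no
  leaf may terminate inside the component) is retyped to S. The
  double-flank requirement is what distinguishes an intrusion from a
  genuine subtree of another structure, which dangles and is left alone.
* *R1, membership.* A node of type S whose parent has another type P
  (P ≠ soma, P ≠ undefined) is retyped to P provided the subsequent nodes
  are correctly connected: it has no children, or all children already have
  type P, or all children continue the same-type chain and that chain
  provably terminates in P-typed nodes. Iterating retypes the head of a
  flanked run on each pass, so whole runs are absorbed.

Each phase only converts nodes toward a fixed target, so every pass
strictly shrinks the violation set and the iteration terminates in ≤ N
passes. Nodes still violating after both phases (e.g. children of mixed
types, or an undefined-typed parent) are reported UNCORRECTABLE_STRUCTURE
and never guessed at. Retyping never produces type 0. With multiple flags
the order is fixed — soma, axon, basal, apical — for determinism; reports
of uncorrectable nodes that a later phase resolves are dropped.

One interaction is worth knowing: when two intrusion runs of the same type
sit on one unbranched path, the host gap between them is itself flanked by
the intruder type, so R2 may briefly absorb it before R1 restores the whole
merged run. The final types are correct (the full tree returns to its
pristine typing in the recovery tests) but the change log can contain
paired edits for the gap nodes.

**Zero-radius repair** visits nodes parents-first and assigns each zero
radius the parent's current radius, so chains of zeros inherit the nearest
positive ancestor (verified against a brute-force ancestor-walk oracle).
Roots with radius 0 have no parent to copy and are reported instead. The
repair applies to all non-root nodes regardless of type, soma included.

**Reindexing** is opt-in (`--reindex`): a stable topological order
(original file order breaks ties) renumbered 1..N with parents remapped.
It is deliberately not bundled with the other fixes because ids are often
used as foreign keys by downstream tooling. It refuses dangling parents
and duplicate ids.

Files with ERROR-severity defects are copied through a batch unmodified
with their issues logged: a correction on a broken tree could silently
destroy data.

## Morphometry

Per file, one O(N) traversal computes: node count and counts by type, root
count, tips (no children), branch points (≥2 children), maximum branch
order (bifurcations on the root-to-node path, root = 0), total cable length
(sum of Euclidean parent distances, µm), bounding box, radius min/mean/max,
and maximum root-to-tip cable distance. Dangling-parent nodes count as
extra roots; distances use raw coordinates with no unit conversion. The
statistic set is an extension point — counts, cable length, topology and
extent cover what batch QC triage needs.

## Synthetic data generator

`generate_morphology` grows a valid single-root cell in the pyramidal
layout where intrusion defects are typically demonstrated: a short soma
chain, an axon with a 12-compartment initial segment, two basal trees and
an apical tree with a 14-compartment trunk. Subtrees grow by a seeded
branching process: per-compartment bifurcation probability 0.05, maximum
branch order 8 (the first three orders always bifurcate — real arbors
rarely terminate that close to the soma), inter-node spacing jittered
around 5 µm, directions random-walking with momentum, radii tapering ×0.8
per branch order from 1.2 µm (soma 3.6 µm). Defaults were chosen to emit
files around 55–60 KB (~1 400 nodes), the size of a typical single-neuron
reconstruction, so a 500-file directory is ~28–29 MB — the scale the batch
run is exercised at. Coordinates are rounded to 3 decimals (nm scale) and
radii to 4, as reconstruction tools emit, which keeps files compact while
still round-tripping exactly.

The injector corrupts a generated cell with seeded, parameterized defects:
type sandwiches (a run of 1–3 retyped nodes chosen from single-child chain
windows, flanked by the host type on both sides; multiple runs never share
flanks), zero radii, index shuffles, child-before-parent reorderings (the
chosen children's parents are never themselves moved, so violations cannot
cancel), dropped fields (returned as raw text, since a 6-token line cannot
live in the data model), root removal (the root is rewired to a descendant,
producing a no-root, cyclic file), and non-soma starts. Each spec has its
own seed stream, so adding a spec never perturbs another's output, and the
exact ground-truth edits are returned for scoring.

What the generator does *not* emulate: real reconstruction geometry
(tortuosity statistics, soma contours, realistic taper profiles),
multi-neuron files, or annotation-rich headers. Passing tests therefore
demonstrate the detection and repair logic on structurally realistic trees,
not fidelity to any particular biological dataset; on real corpora the
validator is the same code, but defect frequencies and co-occurrence will
differ.

## Batch processing

Files are discovered non-recursively, matched on the `.swc` extension
case-insensitively, and processed in lexicographic filename order. Outputs
go to a freshly created folder (`swc_batch_check_out` in the working
directory by default; `_1`, `_2`, … suffixes avoid ever overwriting), with
a single tab-separated error log (`error_log.txt`: file, line, severity or
rule, code, message, raw line; header comments record the command line and
timestamp). Statistics and the command echo go to stdout for piping. The
exit code is 0 only when every file is clean. Per-file results are
independent of the batch — verified by comparing solo and in-batch reports
— which makes parallelism a safe later addition.

## Problem sizes used in the test and acceptance runs

Detection and recovery rates are measured over 50 seeded files per defect
class; round-trip and morphometry-oracle agreement over 100 morphologies;
the batch run over 500 generated files (~29 MB). All complete in about two
minutes on one CPU.

## Known limitations

* Correction is rule-based and local; it cannot recover intrusions that
  are not flanked (a mis-typed terminal subtree is reported, not fixed).
* No geometric plausibility checks (segment-length outliers, soma shape).
* No NeuroML/HOC support, no unit conversion, no subdirectory recursion.
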