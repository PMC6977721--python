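# swcqc

Batch quality control for SWC neuron morphology files: structural
validation, rule-based correction, and per-file morphometry.

## Why

Digitally reconstructed neurons are shared as SWC files — one compartment
per line: index, structure type code (1 soma, 2 axon, 3 basal dendrite,
4 apical dendrite), x/y/z, radius (µm), and parent index (−1 for the root).
Nothing enforces the format, so public corpora and lab pipelines accumulate
defects that silently corrupt downstream simulation and morphometry:
duplicate or shuffled indices, dangling parents, missing roots, zero radii,
and compartments typed as the wrong structure (a run of basal-typed nodes
embedded in an apical branch, apical-typed nodes inside an axon, …).

`swcqc` is for anyone curating such files at scale. It detects every
defect class above, and — on request, per structure — repairs them using
the membership rule that a compartment of structure *S* may only connect
to *S* or to the soma. A wrongly typed node is retyped only when its
surroundings make the correct type unambiguous: a flanked "sandwich" run
inside a host structure is absorbed into the host, a stray node whose
parent and children agree takes their type, and anything ambiguous is
reported rather than guessed. Zero radii take the nearest positive
ancestor's radius; reindexing (opt-in) renumbers nodes 1..N with parents
first while preserving topology exactly. Every edit is logged, and a second
pass with the same flags is guaranteed to change nothing.

## Worked example

Generate two synthetic neurons with injected defects (a 2-node basal run
inside the apical trunk, plus two zero radii each), then validate and
correct them:

```
$ python -c "from swcqc import *; generate_fixture_directory('neurons', 2, seed=5, \
    specs=[DefectSpec(DefectKind.TYPE_SANDWICH, count=1, run_length=2), \
           DefectSpec(DefectKind.ZERO_RADIUS, count=2, seed=1)])"
$ swcqc --d neurons --basal --apic --rad
Command: swcqc --d neurons --basal --apic --rad
Output folder: .../swc_batch_check_out
File: neuron_0000.swc
  nodes: 1990  (soma: 3, axon: 388, basal dendrite: 821, apical dendrite: 778)
  roots: 1  tips: 111  branch points: 107  max branch order: 9
  total cable length: 9939.553 um  max root-to-tip path: 723.240 um
  radius (um) min/mean/max: 0.2013/0.4936/3.6000
  issues: 4  corrections: 4
File: neuron_0001.swc
  ...
Processed 2 file(s); 2 with issues; 8 correction(s) applied.
```

Each file's block reports its compartment counts by structure, tree
topology (tips, branch points, maximum branch order), total dendritic cable
and longest root-to-tip path in µm, and the radius range. The exit status
is 1 because issues were found (0 means a clean directory). Corrected files
land in a newly created `swc_batch_check_out/` folder alongside
`error_log.txt`, which names each defect and the data line containing it,
then each applied change:

```
neuron_0000.swc  524   WARNING  ZERO_RADIUS             node 522 has radius 0         522 3 -4.653 126.893 22.218 0.0 521
neuron_0000.swc  1457  WARNING  STRUCTURE_MISCONNECTED  basal dendrite node 1455 connects to apical dendrite parent 1454   1455 3 6.391 110.487 -149.084 0.3146 1454
neuron_0000.swc  -     CHANGE   MEMBERSHIP_RETYPE       node 1455: type_code 3 -> 4   -
```

Here node 1455 was one of the injected basal-typed intruders on the apical
trunk; with `--basal --apic` it is retyped back to apical (type 4), and the
zero-radius node 522 takes its parent's radius via `--rad`.

The same pipeline is available from Python — see `examples/` for short
scripts covering validation, correction, morphometry, synthetic generation
and batch runs:

```python
from swcqc import validate_text, apply_corrections, CorrectionConfig

morph, issues = validate_text(open("neuron.swc").read(), "neuron.swc")
fixed, changes, remaining = apply_corrections(
    morph, CorrectionConfig(fix_basal=True, fix_apic=True, fix_radius=True))
```

## CLI summary

`swcqc --d <dir>` (required) plus correction flags `--soma`, `--axon`,
`--basal`, `--apic`, `--rad`, `--reindex`; plumbing: `--out <dir>`,
`--tsv <path>` (stats as one row per file), `--quiet`. With no correction
flags the run is validation-only. `swcqc generate --n-files K --seed S
[--defects "TYPE_SANDWICH:count=1,run=2;ZERO_RADIUS:count=3"] --out <dir>`
emits reproducible fixture directories.

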