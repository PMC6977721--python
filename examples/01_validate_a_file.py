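"""Validate a single SWC file and list every structural defect found.

Builds a small defective file in memory: an axon-first record (the file
should start at a soma root), a dangling parent, and a zero radius.
"""

from swcqc import validate_text

TEXT = """\
# a deliberately broken reconstruction
1 2 0.0 0.0 0.0 0.5 -1
2 1 1.0 0.0 0.0 2.0 1
3 3 2.0 0.0 0.0 0.0 2
4 3 3.0 0.0 0.0 0.4 9
"""

morph, issues = validate_text(TEXT, "broken.swc")
print(f"{len(morph.nodes)} nodes parsed, {len(issues)} issue(s):\n")
for issue in issues:
    where = f"line {issue.line_number}" if issue.line_number else "file-level"
    print(f"  [{issue.severity.value:7}] {issue.code.value:24} {where}: {issue.message}")

# Each issue names the defect class, the offending line, and what is wrong —
# the same records the batch error log is built from.
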