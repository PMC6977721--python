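"""Directory-scale processing: validate, correct, and report on every SWC file.

For each file in the input directory (deterministic lexicographic order):
parse -> validate -> optionally correct -> write the (possibly corrected)
file into a newly created output folder.  All issues and changes accumulate
in a single tab-separated error log inside that folder; per-file statistics
and the invoking command line print to standard output so they can be piped
to a file for later troubleshooting.

Files whose tree structure is broken badly enough that a requested
correction would be unsafe (ERROR-severity issues: no root, dangling or
self parents, cycles, unparseable lines) are copied through unmodified with
their issues logged.  Per-file results are independent of the rest of the
batch, so processing a file alone or within any directory gives the same
report.
"""

from __future__ import annotations

import datetime
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, TextIO

from .correction import ChangeRecord, CorrectionConfig, apply_corrections
from .morphometry import MorphometrySummary, summarize
from .swc_io import parse_swc, read_directory, write_swc
from .validation import STRUCTURE_NAMES, Severity, ValidationIssue, has_blocking_errors, validate_file

__all__ = ["BatchReport", "FileResult", "process_directory", "DEFAULT_OUTPUT_DIR", "ERROR_LOG_NAME"]

DEFAULT_OUTPUT_DIR = "swc_batch_check_out"
ERROR_LOG_NAME = "error_log.txt"


@dataclass
class FileResult:
    """Everything produced for one input file."""

    path: str
    issues: list[ValidationIssue]
    changes: list[ChangeRecord]
    summary: MorphometrySummary
    corrected: bool  # corrections were requested and safely applied


@dataclass
class BatchReport:
    command_line: str
    files_processed: int = 0
    files_with_issues: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)
    changes: list[ChangeRecord] = field(default_factory=list)
    summaries: dict[str, MorphometrySummary] = field(default_factory=dict)
    output_dir: str = ""
    per_file: dict[str, FileResult] = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        """0 when every file is clean, 1 when any issue was found."""
        return 0 if not self.issues else 1


def _fresh_output_dir(base: Path) -> Path:
    """Create `base`, or `base_1`, `base_2`, ... — never overwrite."""
    candidate = base
    suffix = 0
    while candidate.exists():
        suffix += 1
        candidate = base.with_name(f"{base.name}_{suffix}")
    candidate.mkdir(parents=True)
    return candidate


def process_file(text: str, source_path: str, config: CorrectionConfig) -> tuple[FileResult, str]:
    """Validate and optionally correct one file; returns the result and the
    output text (corrected, or the original when correction is off/unsafe)."""
    morph, parse_issues = parse_swc(text, source_path)
    issues = validate_file(morph, parse_issues)
    correct = config.any_enabled and morph.nodes and not has_blocking_errors(issues)
    if correct:
        morph, changes, corr_issues = apply_corrections(morph, config)
        issues = issues + corr_issues
        out_text = write_swc(morph)
    else:
        changes = []
        out_text = text
    return FileResult(source_path, issues, changes, summarize(morph), bool(correct)), out_text


def _format_summary(name: str, s: MorphometrySummary) -> str:
    types = ", ".join(
        f"{STRUCTURE_NAMES.get(t, f'type {t}')}: {c}" for t, c in s.counts_by_type.items()
    )
    lines = [
        f"File: {name}",
        f"  nodes: {s.node_count}  ({types})",
        f"  roots: {s.root_count}  tips: {s.tip_count}  branch points: {s.branch_point_count}"
        f"  max branch order: {s.max_branch_order}",
        f"  total cable length: {s.total_length:.3f} um"
        f"  max root-to-tip path: {s.max_path_distance:.3f} um",
        f"  radius (um) min/mean/max: {s.radius_min:.4f}/{s.radius_mean:.4f}/{s.radius_max:.4f}",
    ]
    return "\n".join(lines)


_TSV_COLUMNS = [
    "file", "node_count", "root_count", "tip_count", "branch_point_count",
    "max_branch_order", "total_length_um", "max_path_distance_um",
    "radius_min_um", "radius_mean_um", "radius_max_um",
]


def _tsv_row(name: str, s: MorphometrySummary) -> str:
    return "\t".join(str(v) for v in [
        name, s.node_count, s.root_count, s.tip_count, s.branch_point_count,
        s.max_branch_order, f"{s.total_length:.6f}", f"{s.max_path_distance:.6f}",
        f"{s.radius_min:.6f}", f"{s.radius_mean:.6f}", f"{s.radius_max:.6f}",
    ])


def _log_lines(result: FileResult) -> list[str]:
    name = Path(result.path).name
    lines = []
    for i in result.issues:
        lines.append("\t".join([
            name,
            str(i.line_number) if i.line_number is not None else "-",
            i.severity.value,
            i.code.value,
            i.message,
            i.raw_line if i.raw_line is not None else "-",
        ]))
    for c in result.changes:
        lines.append("\t".join([
            name, "-", "CHANGE", c.rule,
            f"node {c.node_id}: {c.field} {c.old_value} -> {c.new_value}", "-",
        ]))
    return lines


def process_directory(
    input_dir: str | Path,
    config: CorrectionConfig = CorrectionConfig(),
    *,
    output_dir: Optional[str | Path] = None,
    command_line: Optional[str] = None,
    tsv_path: Optional[str | Path] = None,
    quiet: bool = False,
    stream: Optional[TextIO] = None,
) -> BatchReport:
    """Process every ``.swc`` file in *input_dir*; see the module docstring.

    ``output_dir`` overrides the default output folder name (created in the
    current working directory; a numeric suffix is added if it exists).
    ``tsv_path`` additionally writes one statistics row per file.  ``quiet``
    suppresses the stdout report.  Raises FileNotFoundError for a missing
    input directory.
    """
    stream = stream if stream is not None else sys.stdout
    cmd = command_line if command_line is not None else " ".join(sys.argv)
    files = read_directory(input_dir)
    out_dir = _fresh_output_dir(Path(output_dir) if output_dir else Path.cwd() / DEFAULT_OUTPUT_DIR)
    report = BatchReport(command_line=cmd, output_dir=str(out_dir))

    def emit(msg: str) -> None:
        if not quiet:
            print(msg, file=stream)

    emit(f"Command: {cmd}")
    emit(f"Output folder: {out_dir}")
    if not files:
        emit(f"Warning: no SWC files found in {input_dir}")

    log_lines: list[str] = []
    tsv_rows: list[str] = []
    for path, text in files:
        result, out_text = process_file(text, str(path), config)
        (out_dir / path.name).write_text(out_text)
        report.files_processed += 1
        if result.issues:
            report.files_with_issues += 1
        report.issues += result.issues
        report.changes += result.changes
        report.summaries[path.name] = result.summary
        report.per_file[path.name] = result
        log_lines += _log_lines(result)
        tsv_rows.append(_tsv_row(path.name, result.summary))
        emit(_format_summary(path.name, result.summary))
        if result.issues or result.changes:
            emit(f"  issues: {len(result.issues)}  corrections: {len(result.changes)}")

    timestamp = datetime.datetime.now().isoformat(timespec="seconds")
    header = [
        f"# command: {cmd}",
        f"# date: {timestamp}",
        "# file\tline\tseverity_or_rule\tcode\tmessage\traw_line",
    ]
    (out_dir / ERROR_LOG_NAME).write_text("\n".join(header + log_lines) + "\n")
    if tsv_path is not None:
        Path(tsv_path).write_text("\n".join(["\t".join(_TSV_COLUMNS)] + tsv_rows) + "\n")
    emit(f"Processed {report.files_processed} file(s); "
         f"{report.files_with_issues} with issues; "
         f"{len(report.changes)} correction(s) applied.")
    return report
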