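"""Generate reproducible synthetic SWC fixtures with injected defects.

The generator's defaults emulate a typical ~60 KB single-neuron file;
every file and every defect is fully determined by the seeds, so fixture
directories are bit-reproducible.
"""

import tempfile
from pathlib import Path

from swcqc import DefectKind, DefectSpec, generate_fixture_directory, validate_text

out = Path(tempfile.mkdtemp()) / "fixtures"
files = generate_fixture_directory(out, 5, seed=123, specs=[
    DefectSpec(DefectKind.SHUFFLE_INDEX),
    DefectSpec(DefectKind.ZERO_RADIUS, count=3, seed=1),
])

total = sum(f.stat().st_size for f in files)
print(f"wrote {len(files)} files, {total / 1e3:.0f} KB total, to {out}")
for f in files:
    _, issues = validate_text(f.read_text(), str(f))
    codes = sorted({i.code.value for i in issues})
    print(f"  {f.name}: {len(issues)} issues ({', '.join(codes)})")
# The same directories are available from the shell:
#   swcqc generate --n-files 5 --seed 123 --defects "SHUFFLE_INDEX;ZERO_RADIUS:count=3" --out fixtures
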