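"""Batch-render a grid of structures and align two code sets.

Generates a reproducible 45-code corpus, renders it as a column-major grid
(22 rows x 13 columns by default, so 45 codes fill columns 22/22/1), then
aligns two overlapping code files against their sorted superset so the
same structure lands in the same cell of every grid.
"""

import tempfile
from pathlib import Path

from nglycode import (
    FixtureSpec,
    SymbolStyle,
    align_code_sets,
    build_grid,
    random_codes,
    render_grid,
    write_code_file,
)

workdir = Path(tempfile.mkdtemp(prefix="nglycode-"))

codes = random_codes(FixtureSpec(seed=45, n=45))
grid = build_grid(codes)  # default 22 x 13, identifiers shown beneath
doc = render_grid(grid, SymbolStyle(magnification=0.4))
(workdir / "grid.svg").write_text(doc.to_svg(), encoding="utf-8")
print(f"grid: {grid.n_structures()} structures, "
      f"column occupancy {grid.column_occupancy()[:4]}...")

a, b = codes[:30], codes[20:]
write_code_file(workdir / "a.txt", a)
write_code_file(workdir / "b.txt", b)
superset, outs = align_code_sets(
    [workdir / "a.txt", workdir / "b.txt"], workdir / "aligned"
)
print(f"superset: {len(superset.read_text().splitlines())} lines")
for p in outs:
    lines = p.read_text().splitlines()
    print(f"  {p.name}: {sum(1 for l in lines if l)} codes, "
          f"{sum(1 for l in lines if not l)} blanks")
print(f"outputs in {workdir}")
# Each aligned file has one line per superset member (blank where that set
# lacks the code), so grids rendered from them are cell-by-cell comparable.
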