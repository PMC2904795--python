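"""Multi-structure grids and code-set alignment.

A code-list file holds one nine-digit identifier per line; blank lines are
significant (they become blank grid cells) and ``#`` comment lines are
skipped.  Grids are filled column-major — one column at a time, top to
bottom, starting at the left — with a default geometry of 22 rows by 13
columns (the drag-and-drop page size of the original display tool).

Set alignment turns two or more code files into directly comparable grids:
the superset of all codes is sorted numerically, and each input is rewritten
to the superset's length with blank lines where a code is absent, so the
same structure lands in the same cell in every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .codec import CodeError, GlycanCode, format_code, parse_code
from .render import Document, SymbolStyle, render_svg
from .structure import build_tree

logger = logging.getLogger(__name__)

__all__ = [
    "GridDocument",
    "GridOverflowError",
    "read_code_file",
    "write_code_file",
    "build_grid",
    "paginate",
    "render_grid",
    "align_codes",
    "align_code_sets",
    "DEFAULT_ROWS",
    "DEFAULT_COLS",
]

DEFAULT_ROWS = 22
DEFAULT_COLS = 13

Entry = GlycanCode | None  # None = blank cell


class GridOverflowError(ValueError):
    """More entries than rows x cols and paging not requested."""


def read_code_file(path: str | Path, *, strict: bool = False) -> list[Entry]:
    """Read a code-list file: one entry per line, blanks preserved.

    Invalid lines raise in strict mode; otherwise they are logged with
    their line number and read as blanks.
    """
    entries: list[Entry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if not stripped:
                entries.append(None)
                continue
            try:
                entries.append(parse_code(stripped))
            except CodeError as exc:
                if strict:
                    raise CodeError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("%s:%d: %s (treated as blank)", path, lineno, exc)
                entries.append(None)
    return entries


def write_code_file(path: str | Path, entries: Sequence[Entry]) -> None:
    """Inverse of :func:`read_code_file` (blank line per ``None``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(("" if e is None else format_code(e)) + "\n")


@dataclass
class GridDocument:
    """A rows x cols matrix of optional codes, filled column-major."""

    rows: int = DEFAULT_ROWS
    cols: int = DEFAULT_COLS
    show_codes: bool = True
    cells: list[list[Entry]] = field(default_factory=list)  # row-major

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    def cell(self, row: int, col: int) -> Entry:
        return self.cells[row][col]

    def column_occupancy(self) -> list[int]:
        """Non-blank cell count per column."""
        return [
            sum(1 for r in range(self.rows) if self.cells[r][c] is not None)
            for c in range(self.cols)
        ]

    def n_structures(self) -> int:
        return sum(self.column_occupancy())


def build_grid(
    entries: Sequence[Entry],
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    show_codes: bool = True,
) -> GridDocument:
    """Place entries column-major into a grid; overflow raises."""
    if len(entries) > rows * cols:
        raise GridOverflowError(
            f"{len(entries)} entries exceed the {rows}x{cols} grid "
            f"({rows * cols} cells); use paginate() for multiple pages"
        )
    cells: list[list[Entry]] = [[None] * cols for _ in range(rows)]
    for i, entry in enumerate(entries):
        col, row = divmod(i, rows)
        cells[row][col] = entry
    return GridDocument(rows, cols, show_codes, cells)


def paginate(
    entries: Sequence[Entry],
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    show_codes: bool = True,
) -> list[GridDocument]:
    """Split entries into as many grids as needed."""
    cap = rows * cols
    return [
        build_grid(entries[i : i + cap], rows, cols, show_codes)
        for i in range(0, max(len(entries), 1), cap)
    ]


def render_grid(grid: GridDocument, style: SymbolStyle | None = None) -> Document:
    """Render one grid page to a :class:`Document`.

    Every non-blank cell shows its structure (identifier printed beneath
    when ``show_codes``); cell size is uniform so aligned sets line up.
    """
    style = style or SymbolStyle()
    cell_docs: dict[tuple[int, int], Document] = {}
    cw = ch = 1.0
    for r in range(grid.rows):
        for c in range(grid.cols):
            entry = grid.cells[r][c]
            if entry is None:
                continue
            caption = format_code(entry) if grid.show_codes else None
            doc = render_svg(build_tree(entry), style, caption=caption)
            cell_docs[(r, c)] = doc
            cw = max(cw, doc.width)
            ch = max(ch, doc.height)
    page = Document(cw * grid.cols, ch * grid.rows)
    page.merged_from(
        [(doc, c * cw, r * ch) for (r, c), doc in sorted(cell_docs.items())]
    )
    return page


def align_codes(code_sets: Sequence[Sequence[Entry]]) -> tuple[list[GlycanCode], list[list[Entry]]]:
    """Align two or more code collections against their common superset.

    Returns ``(superset, aligned)`` where the superset is the numerically
    sorted union of all codes and each aligned list has one slot per
    superset member — the code if that input contains it, else ``None``.
    Blanks in the inputs are ignored; duplicates within one input collapse
    to a single membership (with a logged warning).
    """
    if len(code_sets) < 2:
        raise ValueError("alignment needs at least two code sets")
    memberships: list[set[GlycanCode]] = []
    for i, entries in enumerate(code_sets):
        codes = [e for e in entries if e is not None]
        uniq = set(codes)
        if len(uniq) < len(codes):
            dupes = sorted(
                {format_code(c) for c in codes if codes.count(c) > 1}
            )
            logger.warning("set %d: duplicate codes collapsed: %s", i + 1,
                           ", ".join(dupes))
        memberships.append(uniq)
    superset = sorted(set().union(*memberships), key=int)
    aligned = [
        [code if code in members else None for code in superset]
        for members in memberships
    ]
    return superset, aligned


def align_code_sets(
    files: Sequence[str | Path], out_dir: str | Path
) -> tuple[Path, list[Path]]:
    """File-level alignment: read each input, align, write one output per
    input plus the superset file into *out_dir*.  Returns the paths."""
    paths = [Path(p) for p in files]
    if len(paths) < 2:
        raise ValueError("alignment needs at least two input files")
    code_sets = [read_code_file(p) for p in paths]
    superset, aligned = align_codes(code_sets)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    superset_path = out / "superset.txt"
    write_code_file(superset_path, superset)
    out_paths = []
    for p, entries in zip(paths, aligned):
        op = out / f"{p.stem}.aligned{p.suffix or '.txt'}"
        write_code_file(op, entries)
        out_paths.append(op)
    return superset_path, out_paths
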