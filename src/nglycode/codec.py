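"""Nine-digit mammalian N-glycan identifier codec.

Every N-glycan in this encoding is built on the invariant trimannosyl core
(Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ1-Asn) and is described by nine
decimal digits:

==== ======= ==========================================================
digit allowed meaning
==== ======= ==========================================================
1    3-6     total number of mannose residues, core included
2    0/1     core fucose (α1-6 on the reducing-end GlcNAc)
3    0/1     bisecting GlcNAc (β1-4 on the β-mannose)
4-7  0-6     extension level of branches 1-4 (see below)
8    0-8     number of galactose residues — derived from digits 4-7
9    0-4     number of N-acetylneuraminic acid residues — derived
==== ======= ==========================================================

Branches attach to the two exposed core mannoses: branch 1 (β1-2) and
branch 2 (β1-4) on the "lower" α1-3 mannose; branch 3 (β1-2) and branch 4
(β1-6) on the "upper" α1-6 mannose.  A branch's single-digit extension
level enumerates how far it has been elaborated:

    0  (absent)
    1  GlcNAc
    2  Galβ1-4GlcNAc                       (LacNAc)
    3  NeuAcα2-3Galβ1-4GlcNAc              (sialylated LacNAc)
    4  GlcNAcβ1-3Galβ1-4GlcNAc             (repeat started)
    5  Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAc      (one LacNAc repeat)
    6  NeuAcα2-3Gal...                     (sialylated repeat)

Digits 8 and 9 are therefore never free: they are recomputed from the four
branch levels whenever the first seven digits change, and any supplied
values are ignored (or, in strict mode, must agree).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GlycanCode",
    "CodeError",
    "ParseError",
    "ValidationError",
    "BRANCH_CHAINS",
    "GAL_INCREMENT",
    "GLCNAC_INCREMENT",
    "NEUAC_INCREMENT",
    "BRANCH_LINKAGES",
    "parse_code",
    "format_code",
    "compute_composition",
    "extract_codes_from_text",
    "classify",
    "is_core_only",
    "all_codes",
]


class CodeError(ValueError):
    """Base class for identifier errors."""


class ParseError(CodeError):
    """The text is not a syntactically well-formed identifier."""


class ValidationError(CodeError):
    """A digit is outside its allowed range (or digits 8-9 disagree in
    strict mode)."""


# Per-level branch chains, grown outward from the core mannose.  Each step
# is (monosaccharide, anomer, parent linkage position).  A branch's first
# GlcNAc takes its position from the branch slot (BRANCH_LINKAGES); every
# later step has a fixed enzyme-determined linkage: Gal is always β1-4 on
# GlcNAc, NeuAc always α2-3 on Gal, the repeat GlcNAc always β1-3 on Gal.
_GN = ("GlcNAc", "b", None)  # position filled in per branch slot
_GAL = ("Gal", "b", 4)
_SIA = ("NeuAc", "a", 3)
_RGN = ("GlcNAc", "b", 3)

BRANCH_CHAINS: tuple[tuple[tuple[str, str, int | None], ...], ...] = (
    (),
    (_GN,),
    (_GN, _GAL),
    (_GN, _GAL, _SIA),
    (_GN, _GAL, _RGN),
    (_GN, _GAL, _RGN, _GAL),
    (_GN, _GAL, _RGN, _GAL, _SIA),
)

GAL_INCREMENT = (0, 0, 1, 1, 1, 2, 2)
GLCNAC_INCREMENT = (0, 1, 1, 1, 2, 2, 2)
NEUAC_INCREMENT = (0, 0, 0, 1, 0, 0, 1)

#: (core mannose arm, linkage position of the branch-initiating GlcNAc)
#: for branches 1..4.
BRANCH_LINKAGES = (("a3", 2), ("a3", 4), ("a6", 2), ("a6", 6))

_MAN_RANGE = range(3, 7)
_LEVEL_RANGE = range(0, 7)


def compute_composition(branch_levels: Sequence[int]) -> tuple[int, int]:
    """Galactose and NeuAc totals implied by four branch extension levels.

    These are digits 8 and 9 of the identifier; they are always derived.
    """
    levels = tuple(branch_levels)
    if len(levels) != 4:
        raise ValidationError(f"expected 4 branch levels, got {len(levels)}")
    for i, lv in enumerate(levels, start=1):
        if lv not in _LEVEL_RANGE:
            raise ValidationError(f"branch {i} level {lv} outside 0-6")
    gal = sum(GAL_INCREMENT[lv] for lv in levels)
    neuac = sum(NEUAC_INCREMENT[lv] for lv in levels)
    return gal, neuac


@dataclass(frozen=True, order=True)
class GlycanCode:
    """A validated nine-digit identifier.

    ``gal_count`` and ``neuac_count`` (digits 8-9) are always consistent
    with ``branch_levels``; the constructor recomputes and checks them.
    """

    man_count: int
    core_fucose: int
    bisecting_glcnac: int
    branch_levels: tuple[int, int, int, int]
    gal_count: int
    neuac_count: int

    def __post_init__(self) -> None:
        if self.man_count not in _MAN_RANGE:
            raise ValidationError(
                f"digit 1 (mannose count) is {self.man_count}, allowed 3-6"
            )
        if self.core_fucose not in (0, 1):
            raise ValidationError(
                f"digit 2 (core fucose) is {self.core_fucose}, allowed 0 or 1"
            )
        if self.bisecting_glcnac not in (0, 1):
            raise ValidationError(
                f"digit 3 (bisecting GlcNAc) is {self.bisecting_glcnac}, "
                "allowed 0 or 1"
            )
        object.__setattr__(self, "branch_levels", tuple(self.branch_levels))
        gal, neuac = compute_composition(self.branch_levels)
        if (self.gal_count, self.neuac_count) != (gal, neuac):
            raise ValidationError(
                f"digits 8-9 ({self.gal_count},{self.neuac_count}) disagree "
                f"with branch levels {self.branch_levels} -> ({gal},{neuac})"
            )

    @classmethod
    def from_digits(
        cls,
        man_count: int,
        core_fucose: int,
        bisecting_glcnac: int,
        branch_levels: Sequence[int],
    ) -> "GlycanCode":
        """Build a code from the seven free digits; digits 8-9 derived."""
        gal, neuac = compute_composition(branch_levels)
        return cls(
            man_count,
            core_fucose,
            bisecting_glcnac,
            tuple(branch_levels),
            gal,
            neuac,
        )

    @property
    def digits(self) -> tuple[int, ...]:
        return (
            self.man_count,
            self.core_fucose,
            self.bisecting_glcnac,
            *self.branch_levels,
            self.gal_count,
            self.neuac_count,
        )

    def __int__(self) -> int:
        return int(str(self))

    def __str__(self) -> str:
        return "".join(str(d) for d in self.digits)


_DIGIT_NAMES = {
    1: "mannose count",
    2: "core fucose",
    3: "bisecting GlcNAc",
    4: "branch 1 level",
    5: "branch 2 level",
    6: "branch 3 level",
    7: "branch 4 level",
}


def parse_code(text: str, *, strict: bool = False) -> GlycanCode:
    """Parse a 7- or 9-digit identifier string into a :class:`GlycanCode`.

    The string may have any number of flanking spaces and a single space
    between digits; no other characters are accepted.  Only the first seven
    digits determine the structure: supplied digits 8-9 are ignored and
    recomputed (a mismatch logs a warning, or raises in strict mode).
    """
    if not isinstance(text, str):
        raise ParseError(f"expected string, got {type(text).__name__}")
    s = text.strip(" ")
    if not s:
        raise ParseError("empty identifier")
    if re.search(r"  ", s):
        raise ParseError(f"multiple consecutive interior spaces in {text!r}")
    compact = s.replace(" ", "")
    if not compact.isdigit() or not compact.isascii():
        raise ParseError(
            f"identifier {text!r} contains characters other than digits "
            "and single spaces"
        )
    if len(compact) not in (7, 9):
        raise ParseError(
            f"identifier {text!r} has {len(compact)} digits, expected 7 or 9"
        )
    d = [int(ch) for ch in compact]
    code = GlycanCode.from_digits(d[0], d[1], d[2], tuple(d[3:7]))
    if len(d) == 9 and (d[7], d[8]) != (code.gal_count, code.neuac_count):
        msg = (
            f"digits 8-9 of {compact} recomputed as "
            f"{code.gal_count}{code.neuac_count} (supplied {d[7]}{d[8]} "
            "ignored)"
        )
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
    return code


def format_code(code: GlycanCode, *, spaced: bool = False) -> str:
    """Inverse of :func:`parse_code`: the nine-digit string form."""
    sep = " " if spaced else ""
    return sep.join(str(d) for d in code.digits)


def extract_codes_from_text(text: str) -> list[GlycanCode]:
    """Pull every valid identifier out of arbitrary text, in order.

    Candidate tokens are delimited by newlines, tabs, or runs of two or
    more spaces (a *single* interior space is a permitted digit separator).
    Tokens that fail to parse are skipped with a logged warning.
    """
    codes: list[GlycanCode] = []
    for line in text.splitlines():
        for token in re.split(r"\t|[ ]{2,}", line):
            token = token.strip(" ")
            if not token:
                continue
            try:
                codes.append(parse_code(token))
            except CodeError as exc:
                logger.warning("skipping token %r: %s", token, exc)
    return codes


def classify(code: GlycanCode) -> str:
    """Structural class: ``oligomannose``, ``hybrid`` or ``complex``.

    Mannose-only arms with extra mannoses are oligomannose; extra mannoses
    alongside at least one antenna make a hybrid; a Man3 core carrying
    antennae is complex.  The bare, unelaborated core is reported as
    complex (see :func:`is_core_only` for the qualifier).
    """
    has_branches = any(lv > 0 for lv in code.branch_levels)
    if code.man_count > 3:
        return "hybrid" if has_branches else "oligomannose"
    return "complex"


def is_core_only(code: GlycanCode) -> bool:
    """True for the unmodified trimannosyl core family (no antennae,
    no extra mannose): e.g. 300000000."""
    return code.man_count == 3 and not any(code.branch_levels)


def all_codes() -> Iterator[GlycanCode]:
    """All 4 x 2 x 2 x 7^4 = 38,416 valid identifiers, ascending."""
    for man in _MAN_RANGE:
        for fuc in (0, 1):
            for bis in (0, 1):
                for b1 in _LEVEL_RANGE:
                    for b2 in _LEVEL_RANGE:
                        for b3 in _LEVEL_RANGE:
                            for b4 in _LEVEL_RANGE:
                                yield GlycanCode.from_digits(
                                    man, fuc, bis, (b1, b2, b3, b4)
                                )
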