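"""GlycoBase-style abbreviations for nine-digit codes.

Complex structures are named by counting branch features:

* ``A`` — antennae: branches with extension level >= 1
* ``G`` — branches whose chain carries a terminal-region galactose
  (levels 2, 3, 5, 6)
* ``F`` — core fucose flag
* ``B`` — bisecting GlcNAc flag
* ``Lac`` — branches bearing an N-acetyllactosamine repeat (levels >= 4)
* ``S`` — total sialic-acid count (digit 9)

so 310333553 is A4G4FLac1S3.  The mapping is many-to-one: the abbreviation
fixes how many branches are sialylated but not *which*, so one name covers
every sialylation placement.  :func:`enumerate_codes` inverts the mapping
under a canonical constraint (repeat-bearing branches occupy the
highest-numbered branch positions), under which A4G4FLac1S3 expands to
exactly four identifiers.

Oligomannose structures are named ``M<n>`` (``M5`` for five mannoses) with
``F``/``B`` appended when present; hybrids, which the abbreviation scheme
was not designed for, are rendered as ``M<n>-<antenna tokens>`` and flagged
as an extension of the convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .codec import GlycanCode, all_codes, classify

__all__ = [
    "GlycoBaseName",
    "NameError_",
    "to_glycobase",
    "enumerate_codes",
    "is_canonical",
]


class NameError_(ValueError):
    """Malformed or internally inconsistent abbreviation."""


_GAL_LEVELS = frozenset({2, 3, 5, 6})

_NAME_RE = re.compile(
    r"^A(?P<A>\d)(?:G(?P<G>\d))?(?P<F>F)?(?P<B>B)?"
    r"(?:Lac(?P<Lac>\d))?(?:S(?P<S>\d))?$"
)


@dataclass(frozen=True)
class GlycoBaseName:
    """Parsed abbreviation for a complex-type structure."""

    antennae: int
    terminal_gal: int
    fucose: bool
    bisect: bool
    lac_repeats: int
    sialic: int

    def __post_init__(self) -> None:
        if not 0 <= self.antennae <= 4:
            raise NameError_(f"antenna count {self.antennae} outside 0-4")
        if self.terminal_gal > self.antennae:
            raise NameError_(
                f"G{self.terminal_gal} exceeds antenna count A{self.antennae}"
            )
        if self.lac_repeats > self.antennae:
            raise NameError_(
                f"Lac{self.lac_repeats} exceeds antenna count A{self.antennae}"
            )
        if self.sialic > self.terminal_gal:
            raise NameError_(
                f"S{self.sialic} exceeds galactosylated branches "
                f"G{self.terminal_gal}: every sialic acid caps a galactose"
            )

    def __str__(self) -> str:
        parts = [f"A{self.antennae}"]
        if self.terminal_gal:
            parts.append(f"G{self.terminal_gal}")
        if self.fucose:
            parts.append("F")
        if self.bisect:
            parts.append("B")
        if self.lac_repeats:
            parts.append(f"Lac{self.lac_repeats}")
        if self.sialic:
            parts.append(f"S{self.sialic}")
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "GlycoBaseName":
        m = _NAME_RE.match(text.strip())
        if not m:
            raise NameError_(f"cannot parse abbreviation {text!r}")
        g = m.groupdict()
        return cls(
            antennae=int(g["A"]),
            terminal_gal=int(g["G"] or 0),
            fucose=g["F"] is not None,
            bisect=g["B"] is not None,
            lac_repeats=int(g["Lac"] or 0),
            sialic=int(g["S"] or 0),
        )


def _complex_name(code: GlycanCode) -> GlycoBaseName:
    levels = code.branch_levels
    return GlycoBaseName(
        antennae=sum(1 for lv in levels if lv >= 1),
        terminal_gal=sum(1 for lv in levels if lv in _GAL_LEVELS),
        fucose=bool(code.core_fucose),
        bisect=bool(code.bisecting_glcnac),
        lac_repeats=sum(1 for lv in levels if lv >= 4),
        sialic=code.neuac_count,
    )


def to_glycobase(code: GlycanCode) -> str:
    """Abbreviation string for any valid code.

    Complex codes use the A/G/F/B/Lac/S tokens; oligomannose codes become
    ``M<n>`` (+F/+B); hybrids use the ``M<n>-...`` extension.
    """
    kind = classify(code)
    if kind == "complex":
        return str(_complex_name(code))
    prefix = f"M{code.man_count}"
    if code.core_fucose:
        prefix += "F"
    if code.bisecting_glcnac:
        prefix += "B"
    if kind == "oligomannose":
        return prefix
    # hybrid: mannose prefix joined to the antenna description (an
    # extension of the convention; F/B stay on the mannose prefix)
    levels = code.branch_levels
    tail = str(
        GlycoBaseName(
            antennae=sum(1 for lv in levels if lv >= 1),
            terminal_gal=sum(1 for lv in levels if lv in _GAL_LEVELS),
            fucose=False,
            bisect=False,
            lac_repeats=sum(1 for lv in levels if lv >= 4),
            sialic=code.neuac_count,
        )
    )
    return f"{prefix}-{tail}"


def is_canonical(code: GlycanCode) -> bool:
    """Canonical placement: LacNAc-repeat branches (levels >= 4) occupy the
    highest-numbered branch positions, branch 4 first."""
    levels = code.branch_levels
    n_lac = sum(1 for lv in levels if lv >= 4)
    if n_lac == 0:
        return True
    return all(lv >= 4 for lv in levels[4 - n_lac :])


def enumerate_codes(name: str | GlycoBaseName) -> list[GlycanCode]:
    """All canonical codes whose abbreviation equals *name*, ascending.

    Brute-force filter of the full 38,416-code space through
    :func:`to_glycobase` plus the canonical repeat-placement constraint.
    """
    if isinstance(name, GlycoBaseName):
        target = str(name)
    else:
        target = str(GlycoBaseName.parse(name)) if name.startswith("A") else name
    matches = [
        c for c in all_codes() if is_canonical(c) and to_glycobase(c) == target
    ]
    return sorted(matches, key=int)
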