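"""Expansion of a nine-digit code into an explicit residue/linkage tree.

The tree is rooted at the asparagine anchor (depth 0) and grows through the
chitobiose stem (GlcNAcβ1-Asn, GlcNAcβ1-4) to the β-mannose and the two
core arm mannoses, then out along each antenna.  Extra mannoses beyond the
core three follow the processing-intermediate topology:

* Man4: Man(α1-3) added on the α1-6 core mannose
* Man5: Man4 plus Man(α1-6) on the α1-6 core mannose
* Man6: Man5 plus Man(α1-2) on the α1-3 core mannose

(the choice matches the two mannosidase trimming activities in the enzyme
rule set: the α1-2 mannose is removed first, then the α1-3/α1-6 pair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

from .codec import (
    BRANCH_CHAINS,
    BRANCH_LINKAGES,
    GlycanCode,
)

logger = logging.getLogger(__name__)

__all__ = ["Residue", "GlycanTree", "build_tree", "to_condensed_text", "census"]

_ANOMER_GLYPH = {"a": "α", "b": "β", None: ""}


@dataclass
class Residue:
    """One node of the tree: a monosaccharide (or the Asn anchor)."""

    monosaccharide: str  # GlcNAc, Man, Gal, NeuAc, Fuc, or Asn
    anomer: str | None  # "a", "b", or None for Asn
    linkage_child_pos: int | str | None  # position on the parent ("N" = Asn)
    depth: int
    children: list["Residue"] = field(default_factory=list)

    def add(self, mono: str, anomer: str, pos: int | str) -> "Residue":
        child = Residue(mono, anomer, pos, self.depth + 1)
        self.children.append(child)
        return child

    @property
    def anomeric_carbon(self) -> int:
        # NeuAc links from C2, the aldoses from C1
        return 2 if self.monosaccharide == "NeuAc" else 1

    def linkage_text(self) -> str:
        """e.g. ``α1-3`` / ``β1-N``; empty for the Asn root."""
        if self.anomer is None:
            return ""
        pos = "" if self.linkage_child_pos == "N" else self.linkage_child_pos
        return f"{_ANOMER_GLYPH[self.anomer]}{self.anomeric_carbon}-{pos}"


@dataclass
class GlycanTree:
    """Rooted residue tree for one identifier."""

    root: Residue  # the Asn anchor
    code: GlycanCode

    def walk(self) -> Iterator[Residue]:
        """Pre-order traversal, root (Asn) first."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def residues(self) -> list[Residue]:
        """All sugar residues (everything but the Asn anchor)."""
        return [r for r in self.walk() if r.monosaccharide != "Asn"]

    def __len__(self) -> int:
        return sum(1 for _ in self.walk())

    def to_adjacency(self) -> str:
        """Tab-separated listing (child_id, parent_id, mono, anomer, pos)."""
        ids: dict[int, int] = {}
        lines = []
        parent_of: dict[int, Residue | None] = {id(self.root): None}
        for node in self.walk():
            ids[id(node)] = len(ids)
            for child in node.children:
                parent_of[id(child)] = node
        for node in self.walk():
            parent = parent_of[id(node)]
            lines.append(
                "\t".join(
                    (
                        str(ids[id(node)]),
                        str(ids[id(parent)]) if parent is not None else "-",
                        node.monosaccharide,
                        node.anomer or "-",
                        str(node.linkage_child_pos)
                        if node.linkage_child_pos is not None
                        else "-",
                    )
                )
            )
        return "\n".join(lines)


def build_tree(code: GlycanCode) -> GlycanTree:
    """Expand a validated code into its residue/linkage tree."""
    asn = Residue("Asn", None, None, 0)
    red_gn = asn.add("GlcNAc", "b", "N")  # reducing-end GlcNAc
    gn2 = red_gn.add("GlcNAc", "b", 4)
    beta_man = gn2.add("Man", "b", 4)
    arm = {
        "a3": beta_man.add("Man", "a", 3),  # "lower" arm
        "a6": beta_man.add("Man", "a", 6),  # "upper" arm
    }

    if code.core_fucose:
        red_gn.add("Fuc", "a", 6)
    if code.bisecting_glcnac:
        beta_man.add("GlcNAc", "b", 4)

    # extra mannoses: Man4/5 on the upper arm, Man6 adds α1-2 on the lower
    if code.man_count >= 4:
        arm["a6"].add("Man", "a", 3)
    if code.man_count >= 5:
        arm["a6"].add("Man", "a", 6)
    if code.man_count >= 6:
        arm["a3"].add("Man", "a", 2)

    for branch_idx, level in enumerate(code.branch_levels):
        if level == 0:
            continue
        arm_key, first_pos = BRANCH_LINKAGES[branch_idx]
        if code.man_count > 3 and arm_key == "a6":
            logger.warning(
                "code %s: branch %d occupies a position held by an extra "
                "mannose when the mannose count is %d; drawn anyway",
                code,
                branch_idx + 1,
                code.man_count,
            )
        node = arm[arm_key]
        for step_i, (mono, anomer, pos) in enumerate(BRANCH_CHAINS[level]):
            node = node.add(mono, anomer, first_pos if step_i == 0 else pos)

    return GlycanTree(asn, code)


def census(tree: GlycanTree) -> dict[str, int]:
    """Residue counts per monosaccharide (Asn anchor excluded)."""
    counts: dict[str, int] = {}
    for r in tree.residues():
        counts[r.monosaccharide] = counts.get(r.monosaccharide, 0) + 1
    return counts


def _serialize(node: Residue) -> str:
    children = sorted(node.children, key=lambda c: str(c.linkage_child_pos))
    parts = []
    for i, child in enumerate(children):
        text = _serialize(child)
        parts.append(text if i == 0 else f"({text})")
    own = node.monosaccharide + node.linkage_text()
    return "".join(parts) + own


def to_condensed_text(tree: GlycanTree) -> str:
    """Deterministic condensed linear serialization.

    Children of a branching residue appear in increasing linkage-position
    order; the first continues the backbone, the rest are parenthesized:
    the bare core reads ``Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ1-Asn``.
    """
    return _serialize(tree.root)
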