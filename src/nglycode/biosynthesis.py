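"""Single-enzyme transitions between nine-digit codes.

Eleven glycosyltransferase/mannosidase activities of the mammalian N-glycan
pathway are expressed as guarded single-digit code transformations: each
application adds or removes exactly one residue, changes exactly one of
digits 1-7, and leaves digits 8-9 to be recomputed.  The activities:

========== ======================= ==========================================
EC number  short name              effect on the code
========== ======================= ==========================================
2.4.1.38   GalT                    branch level 1 -> 2 or 4 -> 5 (adds Gal)
2.4.1.68   FucT8                   digit 2: 0 -> 1 (core fucose)
2.4.1.101  GnT-I                   branch 1: 0 -> 1
2.4.1.143  GnT-II                  branch 3: 0 -> 1
2.4.1.144  GnT-III                 digit 3: 0 -> 1 (bisecting GlcNAc)
2.4.1.145  GnT-IV                  branch 2: 0 -> 1
2.4.1.149  iGnT                    branch level 2 -> 4 (starts LacNAc repeat)
2.4.1.155  GnT-V                   branch 4: 0 -> 1
2.4.99.6   ST3                     branch level 2 -> 3 or 5 -> 6 (adds NeuAc)
3.2.1.113  Man-I                   digit 1: 6 -> 5 (trims the α1-2 mannose)
3.2.1.114  Man-II                  digit 1: 5 -> 4 and 4 -> 3 (one per step)
========== ======================= ==========================================

The EC table names activities but not substrate prerequisites; the
pathway-ordering guards used here (GnT-I before mannosidase II, antenna
initiation only on the trimmed Man3 core for GnT-II/IV/V, and the classical
branch dependencies) follow the canonical mammalian processing order.  Each
guard has a name and can be relaxed per call for users who want the bare
digit arithmetic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Collection, Iterable

from .codec import GlycanCode, format_code

__all__ = [
    "EnzymeRule",
    "Transition",
    "rule_set",
    "ORDERING_GUARDS",
    "successors",
    "predecessors",
    "reachable",
    "reachable_set",
    "transitions_tsv",
    "transitions_dot",
]

#: names of the relaxable pathway-ordering guards
ORDERING_GUARDS = (
    "gnt1_requires_trimming",  # GnT-I: mannose count <= 5
    "man2_requires_gnt1",      # Man-II: branch 1 already initiated
    "gnt2_requires_man3",      # GnT-II on the fully trimmed core
    "gnt4_requires_man3",
    "gnt4_requires_branch1",
    "gnt5_requires_man3",
    "gnt5_requires_branch3",
)


def _with_level(code: GlycanCode, branch: int, level: int) -> GlycanCode:
    levels = list(code.branch_levels)
    levels[branch] = level
    return GlycanCode.from_digits(
        code.man_count, code.core_fucose, code.bisecting_glcnac, levels
    )


def _with_man(code: GlycanCode, man: int) -> GlycanCode:
    return GlycanCode.from_digits(
        man, code.core_fucose, code.bisecting_glcnac, code.branch_levels
    )


@dataclass(frozen=True)
class EnzymeRule:
    """One EC-numbered activity as a guarded code transformation.

    ``sites(code)`` lists the applicable positions (branch indices, or
    ``(-1,)`` for a non-branch digit); ``apply(code, site)`` returns the
    product with digits 8-9 recomputed.  ``residue_delta`` is +1 for
    transferases and -1 for the mannosidase trimming steps.
    """

    ec_number: str
    name: str
    short: str
    residue_delta: int
    _sites: Callable[[GlycanCode], tuple[int, ...]]
    _apply: Callable[[GlycanCode, int], GlycanCode]

    def sites(self, code: GlycanCode) -> tuple[int, ...]:
        return self._sites(code)

    def applicable(self, code: GlycanCode) -> bool:
        return bool(self._sites(code))

    def apply(self, code: GlycanCode, site: int) -> GlycanCode:
        if site not in self._sites(code):
            raise ValueError(
                f"{self.short} not applicable to {format_code(code)} "
                f"at site {site}"
            )
        return self._apply(code, site)


@dataclass(frozen=True)
class Transition:
    rule: EnzymeRule
    site: int
    product: GlycanCode


def rule_set(relax: Collection[str] = ()) -> list[EnzymeRule]:
    """The eleven activities, optionally with named guards relaxed."""
    unknown = set(relax) - set(ORDERING_GUARDS)
    if unknown:
        raise ValueError(f"unknown guard name(s): {sorted(unknown)}")
    on = {g: g not in relax for g in ORDERING_GUARDS}

    def galt_sites(c: GlycanCode) -> tuple[int, ...]:
        return tuple(
            i for i, lv in enumerate(c.branch_levels) if lv in (1, 4)
        )

    def st3_sites(c: GlycanCode) -> tuple[int, ...]:
        return tuple(
            i for i, lv in enumerate(c.branch_levels) if lv in (2, 5)
        )

    def ignt_sites(c: GlycanCode) -> tuple[int, ...]:
        return tuple(i for i, lv in enumerate(c.branch_levels) if lv == 2)

    def bump(c: GlycanCode, i: int) -> GlycanCode:
        return _with_level(c, i, c.branch_levels[i] + 1)

    def ignt_apply(c: GlycanCode, i: int) -> GlycanCode:
        return _with_level(c, i, 4)

    def init_sites(branch: int, *preds: Callable[[GlycanCode], bool]):
        def sites(c: GlycanCode) -> tuple[int, ...]:
            if c.branch_levels[branch] != 0:
                return ()
            if not all(p(c) for p in preds):
                return ()
            return (branch,)

        return sites

    def flag_sites(getter: Callable[[GlycanCode], int]):
        def sites(c: GlycanCode) -> tuple[int, ...]:
            return () if getter(c) else (-1,)

        return sites

    guard = lambda name, pred: (pred if on[name] else (lambda c: True))  # noqa: E731

    rules = [
        EnzymeRule(
            "2.4.1.38",
            "β-N-acetylglucosaminylglycopeptide β-1,4-galactosyltransferase",
            "GalT",
            +1,
            galt_sites,
            bump,
        ),
        EnzymeRule(
            "2.4.1.68",
            "glycoprotein 6-α-L-fucosyltransferase",
            "FucT8",
            +1,
            flag_sites(lambda c: c.core_fucose),
            lambda c, i: GlycanCode.from_digits(
                c.man_count, 1, c.bisecting_glcnac, c.branch_levels
            ),
        ),
        EnzymeRule(
            "2.4.1.101",
            "α-1,3-mannosyl-glycoprotein 2-β-N-acetylglucosaminyltransferase",
            "GnT-I",
            +1,
            init_sites(
                0,
                guard("gnt1_requires_trimming", lambda c: c.man_count <= 5),
            ),
            bump,
        ),
        EnzymeRule(
            "2.4.1.143",
            "α-1,6-mannosyl-glycoprotein 2-β-N-acetylglucosaminyltransferase",
            "GnT-II",
            +1,
            init_sites(
                2, guard("gnt2_requires_man3", lambda c: c.man_count == 3)
            ),
            bump,
        ),
        EnzymeRule(
            "2.4.1.144",
            "β-1,4-mannosyl-glycoprotein 4-β-N-acetylglucosaminyltransferase",
            "GnT-III",
            +1,
            flag_sites(lambda c: c.bisecting_glcnac),
            lambda c, i: GlycanCode.from_digits(
                c.man_count, c.core_fucose, 1, c.branch_levels
            ),
        ),
        EnzymeRule(
            "2.4.1.145",
            "α-1,3-mannosyl-glycoprotein 4-β-N-acetylglucosaminyltransferase",
            "GnT-IV",
            +1,
            init_sites(
                1,
                guard("gnt4_requires_man3", lambda c: c.man_count == 3),
                guard("gnt4_requires_branch1", lambda c: c.branch_levels[0] >= 1),
            ),
            bump,
        ),
        EnzymeRule(
            "2.4.1.149",
            "N-acetyllactosaminide β-1,3-N-acetylglucosaminyltransferase",
            "iGnT",
            +1,
            ignt_sites,
            ignt_apply,
        ),
        EnzymeRule(
            "2.4.1.155",
            "α-1,6-mannosyl-glycoprotein 6-β-N-acetylglucosaminyltransferase",
            "GnT-V",
            +1,
            init_sites(
                3,
                guard("gnt5_requires_man3", lambda c: c.man_count == 3),
                guard("gnt5_requires_branch3", lambda c: c.branch_levels[2] >= 1),
            ),
            bump,
        ),
        EnzymeRule(
            "2.4.99.6",
            "N-acetyllactosaminide α-2,3-sialyltransferase",
            "ST3",
            +1,
            st3_sites,
            bump,
        ),
        EnzymeRule(
            "3.2.1.113",
            "mannosyl-oligosaccharide 1,2-α-mannosidase",
            "Man-I",
            -1,
            lambda c: (-1,) if c.man_count == 6 else (),
            lambda c, i: _with_man(c, 5),
        ),
        EnzymeRule(
            "3.2.1.114",
            "mannosyl-oligosaccharide 1,3-1,6-α-mannosidase",
            "Man-II",
            -1,
            lambda c: (
                (-1,)
                if c.man_count in (4, 5)
                and (not on["man2_requires_gnt1"] or c.branch_levels[0] >= 1)
                else ()
            ),
            lambda c, i: _with_man(c, c.man_count - 1),
        ),
    ]
    assert len(rules) == 11
    return rules


def successors(
    code: GlycanCode, rules: Iterable[EnzymeRule] | None = None
) -> list[Transition]:
    """Every (rule, site, product) applicable to *code*, in rule order."""
    out = []
    for rule in rules if rules is not None else rule_set():
        for site in rule.sites(code):
            out.append(Transition(rule, site, rule.apply(code, site)))
    return out


def predecessors(
    code: GlycanCode, rules: Iterable[EnzymeRule] | None = None
) -> list[Transition]:
    """Every (rule, site, source) with rule(source) -> *code*.

    Candidate sources are generated by inverting each rule's single-digit
    effect and validated by forward application.
    """
    rules = list(rules) if rules is not None else rule_set()
    out = []
    for rule in rules:
        for cand in _inverse_candidates(code, rule):
            for site in rule.sites(cand):
                if rule.apply(cand, site) == code:
                    out.append(Transition(rule, site, cand))
    # deduplicate (a rule can reach the code from one source via one site only,
    # but two rules' candidates may coincide per rule; keep stable order)
    seen = set()
    uniq = []
    for t in out:
        key = (t.rule.ec_number, t.site, t.product)
        if key not in seen:
            seen.add(key)
            uniq.append(t)
    return uniq


def _inverse_candidates(code: GlycanCode, rule: EnzymeRule) -> list[GlycanCode]:
    cands = []
    if rule.short in ("GalT", "ST3", "GnT-I", "GnT-II", "GnT-IV", "GnT-V"):
        for i, lv in enumerate(code.branch_levels):
            if lv >= 1:
                cands.append(_with_level(code, i, lv - 1))
    elif rule.short == "iGnT":
        for i, lv in enumerate(code.branch_levels):
            if lv == 4:
                cands.append(_with_level(code, i, 2))
    elif rule.short == "FucT8":
        if code.core_fucose:
            cands.append(
                GlycanCode.from_digits(
                    code.man_count, 0, code.bisecting_glcnac, code.branch_levels
                )
            )
    elif rule.short == "GnT-III":
        if code.bisecting_glcnac:
            cands.append(
                GlycanCode.from_digits(
                    code.man_count, code.core_fucose, 0, code.branch_levels
                )
            )
    elif rule.short in ("Man-I", "Man-II"):
        if code.man_count < 6:
            cands.append(_with_man(code, code.man_count + 1))
    return cands


def reachable(
    start: GlycanCode,
    goal: GlycanCode,
    rules: Iterable[EnzymeRule] | None = None,
) -> list[Transition] | None:
    """Shortest enzyme sequence from *start* to *goal* (BFS), or None."""
    rules = list(rules) if rules is not None else rule_set()
    if start == goal:
        return []
    came: dict[GlycanCode, tuple[GlycanCode, Transition]] = {}
    queue = deque([start])
    seen = {start}
    while queue:
        cur = queue.popleft()
        for t in successors(cur, rules):
            if t.product in seen:
                continue
            came[t.product] = (cur, t)
            if t.product == goal:
                path = [t]
                node = cur
                while node != start:
                    node, step = came[node]
                    path.append(step)
                return path[::-1]
            seen.add(t.product)
            queue.append(t.product)
    return None


def reachable_set(
    start: GlycanCode, rules: Iterable[EnzymeRule] | None = None
) -> set[GlycanCode]:
    """All codes reachable from *start* (start included)."""
    rules = list(rules) if rules is not None else rule_set()
    seen = {start}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for t in successors(cur, rules):
            if t.product not in seen:
                seen.add(t.product)
                queue.append(t.product)
    return seen


def transitions_tsv(code: GlycanCode, trans: Iterable[Transition]) -> str:
    """Tab-separated successor listing: ec_number, short name, product."""
    lines = [
        "\t".join((t.rule.ec_number, t.rule.short, format_code(t.product)))
        for t in trans
    ]
    return "\n".join(lines)


def transitions_dot(
    start: GlycanCode, rules: Iterable[EnzymeRule] | None = None
) -> str:
    """DOT digraph of the full reachability graph from *start*."""
    rules = list(rules) if rules is not None else rule_set()
    lines = ["digraph biosynthesis {", '  rankdir="LR";']
    for code in sorted(reachable_set(start, rules), key=int):
        for t in successors(code, rules):
            lines.append(
                f'  "{format_code(code)}" -> "{format_code(t.product)}"'
                f' [label="{t.rule.short}"];'
            )
    lines.append("}")
    return "\n".join(lines)
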