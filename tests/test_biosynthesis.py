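"""Enzyme rules: the eleven activities, successors, reachability."""

import pytest

from nglycode import (
    parse_code,
    predecessors,
    reachable,
    reachable_set,
    rule_set,
    successors,
)
from nglycode.biosynthesis import ORDERING_GUARDS, transitions_dot, transitions_tsv


@pytest.fixture(scope="module")
def rules():
    return rule_set()


def by_short(rules, short):
    return next(r for r in rules if r.short == short)


class TestRuleSet:
    def test_eleven_activities(self, rules):
        assert len(rules) == 11
        assert {r.ec_number for r in rules} == {
            "2.4.1.38", "2.4.1.68", "2.4.1.101", "2.4.1.143", "2.4.1.144",
            "2.4.1.145", "2.4.1.149", "2.4.1.155", "2.4.99.6",
            "3.2.1.113", "3.2.1.114",
        }

    def test_sialyltransferase_caps_a_lacnac(self, rules):
        """ST3 adds α2-3 NeuAc to a Gal-terminated branch: level 2 -> 3."""
        st3 = by_short(rules, "ST3")
        code = parse_code("300200010")
        (t,) = [
            st3.apply(code, s) for s in st3.sites(code)
        ]
        assert str(t) == "300300011"

    def test_st3_extends_lacnac_repeat(self, rules):
        st3 = by_short(rules, "ST3")
        code = parse_code("300500020")
        assert str(st3.apply(code, 0)) == "300600021"

    def test_mannosidase_guards(self, rules):
        man1 = by_short(rules, "Man-I")
        assert man1.applicable(parse_code("600000000"))
        assert not man1.applicable(parse_code("500000000"))
        man2 = by_short(rules, "Man-II")
        # requires the branch-1 GlcNAc placed first (processing order)
        assert not man2.applicable(parse_code("500000000"))
        assert man2.applicable(parse_code("500100000"))

    def test_relaxing_a_named_guard(self):
        relaxed = rule_set(relax=["man2_requires_gnt1"])
        assert by_short(relaxed, "Man-II").applicable(parse_code("500000000"))
        with pytest.raises(ValueError, match="unknown guard"):
            rule_set(relax=["no_such_guard"])
        assert len(ORDERING_GUARDS) == 7

    def test_residue_delta_signs(self, rules):
        deltas = {r.short: r.residue_delta for r in rules}
        assert deltas["Man-I"] == deltas["Man-II"] == -1
        assert all(d == 1 for s, d in deltas.items() if not s.startswith("Man"))


class TestSuccessors:
    def test_core_successors(self, rules):
        succ = {(t.rule.short, str(t.product)) for t in successors(
            parse_code("300000000"), rules)}
        assert ("FucT8", "310000000") in succ
        assert ("GnT-I", "300100000") in succ

    def test_fully_decorated_code(self, rules):
        """310333553: sialylated branches accept nothing further; the open
        positions are the bisect and sialylation of the repeat's Gal."""
        succ = successors(parse_code("310333553"), rules)
        shorts = sorted(t.rule.short for t in succ)
        assert shorts == ["GnT-III", "ST3"]
        st3_products = [str(t.product) for t in succ if t.rule.short == "ST3"]
        assert st3_products == ["310333654"]

    def test_closure_over_full_space(self, full_code_space, rules):
        """Every successor of every code is a valid code differing in
        exactly one of digits 1-7, with mannose monotone non-increasing
        and Gal/NeuAc non-decreasing."""
        for code in full_code_space:
            for t in successors(code, rules):
                p = t.product
                assert p != code
                changed = sum(
                    a != b for a, b in zip(code.digits[:7], p.digits[:7])
                )
                assert changed == 1
                assert p.man_count <= code.man_count
                assert p.gal_count >= code.gal_count
                assert p.neuac_count >= code.neuac_count

    def test_no_rule_applies_twice_at_one_site(self, full_code_space, rules):
        """Guards reference from-values, so the (rule, site) pair consumed
        by a step is never immediately applicable to its own product —
        except Man-II, which is modelled as two single-residue trimming
        steps (5 -> 4 -> 3) and so chains by design."""
        for code in full_code_space[::97]:
            for t in successors(code, rules):
                if t.rule.short == "Man-II":
                    continue
                assert t.site not in t.rule.sites(t.product)

    def test_tsv_listing(self, rules):
        code = parse_code("300000000")
        tsv = transitions_tsv(code, successors(code, rules))
        rows = [r.split("\t") for r in tsv.splitlines()]
        assert ["2.4.1.68", "FucT8", "310000000"] in rows


class TestPredecessors:
    def test_inverse_of_successors(self, rules):
        for text in ("310333553", "300100000", "500100000", "310033333"):
            code = parse_code(text)
            for t in successors(code, rules):
                back = predecessors(t.product, rules)
                assert any(
                    b.rule.ec_number == t.rule.ec_number and b.product == code
                    for b in back
                )

    def test_branch_initiated_code_predecessors(self, rules):
        # 300100000 arises from GnT-I on the core or Man-II on 400100000;
        # the bare core itself has no predecessor under the ordering
        # guards (Man-II demands the branch-1 GlcNAc already placed)
        preds = predecessors(parse_code("300100000"), rules)
        assert {t.rule.short for t in preds} == {"GnT-I", "Man-II"}
        assert predecessors(parse_code("300000000"), rules) == []


class TestReachability:
    def test_high_mannose_to_tetraantennary(self, rules):
        path = reachable(
            parse_code("600000000"), parse_code("310333553"), rules
        )
        assert path is not None
        # 17 single-residue steps: 3 mannose trims + 14 additions,
        # net +11 residues (8 sugars in Man6 -> 19 in the product)
        assert len(path) == 17
        assert sum(t.rule.residue_delta for t in path) == 11

    def test_self_path_is_empty(self, rules):
        assert reachable(parse_code("300000000"), parse_code("300000000"),
                         rules) == []

    def test_no_mannose_adding_rule(self, rules):
        assert reachable(
            parse_code("300000000"), parse_code("600000000"), rules
        ) is None

    def test_reachable_set_is_closed_and_valid(self, rules):
        seen = reachable_set(parse_code("600000000"), rules)
        assert parse_code("600000000") in seen
        assert parse_code("310333553") in seen
        # the bare Man3 core is NOT an intermediate: trimming below Man5
        # requires the branch-1 GlcNAc already in place
        assert parse_code("300000000") not in seen
        assert parse_code("300100000") in seen
        # closure: every successor of a member is a member
        for code in seen:
            for t in successors(code, rules):
                assert t.product in seen

    def test_dot_export(self, rules):
        dot = transitions_dot(parse_code("500100000"), rules)
        assert dot.startswith("digraph") and '"500100000"' in dot
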