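"""Walk the single-enzyme reaction network between identifiers.

Lists the glycosyltransferase/mannosidase steps applicable to a code and
finds the shortest enzymatic route from the Man6 high-mannose precursor to
a fully decorated tetraantennary product.
"""

from nglycode import parse_code, reachable, successors

core = parse_code("300000000")
print(f"successors of {core}:")
for t in successors(core):
    print(f"  {t.rule.ec_number:10} {t.rule.short:8} -> {t.product}")

start, goal = parse_code("600000000"), parse_code("310333553")
path = reachable(start, goal)
print(f"\n{start} -> {goal} in {len(path)} single-residue steps:")
print("  " + " -> ".join(t.rule.short for t in path))
# Three mannosidase trims and fourteen residue additions; mannose count
# only ever decreases, so the reverse route does not exist.
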