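"""Decode nine-digit identifiers into explicit structures.

Parses a handful of identifiers, prints each one's residue census,
structural class and condensed text. The last two digits of a code are
always derived from the branch levels, so a wrong tail is corrected.
"""

from nglycode import build_tree, census, classify, parse_code, to_condensed_text

for text in ["300000000", "3 1 0 0 3 3 3 3 3", "310333599", "500000000"]:
    code = parse_code(text)  # digits 8-9 recomputed from digits 4-7
    tree = build_tree(code)
    print(f"input {text!r:24} -> {code}  [{classify(code)}]")
    print(f"  census: {census(tree)}")
    print(f"  {to_condensed_text(tree)}")

# The census always reproduces digits 1, 2, 8 and 9 of the identifier:
# e.g. 310333599 normalizes to 310333553 (5 Gal, 3 NeuAc) because each
# branch level contributes a fixed number of Gal/GlcNAc/NeuAc residues.
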