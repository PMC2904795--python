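"""Convert codes to GlycoBase-style abbreviations and back.

An abbreviation such as A4G4FLac1S3 (4 antennae, 4 galactosylated, core
fucose, one LacNAc repeat, 3 sialic acids) fixes the composition but not
which branches carry the sialic acids, so several identifiers share it.
"""

from nglycode import enumerate_codes, parse_code, to_glycobase

for text in ["310333553", "310033333", "500000000", "300000000"]:
    code = parse_code(text)
    print(f"{code} -> {to_glycobase(code)}")

print()
name = "A4G4FLac1S3"
codes = enumerate_codes(name)
print(f"{name} covers {len(codes)} identifiers:")
for c in codes:
    print(f"  {c}")
# The four codes differ only in where the three sialic acids sit among
# the four antennae (the LacNAc repeat is canonically on branch 4).
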