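# nglycode

A Python toolkit for the nine-digit numeric identifier system used to
encode mammalian *N*-glycans — the asparagine-linked oligosaccharides of
glycoproteins, as found in CHO and other mammalian expression systems. It
is aimed at glycobiologists, systems biologists and bioprocess engineers
who work with these compact codes and need to validate them, name them,
draw them, compare sets of them, or reason about the enzymatic steps that
interconvert them.

## The encoding

Every structure is built on the invariant trimannosyl core
Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ1-Asn and is described by nine
decimal digits:

| digit | range | meaning |
|-------|-------|---------|
| 1 | 3–6 | mannose residues (core included) |
| 2 | 0/1 | core fucose (α1-6 on the reducing GlcNAc) |
| 3 | 0/1 | bisecting GlcNAc (β1-4 on the β-Man) |
| 4–7 | 0–6 | extension level of branches 1–4 |
| 8 | 0–8 | galactose count — **derived** from digits 4–7 |
| 9 | 0–4 | *N*-acetylneuraminic acid count — **derived** |

Branches 1/2 attach β1-2/β1-4 to the α1-3 core mannose and branches 3/4
attach β1-2/β1-6 to the α1-6 mannose. A branch's level enumerates its
elaboration: 1 = GlcNAc, 2 = Galβ1-4GlcNAc, 3 adds α2-3 NeuAc, 4–6 repeat
the series on a β1-3-linked LacNAc unit. Digits 8–9 are recomputed
whenever digits 1–7 change; seven digits therefore specify a structure
uniquely and supplied trailing digits are ignored (or rejected in strict
mode).

The package decodes identifiers into explicit residue/linkage trees,
interconverts with GlycoBase-style abbreviations (`310333553` ⇄
`A4G4FLac1S3`), renders CFG colour / CFG black-and-white / Oxford-style
symbol diagrams to SVG, PNG, JPEG and BMP, batch-renders column-major
grids of structures, aligns code sets against their sorted superset for
cell-by-cell visual comparison, and expresses eleven EC-numbered
glycosyltransferase/mannosidase activities as guarded single-digit code
transitions with successor/predecessor enumeration and shortest-path
search.

## Worked example

```python
>>> from nglycode import parse_code, to_glycobase, enumerate_codes, census, build_tree
>>> code = parse_code("3 1 0 0 3 3 3 3 3")   # single spaces permitted
>>> str(code)
'310033333'
>>> census(build_tree(code))
{'GlcNAc': 5, 'Man': 3, 'Gal': 3, 'NeuAc': 3, 'Fuc': 1}
>>> to_glycobase(code)
'A3G3FS3'
>>> [str(c) for c in enumerate_codes("A4G4FLac1S3")]
['310233653', '310323653', '310332653', '310333553']
```

The census reproduces digits 1, 2, 8 and 9 of the identifier — three
mannoses, a core fucose, three galactoses, three sialic acids — and the
abbreviation `A4G4FLac1S3` expands to exactly the four identifiers that
differ in where the three sialic acids sit among the four antennae.

From the shell:

```sh
nglycode validate "310333599"         # -> 310333553  (corrected ...)
nglycode draw 310333553 -o glycan.svg # prints: A4G4FLac1S3  complex
nglycode grid codes.txt -o grid.svg   # 22x13 column-major page
nglycode align a.txt b.txt -o aligned/
nglycode reactions 300000000          # EC-numbered successor listing
nglycode enumerate A4G4FLac1S3
```

The `examples/` directory holds one short narrative script per
capability; each prints what it computes and what the numbers mean.

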