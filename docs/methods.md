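# Methods

## The encoding model

A nine-digit identifier describes one mammalian *N*-glycan as deviations
from the invariant trimannosyl core. The model's assumptions are those of
the encoding itself: at most four antennae (two per core mannose arm), a
single optional core fucose (α1-6 on the reducing GlcNAc), a single
optional bisecting GlcNAc, sialylation exclusively as α2-3 NeuAc on
galactose, and at most one LacNAc repeat per branch. Structures outside
these assumptions (Neu5Gc capping, polyfucosylation, longer poly-LacNAc,
pentaantennary or plant-type residues) are deliberately not expressible.

Digits 8 and 9 are projections of digits 4–7. Each branch level `ℓ`
contributes fixed residue increments:

    gal_increment    = (0, 0, 1, 1, 1, 2, 2)
    glcnac_increment = (0, 1, 1, 1, 2, 2, 2)
    neuac_increment  = (0, 0, 0, 1, 0, 0, 1)    # levels 3 and 6 only

so over all 7⁴ = 2,401 branch combinations the galactose count spans 0–8
and the sialic-acid count 0–4, which is exactly the printed range of the
two digits. The codec enforces digit ranges only; biologically
implausible but encodable digit patterns (e.g. branch 2 occupied while
branch 1 is empty) are accepted, because the system is display-oriented
and such codes appear in practice.

### Parsing rules

7- or 9-digit strings are accepted, optionally with a single space
between digits and any number of flanking spaces; any other character,
or a run of two or more interior spaces, is rejected. Supplied digits
8–9 are ignored and recomputed (warn-and-correct); `strict=True` turns a
mismatch into an error. Free-text extraction splits candidates on
newlines, tabs and runs of ≥2 spaces, treating a single interior space
as a digit separator, and skips invalid tokens with a logged warning.

### Classification

`oligomannose` = extra mannoses and no antennae; `hybrid` = extra
mannoses plus at least one antenna; `complex` = Man3 core with antennae.
The encoding names these classes without fixing a decision rule, so the
standard glycobiology definitions above are used; the bare core
(300000000 family) is classed complex with a core-only qualifier
available via `is_core_only`.

## Tree expansion

Extra mannoses beyond the core three follow the processing-intermediate
topology: Man4 adds Man(α1-3) on the α1-6 core mannose, Man5 adds
Man(α1-6) there too, Man6 adds Man(α1-2) on the α1-3 mannose. The choice
mirrors the two mannosidase activities in the rule set (the α1-2 mannose
is trimmed first) and affects rendering only — no digit arithmetic
depends on it. Branches 3/4 combined with extra mannoses draw a warning,
since those positions are occupied in real processing intermediates.

Condensed-text serialization lists children of a branching residue in
increasing linkage-position order, first child bare and the rest
parenthesized — `Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ1-Asn` — which
is deterministic and injective over the full 38,416-code space (verified
exhaustively in the tests).

## Abbreviations and enumeration

For complex codes, `A` counts branches with level ≥ 1, `G` branches
whose terminal region carries a galactose (levels 2, 3, 5, 6), `Lac`
branches with a repeat (level ≥ 4), and `S` is the sialic-acid total;
zero tokens are omitted. The inverse mapping is canonicalized by placing
repeat-bearing branches at the highest-numbered branch positions
(branch 4 first): under that convention — and only under it —
`A4G4FLac1S3` expands to exactly four identifiers, one per sialylation
placement, and the name → code-set mapping partitions the canonical
complex space. Oligomannose codes are written `M<n>` (+`F`/`B`); hybrid
codes use an `M<n>-<antenna tokens>` form that extends the convention
(the abbreviation scheme was defined for complex structures only).

## Rendering

Column = tree depth, Asn rightmost, fixed horizontal spacing
(55 px · magnification); vertical positions by post-order subtree
centering with the α1-6 arm above the α1-3 arm and, within an arm, the
higher linkage position on top (branch 4 topmost, as in conventional
tetraantennary figures). Core fucose hangs below the reducing GlcNAc;
the bisecting GlcNAc sits on the β-mannose axis between the arms. With
the default constants (45 px row spacing, 22 px symbols) no two symbol
boxes overlap for any code; the tests check this on representative
worst cases. The linkage pen width is linear in magnification with a
1 px floor; all geometry scales linearly with magnification.

CFG colours are the published SNFG hex values (GlcNAc `#0072BC`, Man
`#00A651`, Gal `#FFD400`, NeuAc `#A54399`, Fuc `#ED1C24`). The
black-and-white set keeps the CFG shapes and distinguishes residues by
fill (solid/open/grey). The Oxford-style set draws hexoses as hexagons
with solid fill marking N-acetylated residues; only the symbol
vocabulary is implemented, not the Oxford linkage-angle system. Drawing
goes through an internal primitive list (shapes, lines, text) serialized
to SVG 1.1 and rasterized identically through Pillow to PNG/JPEG/BMP, so
vector and raster outputs are pixel-dimension consistent
(raster size = canvas × scale).

## Grids and alignment

Grids fill column-major (top to bottom, left to right) with a default
geometry of 22 rows × 13 columns; blank input lines become blank cells
at the same position. Overflow raises by default; `paginate` emits
multiple pages instead (scrolling single windows are out of scope).
Alignment uses set semantics: duplicates within one input collapse with
a warning, the superset is sorted by integer value of the nine-digit
string, and every output file has one line per superset member. Cell
size within a rendered grid page is uniform (the maximum over its
cells), so aligned pages are comparable cell-by-cell.

## Enzyme rules

Eleven EC-numbered activities are guarded single-digit transitions, each
adding or removing exactly one residue; the 5→4 and 4→3 mannose trims
are separate steps of the same mannosidase so the one-residue-per-step
invariant holds (that rule is the only one that can fire twice in
succession at the same site). The EC list itself carries no substrate
prerequisites, so pathway-ordering guards encode the canonical mammalian
processing order: GnT-I requires mannose ≤ 5; mannosidase II requires
the branch-1 GlcNAc; GnT-II/IV/V require the trimmed Man3 core; GnT-IV
requires branch 1 and GnT-V branch 3. Each guard is a named flag
(`ORDERING_GUARDS`) that can be relaxed per call, reducing the rules to
bare digit arithmetic. A consequence worth noting: the bare Man3 core is
not reachable from Man6 under the default guards (trimming below Man5
happens only after GnT-I), which matches the biological pathway.
Reachability uses breadth-first search over successor states; the full
reachable set from 600000000 has 7,280 members and closes in under a
second.

## Synthetic corpora

The fixture generator samples codes uniformly over the digit space with
rejection to hit a requested oligomannose/hybrid/complex mix
(largest-remainder apportionment keeps realized proportions within
rounding of the request) and is fully determined by its seed. Generated
corpora emulate only the *combinatorics* of valid codes — they carry no
information about which structures co-occur in real glycoprofiles, so
passing batch/alignment tests demonstrates correct file and grid
mechanics, not biological realism of the sets. The worked-example corpus
(`reference_corpus`) holds the six identifiers used throughout the
documentation.

## Numerical and testing notes

Everything is integer arithmetic; there are no tolerances. Exhaustive
sweeps (38,416 codes) back the codec, structure and enzyme-closure
properties; the renderer is spot-checked on 500 seeded random codes and
the name-enumeration partition on a deterministic spread of names, each
enumeration being itself a full-space sweep. Hypothesis tests run
derandomized. The acceptance script re-derives its reported quantities
(core identifier, digit extrema, fucosylated tetraantennary identifier)
from the seven free digits and the increment tables at run time.

## Known limitations

- One LacNAc repeat per branch; no Neu5Gc, α2-6 sialylation, antenna
  fucosylation or sulfation.
- Man4/Man6 isomer topology is a drawing convention (see above).
- The Oxford symbol set is shape-vocabulary only.
- Hybrid abbreviations (`M<n>-...`) and the `M<n>` oligomannose form are
  package conventions, not GlycoBase database strings.
- JPEG output uses Pillow defaults; no quality tuning.
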