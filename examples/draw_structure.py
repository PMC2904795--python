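"""Render one structure in CFG colour symbols as SVG and PNG.

Draws the tetraantennary A4G4FLac1S3 structure right-to-left from the Asn
anchor, writes glycan.svg and glycan.png to a temporary directory, and
reports the drawing element counts.
"""

import tempfile
from pathlib import Path

from nglycode import SymbolStyle, export_raster, parse_code, render_code

code = parse_code("310333553")
style = SymbolStyle(symbol_set="cfg", magnification=1.5)
doc = render_code(code, style)

out = Path(tempfile.mkdtemp(prefix="nglycode-"))
(out / "glycan.svg").write_text(doc.to_svg(), encoding="utf-8")
export_raster(doc, str(out / "glycan.png"), "PNG")

print(f"{code}: {len(doc.shapes)} residue symbols, {len(doc.lines)} linkages")
print(f"canvas {doc.width:.0f} x {doc.height:.0f} px at magnification 1.5")
print(f"wrote glycan.svg and glycan.png to {out}")
# 19 symbols = 3 Man + 7 GlcNAc + 5 Gal + 3 NeuAc + 1 Fuc; one line per
# glycosidic bond plus the GlcNAc-Asn attachment.
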