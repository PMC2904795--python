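"""Rendering: layout geometry, SVG structure, raster export."""

import io

import pytest
from lxml import etree
from PIL import Image

from nglycode import (
    FixtureSpec,
    SymbolStyle,
    build_tree,
    census,
    layout_tree,
    parse_code,
    random_codes,
    render_code,
)
from nglycode.render import StyleError


def boxes_overlap(a, b, size):
    return abs(a.x - b.x) < size and abs(a.y - b.y) < size


class TestLayout:
    def test_core_columns(self):
        lay = layout_tree(build_tree(parse_code("300000000")), SymbolStyle())
        cols = sorted({n.column for n in lay.nodes})
        assert cols == [0, 1, 2, 3, 4]
        assert len(lay.nodes) == 6

    def test_right_to_left(self):
        """x strictly decreases with depth: the Asn anchor is rightmost."""
        lay = layout_tree(build_tree(parse_code("310333553")), SymbolStyle())
        asn = next(n for n in lay.nodes if n.residue.monosaccharide == "Asn")
        assert asn.x == max(n.x for n in lay.nodes)
        for a, b in lay.edges:
            if b.column > a.column:
                assert b.x < a.x

    def test_longest_chain_drives_depth(self):
        # level-5 branch: core(4 cols) + GlcNAc-Gal-GlcNAc-Gal = column 8
        lay = layout_tree(build_tree(parse_code("310333553")), SymbolStyle())
        assert max(n.column for n in lay.nodes) == 8
        # a level-6 branch pushes NeuAc one column further
        lay6 = layout_tree(build_tree(parse_code("310333653")), SymbolStyle())
        assert max(n.column for n in lay6.nodes) == 9

    def test_upper_arm_above_lower(self):
        lay = layout_tree(build_tree(parse_code("300330033")), SymbolStyle())
        by_pos = {
            n.residue.linkage_child_pos: n
            for n in lay.nodes
            if n.residue.monosaccharide == "Man" and n.residue.anomer == "a"
        }
        assert by_pos[6].y < by_pos[3].y  # smaller y = higher on canvas

    def test_no_overlapping_symbols(self):
        style = SymbolStyle()
        for text in ("300000000", "611333653", "310333553", "401400010"):
            lay = layout_tree(build_tree(parse_code(text)), style)
            nodes = lay.nodes
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    assert not boxes_overlap(a, b, style.symbol_size), (
                        text,
                        a.residue.monosaccharide,
                        b.residue.monosaccharide,
                    )

    def test_magnification_scales_linearly(self):
        t = build_tree(parse_code("310033333"))
        lay1 = layout_tree(t, SymbolStyle(magnification=1))
        lay2 = layout_tree(t, SymbolStyle(magnification=2))
        for n1, n2 in zip(lay1.nodes, lay2.nodes):
            assert n2.x == pytest.approx(2 * n1.x)
            assert n2.y == pytest.approx(2 * n1.y)


class TestSvg:
    def parse_svg(self, doc):
        return etree.fromstring(doc.to_svg().encode())

    def test_core_element_census(self):
        doc = render_code(parse_code("300000000"))
        kinds = [s.kind for s in doc.shapes]
        assert kinds.count("circle") == 3 and kinds.count("square") == 2
        assert len(doc.lines) == 5  # one per linkage, Asn bond included
        assert [t.content for t in doc.texts] == ["Asn"]

    def test_shape_count_equals_census_on_random_codes(self):
        codes = random_codes(FixtureSpec(seed=7, n=500))
        for code in codes:
            doc = render_code(code)
            assert len(doc.shapes) == sum(census(build_tree(code)).values())

    def test_sialylated_diamonds(self):
        doc = render_code(parse_code("310033333"))
        assert len(doc.shapes) == 15
        assert sum(1 for s in doc.shapes if s.kind == "diamond") == 3

    def test_text_only_mode(self):
        doc = render_code(parse_code("310033333"), SymbolStyle(symbol_set="text"))
        assert doc.shapes == []
        # one token per residue plus the Asn anchor
        assert len(doc.texts) == 16

    def test_svg_is_well_formed_and_complete(self):
        doc = render_code(parse_code("310333553"), SymbolStyle(show_key=True))
        root = self.parse_svg(doc)
        ns = "{http://www.w3.org/2000/svg}"
        shapes = root.findall(f"{ns}circle") + root.findall(f"{ns}polygon")
        assert len(shapes) == len(doc.shapes)
        assert len(root.findall(f"{ns}line")) == len(doc.lines)

    def test_key_lists_monosaccharides_used(self):
        doc = render_code(parse_code("310333553"), SymbolStyle(show_key=True))
        labels = {t.content for t in doc.texts}
        assert {"Fuc", "Gal", "GlcNAc", "Man", "NeuAc"} <= labels

    def test_cfg_palette(self):
        doc = render_code(parse_code("310333553"))
        fills = {s.fill for s in doc.shapes}
        assert fills == {"#0072BC", "#00A651", "#FFD400", "#A54399", "#ED1C24"}

    def test_uoxf_uses_hexagons_for_hexoses(self):
        doc = render_code(parse_code("310333553"), SymbolStyle(symbol_set="uoxf"))
        kinds = {s.kind for s in doc.shapes}
        assert "hexagon" in kinds and "circle" not in kinds

    def test_unknown_symbol_set_rejected(self):
        with pytest.raises(StyleError):
            SymbolStyle(symbol_set="snfg-2019")


class TestRaster:
    def open_raster(self, doc, fmt, scale=1.0):
        return Image.open(io.BytesIO(doc.to_raster(fmt, scale)))

    def test_png_dimensions_and_content(self):
        doc = render_code(parse_code("300000000"))
        img = self.open_raster(doc, "PNG")
        assert img.size == (round(doc.width), round(doc.height))
        # not blank: the green core mannoses must appear
        colors = {c for _, c in img.getcolors(maxcolors=100000)}
        assert (0, 166, 81) in colors

    def test_scale_doubles_pixels(self):
        doc = render_code(parse_code("300000000"))
        w1, h1 = self.open_raster(doc, "PNG").size
        w2, h2 = self.open_raster(doc, "PNG", 2).size
        assert (w2, h2) == (2 * w1, 2 * h1)

    def test_magnification_doubles_canvas(self):
        d1 = render_code(parse_code("300000000"), SymbolStyle(magnification=1))
        d2 = render_code(parse_code("300000000"), SymbolStyle(magnification=2))
        assert (d2.width, d2.height) == (2 * d1.width, 2 * d1.height)

    @pytest.mark.parametrize("fmt", ["PNG", "JPEG", "BMP"])
    def test_format_parity(self, fmt):
        doc = render_code(parse_code("310333553"))
        img = self.open_raster(doc, fmt)
        assert img.size == (round(doc.width), round(doc.height))
        assert img.format == fmt

    def test_unsupported_format(self):
        doc = render_code(parse_code("300000000"))
        with pytest.raises(StyleError):
            doc.to_raster("TIFF")
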