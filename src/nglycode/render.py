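"""Symbol-notation rendering of glycan trees.

Structures are drawn right-to-left from the Asn anchor: the residue column
equals tree depth, with a fixed horizontal spacing, and vertical positions
come from post-order subtree centering with the α1-6 ("upper") arm above
the α1-3 arm.  Two residues get special placement to match convention:
core fucose hangs below the reducing GlcNAc, and the bisecting GlcNAc sits
on the β-mannose's horizontal axis between the two arms.

Four symbol sets are supported:

* ``cfg`` — CFG/SNFG coloured shapes (blue square GlcNAc, green circle
  Man, yellow circle Gal, purple diamond NeuAc, red triangle Fuc)
* ``cfg-bw`` — the same shapes in black and white, distinguished by fill
* ``uoxf`` — Oxford-style monochrome symbols: hexagons for the hexoses,
  solid fill marking N-acetylated residues (symbol shapes only; the full
  Oxford linkage-angle system is not drawn)
* ``text`` — residue names only, no shapes

The renderer produces a :class:`Document` of drawing primitives that
serializes to SVG 1.1 and rasterizes to PNG/JPEG/BMP via Pillow at an
arbitrary scale.  Linkage lines use a pen width proportional to the
magnification with a 1 px floor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence
from xml.sax.saxutils import escape

from .codec import GlycanCode
from .structure import GlycanTree, Residue, build_tree

__all__ = [
    "SymbolStyle",
    "LayoutNode",
    "Layout",
    "Document",
    "layout_tree",
    "render_svg",
    "render_code",
    "export_raster",
    "RASTER_FORMATS",
]

SYMBOL_SETS = ("cfg", "cfg-bw", "uoxf", "text")
RASTER_FORMATS = ("PNG", "JPEG", "BMP")


class StyleError(ValueError):
    """Unsupported symbol set or export format."""


@dataclass(frozen=True)
class SymbolStyle:
    """Rendering parameters.

    ``x_spacing``/``y_spacing`` are the inter-residue distances in px at
    magnification 1; all coordinates scale linearly with magnification.
    """

    symbol_set: str = "cfg"
    magnification: float = 1.0
    x_spacing: float = 55.0
    y_spacing: float = 45.0
    symbol_size: float = 22.0
    margin: float = 30.0
    font_size: float = 13.0
    show_key: bool = False

    def __post_init__(self) -> None:
        if self.symbol_set not in SYMBOL_SETS:
            raise StyleError(
                f"unsupported symbol set {self.symbol_set!r}; "
                f"choose from {SYMBOL_SETS}"
            )
        if self.magnification <= 0:
            raise StyleError("magnification must be positive")

    @property
    def pen_width(self) -> float:
        # linear in magnification, floored at one pixel
        return max(1.0, 1.6 * self.magnification)


# (shape, fill, stroke) per monosaccharide and symbol set.  CFG colours are
# the published SNFG hex values.
_CFG = {
    "GlcNAc": ("square", "#0072BC", "#000000"),
    "Man": ("circle", "#00A651", "#000000"),
    "Gal": ("circle", "#FFD400", "#000000"),
    "NeuAc": ("diamond", "#A54399", "#000000"),
    "Fuc": ("triangle", "#ED1C24", "#000000"),
}
_CFG_BW = {
    "GlcNAc": ("square", "#000000", "#000000"),
    "Man": ("circle", "#000000", "#000000"),
    "Gal": ("circle", "#FFFFFF", "#000000"),
    "NeuAc": ("diamond", "#808080", "#000000"),
    "Fuc": ("triangle", "#FFFFFF", "#000000"),
}
_UOXF = {
    "GlcNAc": ("square", "#000000", "#000000"),  # solid = N-acetylated
    "Man": ("hexagon", "#808080", "#000000"),
    "Gal": ("hexagon", "#FFFFFF", "#000000"),
    "NeuAc": ("diamond", "#000000", "#000000"),
    "Fuc": ("triangle", "#FFFFFF", "#000000"),
}
_SHAPE_MAPS = {"cfg": _CFG, "cfg-bw": _CFG_BW, "uoxf": _UOXF}


# ---------------------------------------------------------------------------
# drawing primitives


@dataclass(frozen=True)
class Shape:
    kind: str  # circle | square | diamond | triangle | hexagon
    cx: float
    cy: float
    size: float  # edge/diameter
    fill: str
    stroke: str
    stroke_width: float

    def translated(self, dx: float, dy: float) -> "Shape":
        return replace(self, cx=self.cx + dx, cy=self.cy + dy)


@dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    width: float
    stroke: str = "#000000"

    def translated(self, dx: float, dy: float) -> "Line":
        return replace(
            self, x1=self.x1 + dx, y1=self.y1 + dy, x2=self.x2 + dx, y2=self.y2 + dy
        )


@dataclass(frozen=True)
class Text:
    x: float
    y: float
    content: str
    size: float
    anchor: str = "middle"  # start | middle | end

    def translated(self, dx: float, dy: float) -> "Text":
        return replace(self, x=self.x + dx, y=self.y + dy)


Primitive = Shape | Line | Text


@dataclass
class Document:
    """A renderable canvas: list of primitives plus dimensions in px."""

    width: float
    height: float
    primitives: list[Primitive] = field(default_factory=list)

    @property
    def shapes(self) -> list[Shape]:
        return [p for p in self.primitives if isinstance(p, Shape)]

    @property
    def lines(self) -> list[Line]:
        return [p for p in self.primitives if isinstance(p, Line)]

    @property
    def texts(self) -> list[Text]:
        return [p for p in self.primitives if isinstance(p, Text)]

    def merged_from(
        self, others: Sequence[tuple["Document", float, float]]
    ) -> None:
        for doc, dx, dy in others:
            self.primitives.extend(p.translated(dx, dy) for p in doc.primitives)

    def to_svg(self) -> str:
        return _to_svg(self)

    def to_raster(self, fmt: str = "PNG", scale: float = 1.0) -> bytes:
        return _rasterize(self, fmt, scale)


def _shape_points(kind: str, cx: float, cy: float, size: float) -> list[tuple[float, float]]:
    h = size / 2.0
    if kind == "square":
        return [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
    if kind == "diamond":
        return [(cx, cy - h), (cx + h, cy), (cx, cy + h), (cx - h, cy)]
    if kind == "triangle":
        return [(cx, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
    if kind == "hexagon":
        q = h / 2.0
        return [
            (cx - q, cy - h),
            (cx + q, cy - h),
            (cx + h, cy),
            (cx + q, cy + h),
            (cx - q, cy + h),
            (cx - h, cy),
        ]
    raise StyleError(f"unknown shape kind {kind!r}")


def _to_svg(doc: Document) -> str:
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{doc.width:g}" height="{doc.height:g}" '
        f'viewBox="0 0 {doc.width:g} {doc.height:g}">',
    ]
    for p in doc.primitives:
        if isinstance(p, Line):
            out.append(
                f'<line x1="{p.x1:g}" y1="{p.y1:g}" x2="{p.x2:g}" '
                f'y2="{p.y2:g}" stroke="{p.stroke}" '
                f'stroke-width="{p.width:g}"/>'
            )
        elif isinstance(p, Shape):
            common = (
                f'fill="{p.fill}" stroke="{p.stroke}" '
                f'stroke-width="{p.stroke_width:g}"'
            )
            if p.kind == "circle":
                out.append(
                    f'<circle cx="{p.cx:g}" cy="{p.cy:g}" '
                    f'r="{p.size / 2:g}" {common}/>'
                )
            else:
                pts = " ".join(
                    f"{x:g},{y:g}" for x, y in _shape_points(p.kind, p.cx, p.cy, p.size)
                )
                out.append(f'<polygon points="{pts}" {common}/>')
        elif isinstance(p, Text):
            out.append(
                f'<text x="{p.x:g}" y="{p.y:g}" font-size="{p.size:g}" '
                f'font-family="Helvetica,Arial,sans-serif" '
                f'text-anchor="{p.anchor}">{escape(p.content)}</text>'
            )
    out.append("</svg>")
    return "\n".join(out)


def _rasterize(doc: Document, fmt: str, scale: float) -> bytes:
    from PIL import Image, ImageDraw

    fmt = fmt.upper()
    if fmt == "JPG":
        fmt = "JPEG"
    if fmt not in RASTER_FORMATS:
        raise StyleError(f"unsupported raster format {fmt!r}; use {RASTER_FORMATS}")
    w = max(1, round(doc.width * scale))
    h = max(1, round(doc.height * scale))
    img = Image.new("RGB", (w, h), "#FFFFFF")
    draw = ImageDraw.Draw(img)
    for p in doc.primitives:
        if isinstance(p, Line):
            draw.line(
                [(p.x1 * scale, p.y1 * scale), (p.x2 * scale, p.y2 * scale)],
                fill=p.stroke,
                width=max(1, round(p.width * scale)),
            )
        elif isinstance(p, Shape):
            if p.kind == "circle":
                r = p.size / 2 * scale
                box = [
                    p.cx * scale - r,
                    p.cy * scale - r,
                    p.cx * scale + r,
                    p.cy * scale + r,
                ]
                draw.ellipse(box, fill=p.fill, outline=p.stroke,
                             width=max(1, round(p.stroke_width * scale)))
            else:
                pts = [
                    (x * scale, y * scale)
                    for x, y in _shape_points(p.kind, p.cx, p.cy, p.size)
                ]
                draw.polygon(pts, fill=p.fill, outline=p.stroke)
        elif isinstance(p, Text):
            x = p.x * scale
            if p.anchor != "start":
                tw = draw.textlength(p.content)
                x -= tw if p.anchor == "end" else tw / 2
            draw.text((x, p.y * scale - p.size * scale * 0.8), p.content,
                      fill="#000000")
    buf = io.BytesIO()
    img.save(buf, format=fmt)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# layout


@dataclass
class LayoutNode:
    residue: Residue
    column: int
    x: float = 0.0
    y: float = 0.0


@dataclass
class Layout:
    nodes: list[LayoutNode]
    edges: list[tuple[LayoutNode, LayoutNode]]
    width: float
    height: float

    def node_for(self, residue: Residue) -> LayoutNode:
        for n in self.nodes:
            if n.residue is residue:
                return n
        raise KeyError(residue)


def _display_children(node: Residue) -> list[Residue]:
    """Top-to-bottom drawing order of a residue's children.

    Upper (α1-6) material is drawn above lower (α1-3) material, so children
    are ordered by *decreasing* linkage position, which puts branch 4
    (β1-6) topmost on the upper arm and branch 1 (β1-2) above branch 2
    (β1-4) on the lower arm.
    """
    return sorted(
        node.children,
        key=lambda c: -(c.linkage_child_pos if isinstance(c.linkage_child_pos, int) else 0),
    )


def layout_tree(tree: GlycanTree, style: SymbolStyle) -> Layout:
    """Assign canvas coordinates: column = depth, Asn rightmost."""
    mag = style.magnification
    dx = style.x_spacing * mag
    dy = style.y_spacing * mag

    red_gn = tree.root.children[0] if tree.root.children else None
    beta_man = None
    if red_gn is not None:
        for c in red_gn.children:
            if c.monosaccharide == "GlcNAc":
                beta_man = c.children[0] if c.children else None

    fucose = None
    bisect = None
    if tree.code.core_fucose and red_gn is not None:
        fucose = next(c for c in red_gn.children if c.monosaccharide == "Fuc")
    if tree.code.bisecting_glcnac and beta_man is not None:
        bisect = next(
            c for c in beta_man.children if c.monosaccharide == "GlcNAc"
        )
    special = {id(fucose), id(bisect)}

    nodes: dict[int, LayoutNode] = {}
    next_slot = [0]

    def place(res: Residue) -> float:
        """Post-order subtree centering; returns the row (in dy units)."""
        kids = [c for c in _display_children(res) if id(c) not in special]
        if not kids:
            row = float(next_slot[0])
            next_slot[0] += 1
        else:
            rows = [place(c) for c in kids]
            row = (min(rows) + max(rows)) / 2.0
        nodes[id(res)] = LayoutNode(res, res.depth, 0.0, row)
        return row

    place(tree.root)

    if bisect is not None and beta_man is not None:
        # on the β-mannose horizontal axis, one column further out
        nodes[id(bisect)] = LayoutNode(
            bisect, beta_man.depth + 1, 0.0, nodes[id(beta_man)].y
        )
    if fucose is not None and red_gn is not None:
        # hangs below the reducing-end GlcNAc in the same column
        nodes[id(fucose)] = LayoutNode(
            fucose, red_gn.depth, 0.0, nodes[id(red_gn)].y + 0.9
        )

    max_col = max(n.column for n in nodes.values())
    max_row = max(n.y for n in nodes.values())
    margin = style.margin * mag
    for n in nodes.values():
        n.x = margin + (max_col - n.column) * dx
        n.y = margin + n.y * dy

    width = margin * 2 + max_col * dx
    height = margin * 2 + max_row * dy

    ordered = [nodes[id(r)] for r in tree.walk()]
    edges = [
        (nodes[id(parent)], nodes[id(child)])
        for parent in tree.walk()
        for child in parent.children
    ]
    return Layout(ordered, edges, width, height)


# ---------------------------------------------------------------------------
# rendering


def render_svg(
    tree: GlycanTree,
    style: SymbolStyle | None = None,
    *,
    caption: str | None = None,
) -> Document:
    """Render a tree to a :class:`Document` (SVG via ``doc.to_svg()``).

    One shape per sugar residue (one text token per residue in text-only
    mode), a text label for the Asn anchor, one line per linkage, an
    optional symbol key, and an optional caption under the structure.
    """
    style = style or SymbolStyle()
    mag = style.magnification
    lay = layout_tree(tree, style)
    doc = Document(lay.width, lay.height)
    size = style.symbol_size * mag
    font = style.font_size * mag
    textual = style.symbol_set == "text"

    for a, b in lay.edges:
        doc.primitives.append(Line(a.x, a.y, b.x, b.y, style.pen_width))

    shape_map = _SHAPE_MAPS.get(style.symbol_set, {})
    used: dict[str, tuple[str, str, str]] = {}
    for node in lay.nodes:
        res = node.residue
        if res.monosaccharide == "Asn":
            # blank out the line ends behind the label, then the label
            doc.primitives.append(Text(node.x, node.y + font * 0.35, "Asn", font))
            continue
        if textual:
            doc.primitives.append(
                Text(node.x, node.y + font * 0.35, res.monosaccharide, font)
            )
            continue
        kind, fill, stroke = shape_map[res.monosaccharide]
        used.setdefault(res.monosaccharide, (kind, fill, stroke))
        doc.primitives.append(
            Shape(kind, node.x, node.y, size, fill, stroke, style.pen_width)
        )

    if caption is not None:
        doc.height += font * 1.8
        doc.primitives.append(
            Text(doc.width / 2, doc.height - font * 0.5, caption, font)
        )

    if style.show_key and not textual:
        key_x = doc.width + size
        y = style.margin * mag
        for mono, (kind, fill, stroke) in sorted(used.items()):
            doc.primitives.append(
                Shape(kind, key_x, y, size * 0.8, fill, stroke, style.pen_width)
            )
            doc.primitives.append(
                Text(key_x + size, y + font * 0.35, mono, font, anchor="start")
            )
            y += size * 1.6
        doc.width = key_x + size * 4.5
        doc.height = max(doc.height, y)

    return doc


def render_code(
    code: GlycanCode, style: SymbolStyle | None = None, **kw
) -> Document:
    """Convenience: build the tree and render it."""
    return render_svg(build_tree(code), style, **kw)


def export_raster(
    doc: Document, path: str, fmt: str | None = None, scale: float = 1.0
) -> None:
    """Write the document as PNG, JPEG or BMP (format from *fmt* or the
    file suffix); pixel dimensions are canvas size times *scale*."""
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    data = doc.to_raster(fmt, scale)
    with open(path, "wb") as fh:
        fh.write(data)
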