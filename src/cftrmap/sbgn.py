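"""SBGN map container, deterministic layout, and SBGN-ML 0.2 serialization.

Maps are held as flat glyph/arc/compartment/style lists mirroring the SBGN-ML
exchange schema.  Two dialects are supported: Process Description (PD), which
encodes mechanism (entity pools, process nodes, consumption/production and
regulation arcs), and Activity Flow (AF), which encodes influence only.

Style (fill/stroke colors) travels in a ``renderInformation`` extension
element, the convention SBGN editors use for color metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

from lxml import etree

from .model import CompartmentName

__all__ = [
    "Dialect",
    "Bbox",
    "Glyph",
    "Arc",
    "CompartmentGlyph",
    "Style",
    "SbgnMap",
    "ColorScheme",
    "LayoutConfig",
    "SbgnError",
    "SbgnParseError",
    "PD_GLYPH_CLASSES",
    "AF_GLYPH_CLASSES",
    "layout_map",
    "write_sbgnml",
    "read_sbgnml",
]

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
RENDER_NS = "http://www.sbml.org/sbml/level3/version1/render/version1"


class SbgnError(ValueError):
    """The map violates an SBGN structural invariant."""


class SbgnParseError(SbgnError):
    """An SBGN-ML document could not be parsed."""


class Dialect(enum.StrEnum):
    PD = "process description"
    AF = "activity flow"


PD_GLYPH_CLASSES = frozenset(
    {
        "macromolecule",
        "nucleic acid feature",
        "simple chemical",
        "complex",
        "source and sink",
        "unspecified entity",
        "perturbing agent",
        "phenotype",
        "process",
        "omitted process",
        "uncertain process",
        "association",
        "dissociation",
    }
)
PD_ARC_CLASSES = frozenset(
    {
        "consumption",
        "production",
        "catalysis",
        "inhibition",
        "stimulation",
        "modulation",
        "necessary stimulation",
    }
)
AF_GLYPH_CLASSES = frozenset({"biological activity", "phenotype", "perturbation"})
AF_ARC_CLASSES = frozenset(
    {"positive influence", "negative influence", "unknown influence", "necessary stimulation"}
)


@dataclass(frozen=True)
class Bbox:
    x: float
    y: float
    w: float
    h: float

    def contains(self, other: "Bbox") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x + other.w <= self.x + self.w
            and other.y + other.h <= self.y + self.h
        )

    def overlaps(self, other: "Bbox") -> bool:
        return not (
            self.x + self.w <= other.x
            or other.x + other.w <= self.x
            or self.y + self.h <= other.y
            or other.y + other.h <= self.y
        )

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass(frozen=True)
class Glyph:
    id: str
    cls: str
    label: str = ""
    compartment: str | None = None  # compartment glyph id
    bbox: Bbox | None = None
    style: str | None = None  # style id
    clone: bool = False  # entity drawn in several compartments


@dataclass(frozen=True)
class Arc:
    id: str
    cls: str
    source: str
    target: str


@dataclass(frozen=True)
class CompartmentGlyph:
    id: str
    name: str
    bbox: Bbox | None = None


@dataclass(frozen=True)
class Style:
    id: str
    fill: str
    stroke: str = "#000000"


@dataclass
class SbgnMap:
    dialect: Dialect
    glyphs: list[Glyph] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    compartments: list[CompartmentGlyph] = field(default_factory=list)
    styles: list[Style] = field(default_factory=list)

    def glyph_ids(self) -> set[str]:
        return {g.id for g in self.glyphs}

    def validate(self) -> None:
        """Raise :class:`SbgnError` on any structural violation."""
        legal = PD_GLYPH_CLASSES if self.dialect == Dialect.PD else AF_GLYPH_CLASSES
        legal_arcs = PD_ARC_CLASSES if self.dialect == Dialect.PD else AF_ARC_CLASSES
        comp_ids = {c.id for c in self.compartments}
        comp_bbox = {c.id: c.bbox for c in self.compartments}
        seen: set[str] = set()
        for g in self.glyphs:
            if g.id in seen:
                raise SbgnError(f"duplicate glyph id {g.id}")
            seen.add(g.id)
            if g.cls not in legal:
                raise SbgnError(f"glyph {g.id}: class {g.cls!r} illegal in {self.dialect.value} maps")
            if g.compartment is not None:
                if g.compartment not in comp_ids:
                    raise SbgnError(f"glyph {g.id}: unknown compartment {g.compartment}")
                cb = comp_bbox[g.compartment]
                if g.bbox is not None and cb is not None and not cb.contains(g.bbox):
                    raise SbgnError(f"glyph {g.id}: bbox outside its compartment {g.compartment}")
        node_ids = seen
        for a in self.arcs:
            if a.cls not in legal_arcs:
                raise SbgnError(f"arc {a.id}: class {a.cls!r} illegal in {self.dialect.value} maps")
            for endpoint in (a.source, a.target):
                if endpoint not in node_ids:
                    raise SbgnError(f"arc {a.id}: endpoint {endpoint} is not a glyph")

    def styled(self, glyph_id: str) -> Style | None:
        by_id = {s.id: s for s in self.styles}
        for g in self.glyphs:
            if g.id == glyph_id and g.style is not None:
                return by_id.get(g.style)
        return None


#: role → fill color; the focal protein is blue, interactors seen in
#: polarization-capable cell lines green, non-polarized-only yellow,
#: degradation-associated red, recycling-associated orange-yellow.
DEFAULT_COLORS: dict[str, str] = {
    "cftr": "#2B6CB0",
    "polarized": "#8FBF8F",
    "non_polarized": "#F2E394",
    "degradation": "#E57373",
    "recycling": "#F2C879",
    "compartment": "#D9D9D9",
    "unspecified": "#FFFFFF",
}


@dataclass(frozen=True)
class ColorScheme:
    mapping: tuple[tuple[str, str], ...] = tuple(sorted(DEFAULT_COLORS.items()))

    def __post_init__(self) -> None:
        for role, color in self.mapping:
            if not (len(color) == 7 and color.startswith("#")):
                raise SbgnError(f"role {role}: {color!r} is not a #RRGGBB color")

    def fill(self, role: str) -> str:
        for r, c in self.mapping:
            if r == role:
                return c
        raise KeyError(role)

    def styles(self) -> list[Style]:
        return [Style(id=f"style_{role}", fill=color) for role, color in self.mapping]


# ---------------------------------------------------------------------------
# layout


@dataclass(frozen=True)
class LayoutConfig:
    """Deterministic grid-layout parameters (abstract layout units)."""

    columns: int = 5
    cell_w: float = 140.0
    cell_h: float = 70.0
    glyph_w: float = 110.0
    glyph_h: float = 44.0
    margin: float = 20.0
    compartment_gap: float = 30.0
    #: bottom-to-top stacking order, mirroring the focal protein's journey
    #: from transcription in the nucleus up to the plasma membrane
    compartment_order: tuple[str, ...] = (
        CompartmentName.NUCLEUS.value,
        CompartmentName.ER.value,
        CompartmentName.GOLGI.value,
        CompartmentName.CYTOPLASM.value,
        CompartmentName.PLASMA_MEMBRANE.value,
        CompartmentName.EXTRACELLULAR_SPACE.value,
    )


def _grid_positions(n: int, cfg: LayoutConfig) -> list[tuple[int, int]]:
    return [(i % cfg.columns, i // cfg.columns) for i in range(n)]


def layout_map(sbgn_map: SbgnMap, config: LayoutConfig | None = None) -> SbgnMap:
    """Assign bounding boxes on a per-compartment grid; pure and deterministic.

    Glyphs are sorted by (label, id) inside each compartment and gridded with
    ``config.columns`` columns; compartments are stacked bottom-to-top in
    ``config.compartment_order`` (unknown compartment names stack above, in
    name order).  Compartments grow to fit their glyph count, so the grid
    never overflows.  Identical input and config yield identical coordinates.
    """
    cfg = config or LayoutConfig()
    order = {name: i for i, name in enumerate(cfg.compartment_order)}
    comps = sorted(
        sbgn_map.compartments,
        key=lambda c: (order.get(c.name, len(order)), c.name, c.id),
    )
    by_comp: dict[str | None, list[Glyph]] = {}
    for g in sbgn_map.glyphs:
        by_comp.setdefault(g.compartment, []).append(g)

    new_comps: list[CompartmentGlyph] = []
    new_glyphs: dict[str, Glyph] = {}

    def place(glyphs: list[Glyph], origin_x: float, origin_y: float) -> tuple[float, float]:
        """Grid `glyphs` below (origin_x, origin_y); return grid width/height."""
        ordered = sorted(glyphs, key=lambda g: (g.label, g.id))
        rows = 0
        for g, (col, row) in zip(ordered, _grid_positions(len(ordered), cfg)):
            rows = max(rows, row + 1)
            bbox = Bbox(
                x=origin_x + cfg.margin + col * cfg.cell_w + (cfg.cell_w - cfg.glyph_w) / 2.0,
                y=origin_y + cfg.margin + row * cfg.cell_h + (cfg.cell_h - cfg.glyph_h) / 2.0,
                w=cfg.glyph_w,
                h=cfg.glyph_h,
            )
            new_glyphs[g.id] = replace(g, bbox=bbox)
        width = cfg.columns * cfg.cell_w + 2 * cfg.margin
        height = max(rows, 1) * cfg.cell_h + 2 * cfg.margin
        return width, height

    # stack compartments bottom-to-top: first in order gets the largest y
    heights: dict[str, tuple[float, float]] = {}
    for comp in comps:
        glyphs = by_comp.get(comp.id, [])
        n_rows = max((len(glyphs) + cfg.columns - 1) // cfg.columns, 1)
        width = cfg.columns * cfg.cell_w + 2 * cfg.margin
        height = n_rows * cfg.cell_h + 2 * cfg.margin
        heights[comp.id] = (width, height)
    total = sum(h for _, h in heights.values()) + cfg.compartment_gap * max(len(comps) - 1, 0)
    y_cursor = total
    for comp in comps:
        width, height = heights[comp.id]
        y_cursor -= height
        bbox = Bbox(x=0.0, y=y_cursor, w=width, h=height)
        new_comps.append(replace(comp, bbox=bbox))
        place(by_comp.get(comp.id, []), 0.0, y_cursor)
        y_cursor -= cfg.compartment_gap

    # glyphs outside any compartment go above the cell
    floating = by_comp.get(None, [])
    if floating:
        place(floating, 0.0, -cfg.compartment_gap - (len(floating) // cfg.columns + 1) * cfg.cell_h - 2 * cfg.margin)

    out = SbgnMap(
        dialect=sbgn_map.dialect,
        glyphs=[new_glyphs.get(g.id, g) for g in sbgn_map.glyphs],
        arcs=list(sbgn_map.arcs),
        compartments=new_comps if comps else list(sbgn_map.compartments),
        styles=list(sbgn_map.styles),
    )
    return out


# ---------------------------------------------------------------------------
# SBGN-ML serialization


def _fmt(value: float) -> str:
    return f"{value:.2f}"


def write_sbgnml(sbgn_map: SbgnMap, path: str | Path) -> None:
    """Serialize to SBGN-ML 0.2; output is byte-identical for identical maps."""
    sbgn_map.validate()
    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap={None: SBGN_NS})
    map_el = etree.SubElement(root, f"{{{SBGN_NS}}}map", language=sbgn_map.dialect.value)

    glyph_styles: dict[str, list[str]] = {}
    for g in sbgn_map.glyphs:
        if g.style is not None:
            glyph_styles.setdefault(g.style, []).append(g.id)
    if sbgn_map.styles:
        ext = etree.SubElement(map_el, f"{{{SBGN_NS}}}extension")
        render = etree.SubElement(
            ext, f"{{{RENDER_NS}}}renderInformation", nsmap={"render": RENDER_NS}, id="renderInfo"
        )
        colors = etree.SubElement(render, f"{{{RENDER_NS}}}listOfColorDefinitions")
        styles_el = etree.SubElement(render, f"{{{RENDER_NS}}}listOfStyles")
        for s in sorted(sbgn_map.styles, key=lambda s: s.id):
            etree.SubElement(colors, f"{{{RENDER_NS}}}colorDefinition", id=f"{s.id}_fill", value=s.fill)
            st = etree.SubElement(
                styles_el,
                f"{{{RENDER_NS}}}style",
                id=s.id,
                idList=" ".join(sorted(glyph_styles.get(s.id, []))),
            )
            etree.SubElement(st, f"{{{RENDER_NS}}}g", fill=s.fill, stroke=s.stroke)

    def bbox_el(parent, bbox: Bbox) -> None:
        etree.SubElement(
            parent,
            f"{{{SBGN_NS}}}bbox",
            x=_fmt(bbox.x),
            y=_fmt(bbox.y),
            w=_fmt(bbox.w),
            h=_fmt(bbox.h),
        )

    for c in sbgn_map.compartments:
        el = etree.SubElement(map_el, f"{{{SBGN_NS}}}glyph", id=c.id)
        el.set("class", "compartment")
        label = etree.SubElement(el, f"{{{SBGN_NS}}}label")
        label.set("text", c.name)
        if c.bbox is not None:
            bbox_el(el, c.bbox)

    centers: dict[str, tuple[float, float]] = {}
    for g in sbgn_map.glyphs:
        el = etree.SubElement(map_el, f"{{{SBGN_NS}}}glyph", id=g.id)
        el.set("class", g.cls)
        if g.compartment is not None:
            el.set("compartmentRef", g.compartment)
        label = etree.SubElement(el, f"{{{SBGN_NS}}}label")
        label.set("text", g.label)
        if g.clone:
            etree.SubElement(el, f"{{{SBGN_NS}}}clone")
        if g.bbox is not None:
            bbox_el(el, g.bbox)
            centers[g.id] = g.bbox.center
        else:
            centers[g.id] = (0.0, 0.0)

    for a in sbgn_map.arcs:
        el = etree.SubElement(map_el, f"{{{SBGN_NS}}}arc", id=a.id, source=a.source, target=a.target)
        el.set("class", a.cls)
        sx, sy = centers.get(a.source, (0.0, 0.0))
        tx, ty = centers.get(a.target, (0.0, 0.0))
        etree.SubElement(el, f"{{{SBGN_NS}}}start", x=_fmt(sx), y=_fmt(sy))
        etree.SubElement(el, f"{{{SBGN_NS}}}end", x=_fmt(tx), y=_fmt(ty))

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _parse_bbox(el) -> Bbox | None:
    bb = el.find(f"{{{SBGN_NS}}}bbox")
    if bb is None:
        return None
    return Bbox(x=float(bb.get("x")), y=float(bb.get("y")), w=float(bb.get("w")), h=float(bb.get("h")))


def read_sbgnml(path: str | Path) -> SbgnMap:
    """Parse an SBGN-ML 0.2 document written by :func:`write_sbgnml`.

    Raises :class:`SbgnParseError` (with the offending line number where
    available) on malformed XML, unknown dialects, or arcs referencing
    missing glyphs.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SbgnParseError(f"{path}: not SBGN-ML ({exc})") from exc
    root = tree.getroot()
    map_el = root.find(f"{{{SBGN_NS}}}map")
    if map_el is None:
        raise SbgnParseError(f"{path}: no <map> element (line {root.sourceline})")
    try:
        dialect = Dialect(map_el.get("language"))
    except ValueError:
        raise SbgnParseError(
            f"{path}: unknown map language {map_el.get('language')!r} (line {map_el.sourceline})"
        ) from None

    styles: list[Style] = []
    style_of: dict[str, str] = {}
    for st in map_el.iterfind(f".//{{{RENDER_NS}}}style"):
        g = st.find(f"{{{RENDER_NS}}}g")
        styles.append(Style(id=st.get("id"), fill=g.get("fill"), stroke=g.get("stroke", "#000000")))
        for gid in (st.get("idList") or "").split():
            style_of[gid] = st.get("id")

    compartments: list[CompartmentGlyph] = []
    glyphs: list[Glyph] = []
    for el in map_el.iterfind(f"{{{SBGN_NS}}}glyph"):
        cls = el.get("class")
        label_el = el.find(f"{{{SBGN_NS}}}label")
        label = label_el.get("text") if label_el is not None else ""
        if cls == "compartment":
            compartments.append(CompartmentGlyph(id=el.get("id"), name=label, bbox=_parse_bbox(el)))
        else:
            glyphs.append(
                Glyph(
                    id=el.get("id"),
                    cls=cls,
                    label=label,
                    compartment=el.get("compartmentRef"),
                    bbox=_parse_bbox(el),
                    style=style_of.get(el.get("id")),
                    clone=el.find(f"{{{SBGN_NS}}}clone") is not None,
                )
            )

    glyph_ids = {g.id for g in glyphs}
    arcs: list[Arc] = []
    for el in map_el.iterfind(f"{{{SBGN_NS}}}arc"):
        for endpoint in (el.get("source"), el.get("target")):
            if endpoint not in glyph_ids:
                raise SbgnParseError(
                    f"{path}: arc {el.get('id')} references missing glyph {endpoint!r} "
                    f"(line {el.sourceline})"
                )
        arcs.append(Arc(id=el.get("id"), cls=el.get("class"), source=el.get("source"), target=el.get("target")))

    return SbgnMap(dialect=dialect, glyphs=glyphs, arcs=arcs, compartments=compartments, styles=styles)
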