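"""Map generation: detailed PD core map and auto-generated AF coarse submaps.

The core map renders the curated layer mechanistically: one entity-pool glyph
per (entity, compartment) occurrence, one process glyph per reaction, with
consumption/production arcs and typed regulation arcs.  Entities drawn in
more than one compartment carry SBGN clone markers.

Coarse submaps abstract one lifecycle step into a single state transition:
a focal-protein input activity, a central transition, and an output activity.
Every high-throughput interactor becomes one activity glyph whose influence
arc lands either on the input node (gene-directed categories such as DNA
replication) or on the transition itself (everything else).
"""

from __future__ import annotations

import logging

from .curation import PolarityStatus, polarity_status
from .model import (
    CompartmentName,
    Interactor,
    Layer,
    Reaction,
    ReactionType,
    Regulation,
    SpeciesKind,
)
from .sbgn import (
    Arc,
    ColorScheme,
    CompartmentGlyph,
    Dialect,
    Glyph,
    LayoutConfig,
    SbgnError,
    SbgnMap,
    layout_map,
)

__all__ = [
    "build_core_map",
    "build_coarse_submap",
    "GENE_DIRECTED_CATEGORIES",
    "PD_CLASS_BY_KIND",
]

log = logging.getLogger(__name__)

#: species kind → PD entity-pool glyph class
PD_CLASS_BY_KIND: dict[SpeciesKind, str] = {
    SpeciesKind.GENE: "nucleic acid feature",
    SpeciesKind.RNA: "nucleic acid feature",
    SpeciesKind.PROTEIN: "macromolecule",
    SpeciesKind.TRUNCATED_PROTEIN: "macromolecule",
    SpeciesKind.RECEPTOR: "macromolecule",
    SpeciesKind.ION_CHANNEL: "macromolecule",
    SpeciesKind.COMPLEX: "complex",
    SpeciesKind.SIMPLE_MOLECULE: "simple chemical",
    SpeciesKind.ION: "simple chemical",
    SpeciesKind.DEGRADED_POOL: "source and sink",
}

_PROCESS_CLASS: dict[ReactionType, str] = {
    ReactionType.COMPLEX_ASSOCIATION: "association",
    ReactionType.COMPLEX_DISSOCIATION: "dissociation",
}

_REGULATION_ARC: dict[Regulation, str] = {
    Regulation.CATALYSIS: "catalysis",
    Regulation.INHIBITION: "inhibition",
    Regulation.PHYSICAL_STIMULATION: "stimulation",
    Regulation.MODULATION: "modulation",
}

#: functional categories whose influence targets the gene (input) node rather
#: than the central state transition of a coarse submap
GENE_DIRECTED_CATEGORIES = frozenset({"dna replication", "dna repair", "chromatin"})

#: functional category → color role for coarse submaps
_CATEGORY_ROLES = {
    "degradation": "degradation",
    "erad": "degradation",
    "both": "degradation",
    "recycling": "recycling",
}


def _glyph_id(symbol: str, compartment: CompartmentName) -> str:
    return f"g_{symbol}_{compartment.value}"


def _is_focal(interactor: Interactor, focal_symbol: str) -> bool:
    root = interactor.symbol.split("-")[0].split("_")[0]
    return root == focal_symbol


def build_core_map(
    interactors: list[Interactor],
    reactions: list[Reaction],
    compartments: list[CompartmentName] | None = None,
    colors: ColorScheme | None = None,
    focal_symbol: str = "CFTR",
    layout: LayoutConfig | None = None,
) -> SbgnMap:
    """Build the PD core map from curated entities and reactions.

    One glyph is created per (entity, compartment) occurrence — the union of
    the entity's annotated localizations and the compartments it participates
    in reactions at — with a clone marker when an entity occupies several
    compartments.  One process glyph is created per reaction.  Fill colors
    follow polarity provenance; the focal protein's forms are colored as such.

    Raises :class:`SbgnError` if a reaction names a compartment missing from
    the layout compartment list.
    """
    colors = colors or ColorScheme()
    core = [i for i in interactors if i.layer == Layer.CORE]
    by_symbol = {i.symbol: i for i in core}

    # compartment layout set: default = all compartments actually used
    occurrences: dict[str, set[CompartmentName]] = {i.symbol: set(i.localizations) for i in core}
    reaction_comps: set[CompartmentName] = set()
    for r in reactions:
        reaction_comps.add(r.compartment)
        for sym, comp in r.reactants + r.products:
            if sym in occurrences:
                occurrences[sym].add(comp)
        for sym, _ in r.regulators:
            if sym in occurrences:
                occurrences[sym].add(r.compartment)
    used = reaction_comps | {c for comps in occurrences.values() for c in comps}
    comp_list = compartments if compartments is not None else sorted(used, key=lambda c: c.value)
    missing = reaction_comps - set(comp_list)
    if missing:
        raise SbgnError(
            "reactions reference compartments absent from the layout: "
            + ", ".join(sorted(c.value for c in missing))
        )

    comp_glyphs = [CompartmentGlyph(id=f"c_{c.value}", name=c.value) for c in comp_list]
    glyphs: list[Glyph] = []
    for i in sorted(core, key=lambda x: x.symbol):
        comps = sorted(occurrences[i.symbol] & set(comp_list), key=lambda c: c.value)
        if not comps:
            comps = [comp_list[0]] if comp_list else []
        if _is_focal(i, focal_symbol):
            role = "cftr"
        else:
            role = {
                PolarityStatus.POLARIZED: "polarized",
                PolarityStatus.NON_POLARIZED_ONLY: "non_polarized",
                PolarityStatus.NO_CELL_EVIDENCE: "unspecified",
            }[polarity_status(i.evidence)]
        for comp in comps:
            glyphs.append(
                Glyph(
                    id=_glyph_id(i.symbol, comp),
                    cls=PD_CLASS_BY_KIND[i.species_kind],
                    label=i.display_name or i.symbol,
                    compartment=f"c_{comp.value}",
                    style=f"style_{role}",
                    clone=len(comps) > 1,
                )
            )
    glyph_ids = {g.id for g in glyphs}

    arcs: list[Arc] = []
    for r in reactions:
        pid = f"p_{r.id}"
        glyphs.append(
            Glyph(
                id=pid,
                cls=_PROCESS_CLASS.get(r.rtype, "process"),
                label=r.rtype.value,
                compartment=f"c_{r.compartment.value}",
            )
        )

        def entity_glyph(sym: str, comp: CompartmentName) -> str:
            gid = _glyph_id(sym, comp)
            if gid not in glyph_ids:
                raise SbgnError(f"reaction {r.id}: participant {sym}@{comp.value} has no glyph")
            return gid

        for n, (sym, comp) in enumerate(r.reactants):
            arcs.append(Arc(id=f"a_{r.id}_r{n}", cls="consumption", source=entity_glyph(sym, comp), target=pid))
        for n, (sym, comp) in enumerate(r.products):
            arcs.append(Arc(id=f"a_{r.id}_p{n}", cls="production", source=pid, target=entity_glyph(sym, comp)))
        for n, (sym, reg) in enumerate(r.regulators):
            arcs.append(
                Arc(
                    id=f"a_{r.id}_m{n}",
                    cls=_REGULATION_ARC[reg],
                    source=entity_glyph(sym, r.compartment),
                    target=pid,
                )
            )

    out = SbgnMap(
        dialect=Dialect.PD,
        glyphs=glyphs,
        arcs=arcs,
        compartments=comp_glyphs,
        styles=colors.styles(),
    )
    out = layout_map(out, layout)
    out.validate()
    return out


def build_coarse_submap(
    name: str,
    interactors: list[Interactor],
    abstraction: str,
    submap_categories: set[str] | None = None,
    colors: ColorScheme | None = None,
    influence_class: str = "unknown influence",
    focal_symbol: str = "CFTR",
    layout: LayoutConfig | None = None,
) -> SbgnMap:
    """Build one AF coarse submap around a central state-transition abstraction.

    The map always contains a focal-protein input activity, a transition node
    labelled ``abstraction``, and a focal-protein output activity.  Each
    interactor with at least one functional category belonging to this submap
    becomes a biological-activity glyph with one influence arc: onto the
    input (gene) node for gene-directed categories, onto the transition
    otherwise.  Interactors with no matching category are skipped with a
    logged warning.
    """
    colors = colors or ColorScheme()
    central = [
        Glyph(id="cftr_in", cls="biological activity", label=focal_symbol, style="style_cftr"),
        Glyph(id="transition", cls="biological activity", label=abstraction, style="style_compartment"),
        Glyph(id="cftr_out", cls="biological activity", label=focal_symbol, style="style_cftr"),
    ]
    glyphs = list(central)
    arcs = [
        Arc(id="a_in", cls="positive influence", source="cftr_in", target="transition"),
        Arc(id="a_out", cls="positive influence", source="transition", target="cftr_out"),
    ]

    for i in sorted(interactors, key=lambda x: x.symbol):
        cats = {c.lower() for c in i.functional_categories}
        if submap_categories is not None:
            cats &= {c.lower() for c in submap_categories}
        if not cats:
            log.warning("submap %s: interactor %s has no category here; skipped", name, i.symbol)
            continue
        role = next((_CATEGORY_ROLES[c] for c in sorted(cats) if c in _CATEGORY_ROLES), "non_polarized")
        gid = f"g_{i.symbol}"
        glyphs.append(Glyph(id=gid, cls="biological activity", label=i.display_name or i.symbol, style=f"style_{role}"))
        target = "cftr_in" if cats & GENE_DIRECTED_CATEGORIES else "transition"
        arcs.append(Arc(id=f"a_{i.symbol}", cls=influence_class, source=gid, target=target))

    out = SbgnMap(dialect=Dialect.AF, glyphs=glyphs, arcs=arcs, compartments=[], styles=colors.styles())
    out = layout_map(out, layout)
    out.validate()
    return out
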