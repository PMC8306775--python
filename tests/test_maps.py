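"""PD/AF map generation, deterministic layout, SBGN-ML round trips."""

from itertools import combinations

import pytest

from cftrmap.mapbuild import build_coarse_submap, build_core_map
from cftrmap.model import (
    CompartmentName,
    EvidenceClass,
    EvidenceRecord,
    Interactor,
    Layer,
    Reaction,
    ReactionType,
    Regulation,
    SpeciesKind,
)
from cftrmap.sbgn import (
    Bbox,
    Dialect,
    Glyph,
    LayoutConfig,
    SbgnError,
    SbgnMap,
    SbgnParseError,
    layout_map,
    read_sbgnml,
    write_sbgnml,
)

CENTRAL = {"cftr_in", "transition", "cftr_out"}


def protein(symbol, compartment=CompartmentName.CYTOPLASM, categories=(), polarized=False):
    return Interactor(
        symbol,
        species_kind=SpeciesKind.PROTEIN,
        localizations={compartment},
        functional_categories=set(categories),
        layer=Layer.CORE,
        evidence=[
            EvidenceRecord(
                pmid=11,
                evidence_class=EvidenceClass.SMALL_SCALE_EXPERIMENT,
                cell_line="CALU-3" if polarized else "HEK293",
                polarized_capable=polarized,
                human_cells=True,
            )
        ],
    )


class TestBuildCoreMap:
    def test_single_reaction_two_entities_one_process_two_arcs(self):
        interactors = [protein("A"), protein("B")]
        reaction = Reaction(
            id="r1",
            rtype=ReactionType.STATE_TRANSITION,
            reactants=[("A", CompartmentName.CYTOPLASM)],
            products=[("B", CompartmentName.CYTOPLASM)],
        )
        m = build_core_map(interactors, [reaction])
        entity_glyphs = [g for g in m.glyphs if g.cls == "macromolecule"]
        process_glyphs = [g for g in m.glyphs if g.cls == "process"]
        assert (len(entity_glyphs), len(process_glyphs), len(m.arcs)) == (2, 1, 2)
        assert {a.cls for a in m.arcs} == {"consumption", "production"}

    def test_inhibition_regulator_becomes_inhibition_arc(self):
        interactors = [protein("A"), protein("B"), protein("I")]
        reaction = Reaction(
            id="r1",
            rtype=ReactionType.STATE_TRANSITION,
            reactants=[("A", CompartmentName.CYTOPLASM)],
            products=[("B", CompartmentName.CYTOPLASM)],
            regulators=[("I", Regulation.INHIBITION)],
        )
        m = build_core_map(interactors, [reaction])
        assert sum(1 for a in m.arcs if a.cls == "inhibition") == 1

    def test_entity_in_two_compartments_gets_clone_markers(self):
        i = protein("A")
        i.localizations = {CompartmentName.ER, CompartmentName.GOLGI}
        m = build_core_map([i], [])
        clones = [g for g in m.glyphs if g.label == "A"]
        assert len(clones) == 2 and all(g.clone for g in clones)

    def test_reaction_in_unlisted_compartment_raises(self):
        interactors = [protein("A"), protein("B")]
        reaction = Reaction(
            id="r1",
            rtype=ReactionType.TRANSPORT,
            reactants=[("A", CompartmentName.CYTOPLASM)],
            products=[("B", CompartmentName.CYTOPLASM)],
            compartment=CompartmentName.GOLGI,
        )
        with pytest.raises(SbgnError, match="golgi"):
            build_core_map(interactors, [reaction], compartments=[CompartmentName.CYTOPLASM])

    def test_packaged_fixture_yields_one_process_glyph_per_reaction(self, cftr_fixture, core_entities):
        m = build_core_map(core_entities, cftr_fixture.dataset.reactions)
        n_process = sum(1 for g in m.glyphs if g.cls in ("process", "association", "dissociation"))
        assert n_process == 156

    def test_polarity_drives_fill_color(self):
        m = build_core_map([protein("A", polarized=True), protein("B", polarized=False)], [])
        styles = {g.label: g.style for g in m.glyphs}
        assert styles["A"] == "style_polarized"
        assert styles["B"] == "style_non_polarized"


class TestBuildCoarseSubmap:
    def test_gene_directed_and_transition_directed_routing(self):
        members = [protein(f"G{i}", categories=["dna replication"]) for i in range(7)]
        members += [protein(f"T{i}", categories=["transcription"]) for i in range(10)]
        m = build_coarse_submap("transcription", members, "transcription")
        non_central = [g for g in m.glyphs if g.id not in CENTRAL]
        onto_gene = [a for a in m.arcs if a.target == "cftr_in"]
        onto_transition = [a for a in m.arcs if a.target == "transition" and a.id != "a_in"]
        assert (len(non_central), len(onto_gene), len(onto_transition)) == (17, 7, 10)

    def test_empty_group_leaves_only_the_abstraction(self):
        m = build_coarse_submap("x", [], "state transition")
        assert {g.id for g in m.glyphs} == CENTRAL
        assert len(m.arcs) == 2

    def test_uncategorized_interactor_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            m = build_coarse_submap("x", [protein("A")], "t")
        assert {g.id for g in m.glyphs} == CENTRAL
        assert any("skipped" in r.message for r in caplog.records)

    def test_influence_arc_count_equals_non_skipped_interactors(self, coarse_entities):
        members = [i for i in coarse_entities if "translation_folding_erqc" in i.submaps]
        m = build_coarse_submap("translation_folding_erqc", members, "folding and ER quality control")
        influence = [a for a in m.arcs if a.id not in ("a_in", "a_out")]
        assert len(influence) == len(m.glyphs) - len(CENTRAL) == len(members)

    def test_degradation_category_colored_red_family(self, coarse_entities):
        members = [i for i in coarse_entities if "degradation" in i.functional_categories]
        m = build_coarse_submap("endocytosis_recycling_degradation", members, "recycling vs degradation")
        non_central = [g for g in m.glyphs if g.id not in CENTRAL]
        assert all(g.style == "style_degradation" for g in non_central)


class TestLayout:
    def grid_map(self, n):
        glyphs = [Glyph(id=f"g{i}", cls="biological activity", label=f"L{i:02d}") for i in range(n)]
        return SbgnMap(dialect=Dialect.AF, glyphs=glyphs)

    def test_four_glyphs_two_columns_reproducible(self):
        cfg = LayoutConfig(columns=2)
        a = layout_map(self.grid_map(4), cfg)
        b = layout_map(self.grid_map(4), cfg)
        assert [g.bbox for g in a.glyphs] == [g.bbox for g in b.glyphs]
        xs = {g.bbox.x for g in a.glyphs}
        ys = {g.bbox.y for g in a.glyphs}
        assert len(xs) == 2 and len(ys) == 2

    def test_zero_glyphs_min_compartment_size(self):
        from cftrmap.sbgn import CompartmentGlyph

        m = SbgnMap(dialect=Dialect.PD, compartments=[CompartmentGlyph(id="c1", name="cytoplasm")])
        out = layout_map(m, LayoutConfig(columns=3))
        (c,) = out.compartments
        assert c.bbox.h == 1 * LayoutConfig().cell_h + 2 * LayoutConfig().margin

    def test_thirty_glyphs_five_columns_six_rows_all_disjoint(self):
        out = layout_map(self.grid_map(30), LayoutConfig(columns=5))
        boxes = [g.bbox for g in out.glyphs]
        rows = {b.y for b in boxes}
        assert len(rows) == 6
        for a, b in combinations(boxes, 2):  # exhaustive pairwise oracle
            assert not a.overlaps(b)

    def test_compartments_stack_bottom_to_top(self):
        from cftrmap.sbgn import CompartmentGlyph

        m = SbgnMap(
            dialect=Dialect.PD,
            compartments=[
                CompartmentGlyph(id="c_pm", name="plasma_membrane"),
                CompartmentGlyph(id="c_nuc", name="nucleus"),
            ],
        )
        out = layout_map(m)
        by_name = {c.name: c.bbox for c in out.compartments}
        # SBGN y grows downward: the nucleus sits below the plasma membrane
        assert by_name["nucleus"].y > by_name["plasma_membrane"].y


class TestSbgnmlRoundTrip:
    def test_af_submap_round_trip_is_identity(self, tmp_path, coarse_entities):
        members = [i for i in coarse_entities if "transcription" in i.submaps]
        m = build_coarse_submap("transcription", members, "transcription")
        write_sbgnml(m, tmp_path / "t.sbgn")
        assert read_sbgnml(tmp_path / "t.sbgn") == m

    def test_core_map_round_trip_preserves_process_count(self, tmp_path, cftr_fixture, core_entities):
        m = build_core_map(core_entities, cftr_fixture.dataset.reactions)
        write_sbgnml(m, tmp_path / "core.sbgn")
        back = read_sbgnml(tmp_path / "core.sbgn")
        assert back == m
        assert sum(1 for g in back.glyphs if g.cls in ("process", "association", "dissociation")) == 156

    def test_identical_input_gives_byte_identical_output(self, tmp_path, coarse_entities):
        members = [i for i in coarse_entities if "immunity" in i.submaps]
        for name in ("a.sbgn", "b.sbgn"):
            write_sbgnml(build_coarse_submap("immunity", members, "immune response"), tmp_path / name)
        assert (tmp_path / "a.sbgn").read_bytes() == (tmp_path / "b.sbgn").read_bytes()

    def test_arc_to_missing_glyph_is_parse_error_with_line(self, tmp_path):
        text = """<?xml version='1.0' encoding='UTF-8'?>
<sbgn xmlns="http://sbgn.org/libsbgn/0.2">
<map language="activity flow">
<glyph id="g1" class="biological activity"><label text="A"/></glyph>
<arc id="a1" class="unknown influence" source="g1" target="ghost"/>
</map>
</sbgn>
"""
        p = tmp_path / "bad.sbgn"
        p.write_text(text)
        with pytest.raises(SbgnParseError, match=r"ghost.*line 5"):
            read_sbgnml(p)

    def test_non_xml_file_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.sbgn"
        p.write_text("this is not xml")
        with pytest.raises(SbgnParseError):
            read_sbgnml(p)


def test_validate_rejects_illegal_class_for_dialect():
    m = SbgnMap(dialect=Dialect.AF, glyphs=[Glyph(id="g1", cls="macromolecule")])
    with pytest.raises(SbgnError, match="illegal"):
        m.validate()
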