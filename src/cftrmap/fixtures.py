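"""Synthetic dataset generation and the packaged reference fixture.

Two entry points:

* :func:`generate_dataset` builds a parametric synthetic dataset (interactor
  and evidence tables, reactions, a PPI edge list, GMT annotations) from a
  :class:`FixtureSpec`, fully deterministic given one seed.

* :func:`packaged_cftr_fixture` builds the packaged CFTR fixture: a synthetic
  realization of the published aggregate description of the CFTR Lifecycle
  Map (entity censuses, layer sizes and overlap, per-submap category counts,
  and the PPI-network degree profile).  Aggregates are exact; gene-level
  content is synthetic except for the handful of symbols whose roles are
  fixed by the published description (CFTR, HSP90AA1, STUB1, UBE2I, NR3C1,
  VCP, SLC9A3R1, ANO1, ADRB2).  Synthetic filler symbols are prefixed ``CP``
  (core proteins) and ``HT`` (high-throughput interactors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .curation import round_half_up
from .enrichment import AnnotationSet
from .model import (
    CompartmentName,
    Dataset,
    EvidenceClass,
    EvidenceRecord,
    Identifier,
    Interactor,
    Layer,
    Namespace,
    Reaction,
    ReactionType,
    Regulation,
    SpeciesKind,
    write_evidence_table,
    write_interactor_table,
    write_reaction_table,
)
from .topology import PpiNetwork, build_network

__all__ = ["FixtureSpec", "GeneratedDataset", "CftrFixture", "generate_dataset", "packaged_cftr_fixture", "TABLE2_CATEGORY_COUNTS"]


# ---------------------------------------------------------------------------
# parametric generator


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-layer dataset."""

    n_core: int = 20
    n_coarse: int = 60
    n_overlap: int = 5
    polarized_fraction: float = 0.7
    accepted_fraction: float = 1.0
    submaps: tuple[tuple[str, int], ...] | None = None  # (name, n_interactors)
    coarse_categories: tuple[tuple[str, int], ...] | None = None
    n_reactions: int = 10
    graph_model: str = "preferential_attachment"  # or erdos_renyi / planted_partition
    graph_n: int = 100
    graph_m: int = 2
    graph_p: float = 0.05
    partition_blocks: int = 2
    partition_block_size: int = 30
    partition_p_in: float = 0.5
    partition_p_out: float = 0.02
    n_terms: int = 20
    term_size: tuple[int, int] = (4, 12)

    def validate(self) -> None:
        if self.n_overlap > min(self.n_core, self.n_coarse):
            raise ValueError("overlap exceeds a layer size")
        if not (0.0 <= self.polarized_fraction <= 1.0 and 0.0 <= self.accepted_fraction <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        if self.submaps is not None and sum(n for _, n in self.submaps) != self.n_core:
            raise ValueError("submap sizes must sum to n_core")
        for _, n in self.submaps or ():
            if round_half_up(n * self.polarized_fraction) > n:
                raise ValueError("polarized count exceeds submap size")


@dataclass
class GeneratedDataset:
    spec: FixtureSpec
    seed: int
    dataset: Dataset
    core_symbols: list[str]
    coarse_symbols: list[str]
    edge_rows: list[tuple[str, str, int]]
    annotation: AnnotationSet

    @property
    def network(self) -> PpiNetwork:
        return build_network(self.edge_rows)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        return _write_bundle(
            outdir, self.dataset, self.edge_rows, self.annotation, self.core_symbols, self.coarse_symbols
        )


def _write_bundle(outdir, dataset, edge_rows, annotation, core_symbols, coarse_symbols) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}" for name in
             ("interactors.tsv", "evidence.tsv", "reactions.tsv", "edges.tsv", "annotations.gmt",
              "core_interactors.txt", "coarse_raw.txt")}
    write_interactor_table(dataset.interactors, paths["interactors.tsv"])
    write_evidence_table(dataset.interactors, paths["evidence.tsv"])
    write_reaction_table(dataset.reactions, paths["reactions.tsv"])
    with open(paths["edges.tsv"], "w") as fh:
        fh.write("symbol_a\tsymbol_b\tpmid\n")
        for a, b, pmid in edge_rows:
            fh.write(f"{a}\t{b}\t{pmid}\n")
    with open(paths["annotations.gmt"], "w") as fh:
        for tid in sorted(annotation.terms):
            name, genes = annotation.terms[tid]
            fh.write("\t".join([tid, name] + sorted(genes)) + "\n")
    paths["core_interactors.txt"].write_text("".join(s + "\n" for s in core_symbols))
    paths["coarse_raw.txt"].write_text("".join(s + "\n" for s in coarse_symbols))
    return paths


_DEFAULT_CATEGORIES = ("folding", "trafficking", "activity", "degradation", "recycling", "other")
_SUBMAP_COMPARTMENT = {
    "transcription": CompartmentName.NUCLEUS,
    "rna_processing": CompartmentName.NUCLEUS,
    "translation_folding_erqc": CompartmentName.ER,
    "secretory_pathway": CompartmentName.GOLGI,
    "activity_regulation": CompartmentName.PLASMA_MEMBRANE,
    "endocytosis_recycling_degradation": CompartmentName.ENDOSOME,
    "cytoskeleton": CompartmentName.CYTOPLASM,
    "immunity": CompartmentName.EXTRACELLULAR_SPACE,
    "other": CompartmentName.CYTOPLASM,
}


def _evidence_pair(pmid_a: int, pmid_b: int, polarized: bool, group_mod: int = 37) -> list[EvidenceRecord]:
    cell = "CALU-3" if polarized else "HEK293"
    return [
        EvidenceRecord(
            pmid=pmid_a,
            evidence_class=EvidenceClass.SMALL_SCALE_EXPERIMENT,
            method="co-immunoprecipitation",
            cell_line=cell,
            polarized_capable=polarized,
            human_cells=True,
            research_group=f"grp{pmid_a % group_mod}",
        ),
        EvidenceRecord(
            pmid=pmid_b,
            evidence_class=EvidenceClass.SMALL_SCALE_EXPERIMENT,
            method="pull-down assay",
            cell_line="HEK293",
            polarized_capable=False,
            human_cells=True,
            research_group=f"grp{pmid_b % group_mod}",
        ),
    ]


def generate_dataset(spec: FixtureSpec, seed: int, outdir: str | Path | None = None) -> GeneratedDataset:
    """Generate a synthetic dataset; byte-identical output for same spec+seed.

    Per submap, exactly ``round_half_up(n * polarized_fraction)`` interactors
    carry polarized-cell evidence.  A fraction ``accepted_fraction`` of the
    core interactors receives evidence satisfying the two-independent-
    references inclusion rule; the rest get a single (insufficient) record.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    core_symbols = [f"CG{i:04d}" for i in range(1, spec.n_core + 1)]
    submaps = list(spec.submaps) if spec.submaps is not None else [("main", spec.n_core)]
    interactors: list[Interactor] = []
    idx = 0
    n_accepted = round_half_up(spec.n_core * spec.accepted_fraction)
    for submap, n in submaps:
        n_polarized = round_half_up(n * spec.polarized_fraction)
        comp = _SUBMAP_COMPARTMENT.get(submap, CompartmentName.CYTOPLASM)
        for j in range(n):
            sym = core_symbols[idx]
            polarized = j < n_polarized
            evidence = _evidence_pair(30000000 + 2 * idx, 30000001 + 2 * idx, polarized)
            if idx >= n_accepted:  # deliberately insufficient support
                evidence = evidence[:1]
            interactors.append(
                Interactor(
                    symbol=sym,
                    species_kind=SpeciesKind.PROTEIN,
                    localizations={comp},
                    submaps={submap},
                    functional_categories={_DEFAULT_CATEGORIES[idx % len(_DEFAULT_CATEGORIES)]},
                    layer=Layer.CORE,
                    annotations=[Identifier(Namespace.HGNC, str(1000 + idx))],
                    evidence=evidence,
                )
            )
            idx += 1

    coarse_shared = core_symbols[: spec.n_overlap]
    coarse_new = [f"HG{i:04d}" for i in range(1, spec.n_coarse - spec.n_overlap + 1)]
    coarse_symbols = coarse_shared + coarse_new
    categories = list(spec.coarse_categories) if spec.coarse_categories is not None else None
    coarse_interactors = []
    for i, sym in enumerate(coarse_new):
        if categories is not None:
            cat = _category_at(categories, i)
        else:
            cat = _DEFAULT_CATEGORIES[i % len(_DEFAULT_CATEGORIES)]
        coarse_interactors.append(
            Interactor(
                symbol=sym,
                species_kind=SpeciesKind.PROTEIN,
                submaps={cat},
                functional_categories={cat},
                layer=Layer.COARSE,
            )
        )

    reactions = []
    pool = core_symbols or ["CG0000"]
    for i in range(spec.n_reactions):
        comp = CompartmentName.CYTOPLASM
        a, b = pool[(2 * i) % len(pool)], pool[(2 * i + 1) % len(pool)]
        if a == b:
            b = pool[(2 * i + 2) % len(pool)]
        regulators = []
        if i % 3 == 0 and len(pool) > 2:
            regulators = [(pool[(2 * i + 3) % len(pool)], Regulation.CATALYSIS)]
        reactions.append(
            Reaction(
                id=f"re{i + 1:03d}",
                rtype=list(ReactionType)[i % len(list(ReactionType))],
                reactants=[(a, comp)],
                products=[(b, comp)],
                regulators=regulators,
                compartment=comp,
                pmids=[30000000 + i],
            )
        )

    edge_rows = _generate_graph(spec, int(rng.integers(0, 2**31 - 1)))
    annotation = _generate_annotation(spec, rng, core_symbols, coarse_symbols)

    result = GeneratedDataset(
        spec=spec,
        seed=seed,
        dataset=Dataset(interactors=interactors + coarse_interactors, reactions=reactions),
        core_symbols=core_symbols,
        coarse_symbols=coarse_symbols,
        edge_rows=edge_rows,
        annotation=annotation,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def _category_at(categories: list[tuple[str, int]], i: int) -> str:
    for name, n in categories:
        if i < n:
            return name
        i -= n
    return categories[-1][0]


def _generate_graph(spec: FixtureSpec, seed: int) -> list[tuple[str, str, int]]:
    if spec.graph_model == "preferential_attachment":
        g = nx.barabasi_albert_graph(spec.graph_n, spec.graph_m, seed=seed)
    elif spec.graph_model == "erdos_renyi":
        g = nx.gnp_random_graph(spec.graph_n, spec.graph_p, seed=seed)
    elif spec.graph_model == "planted_partition":
        g = nx.planted_partition_graph(
            spec.partition_blocks, spec.partition_block_size, spec.partition_p_in, spec.partition_p_out, seed=seed
        )
    else:
        raise ValueError(f"unknown graph model {spec.graph_model!r}")
    return [
        (f"N{min(a, b):04d}", f"N{max(a, b):04d}", 40000000 + n)
        for n, (a, b) in enumerate(sorted((min(a, b), max(a, b)) for a, b in g.edges()))
    ]


def _generate_annotation(
    spec: FixtureSpec, rng: np.random.Generator, core_symbols: list[str], coarse_symbols: list[str]
) -> AnnotationSet:
    universe = sorted(set(core_symbols) | set(coarse_symbols))
    lo, hi = spec.term_size
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(spec.n_terms):
        size = min(int(rng.integers(lo, hi + 1)), len(universe))
        members = rng.choice(len(universe), size=size, replace=False)
        terms[f"T{t:04d}"] = (f"synthetic term {t}", frozenset(universe[i] for i in sorted(members)))
    return AnnotationSet(terms=terms, universe=frozenset(universe))


# ---------------------------------------------------------------------------
# packaged fixture


#: deduplicated coarse-layer interactor counts per (submap, functional category)
TABLE2_CATEGORY_COUNTS: tuple[tuple[str, str, int], ...] = (
    ("transcription", "dna replication", 7),
    ("transcription", "transcription", 10),
    ("rna_processing", "rna processing", 36),
    ("translation_folding_erqc", "folding", 57),
    ("translation_folding_erqc", "erad", 1),
    ("translation_folding_erqc", "both", 3),
    ("translation_folding_erqc", "unspecified", 653),
    ("secretory_pathway", "trafficking", 22),
    ("activity_regulation", "activity", 38),
    ("activity_regulation", "unspecified", 145),
    ("endocytosis_recycling_degradation", "recycling", 12),
    ("endocytosis_recycling_degradation", "degradation", 32),
    ("cytoskeleton", "cytoskeleton", 62),
    ("immunity", "immunity", 10),
    ("other", "other", 250),
)

#: per-submap (interactor count, polarized count) of the curated core layer;
#: denominators chosen so the rounded percentages equal 97/69/52/82/74
_CORE_SUBMAP_PLAN: tuple[tuple[str, int, int], ...] = (
    ("transcription", 33, 32),
    ("translation_folding_erqc", 39, 27),
    ("secretory_pathway", 33, 17),
    ("activity_regulation", 38, 31),
    ("endocytosis_recycling_degradation", 27, 20),
)

#: PPI degree sequence: focal protein 38, the five named hubs 30/27/24/22/20,
#: exactly 30 degree-1 and 10 degree-6 nodes, 145 nodes / 326 edges in total
_DEGREE_SEQUENCE: tuple[int, ...] = (
    (38, 30, 27, 24, 22, 20)
    + (6,) * 10
    + (2,) * 28
    + (3,) * 25
    + (4,) * 15
    + (5,) * 10
    + (7,) * 15
    + (8,) * 3
    + (9, 10, 12)
    + (1,) * 30
)

_NAMED_HUBS = ("CFTR", "HSP90AA1", "STUB1", "UBE2I", "NR3C1", "VCP")


@dataclass
class CftrFixture:
    """Synthetic realization of the published CFTR Lifecycle Map aggregates."""

    dataset: Dataset  # deduplicated: 262 core entities + 1338 coarse interactors
    pre_dedup_interactors: list[Interactor]  # 262 core + 1384 coarse (46 shared symbols)
    core_interactor_symbols: list[str]  # 170
    coarse_symbols: list[str]  # 1384, pre-dedup
    edge_rows: list[tuple[str, str, int]]
    annotation: AnnotationSet
    expected_submap_counts: dict[str, int]
    expected_census: dict[str, int]

    @property
    def network(self) -> PpiNetwork:
        return build_network(self.edge_rows)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        return _write_bundle(
            outdir, self.dataset, self.edge_rows, self.annotation,
            self.core_interactor_symbols, self.coarse_symbols,
        )


def _core_entities() -> tuple[list[Interactor], list[str]]:
    """262 core entities with the published species-kind census; 170 interactors."""
    entities: list[Interactor] = []
    interactor_symbols: list[str] = []
    pmid_pool = [10000001 + i for i in range(221)]  # 221 distinct references
    pmid_idx = 0

    def next_pmid_pair() -> tuple[int, int]:
        # cycles through the pool so 340 draws cover all 221 references
        nonlocal pmid_idx
        pair = (pmid_pool[pmid_idx % 221], pmid_pool[(pmid_idx + 1) % 221])
        pmid_idx += 2
        return pair

    # focal-protein forms and other non-interactor entities carry no evidence
    cftr_forms = [
        Interactor("CFTR-GENE", "CFTR gene", SpeciesKind.GENE, {CompartmentName.NUCLEUS},
                   {"transcription"}, set(), Layer.CORE, [Identifier(Namespace.HGNC, "1884")],
                   is_interactor=False),
        Interactor("CFTR-MRNA", "CFTR mRNA", SpeciesKind.RNA, {CompartmentName.NUCLEUS, CompartmentName.CYTOPLASM},
                   {"transcription", "translation_folding_erqc"}, set(), Layer.CORE, [], is_interactor=False),
        Interactor("CFTR", "CFTR", SpeciesKind.ION_CHANNEL,
                   {CompartmentName.ER, CompartmentName.GOLGI, CompartmentName.PLASMA_MEMBRANE},
                   {"translation_folding_erqc", "secretory_pathway", "activity_regulation",
                    "endocytosis_recycling_degradation"},
                   set(), Layer.CORE, [Identifier(Namespace.UNIPROT, "P13569")], is_interactor=False),
        Interactor("CFTR-TRUNC", "truncated CFTR", SpeciesKind.TRUNCATED_PROTEIN, {CompartmentName.ER},
                   {"translation_folding_erqc"}, set(), Layer.CORE, [], is_interactor=False),
        Interactor("CFTR-GLYC", "glycosylated CFTR", SpeciesKind.PROTEIN,
                   {CompartmentName.GOLGI, CompartmentName.PLASMA_MEMBRANE},
                   {"secretory_pathway", "activity_regulation"}, set(), Layer.CORE, [], is_interactor=False),
    ]
    entities.extend(cftr_forms)

    # 170 interactors: 146 protein-kind + 5 genes + 4 RNAs + 13 ions + 2 small molecules
    named = ["HSP90AA1", "STUB1", "UBE2I", "NR3C1", "VCP", "SLC9A3R1"]
    protein_symbols = named + ["ANO1", "ADRB2"] + [f"CP{i:03d}" for i in range(1, 139)]  # 146
    kind_of = {"ANO1": SpeciesKind.ION_CHANNEL, "ADRB2": SpeciesKind.RECEPTOR, "CP001": SpeciesKind.RECEPTOR}
    gene_symbols = [f"TG{i:02d}" for i in range(1, 6)]  # 5 interactor genes
    rna_symbols = [f"TR{i:02d}" for i in range(1, 5)]  # 4 interactor RNAs
    ion_symbols = ["CL", "HCO3", "NA", "K", "CA"] + [f"ION{i:02d}" for i in range(1, 9)]  # 13
    interactor_molecules = ["ATP", "CAMP"]

    plan = []  # (symbol, kind) in submap assignment order
    for s in protein_symbols:
        plan.append((s, kind_of.get(s, SpeciesKind.PROTEIN)))
    for s in gene_symbols:
        plan.append((s, SpeciesKind.GENE))
    for s in rna_symbols:
        plan.append((s, SpeciesKind.RNA))
    for s in ion_symbols:
        plan.append((s, SpeciesKind.ION))
    for s in interactor_molecules:
        plan.append((s, SpeciesKind.SIMPLE_MOLECULE))
    assert len(plan) == 170

    idx = 0
    for submap, n, n_polarized in _CORE_SUBMAP_PLAN:
        comp = _SUBMAP_COMPARTMENT[submap]
        for j in range(n):
            sym, kind = plan[idx]
            evidence = _evidence_pair(*next_pmid_pair(), polarized=j < n_polarized)
            entities.append(
                Interactor(
                    symbol=sym,
                    species_kind=kind,
                    localizations={comp},
                    submaps={submap},
                    functional_categories=set(),
                    layer=Layer.CORE,
                    evidence=evidence,
                    is_interactor=True,
                )
            )
            interactor_symbols.append(sym)
            idx += 1

    # non-interactor entities complete the census: 26 small molecules,
    # 58 complexes, 3 degraded/recycled pools
    submap_cycle = [s for s, _, _ in _CORE_SUBMAP_PLAN]
    for i in range(1, 27):
        entities.append(
            Interactor(f"SM{i:02d}", species_kind=SpeciesKind.SIMPLE_MOLECULE,
                       localizations={CompartmentName.CYTOPLASM},
                       submaps={submap_cycle[i % len(submap_cycle)]},
                       layer=Layer.CORE, is_interactor=False)
        )
    for i in range(1, 59):
        entities.append(
            Interactor(f"CPX{i:02d}", species_kind=SpeciesKind.COMPLEX,
                       localizations={CompartmentName.ER},
                       submaps={submap_cycle[i % len(submap_cycle)]},
                       layer=Layer.CORE, is_interactor=False)
        )
    for name in ("POOL-DEGRADED", "POOL-AA", "POOL-NT"):
        entities.append(
            Interactor(name, species_kind=SpeciesKind.DEGRADED_POOL,
                       localizations={CompartmentName.CYTOPLASM},
                       submaps={"endocytosis_recycling_degradation"},
                       layer=Layer.CORE, is_interactor=False)
        )
    return entities, interactor_symbols


def _core_reactions(entities: list[Interactor]) -> list[Reaction]:
    """156 reactions threading the core entities through their compartments."""
    reactions = []
    pool = [i for i in entities if i.species_kind != SpeciesKind.DEGRADED_POOL]
    rtypes = list(ReactionType)
    regs = list(Regulation)
    for i in range(156):
        a = pool[(2 * i) % len(pool)]
        b = pool[(2 * i + 1) % len(pool)]
        if b.symbol == a.symbol:
            b = pool[(2 * i + 2) % len(pool)]
        comp = sorted(a.localizations)[0] if a.localizations else CompartmentName.CYTOPLASM
        regulators = []
        if i % 4 == 0:
            reg = pool[(2 * i + 5) % len(pool)]
            if reg.symbol not in (a.symbol, b.symbol):
                regulators = [(reg.symbol, regs[i % len(regs)])]
        reactions.append(
            Reaction(
                id=f"re{i + 1:03d}",
                rtype=rtypes[i % len(rtypes)],
                reactants=[(a.symbol, comp)],
                products=[(b.symbol, comp)],
                regulators=regulators,
                compartment=comp,
                pmids=[10000001 + (i % 221)],
            )
        )
    return reactions


def _coarse_layer(core_interactor_symbols: list[str]) -> tuple[list[Interactor], list[str]]:
    """1384 coarse interactors, 46 sharing symbols with the core layer."""
    shared = [s for s in core_interactor_symbols if s.startswith("CP")][:46]
    coarse: list[Interactor] = []
    coarse_symbols: list[str] = []
    i = 0
    for submap, category, n in TABLE2_CATEGORY_COUNTS:
        comp = _SUBMAP_COMPARTMENT[submap]
        for _ in range(n):
            i += 1
            sym = f"HT{i:04d}"
            coarse_symbols.append(sym)
            coarse.append(
                Interactor(
                    symbol=sym,
                    species_kind=SpeciesKind.PROTEIN,
                    localizations={comp},
                    submaps={submap},
                    functional_categories={category},
                    layer=Layer.COARSE,
                )
            )
    # the 46 interactors seen by both approaches (removed again at dedup)
    for n, sym in enumerate(shared):
        coarse_symbols.append(sym)
        coarse.append(
            Interactor(
                symbol=sym,
                species_kind=SpeciesKind.PROTEIN,
                submaps={"other"},
                functional_categories={"other"},
                layer=Layer.COARSE,
            )
        )
    return coarse, coarse_symbols


def _ppi_edges(core_interactor_symbols: list[str]) -> list[tuple[str, str, int]]:
    """Havel–Hakimi realization of the designed 145-node degree sequence."""
    seq = sorted(_DEGREE_SEQUENCE, reverse=True)
    g = nx.havel_hakimi_graph(seq)
    ranked = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    protein_interactors = sorted(
        s for s in core_interactor_symbols
        if s not in _NAMED_HUBS and (s.startswith("CP") or s in ("ANO1", "ADRB2", "SLC9A3R1"))
    )
    labels = list(_NAMED_HUBS) + protein_interactors[:139]
    assert len(labels) >= len(ranked)
    mapping = {node: labels[i] for i, (node, _) in enumerate(ranked)}
    edges = sorted(
        (min(mapping[a], mapping[b]), max(mapping[a], mapping[b])) for a, b in g.edges()
    )
    return [(a, b, 20000001 + n) for n, (a, b) in enumerate(edges)]


def _fixture_annotation(core_symbols: list[str], coarse_only: list[str]) -> AnnotationSet:
    universe = sorted(set(core_symbols) | set(coarse_only))
    rng = np.random.default_rng(7590)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    process_names = [
        "protein folding", "intracellular transport", "vesicle-mediated transport",
        "protein localization", "ion transport", "response to stress",
        "protein ubiquitination", "chaperone-mediated folding",
    ]
    for t in range(30):
        size = int(rng.integers(10, 60))
        members = rng.choice(len(universe), size=size, replace=False)
        name = process_names[t % len(process_names)] + ("" if t < len(process_names) else f" {t}")
        terms[f"GO:{7000000 + t}"] = (name, frozenset(universe[i] for i in sorted(members)))
    return AnnotationSet(terms=terms, universe=frozenset(universe))


def packaged_cftr_fixture() -> CftrFixture:
    """Build the packaged CFTR fixture (deterministic, no external data).

    The fixture reproduces the published aggregates exactly: 262 core
    entities (149 proteins / 58 complexes / 28 simple molecules / 13 ions /
    6 genes / 5 RNAs / 3 pools) of which 170 are interactors; 156 reactions
    supported by 221 distinct references; a coarse layer of 1384 interactors
    overlapping the core in 46 symbols (1338 after deduplication, with the
    published per-category counts); and a 145-node / 326-edge PPI network
    whose highest-degree node (38) is the focal protein.
    """
    entities, core_interactor_symbols = _core_entities()
    reactions = _core_reactions(entities)
    coarse, coarse_symbols = _coarse_layer(core_interactor_symbols)

    core_symbol_set = {e.symbol for e in entities}
    pre_dedup = entities + coarse
    deduped = entities + [i for i in coarse if i.symbol not in core_symbol_set]

    edge_rows = _ppi_edges(core_interactor_symbols)
    coarse_only = [s for s in coarse_symbols if s not in core_symbol_set]
    annotation = _fixture_annotation(core_interactor_symbols, coarse_only)

    expected_submap_counts: dict[str, int] = {}
    for submap, _, n in TABLE2_CATEGORY_COUNTS:
        expected_submap_counts[submap] = expected_submap_counts.get(submap, 0) + n
    expected_census = {
        "protein": 149, "complex": 58, "simple_molecule": 28, "ion": 13,
        "gene": 6, "rna": 5, "degraded_pool": 3, "total": 262,
    }
    return CftrFixture(
        dataset=Dataset(interactors=deduped, reactions=reactions),
        pre_dedup_interactors=pre_dedup,
        core_interactor_symbols=core_interactor_symbols,
        coarse_symbols=coarse_symbols,
        edge_rows=edge_rows,
        annotation=annotation,
        expected_submap_counts=expected_submap_counts,
        expected_census=expected_census,
    )
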