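"""Domain types and tabular I/O for curated interactor datasets.

The toolkit models a two-layer interactome map of a focal protein (the CFTR
ion channel in the packaged fixture): a manually curated *core* layer in which
every molecular entity carries literature evidence, and a *coarse* layer of
high-throughput interactor gene lists.  Entities are keyed by their
HUGO-approved gene symbol; small molecules and ions by their ChEBI name.

All tables are plain TSV.  ``interactors.tsv`` holds one row per
(entity, attribute combination); rows sharing a symbol are merged on load.
``evidence.tsv`` holds one literature-support record per row and is joined to
interactors by symbol.  ``reactions.tsv`` holds one biochemical reaction per
row with ``SYMBOL@compartment`` participant encoding.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SpeciesKind",
    "Layer",
    "CompartmentName",
    "Namespace",
    "EvidenceClass",
    "Regulation",
    "ReactionType",
    "Identifier",
    "EvidenceRecord",
    "Interactor",
    "Reaction",
    "Dataset",
    "ValidationReport",
    "FormatError",
    "ValidationError",
    "PROTEIN_KINDS",
    "MAIN_COMPARTMENTS",
    "read_interactor_table",
    "read_evidence_table",
    "read_reaction_table",
    "write_interactor_table",
    "write_evidence_table",
    "write_reaction_table",
    "validate_dataset",
    "entity_census",
]


class FormatError(ValueError):
    """A table violates the expected file format (missing column, bad enum)."""


class ValidationError(ValueError):
    """A table is well-formed but internally inconsistent."""


class SpeciesKind(enum.StrEnum):
    GENE = "gene"
    RNA = "rna"
    PROTEIN = "protein"
    TRUNCATED_PROTEIN = "truncated_protein"
    RECEPTOR = "receptor"
    ION_CHANNEL = "ion_channel"
    COMPLEX = "complex"
    SIMPLE_MOLECULE = "simple_molecule"
    ION = "ion"
    DEGRADED_POOL = "degraded_pool"


#: kinds that count as "proteins" in grouped entity censuses
PROTEIN_KINDS = frozenset(
    {
        SpeciesKind.PROTEIN,
        SpeciesKind.TRUNCATED_PROTEIN,
        SpeciesKind.RECEPTOR,
        SpeciesKind.ION_CHANNEL,
    }
)


class Layer(enum.StrEnum):
    CORE = "core"
    COARSE = "coarse"


class CompartmentName(enum.StrEnum):
    CYTOPLASM = "cytoplasm"
    PLASMA_MEMBRANE = "plasma_membrane"
    EXTRACELLULAR_SPACE = "extracellular_space"
    NUCLEUS = "nucleus"
    ER = "er"
    GOLGI = "golgi"
    VESICLE = "vesicle"
    ENDOSOME = "endosome"
    LYSOSOME = "lysosome"
    MITOCHONDRION = "mitochondrion"


#: the six main cellular compartments of the core map layout
MAIN_COMPARTMENTS = frozenset(
    {
        CompartmentName.CYTOPLASM,
        CompartmentName.PLASMA_MEMBRANE,
        CompartmentName.EXTRACELLULAR_SPACE,
        CompartmentName.NUCLEUS,
        CompartmentName.ER,
        CompartmentName.GOLGI,
    }
)


class Namespace(enum.StrEnum):
    HGNC = "hgnc"
    UNIPROT = "uniprot"
    CHEBI = "chebi"
    PUBCHEM_CID = "pubchem_cid"
    PMID = "pmid"


# per-namespace accession syntax (MIRIAM-style sanity checks, not registry lookups)
_ID_PATTERNS: dict[Namespace, re.Pattern[str]] = {
    Namespace.HGNC: re.compile(r"^(HGNC:)?\d+$"),
    Namespace.UNIPROT: re.compile(r"^[A-Z][A-Z0-9]{5,9}$"),
    Namespace.CHEBI: re.compile(r"^(CHEBI:)?\d+$"),
    Namespace.PUBCHEM_CID: re.compile(r"^\d+$"),
    Namespace.PMID: re.compile(r"^\d+$"),
}


class EvidenceClass(enum.StrEnum):
    SMALL_SCALE_EXPERIMENT = "small_scale_experiment"
    REVIEW = "review"
    HIGH_THROUGHPUT = "high_throughput"


class ReactionType(enum.StrEnum):
    STATE_TRANSITION = "state_transition"
    TRANSCRIPTION = "transcription"
    TRANSLATION = "translation"
    TRANSPORT = "transport"
    COMPLEX_ASSOCIATION = "complex_association"
    COMPLEX_DISSOCIATION = "complex_dissociation"


class Regulation(enum.StrEnum):
    CATALYSIS = "catalysis"
    INHIBITION = "inhibition"
    PHYSICAL_STIMULATION = "physical_stimulation"
    MODULATION = "modulation"


@dataclass(frozen=True)
class Identifier:
    """A MIRIAM-style database cross-reference."""

    namespace: Namespace
    accession: str

    def is_wellformed(self) -> bool:
        return bool(_ID_PATTERNS[self.namespace].match(self.accession))


@dataclass(frozen=True)
class EvidenceRecord:
    """One literature support item for an interactor.

    ``polarized_capable`` records whether the cell line used has the general
    ability to polarize (form apical/basolateral domains); ``human_cells``
    whether the experiment was conducted in human cells.  Review records
    typically carry no cell line.
    """

    pmid: int
    evidence_class: EvidenceClass
    method: str = ""
    cell_line: str = ""
    polarized_capable: bool = False
    human_cells: bool = False
    research_group: str = ""

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValidationError(f"pmid must be positive, got {self.pmid}")


@dataclass
class Interactor:
    """One molecular entity of the map, keyed by gene symbol."""

    symbol: str
    display_name: str = ""
    species_kind: SpeciesKind = SpeciesKind.PROTEIN
    localizations: set[CompartmentName] = field(default_factory=set)
    submaps: set[str] = field(default_factory=set)
    functional_categories: set[str] = field(default_factory=set)
    layer: Layer = Layer.CORE
    annotations: list[Identifier] = field(default_factory=list)
    evidence: list[EvidenceRecord] = field(default_factory=list)
    aliases: set[str] = field(default_factory=set)
    #: True for entities counted in the interactor lists used for layer
    #: comparison (excludes the focal protein's own forms and complexes)
    is_interactor: bool = True

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("interactor symbol must be nonempty")
        self.symbol = self.symbol.upper()
        self.aliases = {a.upper() for a in self.aliases}
        if not self.display_name:
            self.display_name = self.symbol


@dataclass
class Reaction:
    """A biochemical reaction; participants are (symbol, compartment) pairs."""

    id: str
    rtype: ReactionType
    reactants: list[tuple[str, CompartmentName]]
    products: list[tuple[str, CompartmentName]]
    regulators: list[tuple[str, Regulation]] = field(default_factory=list)
    compartment: CompartmentName = CompartmentName.CYTOPLASM
    pmids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ValidationError(f"reaction {self.id}: reactants and products must be nonempty")


@dataclass
class Dataset:
    """A loaded two-layer dataset: entities of both layers plus reactions."""

    interactors: list[Interactor] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def layer(self, layer: Layer) -> list[Interactor]:
        return [i for i in self.interactors if i.layer == layer]

    def symbols(self, layer: Layer | None = None, interactors_only: bool = False) -> set[str]:
        pool = self.interactors if layer is None else self.layer(layer)
        if interactors_only:
            pool = [i for i in pool if i.is_interactor]
        return {i.symbol for i in pool}

    def by_symbol(self) -> dict[str, Interactor]:
        return {i.symbol: i for i in self.interactors}


# ---------------------------------------------------------------------------
# tabular I/O

_INTERACTOR_COLUMNS = [
    "symbol",
    "display_name",
    "species_kind",
    "localizations",
    "submaps",
    "functional_categories",
    "layer",
    "hgnc",
    "uniprot",
    "chebi",
    "pubchem_cid",
]
_EVIDENCE_COLUMNS = [
    "symbol",
    "pmid",
    "evidence_class",
    "method",
    "cell_line",
    "polarized_capable",
    "human_cells",
    "research_group",
]
_REACTION_COLUMNS = ["id", "rtype", "reactants", "products", "regulators", "compartment", "pmids"]


def _read_tsv(path: str | Path, mandatory: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{col}'")
    return df


def _split(cell: str) -> list[str]:
    return [part for part in cell.split(";") if part]


def _coerce_enum(enum_cls: type[enum.StrEnum], value: str, context: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise FormatError(f"{context}: unknown {enum_cls.__name__} value {value!r} (allowed: {allowed})") from None


def read_evidence_table(path: str | Path) -> dict[str, list[EvidenceRecord]]:
    """Read ``evidence.tsv`` into per-symbol record lists.

    Duplicate records for one symbol sharing a PMID are collapsed, keeping the
    first occurrence, so re-stated references cannot inflate evidence counts.
    """
    df = _read_tsv(path, _EVIDENCE_COLUMNS)
    records: dict[str, list[EvidenceRecord]] = {}
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        symbol = str(row.symbol).upper()
        pmid = int(row.pmid)
        if (symbol, pmid) in seen:
            continue
        seen.add((symbol, pmid))
        records.setdefault(symbol, []).append(
            EvidenceRecord(
                pmid=pmid,
                evidence_class=_coerce_enum(EvidenceClass, row.evidence_class, f"{path} symbol {symbol}"),
                method=row.method,
                cell_line=row.cell_line,
                polarized_capable=str(row.polarized_capable) in ("1", "true", "True"),
                human_cells=str(row.human_cells) in ("1", "true", "True"),
                research_group=row.research_group,
            )
        )
    return records


def read_interactor_table(path: str | Path, evidence_path: str | Path | None = None) -> list[Interactor]:
    """Read ``interactors.tsv``; merge rows sharing a symbol; join evidence.

    Rows with the same (uppercased) symbol are merged by set-union of their
    localizations, submaps, categories, aliases and annotations.  A symbol
    appearing with two different species kinds is a validation error.
    """
    df = _read_tsv(path, _INTERACTOR_COLUMNS)
    evidence = read_evidence_table(evidence_path) if evidence_path is not None else {}

    merged: dict[str, Interactor] = {}
    for row in df.itertuples(index=False):
        symbol = str(row.symbol).upper()
        kind = _coerce_enum(SpeciesKind, row.species_kind, f"{path} symbol {symbol}")
        layer = _coerce_enum(Layer, row.layer, f"{path} symbol {symbol}")
        locs = {_coerce_enum(CompartmentName, c, f"{path} symbol {symbol}") for c in _split(row.localizations)}
        annots = [
            Identifier(ns, acc)
            for ns in (Namespace.HGNC, Namespace.UNIPROT, Namespace.CHEBI, Namespace.PUBCHEM_CID)
            if (acc := getattr(row, ns.value))
        ]
        aliases = set(_split(getattr(row, "aliases", "")))
        is_interactor = str(getattr(row, "is_interactor", "1")) in ("1", "true", "True")
        if symbol in merged:
            existing = merged[symbol]
            if existing.species_kind != kind:
                raise ValidationError(
                    f"{path}: symbol {symbol} declared as both "
                    f"{existing.species_kind.value} and {kind.value}"
                )
            existing.localizations |= locs
            existing.submaps |= set(_split(row.submaps))
            existing.functional_categories |= set(_split(row.functional_categories))
            existing.aliases |= {a.upper() for a in aliases}
            for a in annots:
                if a not in existing.annotations:
                    existing.annotations.append(a)
        else:
            merged[symbol] = Interactor(
                symbol=symbol,
                display_name=row.display_name or symbol,
                species_kind=kind,
                localizations=locs,
                submaps=set(_split(row.submaps)),
                functional_categories=set(_split(row.functional_categories)),
                layer=layer,
                annotations=annots,
                evidence=list(evidence.get(symbol, [])),
                aliases=aliases,
                is_interactor=is_interactor,
            )
    return list(merged.values())


def read_reaction_table(path: str | Path) -> list[Reaction]:
    """Read ``reactions.tsv``.  Participants are encoded ``SYMBOL@compartment``."""
    df = _read_tsv(path, _REACTION_COLUMNS)

    def parse_participants(cell: str, context: str) -> list[tuple[str, CompartmentName]]:
        out = []
        for token in _split(cell):
            if "@" not in token:
                raise FormatError(f"{context}: participant {token!r} is not SYMBOL@compartment")
            sym, comp = token.split("@", 1)
            out.append((sym.upper(), _coerce_enum(CompartmentName, comp, context)))
        return out

    reactions = []
    for row in df.itertuples(index=False):
        ctx = f"{path} reaction {row.id}"
        regulators = []
        for token in _split(row.regulators):
            if ":" not in token:
                raise FormatError(f"{ctx}: regulator {token!r} is not SYMBOL:regulation")
            sym, reg = token.split(":", 1)
            regulators.append((sym.upper(), _coerce_enum(Regulation, reg, ctx)))
        reactions.append(
            Reaction(
                id=row.id,
                rtype=_coerce_enum(ReactionType, row.rtype, ctx),
                reactants=parse_participants(row.reactants, ctx),
                products=parse_participants(row.products, ctx),
                regulators=regulators,
                compartment=_coerce_enum(CompartmentName, row.compartment, ctx),
                pmids=[int(p) for p in _split(row.pmids)],
            )
        )
    return reactions


def _join(values) -> str:
    return ";".join(values)


def write_interactor_table(interactors: list[Interactor], path: str | Path) -> None:
    rows = []
    for i in sorted(interactors, key=lambda x: x.symbol):
        by_ns = {a.namespace.value: a.accession for a in i.annotations}
        rows.append(
            {
                "symbol": i.symbol,
                "display_name": i.display_name,
                "species_kind": i.species_kind.value,
                "localizations": _join(sorted(c.value for c in i.localizations)),
                "submaps": _join(sorted(i.submaps)),
                "functional_categories": _join(sorted(i.functional_categories)),
                "layer": i.layer.value,
                "hgnc": by_ns.get("hgnc", ""),
                "uniprot": by_ns.get("uniprot", ""),
                "chebi": by_ns.get("chebi", ""),
                "pubchem_cid": by_ns.get("pubchem_cid", ""),
                "aliases": _join(sorted(i.aliases)),
                "is_interactor": "1" if i.is_interactor else "0",
            }
        )
    pd.DataFrame(rows, columns=_INTERACTOR_COLUMNS + ["aliases", "is_interactor"]).to_csv(
        path, sep="\t", index=False
    )


def write_evidence_table(interactors: list[Interactor], path: str | Path) -> None:
    rows = []
    for i in sorted(interactors, key=lambda x: x.symbol):
        for e in i.evidence:
            rows.append(
                {
                    "symbol": i.symbol,
                    "pmid": e.pmid,
                    "evidence_class": e.evidence_class.value,
                    "method": e.method,
                    "cell_line": e.cell_line,
                    "polarized_capable": "1" if e.polarized_capable else "0",
                    "human_cells": "1" if e.human_cells else "0",
                    "research_group": e.research_group,
                }
            )
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_reaction_table(reactions: list[Reaction], path: str | Path) -> None:
    rows = []
    for r in reactions:
        rows.append(
            {
                "id": r.id,
                "rtype": r.rtype.value,
                "reactants": _join(f"{s}@{c.value}" for s, c in r.reactants),
                "products": _join(f"{s}@{c.value}" for s, c in r.products),
                "regulators": _join(f"{s}:{g.value}" for s, g in r.regulators),
                "compartment": r.compartment.value,
                "pmids": _join(str(p) for p in r.pmids),
            }
        )
    pd.DataFrame(rows, columns=_REACTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation and census


@dataclass
class ValidationReport:
    unresolved_participants: list[str] = field(default_factory=list)
    malformed_identifiers: list[str] = field(default_factory=list)
    empty_evidence_core: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not (self.unresolved_participants or self.malformed_identifiers or self.empty_evidence_core)


def validate_dataset(
    interactors: list[Interactor],
    reactions: list[Reaction] | None = None,
    require_core_evidence: bool = True,
) -> ValidationReport:
    """Cross-check a dataset; returns a report instead of raising.

    Flags reaction participants or regulators that do not resolve in the
    interactor table, identifier accessions failing their namespace syntax,
    and curated core entities with no supporting evidence.
    """
    report = ValidationReport()
    known = {i.symbol for i in interactors}
    aliases = {a for i in interactors for a in i.aliases}
    for i in interactors:
        for a in i.annotations:
            if not a.is_wellformed():
                report.malformed_identifiers.append(f"{i.symbol}: {a.namespace.value}:{a.accession}")
        if require_core_evidence and i.layer == Layer.CORE and i.is_interactor and not i.evidence:
            report.empty_evidence_core.append(i.symbol)
    for r in reactions or []:
        participants = [s for s, _ in r.reactants] + [s for s, _ in r.products] + [s for s, _ in r.regulators]
        for sym in participants:
            if sym not in known and sym not in aliases:
                report.unresolved_participants.append(f"{r.id}: {sym}")
    return report


def entity_census(interactors: list[Interactor], grouped: bool = False) -> dict[str, int]:
    """Count entities per species kind; one count per (symbol, kind) pair.

    With ``grouped=True`` the protein subkinds (generic, truncated, receptor,
    ion channel) are rolled up under ``protein``, matching how curated map
    summaries usually report "proteins".  The returned mapping carries a
    ``total`` key equal to the sum over kinds.
    """
    counts: dict[str, int] = {}
    for pair in {(i.symbol, i.species_kind) for i in interactors}:
        kind = pair[1]
        key = "protein" if grouped and kind in PROTEIN_KINDS else kind.value
        counts[key] = counts.get(key, 0) + 1
    counts["total"] = sum(counts.values())
    return counts
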