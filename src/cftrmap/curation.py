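"""Literature-evidence curation: inclusion rule, polarity flags, submap summaries.

An interactor enters the curated core layer only when supported by at least
two *independent* pieces of high-quality evidence: either two small-scale
experiments conducted in human cells with distinct PMIDs, or two reviews from
different research groups.  High-throughput records are stored but never
count toward inclusion; they mark coarse-layer candidates.

Polarity provenance is tracked per evidence record: a cell line is flagged
polarized when it has the general ability to polarize.  An interactor is
"polarized" as soon as one supporting record comes from such a cell line.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .model import EvidenceClass, EvidenceRecord, Interactor, PROTEIN_KINDS

__all__ = [
    "Basis",
    "PolarityStatus",
    "CurationDecision",
    "SubmapSummary",
    "passes_inclusion_rule",
    "polarity_status",
    "curate",
    "summarize_submaps",
    "round_half_up",
]


class Basis(enum.StrEnum):
    TWO_SMALL_SCALE = "two_small_scale"
    TWO_REVIEWS = "two_reviews"
    REJECTED = "rejected"


class PolarityStatus(enum.StrEnum):
    POLARIZED = "polarized"
    NON_POLARIZED_ONLY = "non_polarized_only"
    NO_CELL_EVIDENCE = "no_cell_evidence"


@dataclass(frozen=True)
class CurationDecision:
    symbol: str
    accepted: bool
    basis: Basis
    polarity_status: PolarityStatus

    def __post_init__(self) -> None:
        assert self.accepted == (self.basis != Basis.REJECTED)


def passes_inclusion_rule(evidence: list[EvidenceRecord]) -> Basis:
    """Apply the two-independent-references inclusion rule.

    Acceptance bases, in order of precedence:

    * ``two_small_scale`` — at least two records of class
      ``small_scale_experiment`` in human cells with distinct PMIDs;
    * ``two_reviews`` — at least two ``review`` records from distinct
      research groups;
    * otherwise ``rejected``.

    High-throughput records never contribute.  Independence is
    operationalized as distinct PMIDs for experiments and distinct research
    groups for reviews.
    """
    experimental_pmids = {
        e.pmid
        for e in evidence
        if e.evidence_class == EvidenceClass.SMALL_SCALE_EXPERIMENT and e.human_cells
    }
    if len(experimental_pmids) >= 2:
        return Basis.TWO_SMALL_SCALE
    review_groups = {
        e.research_group for e in evidence if e.evidence_class == EvidenceClass.REVIEW and e.research_group
    }
    if len(review_groups) >= 2:
        return Basis.TWO_REVIEWS
    return Basis.REJECTED


def polarity_status(evidence: list[EvidenceRecord]) -> PolarityStatus:
    """Classify polarity provenance from the evidence list.

    ``polarized`` if any record comes from a polarization-capable cell line;
    ``non_polarized_only`` if cell-based records exist but none is
    polarization-capable; ``no_cell_evidence`` when no record names a cell
    line (e.g. review-only support).
    """
    if any(e.polarized_capable for e in evidence):
        return PolarityStatus.POLARIZED
    if any(e.cell_line for e in evidence):
        return PolarityStatus.NON_POLARIZED_ONLY
    return PolarityStatus.NO_CELL_EVIDENCE


def curate(interactors: list[Interactor]) -> list[CurationDecision]:
    """One decision per interactor, in input order."""
    decisions = []
    for i in interactors:
        basis = passes_inclusion_rule(i.evidence)
        decisions.append(
            CurationDecision(
                symbol=i.symbol,
                accepted=basis != Basis.REJECTED,
                basis=basis,
                polarity_status=polarity_status(i.evidence),
            )
        )
    return decisions


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (52.5 → 53)."""
    return int(math.floor(x + 0.5))


@dataclass
class SubmapSummary:
    submap: str
    entity_counts: dict[str, int] = field(default_factory=dict)
    n_interactors: int = 0
    n_polarized: int = 0
    polarized_fraction: int = 0  # integer percent, half-up


def summarize_submaps(interactors: list[Interactor], grouped: bool = True) -> list[SubmapSummary]:
    """Per-submap entity counts and percentage of polarized interactors.

    Entity counts cover every entity assigned to the submap (an entity in k
    submaps contributes to all k).  The polarized percentage uses interactors
    only (``is_interactor``) as denominator: 100 x polarized / interactors,
    rounded half-up to an integer.  With ``grouped=True`` protein subkinds
    are rolled up under ``protein``.
    """
    summaries: dict[str, SubmapSummary] = {}
    for i in interactors:
        status = polarity_status(i.evidence)
        for submap in i.submaps:
            s = summaries.setdefault(submap, SubmapSummary(submap=submap))
            kind = i.species_kind
            key = "protein" if grouped and kind in PROTEIN_KINDS else kind.value
            s.entity_counts[key] = s.entity_counts.get(key, 0) + 1
            if i.is_interactor:
                s.n_interactors += 1
                if status == PolarityStatus.POLARIZED:
                    s.n_polarized += 1
    for s in summaries.values():
        if s.n_interactors:
            s.polarized_fraction = round_half_up(100.0 * s.n_polarized / s.n_interactors)
    return sorted(summaries.values(), key=lambda s: s.submap)
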