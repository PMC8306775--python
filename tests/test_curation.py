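"""Inclusion rule, polarity classification, and submap summaries."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cftrmap.curation import (
    Basis,
    PolarityStatus,
    curate,
    passes_inclusion_rule,
    polarity_status,
    round_half_up,
    summarize_submaps,
)
from cftrmap.model import EvidenceClass, EvidenceRecord, Interactor, SpeciesKind


def rec(pmid, cls=EvidenceClass.SMALL_SCALE_EXPERIMENT, human=True, group="g", cell="HEK293", polarized=False):
    return EvidenceRecord(
        pmid=pmid,
        evidence_class=cls,
        cell_line=cell,
        polarized_capable=polarized,
        human_cells=human,
        research_group=group,
    )


class TestInclusionRule:
    def test_two_distinct_pmid_human_experiments_accepted(self):
        # the well-documented scaffold-protein situation: several independent
        # experimental confirmations in human cells
        evidence = [rec(1), rec(2), rec(3, cls=EvidenceClass.REVIEW, group="r1")]
        assert passes_inclusion_rule(evidence) == Basis.TWO_SMALL_SCALE

    def test_single_experimental_reference_rejected(self):
        # a transcription factor reported once and never confirmed elsewhere
        assert passes_inclusion_rule([rec(1)]) == Basis.REJECTED

    def test_empty_evidence_rejected(self):
        assert passes_inclusion_rule([]) == Basis.REJECTED

    def test_two_reviews_same_group_fail_independence(self):
        evidence = [rec(1, cls=EvidenceClass.REVIEW, group="g1"), rec(2, cls=EvidenceClass.REVIEW, group="g1")]
        assert passes_inclusion_rule(evidence) == Basis.REJECTED

    def test_two_reviews_different_groups_accepted(self):
        evidence = [rec(1, cls=EvidenceClass.REVIEW, group="g1"), rec(2, cls=EvidenceClass.REVIEW, group="g2")]
        assert passes_inclusion_rule(evidence) == Basis.TWO_REVIEWS

    def test_same_pmid_twice_is_one_reference(self):
        assert passes_inclusion_rule([rec(7), rec(7)]) == Basis.REJECTED

    def test_non_human_experiments_do_not_count(self):
        assert passes_inclusion_rule([rec(1, human=False), rec(2, human=False)]) == Basis.REJECTED

    def test_high_throughput_records_never_contribute(self):
        evidence = [rec(1, cls=EvidenceClass.HIGH_THROUGHPUT), rec(2, cls=EvidenceClass.HIGH_THROUGHPUT)]
        assert passes_inclusion_rule(evidence) == Basis.REJECTED


class TestPolarityStatus:
    def test_one_polarized_record_among_five_suffices(self):
        evidence = [rec(i) for i in range(1, 5)] + [rec(5, cell="CALU-3", polarized=True)]
        assert polarity_status(evidence) == PolarityStatus.POLARIZED

    def test_all_non_polarized_cell_lines(self):
        assert polarity_status([rec(1), rec(2), rec(3)]) == PolarityStatus.NON_POLARIZED_ONLY

    def test_review_only_evidence_has_no_cell_information(self):
        evidence = [rec(1, cls=EvidenceClass.REVIEW, cell=""), rec(2, cls=EvidenceClass.REVIEW, cell="")]
        assert polarity_status(evidence) == PolarityStatus.NO_CELL_EVIDENCE


evidence_strategy = st.lists(
    st.builds(
        rec,
        pmid=st.integers(min_value=1, max_value=50),
        cls=st.sampled_from(list(EvidenceClass)),
        human=st.booleans(),
        group=st.sampled_from(["g1", "g2", "g3"]),
        cell=st.sampled_from(["", "HEK293", "CALU-3"]),
        polarized=st.booleans(),
    ),
    max_size=8,
)


@settings(max_examples=200, derandomize=True)
@given(evidence=evidence_strategy, extra=evidence_strategy)
def test_appending_evidence_is_monotone(evidence, extra):
    """More evidence can only strengthen a decision, never weaken it."""
    before_basis = passes_inclusion_rule(evidence)
    after_basis = passes_inclusion_rule(evidence + extra)
    if before_basis != Basis.REJECTED:
        assert after_basis != Basis.REJECTED
    if polarity_status(evidence) == PolarityStatus.POLARIZED:
        assert polarity_status(evidence + extra) == PolarityStatus.POLARIZED


@settings(max_examples=100, derandomize=True)
@given(evidence=evidence_strategy)
def test_duplicated_pmids_change_no_decision(evidence):
    doubled = evidence + [EvidenceRecord(**e.__dict__) for e in evidence]
    assert passes_inclusion_rule(doubled) == passes_inclusion_rule(evidence)
    assert polarity_status(doubled) == polarity_status(evidence)


@settings(max_examples=100, derandomize=True)
@given(evidence=evidence_strategy)
def test_polarity_matches_direct_predicate_evaluation(evidence):
    """Cross-check against a literal re-statement of the classification rule."""
    expected = (
        PolarityStatus.POLARIZED
        if any(e.polarized_capable for e in evidence)
        else PolarityStatus.NON_POLARIZED_ONLY
        if any(e.cell_line != "" for e in evidence)
        else PolarityStatus.NO_CELL_EVIDENCE
    )
    assert polarity_status(evidence) == expected


def _interactor(symbol, submap, polarized, kind=SpeciesKind.PROTEIN, is_interactor=True):
    evidence = [rec(hash(symbol) % 1000 + 1, polarized=polarized, cell="CALU-3" if polarized else "HEK293")]
    return Interactor(
        symbol, species_kind=kind, submaps={submap}, evidence=evidence, is_interactor=is_interactor
    )


class TestSummarizeSubmaps:
    def test_two_of_three_polarized_rounds_to_67(self):
        members = [_interactor(f"A{i}", "m", polarized=i < 2) for i in range(3)]
        (summary,) = summarize_submaps(members)
        assert summary.polarized_fraction == 67

    def test_all_polarized_is_100(self):
        members = [_interactor(f"A{i}", "m", polarized=True) for i in range(4)]
        assert summarize_submaps(members)[0].polarized_fraction == 100

    def test_fraction_invariant_under_reordering(self):
        members = [_interactor(f"A{i}", "m", polarized=i % 3 == 0) for i in range(10)]
        shuffled = members.copy()
        random.Random(1).shuffle(shuffled)
        assert summarize_submaps(members) == summarize_submaps(shuffled)

    def test_interactor_in_k_submaps_counts_k_times(self):
        i = _interactor("A", "m1", polarized=True)
        i.submaps = {"m1", "m2"}
        summaries = summarize_submaps([i])
        assert [s.submap for s in summaries] == ["m1", "m2"]
        assert all(s.n_interactors == 1 for s in summaries)

    def test_transcription_shaped_submap_matches_published_row(self):
        """A nucleus submap with 28 proteins, 16 nucleic-acid entities and one
        small molecule, whose interactor subset is 32/33 polarized -> 97%."""
        members = []
        for i in range(28):
            members.append(_interactor(f"P{i:02d}", "transcription", polarized=True))
        for i in range(16):
            kind = SpeciesKind.RNA if i % 2 else SpeciesKind.GENE
            members.append(
                _interactor(f"N{i:02d}", "transcription", polarized=i < 4, kind=kind, is_interactor=i < 5)
            )
        members.append(
            _interactor("ATP", "transcription", polarized=False, kind=SpeciesKind.SIMPLE_MOLECULE, is_interactor=False)
        )
        # interactors: 28 proteins + 5 nucleic acids (4 polarized) = 33, 32 polarized
        (summary,) = summarize_submaps(members)
        assert summary.entity_counts["protein"] == 28
        assert summary.entity_counts["rna"] + summary.entity_counts["gene"] == 16
        assert summary.entity_counts["simple_molecule"] == 1
        assert summary.n_interactors == 33
        assert summary.polarized_fraction == 97


def test_packaged_fixture_reproduces_all_published_percentages(core_entities):
    by_submap = {s.submap: s.polarized_fraction for s in summarize_submaps(core_entities)}
    assert by_submap == {
        "transcription": 97,
        "translation_folding_erqc": 69,
        "secretory_pathway": 52,
        "activity_regulation": 82,
        "endocytosis_recycling_degradation": 74,
    }


def test_curate_decisions_align_with_rule(core_entities):
    decisions = curate(core_entities)
    for i, d in zip(core_entities, decisions):
        assert d.accepted == (passes_inclusion_rule(i.evidence) != Basis.REJECTED)


@pytest.mark.parametrize("x,expected", [(51.5, 52), (96.97, 97), (0.4, 0), (0.5, 1)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
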