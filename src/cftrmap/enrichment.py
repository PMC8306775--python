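"""Over-representation analysis of annotation terms and top-k list comparison.

This is a transparent, documented stand-in for semantic-network gene-list
prioritization services: each term is tested with the hypergeometric upper
tail (population = universe, successes = term members, draws = query) and
p-values are Benjamini–Hochberg adjusted across all tested terms.  Ranks are
deterministic, breaking adjusted-p ties by term id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "TopTermComparison",
    "GmtParseError",
    "load_gmt",
    "ora",
    "compare_top_terms",
]

log = logging.getLogger(__name__)


class GmtParseError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Term id → (name, member gene set) over an explicit background universe."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise GmtParseError(f"term {term_id} is empty")
            if not genes <= self.universe:
                raise GmtParseError(f"term {term_id} has members outside the universe")


def load_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationSet:
    """Load a GMT gene-set file (term, description, tab-separated genes).

    Symbols are uppercased and de-duplicated within each term.  When a
    universe is supplied, member genes outside it are dropped (with a logged
    count) and terms left empty are discarded; otherwise the universe
    defaults to the union of all term members.
    """
    path = Path(path)
    universe_set = {s.upper() for s in universe} if universe is not None else None
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    dropped_genes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            term_id, description = fields[0], fields[1]
            genes = {g.upper() for g in fields[2:] if g}
            if universe_set is not None:
                kept = genes & universe_set
                dropped_genes += len(genes - universe_set)
                genes = kept
            if genes:
                terms[term_id] = (description, frozenset(genes))
            else:
                log.info("%s:%d: term %s dropped (no members in universe)", path, lineno, term_id)
    if dropped_genes:
        log.info("%s: dropped %d gene memberships outside the universe", path, dropped_genes)
    if universe_set is None:
        universe_set = set().union(*(g for _, g in terms.values())) if terms else set()
    return AnnotationSet(terms=terms, universe=frozenset(universe_set))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p_value: float
    adjusted_p: float
    rank: int
    percent_query: float  # share of query genes carrying the term, in percent


def ora(query: Iterable[str], annotation: AnnotationSet) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every annotated term in a query.

    Query genes outside the universe are dropped with a warning; an empty
    query after filtering is an error.  For each term, the p-value is
    :math:`P(X \\ge k)` for a hypergeometric draw of the query size from the
    universe with the term members as successes.  Benjamini–Hochberg
    adjustment spans all tested terms; results are returned rank-ordered
    (adjusted p, then term id).
    """
    query_set = {s.upper() for s in query}
    outside = query_set - annotation.universe
    if outside:
        log.warning("ora: %d query genes outside the universe dropped", len(outside))
        query_set -= outside
    if not query_set:
        raise ValueError("query is empty after restricting to the universe")

    M = len(annotation.universe)
    n = len(query_set)
    term_ids = sorted(annotation.terms)
    pvals = []
    overlaps = []
    for tid in term_ids:
        _, members = annotation.terms[tid]
        k = len(query_set & members)
        overlaps.append(k)
        pvals.append(float(hypergeom.sf(k - 1, M, len(members), n)))
    adjusted = multipletests(pvals, method="fdr_bh")[1] if pvals else []

    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=annotation.terms[tid][0],
            overlap=k,
            query_size=n,
            term_size=len(annotation.terms[tid][1]),
            universe_size=M,
            p_value=p,
            adjusted_p=float(ap),
            rank=0,
            percent_query=100.0 * k / n,
        )
        for tid, k, p, ap in zip(term_ids, overlaps, pvals, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term_id))
    return [
        EnrichmentResult(**{**r.__dict__, "rank": i}) for i, r in enumerate(results, start=1)
    ]


def to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("term_id")


@dataclass(frozen=True)
class TopTermComparison:
    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def compare_top_terms(
    result_a: list[EnrichmentResult], result_b: list[EnrichmentResult], k: int
) -> TopTermComparison:
    """Set comparison of the top-k ranked term ids of two enrichment results."""
    if k > len(result_a) or k > len(result_b):
        raise ValueError(f"k={k} exceeds the number of ranked terms")
    top_a = {r.term_id for r in sorted(result_a, key=lambda r: r.rank)[:k]}
    top_b = {r.term_id for r in sorted(result_b, key=lambda r: r.rank)[:k]}
    return TopTermComparison(
        shared=frozenset(top_a & top_b),
        only_a=frozenset(top_a - top_b),
        only_b=frozenset(top_b - top_a),
    )
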