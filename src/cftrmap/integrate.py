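"""Core/coarse layer comparison: overlap, deduplication, consistency checks.

The two layers of the map are compared on gene symbols (after uppercasing
and alias resolution).  Interactors present in both layers are kept only in
the manually curated core layer; the coarse layer is deduplicated against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .model import Dataset, Interactor, Layer, entity_census

__all__ = ["LayerOverlap", "ConsistencyCheck", "compute_overlap", "dedup_coarse", "consistency_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LayerOverlap:
    core_only: frozenset[str]
    shared: frozenset[str]
    coarse_only: frozenset[str]

    @property
    def n_core_only(self) -> int:
        return len(self.core_only)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_coarse_only(self) -> int:
        return len(self.coarse_only)


def compute_overlap(core: Iterable[str], coarse: Iterable[str]) -> LayerOverlap:
    """Partition two symbol lists into core-only / shared / coarse-only sets.

    Inputs are uppercased; duplicates and ordering are irrelevant.
    """
    core_set = {s.upper() for s in core}
    coarse_set = {s.upper() for s in coarse}
    return LayerOverlap(
        core_only=frozenset(core_set - coarse_set),
        shared=frozenset(core_set & coarse_set),
        coarse_only=frozenset(coarse_set - core_set),
    )


def dedup_coarse(interactors: list[Interactor]) -> tuple[list[Interactor], list[Interactor]]:
    """Drop coarse-layer entries whose symbol also appears in the core layer.

    Returns ``(kept, removed)``; ``kept`` preserves input order.  Idempotent:
    a second pass removes nothing.
    """
    core_symbols = {i.symbol for i in interactors if i.layer == Layer.CORE}
    core_symbols |= {a for i in interactors if i.layer == Layer.CORE for a in i.aliases}
    kept, removed = [], []
    for i in interactors:
        if i.layer == Layer.COARSE and i.symbol in core_symbols:
            removed.append(i)
            log.info("dedup: %s removed from coarse layer (kept in core)", i.symbol)
        else:
            kept.append(i)
    return kept, removed


@dataclass(frozen=True)
class ConsistencyCheck:
    name: str
    expected: int
    observed: int

    @property
    def passed(self) -> bool:
        return self.expected == self.observed


def consistency_report(
    dataset: Dataset,
    expected_submap_counts: dict[str, int] | None = None,
    expected_census: dict[str, int] | None = None,
) -> list[ConsistencyCheck]:
    """Cross-table arithmetic checks on a two-layer dataset.

    Always checks that the per-submap interactor counts of the deduplicated
    coarse layer sum to its size (each interactor counted once per submap it
    belongs to — exact when submap membership is unique) and that the entity
    census total equals the sum of its per-kind counts.  Externally expected
    counts (e.g. a published summary table) can be supplied for comparison.
    """
    checks: list[ConsistencyCheck] = []
    deduped, _ = dedup_coarse(dataset.interactors)
    coarse = [i for i in deduped if i.layer == Layer.COARSE]

    submap_counts: dict[str, int] = {}
    for i in coarse:
        for s in sorted(i.submaps) or ["(none)"]:
            submap_counts[s] = submap_counts.get(s, 0) + 1
    checks.append(
        ConsistencyCheck(
            name="coarse_submap_counts_sum_to_dedup_size",
            expected=len(coarse),
            observed=sum(submap_counts.values()),
        )
    )
    census = entity_census(dataset.interactors)
    checks.append(
        ConsistencyCheck(
            name="census_total_equals_kind_sum",
            expected=census["total"],
            observed=sum(v for k, v in census.items() if k != "total"),
        )
    )
    for s, n in submap_counts.items():
        checks.append(ConsistencyCheck(name=f"submap_count_nonnegative:{s}", expected=abs(n), observed=n))
    if expected_submap_counts is not None:
        for s, n in sorted(expected_submap_counts.items()):
            checks.append(
                ConsistencyCheck(name=f"submap_count:{s}", expected=n, observed=submap_counts.get(s, 0))
            )
        checks.append(
            ConsistencyCheck(
                name="expected_submap_counts_sum_to_dedup_size",
                expected=len(coarse),
                observed=sum(expected_submap_counts.values()),
            )
        )
    if expected_census is not None:
        # published entity censuses describe the curated core map
        grouped = entity_census(dataset.layer(Layer.CORE), grouped=True)
        for kind, n in sorted(expected_census.items()):
            checks.append(ConsistencyCheck(name=f"census:{kind}", expected=n, observed=grouped.get(kind, 0)))
    return checks
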