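# Methods

## The two-layer map model

The toolkit models a focal protein's interactome as two layers with
explicitly different evidential standing. The *core* layer is a mechanistic
SBGN Process Description model: entities (genes, RNAs, proteins and their
truncated/receptor/ion-channel subkinds, complexes, simple molecules, ions,
and degraded-material pools) are keyed by HUGO gene symbol (ChEBI name for
small molecules), placed in cellular compartments, and connected through
typed reactions (state transition, transcription, translation, transport,
complex association/dissociation) with typed regulations (catalysis,
inhibition, physical stimulation, modulation). Every entity can carry
MIRIAM-style identifier annotations (HGNC, UniProt, ChEBI, PubChem CID,
PMID), syntax-checked per namespace. The *coarse* layer is a flat list of
interactor genes from high-throughput screens, each with a subcellular
localization, a submap assignment, and a functional category taken from the
source publication.

### Inclusion rule and independence

An interactor is accepted into the core layer when it has **(a)** at least
two `small_scale_experiment` records with `human_cells=True` and distinct
PMIDs, or **(b)** at least two `review` records from distinct research
groups. Independence is operationalized as *distinct PMIDs* for experiments
and *distinct research-group keys* for reviews; the underlying sources do
not define independence more formally, and any sharper notion (shared
authors, shared labs across PMIDs) would need data the tables do not carry.
High-throughput records are stored but never count toward inclusion — they
mark coarse-layer candidates. Duplicate PMIDs within one interactor's
evidence are collapsed at load time, which makes the rule idempotent; adding
evidence can only strengthen a decision (monotonicity), and both properties
are enforced by tests.

### Polarity provenance

Cell lines are classified by their *general ability to polarize*, not by
whether they were actually polarized in a given experiment (which the data
cannot resolve). An interactor is `polarized` as soon as one supporting
record names a polarization-capable line, `non_polarized_only` when
cell-based records exist but none qualifies, and `no_cell_evidence` for
review-only support. Submap summaries report the percentage of polarized
interactors with the **interactor count as denominator** (not the full
entity count, which includes complexes and metabolite pools that carry no
cell-line provenance); percentages are rounded half-up to integers.

## Map generation

`build_core_map` emits one PD entity-pool glyph per (entity, compartment)
occurrence — the union of annotated localizations and reaction-participation
compartments — with SBGN clone markers for entities present in several
compartments, one process glyph per reaction (`association`/`dissociation`
classes for complex formation and breakup), consumption/production arcs, and
regulation arcs mapped to the PD classes catalysis/inhibition/stimulation/
modulation. Fill colors encode role: blue for the focal protein's forms,
green for polarized provenance, yellow for non-polarized-only, grey
compartments, red/orange for degradation/recycling categories in coarse
maps. The concrete hex values are package defaults chosen to match those
verbal color families and are configurable through `ColorScheme`.

`build_coarse_submap` abstracts one lifecycle step into a central triple —
focal input activity → state transition → focal output activity — and adds
one `biological activity` glyph plus one influence arc per interactor.
Gene-directed categories (`dna replication`, `dna repair`, `chromatin`)
route their arc onto the input (gene) node; all other categories influence
the transition. Influence arcs default to `unknown influence` because the
source gene lists rarely state a direction; the class is a parameter.
Interactors with no category in the submap are skipped with a logged
warning, so the invariant `#influence arcs = #non-skipped interactors`
always holds.

### Layout and serialization

The layout is an original, deliberately simple deterministic grid: within
each compartment glyphs are sorted by (label, id) and placed on a
fixed-width grid; compartments are stacked bottom-to-top in the order
nucleus → ER → Golgi → cytoplasm → plasma membrane → extracellular space,
mirroring the focal protein's journey, and grow to fit their glyph count so
grids never overflow. Identical input and configuration produce
byte-identical SBGN-ML, which the tests assert. Coordinates are written with
two decimals; the layout only ever produces values exact at that precision,
so write→read round trips are exact.

SBGN-ML 0.2 is read and written directly with `lxml` (the historical
`libsbgnpy` helper is not a dependency); fill/stroke styles travel in a
`renderInformation` extension as SBGN editors do. The reader reports the
XML line number for malformed documents and for arcs referencing missing
glyphs.

## Layer integration

Overlap between layers is computed on uppercased gene symbols after alias
resolution (an explicit alias column, never fuzzy matching); the three
membership sets are disjoint by construction. Deduplication removes coarse
entries whose symbol (or alias target) exists in the core layer and is
idempotent. Consistency checks are plain integer arithmetic: per-submap
coarse counts must sum to the deduplicated coarse size, and entity-census
totals must equal the sum of per-kind counts; externally published summary
counts can be supplied and are compared check-by-check. Published entity
censuses are compared against the **core layer's** census, since that is
what such censuses describe.

## Network topology

The PPI network is a weighted undirected `networkx` graph; edge weight
counts distinct supporting records and PMIDs are kept per edge. Betweenness
uses Brandes' exact algorithm, unweighted by default (the provenance of
interaction-record counts is too heterogeneous to justify distances by
default) with an optional 1/weight distance mode. Hub ranking is by degree
with lexicographic tie-breaks. Communities come from seeded Louvain
(`networkx.community.louvain_communities`, resolution 1.0 by default).

The power-law fit is implemented in-package: discrete maximum likelihood
for `p(k) ∝ k^(−α)` on the tail `k ≥ k_min` (Hurwitz-zeta normalization,
bounded scalar minimization), with `k_min` selected by minimizing the KS
distance between empirical and fitted tail CDFs over candidates retaining
at least `min_tail = 10` observations. The *plausibly power-law* verdict
requires `KS < 0.1` **and** `α ≤ 5`. The exponent bound matters: a Poisson
degree tail (Erdős–Rényi graph) can reach KS ≈ 0.03–0.07 on a short tail,
but only with MLE exponents of 8–20, far outside the α ≈ 2–3.5 range of
empirical scale-free networks, whereas preferential-attachment graphs fit
with α ≈ 2.6–2.9. Both thresholds are configurable. A histogram with fewer
than two distinct positive degrees returns a failure result rather than
raising.

## Term enrichment

The enrichment module is a transparent stand-in for proprietary semantic-
network prioritization services, which publish no algorithmic detail to
replicate. It performs classical over-representation analysis: per term the
hypergeometric upper tail `P(X ≥ overlap)` with the annotation universe as
population, Benjamini–Hochberg adjustment across all tested terms
(`statsmodels`), and deterministic ranking by (adjusted p, term id). The
universe defaults to the union of all loaded term members but should be
supplied explicitly — enrichment is not interpretable without a deliberate
background choice. Top-k comparisons between two ranked results are plain
set arithmetic on term ids; agreement figures published for proprietary
rankings are database-version- and algorithm-dependent and are not
reproduced here.

## Synthetic data

`generate_dataset` emulates the *shape* of curated data: per-submap
interactor counts with an exact number of polarized interactors
(`round_half_up(n · fraction)`), evidence satisfying or violating the
inclusion rule in controlled proportions, chain-structured reactions,
PPI edge lists drawn from seeded preferential-attachment, Erdős–Rényi, or
planted-partition models, and random GMT gene sets. Everything flows from
one explicit seed and regenerates byte-identically.

`packaged_cftr_fixture` realizes the published **aggregate** description of
the CFTR Lifecycle Map: 262 core entities with the published species-kind
census (149/58/28/13/6/5/3), 170 of them interactors; 156 reactions drawing
on 221 distinct references; per-submap polarized percentages 97/69/52/82/74
(denominators chosen per submap so the integer rounding is exact); a coarse
layer of 1384 interactors overlapping the core in 46 symbols, whose
deduplicated 1338 members follow the published per-category counts; and a
145-node/326-edge PPI network realized by the Havel–Hakimi algorithm on a
hand-designed degree sequence (focal protein degree 38; named hubs
HSP90AA1/STUB1/UBE2I/NR3C1/VCP at 30/27/24/22/20; exactly 30 degree-1 and
10 degree-6 nodes). Four of the 149 proteins are deliberately absent from
the network, matching the published node count; the toolkit reports such
absentees explicitly rather than guessing why. The fixture is synthetic at
the gene level — filler symbols are prefixed `CP`/`HT` — and claims
fidelity only for the aggregates; passing tests therefore demonstrate
correct arithmetic and construction logic, not gene-level agreement with
any real curation.

One published inconsistency is worth noting: the Transcription submap is
described as holding 28 proteins plus 16 RNAs/gene elements, while the
global census admits only 11 nucleic-acid entities in total, and a 97%
polarized share is unreachable with a 44- or 45-element denominator. The
summary tests therefore exercise that submap shape with an interactor
subset (33 interactors, 32 polarized → 96.97 → 97%) rather than forcing the
entity counts to double as denominators.

## Numerical and scale choices

Percentages round half-up to integers. BH-adjusted p-value ties break by
term id; degree ties by symbol. Property tests that need an exhaustive
oracle run at small sizes where enumeration is exact: betweenness against
all-pairs shortest-path enumeration on graphs of ≤ 40 nodes, ORA against
combinatorial enumeration on universes of ≤ 15 genes. Power-law verdicts
are checked across 20 seeds per graph model at n = 2000, a size where the
two models separate cleanly while the full suite stays fast.

## Limitations

The toolkit deliberately performs no literature reading, no live database
queries (localization and interaction tables are consumed pre-resolved),
and no semantic-network prioritization. The grid layout is legible and
deterministic but makes no attempt at the aesthetics of hand-drawn maps.
The power-law assessment is a goodness heuristic, not a likelihood-ratio
model comparison against alternatives such as log-normal tails.
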