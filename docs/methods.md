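# Methods

This note documents the models and procedures implemented in `domarch`, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, what the synthetic data generator does and does
not emulate, and the package's known limitations.

## Coordinates and identity scoring

All domain coordinates are 1-based inclusive, everywhere (the convention of
InterPro's display and of iTOL annotation files). A call spanning (s, e) has
length e − s + 1, and excising it yields a peptide of exactly that length.

Pairwise sequence identity is defined through global alignment under
match = 1, mismatch = 0, gap = 0 scoring. Under this scheme the optimal
score equals the maximal number of identically aligned residue pairs (gaps
are free, so mismatches can always be avoided), which is computed with
Biopython's `PairwiseAligner`. Identity is that count divided by:

- the **shorter** sequence — clustering (CD-HIT convention);
- the **longer** sequence — domain-level comparisons (conservative: a
  fragment is not "100 % identical" to a full-length domain);
- the **query** — characterized-protein rescue and assembly attribution,
  where the query's full length is the natural reference.

Because only matches score, "alignment coverage" of a sequence coincides
with identical matches over that sequence's length; the clustering coverage
floors (`coverage_short`, `coverage_long`, both default 0) are interpreted
accordingly.

## Sequence preparation

Deduplication keeps the first occurrence of any identifier or exact
sequence string. Partial proteins are detected by a case-insensitive,
word-boundary `partial` token in the description ("partially" does not
match). Reference-presence filtering takes an explicit identifier list (in
production workflows this is the set of sequences present in a
comprehensive archive such as UniParc; annotations only exist for those).

Clustering is greedy and incremental: sequences are visited longest-first;
each joins the first representative it matches at `identity_threshold`
(default **0.85**, deliberately permissive because the unit of interest is
the architecture, not fine sequence variation) or founds a new cluster.
Every cluster member therefore satisfies the threshold against its
representative by construction, which the tests assert exhaustively. The
word-filter heuristics of CD-HIT itself are not reproduced; CD-HIT can be
substituted behind the same contract when exact parity at scale matters.

Characterized proteins are always added back after clustering. When a
characterized protein is absent from the dataset entirely, its best hit in
a user-supplied rescue pool stands in iff identical matches / query length
≥ `min_similarity` (default **0.95**); rescue requires the characterized
sequence itself (an identifier alone cannot be aligned), so the rescue API
accepts an id → record mapping, and ids without sequences are logged as
unrescued.

## Annotation consolidation

The consolidation pipeline is: **curate → eligibility filter → same-name
merge → overlap resolution**.

Eligibility drops an annotation when (a) its name is missing or the literal
`"None"`; (b) it marks a signal peptide — a marker substring (default
`SIGNAL`, case-sensitive; configurable) in the name or a signal-prediction
source database (default PHOBIUS); or (c) its span is outside
[`min_domain_size`, `max_domain_size`] = **[10, 800] AA** by default —
shorter hits are typically conserved sites, longer ones typically cover
several domains.

Same-name merging replaces every chain of overlapping same-protein,
same-curated-name annotations with one call spanning the outermost
positions, sources and accessions unioned. This repairs split detections of
a single domain by different databases. Disjoint same-name calls are kept:
repeated domains are real. Merging runs before overlap resolution so that a
domain split across two databases competes as one full-length call.

Overlap resolution: two calls conflict when their intersection exceeds
`overlap_threshold` (default **0.31**) of the **shorter** span. The shorter
denominator is the conservative choice — it flags containment, which the
longer denominator can miss. The winner of a conflict is decided by a
strict total order: best database priority (default order: curated
signature databases before structure-inferred and disorder databases, fully
user-overridable), then longer span, then smaller start, then smaller name.
Same-name conflicts cannot reach this stage (they were merged), so the
chain never ties.

Resolution deletes the loser of one conflicting pair at a time, with one
restriction: **a pair is only resolvable while its winner is itself
undefeated** (loses no conflict of its own). Without this restriction the
fixpoint depends on the order pairs are visited — a call can be deleted by
a winner that is later deleted itself, even though the first call conflicts
with nothing that survives. With it, the procedure is confluent: conflict
edges only disappear as calls are deleted, so an undefeated call stays
undefeated, every deletion is justified by a surviving winner, and the
result equals greedy retention in winner-rank order. The tests verify this
equivalence against an exhaustive enumeration of all deletion orders. The
post-condition — no retained pair overlaps by more than the threshold — is
asserted on every run.

A caveat worth knowing: the retained **count** is not monotone in
`max_domain_size`. Widening the window can admit a long span that wins
conflicts against two shorter retained calls, shrinking the set net by one.
The monotone facts are that the *eligible* set grows with the window and
that retention is monotone on conflict-free inputs.

## Architectures, attribution and the co-occurrence network

The architecture of a protein is its calls' curated names in start order,
joined canonically with `" + "`. Order is significant: `A + B` and `B + A`
are distinct assemblies. Assemblies are enumerated over all proteins with
at least one call; member lists partition those proteins (asserted), and
per-assembly taxonomy and EC metadata are aggregated from the records.

Additional sequences are attributed to assemblies by best-identity hit
against the analyzed representatives (identity = matches / query length),
assigned when the best identity reaches `min_identity` — default **0.85**,
matching the clustering threshold, since no separate attribution cutoff is
canonical. Prevalences (assigned fraction per assembly plus an unassigned
remainder) sum to 1.

The co-occurrence network counts each domain instance once per analyzed
protein (each assembly weighted by its member count; a per-assembly
weighting is available since either universe can be of interest) and each
consecutive pair in an architecture as one adjacency; tandem repeats yield
self-loops. Conservation laws — node counts sum to total instances, edge
counts to Σ(architecture length − 1) — are validated after every build.
GraphML export carries `occurrence`/`frequency` attributes and round-trips
losslessly.

## Trees and iTOL annotation

Alignment and tree inference are delegated to MAFFT and FastTree (both at
default settings; FastTree's default local supports are Shimodaira-Hasegawa
values from 1000 resamples) behind adapter objects with in-process stubs
for testing. Proteins without any detected domain are excluded from the
alignment and logged — including characterized ones; there is nothing to
draw for them, and a domainless leaf would misrepresent the analysis.

Two annotation files are produced. `DATASET_DOMAINS` draws each leaf's
architecture as shapes with 1-based inclusive coordinates; shape/colour
pairs are assigned by walking the shape × colour product in sorted-name
order, so the assignment is unique per domain and stable across runs.
`TREE_COLORS` colours the labels of characterized leaves by activity; a
protein with several recorded EC numbers triggers a warning and uses the
first EC in dotted-integer-tuple order (numeric, so 3.2.1.4 precedes
3.2.1.176; wildcard components sort last). The three activities with
conventional colours (blue 3.2.1.14, green 3.2.1.91, red 3.2.1.176) claim
them first; other ECs draw from the palette. Both writers are
byte-deterministic for identical inputs.

## Domain-level evolution statistics

Domains are excised by their stored boundaries and compared within named
groups: all C(n, 2) unordered within-group pairs are scored (self-pairs
excluded), identities use the longer-sequence denominator, and groups are
compared with Kruskal-Wallis (mid-rank tie correction; the degenerate
all-identical input returns H = 0, p = 1 by convention) followed by Dunn's
post hoc z tests with tie correction,

z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j) ),

two-sided normal p-values, Bonferroni-adjusted by default (Holm and
unadjusted available). Summaries report percent identities; fractions are
used internally.

A statistical caveat: the C(n, 2) pairwise identities of a group are not
independent observations (each sequence participates in n − 1 pairs), so
rank tests on them overstate power. With many short sequences per group
even trivial differences reach significance. The discrimination test in
this package therefore uses groups of 10 members and 300 AA peptides —
domain-sized sequences, few enough pairs that same-divergence groups are
typically indistinguishable while a 5-fold divergence difference is
separated at p < 0.001.

## Synthetic data generator

The generator emulates the input statistics the consolidation step faces in
real annotation data: every planted domain is reported by
`n_sources_per_domain` (default 3) member databases under
database-specific raw names (exercising curation and same-name merging)
with independently jittered edges, and decoy annotations are mixed in at
per-protein rates — signal peptides (0.3), `"None"`-named hits (0.2),
spans covering several domains or exceeding the size cap (0.15), and
sub-minimum fragments (0.2). Domain lengths default to 40–160 AA, linkers
to 6–30 AA, and residues are uniform over the 20 canonical amino acids.

The default architecture pool contains 35 assemblies: the 8 architectures
observed among characterized members of a GH48-like cellulase family
(weighted by their observed prevalence, from the dominant
`CBM + Immunoglobulin-like + Catalytic domain` at 43 down to the rare
double-catalytic arrangement at 1) plus 27 rare novel combinations built
deterministically from a ten-type domain alphabet. The first 35 generated
proteins cover every pool architecture once; 8 proteins are marked
characterized with family ECs.

Recovery of the planted truth is guaranteed by construction, and the
generator asserts both halves of the guarantee on every protein: edge
jitter is capped at min(⌊jitter·length⌋, ⌊(min linker − 1)/2⌋), so (i) all
hits of one domain contain the domain core and hence chain-overlap into a
single merged call, and (ii) hits of neighbouring domains can never touch.
Multi-domain decoy spans carry distinct names (no false merging) and come
from low-priority databases (they lose every conflict against true calls).

What the generator does **not** emulate: realistic domain sequence content
(no HMM-emission realism — residues are uniform), database-specific
boundary biases, correlated errors between member databases, and taxonomy-
or clade-structured sequence similarity. Passing tests therefore
demonstrate the correctness of the algorithms under the stated noise
model, not annotation accuracy on real proteins — which is bounded by the
upstream signature databases themselves.

## Problem sizes and determinism

The verification suite runs at: 1000 random instances of ≤ 8 annotations
for the resolution oracle; 200 proteins / 35 architectures / 3 sources per
domain with decoys for end-to-end recovery; 500 random short pairs for the
alignment oracle; 5 families × 10 mutants at 5 % divergence for clustering;
10-member, 300 AA groups at 5 %/5 %/25 % divergence for the statistics; and
30-protein bundles for round-trips. These sizes give fully deterministic,
seconds-scale runs while exercising every code path; all randomness flows
from explicit seeds, and repeated runs are byte-identical.

## Known limitations

- Consolidation quality is bounded by the upstream annotations; the package
  consolidates predictions, it does not make them.
- The 31 % overlap threshold and 10–800 AA size window are calibration
  constants adopted from surveys of large annotation collections; they are
  configuration, not re-derived here.
- The greedy clusterer is exact to its stated definition but quadratic; for
  very large families use the CD-HIT adapter path.
- Attribution requires no minimum coverage of the hit beyond the identity
  ratio itself; a short query can be attributed on a strong partial match.
- Taxonomy is input metadata; conflicting sources are not reconciled.
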