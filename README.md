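# domarch — protein domain architecture analysis

`domarch` analyses the modular structure of protein families, with
carbohydrate-active enzymes (CAZymes) as the motivating use case. Enzymes in
families such as the glycoside hydrolases are frequently multi-domain: a
catalytic domain is combined with carbohydrate-binding modules (CBMs),
immunoglobulin-like domains, dockerins and other auxiliary modules, and this
domain *architecture* — the ordered N→C list of domains — governs substrate
targeting, activity and evolutionary fate.

The practical obstacle is that domain annotations come from many signature
databases at once (Pfam, CDD, SMART, PROSITE profiles, PRINTS, HAMAP, PIRSF,
SFLD, NCBIFAMs, PANTHER, CATH-Gene3D, SUPERFAMILY, MobiDB Lite), so a single
protein region typically carries several partially overlapping hits under
different names. `domarch` turns that redundant pile into exactly one clean
architecture per protein and builds the family-level summaries on top of it:

- **io_store** — FASTA, annotation tables (TSV/JSON), characterized-protein
  and curation tables, and a three-table SQLite store
  (`ProteinSequences`, `DomainAssemblies`, `DomainCuration`).
- **sequence_prep** — deduplication, partial-protein and reference-presence
  filtering, greedy CD-HIT-style clustering (default identity 0.85), and the
  rule that experimentally characterized proteins always survive clustering
  (with a ≥95 % best-hit rescue when one is missing from the dataset).
- **consolidation** — the core algorithm: name curation, eligibility rules
  (valid name; not a signal peptide; span within 10–800 AA), outermost-edge
  merging of split same-domain detections, and iterative overlap resolution
  (conflict when two calls overlap by more than 31 % of the shorter span;
  the winner is decided by database preference, then span length).
- **architecture** — canonical architecture strings
  (`"CBM + Immunoglobulin-like + Catalytic domain"`), enumeration of the
  distinct assemblies in a dataset, and attribution of extra sequences to
  assemblies by best-hit identity.
- **cooccurrence** — the domain co-occurrence network (node = occurrence
  count, edge = adjacency count, self-loops for tandem repeats), exported as
  Cytoscape-importable GraphML or edge TSV.
- **phylo_annotation** — MAFFT/FastTree adapters and the two iTOL annotation
  files: a `DATASET_DOMAINS` file drawing each leaf's architecture and a
  `TREE_COLORS` file colouring characterized leaves by enzymatic activity.
- **domain_evolution** — excision of individual domains by stored
  boundaries, all-pairs identity within groups (best global alignment score
  over the longer sequence), Kruskal-Wallis and Dunn's post hoc tests.
- **synthetic_fixtures** — seeded generators of proteins, redundant noisy
  multi-source annotations and decoys with known ground truth, so the whole
  pipeline is testable offline.

Pairwise identity everywhere uses the classical match-count scoring
(match = 1, mismatch = 0, gaps free): the optimal global alignment score is
the maximal number of identically aligned residues, divided by the shorter
sequence, the longer sequence, or the query, depending on the step.

## Worked example

Consolidating one protein annotated redundantly by five databases plus a
signal-peptide hit:

```python
from domarch import ConsolidationConfig, CurationMap, consolidate, architecture_string
from domarch.model import RawAnnotation

hits = [
    RawAnnotation("AAD39947.1", "Pfam",        "PF02011",  "Glyco_hydro_48",  95, 719),
    RawAnnotation("AAD39947.1", "SUPERFAMILY", "SSF52047", "GH48_like",      101, 741),
    RawAnnotation("AAD39947.1", "CDD",         "cd07958",  "GH48",           120, 705),
    RawAnnotation("AAD39947.1", "Pfam",        "PF00942",  "CBM_3",           35,  88),
    RawAnnotation("AAD39947.1", "SMART",       "SM01063",  "CBM3",            33,  90),
    RawAnnotation("AAD39947.1", "PHOBIUS",     "SIGNAL",   "SIGNAL_PEPTIDE",   1,  28),
]
curation = CurationMap(entries={
    "Glyco_hydro_48": "Catalytic domain", "GH48_like": "Catalytic domain",
    "GH48": "Catalytic domain", "CBM_3": "CBM", "CBM3": "CBM",
})
calls, drops = consolidate("AAD39947.1", hits, curation, ConsolidationConfig())
for c in calls:
    print(f"{c.curated_name:18s} {c.start:4d}-{c.end:<4d} sources={sorted(c.source_dbs)}")
print("architecture:", architecture_string(calls))
print("dropped:", len(drops), "annotations")
```

prints

```
CBM                  33-90   sources=['Pfam', 'SMART']
Catalytic domain     95-741  sources=['CDD', 'Pfam', 'SUPERFAMILY']
architecture: CBM + Catalytic domain
dropped: 4 annotations
```

The signal peptide was removed by the eligibility rules, the three partial
catalytic-domain detections were merged to their outermost edges (95–741),
and the two CBM hits collapsed to a single call — one clean two-domain
architecture remains.

The same flow scales to whole families through the CLI:

```
$ domarch simulate --outdir demo --seed 1 --n-proteins 40
$ domarch annotate --fasta demo/proteins.fasta --annotations demo/annotations.tsv \
    --curation demo/curation.tsv --characterized demo/characterized.tsv \
    --presence demo/presence.txt --store demo/analysis.sqlite \
    --assemblies-tsv demo/assemblies.tsv --no-cluster
40 sequences analyzed (0 duplicates, 0 partial dropped)
35 distinct domain assemblies -> demo/analysis.sqlite
$ domarch network --store demo/analysis.sqlite --out demo/net.graphml
10 domain types, 135 instances, 95 adjacencies -> demo/net.graphml
```

`demo/assemblies.tsv` then lists each architecture with its member count,
taxonomy and the EC numbers of its characterized members, and
`domarch itol` writes the tree plus both iTOL annotation files
(`--tree` accepts a precomputed Newick file if MAFFT/FastTree are not
available).

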