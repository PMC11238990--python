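"""Core data model shared by all pipeline stages.

Coordinates are 1-based inclusive everywhere (the convention used by
InterPro's web display and by iTOL annotation files); converters, if any,
live at module boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Taxonomic super-groups a protein may be assigned to.
TAXONOMY_GROUPS = ("Archaea", "Bacteria", "Viruses", "Eukaryota", "Unclassified")

#: The 13 InterPro member databases whose hits the consolidation step merges,
#: plus PHOBIUS (whose hits mark signal peptides / transmembrane topology and
#: are always discarded by the eligibility rules).
MEMBER_DATABASES = (
    "CATH-Gene3D",
    "CDD",
    "HAMAP",
    "MobiDB Lite",
    "PANTHER",
    "Pfam",
    "PIRSF",
    "PRINTS",
    "PROSITE profiles",
    "SFLD",
    "SMART",
    "SUPERFAMILY",
    "NCBIFAMs",
    "PHOBIUS",
)

#: Default database preference for overlap resolution: curated, signature
#: focused databases before structure-inferred or disorder databases.
#: Fully user-overridable via ConsolidationConfig.db_priority.
DEFAULT_DB_PRIORITY = (
    "Pfam",
    "CDD",
    "SMART",
    "PROSITE profiles",
    "PRINTS",
    "HAMAP",
    "PIRSF",
    "SFLD",
    "NCBIFAMs",
    "PANTHER",
    "CATH-Gene3D",
    "SUPERFAMILY",
    "MobiDB Lite",
)

#: Strings treated as "no name" on an annotation (rule a of eligibility).
MISSING_NAME_MARKERS = ("None", "")

AMINO_ACID_ALPHABET = "ACDEFGHIKLMNPQRSTVWYXBZJUO*"

#: Separator used to render an architecture as a single string.
ARCHITECTURE_SEPARATOR = " + "


@dataclass
class ProteinRecord:
    """One protein sequence plus the metadata the pipeline tracks for it."""

    protein_id: str
    sequence: str
    description: str = ""
    taxonomy_group: str = "Unclassified"
    characterized: bool = False
    ec_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must be nonempty")
        if self.taxonomy_group not in TAXONOMY_GROUPS:
            raise ValueError(
                f"{self.protein_id}: unknown taxonomy group {self.taxonomy_group!r}"
            )
        if not self.characterized and self.ec_numbers:
            raise ValueError(
                f"{self.protein_id}: EC numbers given but characterized=False"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RawAnnotation:
    """One domain hit from one source database, 1-based inclusive coordinates."""

    protein_id: str
    source_db: str
    accession: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.accession}: invalid span "
                f"({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainCall:
    """A retained, curated, possibly merged annotation after consolidation."""

    protein_id: str
    curated_name: str
    start: int
    end: int
    source_dbs: frozenset[str] = frozenset()
    accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.curated_name}: invalid span "
                f"({self.start}, {self.end})"
            )
        self.source_dbs = frozenset(self.source_dbs)
        self.accessions = frozenset(self.accessions)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Architecture:
    """One distinct ordered (N-to-C) combination of domains across a dataset."""

    ordered_names: list[str]
    protein_ids: list[str] = field(default_factory=list)
    prevalence: Optional[float] = None
    taxonomy_set: set[str] = field(default_factory=set)
    example_id: Optional[str] = None
    ec_set: set[str] = field(default_factory=set)

    @property
    def canonical(self) -> str:
        return ARCHITECTURE_SEPARATOR.join(self.ordered_names)

    @property
    def member_count(self) -> int:
        return len(self.protein_ids)


@dataclass
class ClusterConfig:
    """Greedy clustering parameters (CD-HIT-style).

    identity_threshold: minimum identity of a member to its representative,
        measured against the shorter of the two sequences; default 0.85.
    coverage_short / coverage_long: minimum fraction of the shorter / longer
        sequence covered by identical aligned positions; both default 0.
    """

    identity_threshold: float = 0.85
    coverage_short: float = 0.0
    coverage_long: float = 0.0

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_short", "coverage_long"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class CharacterizedRescueConfig:
    """Substitution rule for characterized proteins missing from the dataset.

    min_similarity: identical matches divided by the query protein length must
        reach this fraction for the best hit to stand in; default 0.95.
    """

    min_similarity: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_similarity <= 1.0):
            raise ValueError("min_similarity must lie in [0, 1]")


@dataclass
class ConsolidationConfig:
    """Parameters of the annotation cleaning step.

    overlap_threshold: two annotations conflict when their intersection
        exceeds this fraction of the shorter span; default 0.31.
    min_domain_size / max_domain_size: retained spans must be 10-800 AA by
        default (shorter hits are conserved sites, longer ones typically
        cover several domains).
    db_priority: source databases from most to least preferred; the winner of
        a conflicting pair comes from the earlier database.
    signal_markers / signal_sources: annotations whose name contains a marker
        substring, or that come from a signal-prediction source, are dropped.
    """

    overlap_threshold: float = 0.31
    min_domain_size: int = 10
    max_domain_size: int = 800
    db_priority: tuple[str, ...] = DEFAULT_DB_PRIORITY
    signal_markers: frozenset[str] = frozenset({"SIGNAL"})
    signal_sources: frozenset[str] = frozenset({"PHOBIUS"})

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must lie in [0, 1]")
        if not (0 < self.min_domain_size <= self.max_domain_size):
            raise ValueError("need 0 < min_domain_size <= max_domain_size")
        self.db_priority = tuple(self.db_priority)
        self.signal_markers = frozenset(self.signal_markers)
        self.signal_sources = frozenset(self.signal_sources)

    def priority_index(self, source_db: str) -> int:
        """Rank of a database; unknown databases rank after all listed ones."""
        try:
            return self.db_priority.index(source_db)
        except ValueError:
            return len(self.db_priority)


@dataclass
class CurationMap:
    """User-chosen overarching names replacing raw signature names."""

    entries: dict[str, str] = field(default_factory=dict)
    applied_log: list[tuple[str, str]] = field(default_factory=list)

    def curate(self, raw_name: str) -> str:
        """Return the curated name for ``raw_name``, logging any substitution."""
        curated = self.entries.get(raw_name, raw_name)
        if curated != raw_name:
            self.applied_log.append((raw_name, curated))
        return curated
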