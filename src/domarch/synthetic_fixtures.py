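"""Seeded synthetic datasets with known ground truth.

Emulates the statistics of real multi-source domain annotation data:
every planted domain is reported redundantly by several member databases
under database-specific raw names and with jittered boundaries, and decoy
annotations (signal peptides, nameless hits, spans covering multiple
domains, sub-minimum fragments) are mixed in. The planted architectures
are the ground truth against which consolidation, assembly enumeration,
clustering and network construction are checked.

The jitter bound is derived so that recovery is guaranteed by
construction: jittered same-domain hits always chain-overlap (they share
the domain core), and jittered hits of neighbouring domains never touch
(edge shifts are capped below half the shortest linker). The generator
asserts both properties on every emitted protein.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .model import ProteinRecord, RawAnnotation

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: The four core domain types of a multi-domain cellulase family plus the
#: rarer auxiliary types used to build novel assemblies.
CORE_DOMAIN_NAMES = ("Catalytic domain", "CBM", "Dockerin", "Immunoglobulin-like")
EXTRA_DOMAIN_NAMES = (
    "Sialidase",
    "GH10 catalytic domain",
    "Concanavalin A-like lectin",
    "Selenoprotein W-like",
    "CalX-like",
    "Keratinocyte proline-rich",
)

#: Architectures of characterized proteins in a GH48-like family, with
#: weights proportional to their observed prevalence among characterized
#: representatives.
KNOWN_ARCHITECTURES: tuple[tuple[tuple[str, ...], float], ...] = (
    (("Catalytic domain",), 23.0),
    (("Catalytic domain", "CBM"), 4.5),
    (("Catalytic domain", "Dockerin"), 3.6),
    (("Catalytic domain", "Immunoglobulin-like", "CBM"), 10.0),
    (("CBM", "Immunoglobulin-like", "Catalytic domain"), 43.0),
    (("Catalytic domain", "Immunoglobulin-like", "Immunoglobulin-like", "CBM"), 2.7),
    (
        (
            "Catalytic domain",
            "Immunoglobulin-like",
            "Immunoglobulin-like",
            "Immunoglobulin-like",
            "CBM",
        ),
        1.9,
    ),
    (("Catalytic domain", "CBM", "CBM", "CBM", "Catalytic domain"), 1.0),
)

#: ECs of the four activities known in the emulated family.
FAMILY_ECS = ("3.2.1.4", "3.2.1.14", "3.2.1.91", "3.2.1.176")

_TRUE_HIT_SOURCES = ("Pfam", "CDD", "SMART", "PROSITE profiles", "PRINTS", "HAMAP")
_DECOY_SOURCES = ("SUPERFAMILY", "CATH-Gene3D", "MobiDB Lite")


def default_architecture_pool(
    n_novel: int = 27,
) -> list[tuple[tuple[str, ...], float]]:
    """The 8 known architectures plus ``n_novel`` deterministic novel ones.

    Novel assemblies are built from the full domain-name alphabet by a
    fixed-seed shuffle, are distinct from each other and from the known
    set, and each carries a small sampling weight (rare architectures).
    """
    rng = random.Random(20240711)
    known = {names for names, _ in KNOWN_ARCHITECTURES}
    pool = list(KNOWN_ARCHITECTURES)
    alphabet = CORE_DOMAIN_NAMES + EXTRA_DOMAIN_NAMES
    seen = set(known)
    while len(pool) < len(KNOWN_ARCHITECTURES) + n_novel:
        length = rng.randint(1, 6)
        candidate = tuple(rng.choice(alphabet) for _ in range(length))
        if candidate in seen:
            continue
        seen.add(candidate)
        pool.append((candidate, 0.4))
    return pool


@dataclass
class FixtureSpec:
    """Parameters of a synthetic annotation dataset."""

    seed: int = 0
    n_proteins: int = 200
    architecture_pool: list[tuple[tuple[str, ...], float]] = field(
        default_factory=default_architecture_pool
    )
    domain_length_range: tuple[int, int] = (40, 160)
    linker_length_range: tuple[int, int] = (6, 30)
    n_sources_per_domain: int = 3
    boundary_jitter: float = 0.1
    decoy_rates: dict[str, float] = field(
        default_factory=lambda: {
            "signal": 0.3,
            "none_name": 0.2,
            "oversized": 0.15,
            "undersized": 0.2,
        }
    )
    mutation_rate_for_families: float = 0.05
    n_characterized: int = 8
    min_domain_size: int = 10
    max_domain_size: int = 800

    def __post_init__(self) -> None:
        if not (0.0 <= self.boundary_jitter <= 1.0):
            raise ValueError("boundary_jitter must lie in [0, 1]")
        for key, rate in self.decoy_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"decoy rate {key!r} must lie in [0, 1]")
        if self.n_sources_per_domain < 1:
            raise ValueError("n_sources_per_domain must be >= 1")
        if self.domain_length_range[0] < self.min_domain_size + 2 * self.jitter_cap:
            raise ValueError(
                "domains too short: jittered hits could fall below min_domain_size"
            )

    @property
    def jitter_cap(self) -> int:
        """Maximum edge shift: below half the shortest linker, so jittered
        hits of neighbouring domains can never meet."""
        return max(0, (self.linker_length_range[0] - 1) // 2)


@dataclass
class FixtureBundle:
    """Everything :func:`generate` emits, with ground truth."""

    records: list[ProteinRecord]
    annotations: list[RawAnnotation]
    characterized_table: dict[str, list[str]]
    presence_ids: set[str]
    curation_entries: dict[str, str]
    truth_architectures: dict[str, str]
    truth_boundaries: dict[str, list[tuple[str, int, int]]]


def _raw_alias(name: str, source_index: int) -> str:
    """Database-specific raw signature name for a curated domain name."""
    suffixes = ("", " signature", " superfamily", " profile", " conserved region")
    return name + suffixes[source_index % len(suffixes)]


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a synthetic dataset; deterministic for a fixed seed."""
    rng = random.Random(spec.seed)
    pool = list(spec.architecture_pool)
    if not pool:
        raise ValueError("architecture_pool must be nonempty")
    weights = [w for _, w in pool]

    records: list[ProteinRecord] = []
    annotations: list[RawAnnotation] = []
    characterized_table: dict[str, list[str]] = {}
    curation_entries: dict[str, str] = {}
    truth_arch: dict[str, str] = {}
    truth_bounds: dict[str, list[tuple[str, int, int]]] = {}

    acc_counter = 0

    def next_accession() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:06d}"

    for index in range(spec.n_proteins):
        # the first len(pool) proteins cover every architecture once, the
        # rest are sampled by weight
        if index < len(pool):
            arch_names = pool[index][0]
        else:
            arch_names = rng.choices([names for names, _ in pool], weights=weights)[0]
        pid = f"SYNP{index + 1:05d}.1"

        # lay out termini, domains and linkers along the sequence
        segments: list[tuple[str | None, int]] = []
        segments.append((None, rng.randint(*spec.linker_length_range)))
        for i, name in enumerate(arch_names):
            if i > 0:
                segments.append((None, rng.randint(*spec.linker_length_range)))
            length = rng.randint(*spec.domain_length_range)
            if not (spec.min_domain_size <= length <= spec.max_domain_size):
                raise ValueError("infeasible spec: domain length outside size window")
            segments.append((name, length))
        segments.append((None, rng.randint(*spec.linker_length_range)))

        boundaries: list[tuple[str, int, int]] = []
        pos = 1
        for name, length in segments:
            if name is not None:
                boundaries.append((name, pos, pos + length - 1))
            pos += length
        protein_length = pos - 1
        sequence = "".join(rng.choice(CANONICAL_AA) for _ in range(protein_length))

        characterized = index < spec.n_characterized
        ecs = sorted(rng.sample(FAMILY_ECS, rng.randint(1, 2))) if characterized else []
        taxonomy = rng.choices(
            ("Bacteria", "Eukaryota", "Viruses", "Unclassified"),
            weights=(0.8, 0.12, 0.03, 0.05),
        )[0]
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=sequence,
                description="synthetic multi-domain protein",
                taxonomy_group=taxonomy,
                characterized=characterized,
                ec_numbers=ecs,
            )
        )
        if characterized:
            characterized_table[pid] = ecs

        # redundant true hits: several sources per domain, jittered edges,
        # database-specific raw names
        for name, start, end in boundaries:
            length = end - start + 1
            jitter = min(spec.jitter_cap, int(spec.boundary_jitter * length))
            source_offset = rng.randrange(len(_TRUE_HIT_SOURCES))
            hit_spans = []
            for s in range(spec.n_sources_per_domain):
                source = _TRUE_HIT_SOURCES[
                    (source_offset + s) % len(_TRUE_HIT_SOURCES)
                ]
                ds = rng.randint(-jitter, jitter)
                de = rng.randint(-jitter, jitter)
                hs = max(1, start + ds)
                he = min(protein_length, end + de)
                raw = _raw_alias(name, s)
                if raw != name:
                    curation_entries[raw] = name
                annotations.append(
                    RawAnnotation(pid, source, next_accession(), raw, hs, he)
                )
                hit_spans.append((hs, he))
            # recovery guarantee, part 1: all hits share the domain core
            core = (start + jitter, end - jitter)
            assert all(hs <= core[0] and he >= core[1] for hs, he in hit_spans)

        # recovery guarantee, part 2: neighbouring merged extents stay disjoint
        for (_, _, e1), (_, s2, _) in zip(boundaries, boundaries[1:]):
            assert e1 + spec.jitter_cap < s2 - spec.jitter_cap

        # decoys
        rates = spec.decoy_rates
        if rng.random() < rates.get("signal", 0.0):
            sig_end = min(protein_length, rng.randint(15, 30))
            source, name_ = (
                ("PHOBIUS", "SIGNAL_PEPTIDE")
                if rng.random() < 0.5
                else ("Pfam", "SIGNAL_PEPTIDE_REGION")
            )
            annotations.append(
                RawAnnotation(pid, source, next_accession(), name_, 1, sig_end)
            )
        if rng.random() < rates.get("none_name", 0.0):
            s = rng.randint(1, max(1, protein_length - 30))
            annotations.append(
                RawAnnotation(
                    pid, rng.choice(_DECOY_SOURCES), next_accession(), "None",
                    s, min(protein_length, s + rng.randint(15, 60)),
                )
            )
        if rng.random() < rates.get("oversized", 0.0):
            if protein_length > spec.max_domain_size:
                span = (1, spec.max_domain_size + 1)
            else:
                span = (1, protein_length)  # covers every domain; loses on priority
            annotations.append(
                RawAnnotation(
                    pid, rng.choice(_DECOY_SOURCES), next_accession(),
                    "Uncharacterized protein region", span[0], span[1],
                )
            )
        if rng.random() < rates.get("undersized", 0.0):
            s = rng.randint(1, max(1, protein_length - 8))
            annotations.append(
                RawAnnotation(
                    pid, rng.choice(_DECOY_SOURCES), next_accession(),
                    "Conserved site", s, s + rng.randint(2, spec.min_domain_size - 2),
                )
            )

        from .model import ARCHITECTURE_SEPARATOR

        truth_arch[pid] = ARCHITECTURE_SEPARATOR.join(arch_names)
        truth_bounds[pid] = boundaries

    return FixtureBundle(
        records=records,
        annotations=annotations,
        characterized_table=characterized_table,
        presence_ids={rec.protein_id for rec in records},
        curation_entries=curation_entries,
        truth_architectures=truth_arch,
        truth_boundaries=truth_bounds,
    )


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to disk in the exact dialects the readers accept."""
    from . import io_store

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "annotations": outdir / "annotations.tsv",
        "characterized": outdir / "characterized.tsv",
        "presence": outdir / "presence.txt",
        "curation": outdir / "curation.tsv",
        "truth": outdir / "truth.tsv",
    }
    io_store.write_fasta(bundle.records, paths["fasta"])
    with open(paths["annotations"], "w") as handle:
        handle.write("\t".join(io_store.ANNOTATION_TSV_COLUMNS) + "\n")
        for ann in bundle.annotations:
            handle.write(
                f"{ann.protein_id}\t{ann.source_db}\t{ann.accession}\t"
                f"{ann.name}\t{ann.start}\t{ann.end}\n"
            )
    with open(paths["characterized"], "w") as handle:
        for pid, ecs in bundle.characterized_table.items():
            handle.write(f"{pid}\t{';'.join(ecs)}\n")
    with open(paths["presence"], "w") as handle:
        for pid in sorted(bundle.presence_ids):
            handle.write(pid + "\n")
    with open(paths["curation"], "w") as handle:
        for raw in sorted(bundle.curation_entries):
            handle.write(f"{raw}\t{bundle.curation_entries[raw]}\n")
    with open(paths["truth"], "w") as handle:
        handle.write("protein_id\tarchitecture\tboundaries\n")
        for pid in bundle.truth_architectures:
            bounds = ";".join(
                f"{name}:{s}-{e}" for name, s, e in bundle.truth_boundaries[pid]
            )
            handle.write(f"{pid}\t{bundle.truth_architectures[pid]}\t{bounds}\n")
    return paths


# ---------------------------------------------------------------------------
# Sequence-family and peptide-group generators
# ---------------------------------------------------------------------------

def _mutate(sequence: str, rate: float, rng: random.Random) -> str:
    """Substitute each position with probability ``rate`` (always to a
    different residue)."""
    out = []
    for ch in sequence:
        if rng.random() < rate:
            out.append(rng.choice([a for a in CANONICAL_AA if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def generate_family_clusters(
    n_families: int = 5,
    members_per_family: int = 10,
    mutation_rate: float = 0.05,
    seed_length: int = 200,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Plant ``n_families`` mutation families for clustering tests.

    Each family is one random seed sequence expanded into
    ``members_per_family`` substitution mutants at the given per-position
    rate. Returns the records (family members interleaved in family order)
    and the planted label of each record (``protein_id -> family id``).
    """
    rng = random.Random(seed)
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for f in range(n_families):
        family = f"FAM{f + 1}"
        ancestor = "".join(rng.choice(CANONICAL_AA) for _ in range(seed_length))
        for m in range(members_per_family):
            pid = f"{family}_M{m + 1}"
            seq = ancestor if m == 0 else _mutate(ancestor, mutation_rate, rng)
            records.append(ProteinRecord(pid, seq, description=f"member of {family}"))
            labels[pid] = family
    return records, labels


def generate_peptide_groups(
    group_specs: Sequence[tuple[str, int, float]],
    peptide_length: int = 150,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Groups of peptides with planted within-group divergence.

    Each ``(name, n_members, mutation_rate)`` group descends from its own
    random ancestor; members are independent substitution mutants of that
    ancestor, so expected pairwise divergence grows with the rate.
    """
    rng = random.Random(seed)
    groups: dict[str, list[str]] = {}
    for name, n_members, rate in group_specs:
        ancestor = "".join(rng.choice(CANONICAL_AA) for _ in range(peptide_length))
        groups[name] = [_mutate(ancestor, rate, rng) for _ in range(n_members)]
    return groups
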