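"""Architecture strings, assembly enumeration and sequence attribution.

An architecture is the ordered N-to-C list of a protein's curated domain
names, rendered canonically as ``"name + name + ..."``. Order matters:
``CBM + Catalytic domain`` and ``Catalytic domain + CBM`` are distinct
assemblies.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .model import (
    ARCHITECTURE_SEPARATOR,
    Architecture,
    DomainCall,
    ProteinRecord,
)
from .consolidation import overlap_fraction
from .sequence_prep import global_identity

UNASSIGNED = "unassigned"


def architecture_string(
    calls: Sequence[DomainCall], overlap_threshold: float = 0.31
) -> str:
    """Canonical architecture string of one protein's consolidated calls.

    Names are taken in start order and joined with ``" + "``. An empty
    call list yields the empty string. Calls that still overlap above the
    threshold violate the consolidation contract and raise.
    """
    ordered = sorted(calls, key=lambda c: (c.start, c.end))
    for a, b in zip(ordered, ordered[1:]):
        frac = overlap_fraction((a.start, a.end), (b.start, b.end))
        if frac > overlap_threshold:
            raise ValueError(
                f"{a.protein_id}: calls {a.curated_name} and {b.curated_name} "
                f"overlap by {frac:.2f} (> {overlap_threshold}); run consolidation first"
            )
    return ARCHITECTURE_SEPARATOR.join(c.curated_name for c in ordered)


def enumerate_assemblies(
    calls_by_protein: Mapping[str, Sequence[DomainCall]],
    records: Optional[Mapping[str, ProteinRecord]] = None,
) -> list[Architecture]:
    """Enumerate the distinct domain assemblies across a dataset.

    One :class:`Architecture` per distinct canonical string among proteins
    with at least one call; member lists partition those proteins. When
    ``records`` is given, taxonomy and EC metadata of members (the latter
    for characterized members only) are aggregated. Output is sorted by
    member count descending, then canonical string.
    """
    by_canonical: dict[str, Architecture] = {}
    for protein_id in calls_by_protein:
        calls = calls_by_protein[protein_id]
        if not calls:
            continue
        canonical = architecture_string(calls)
        asm = by_canonical.get(canonical)
        if asm is None:
            ordered = [
                c.curated_name for c in sorted(calls, key=lambda c: (c.start, c.end))
            ]
            asm = Architecture(ordered_names=ordered, example_id=protein_id)
            by_canonical[canonical] = asm
        asm.protein_ids.append(protein_id)
        if records is not None and protein_id in records:
            rec = records[protein_id]
            asm.taxonomy_set.add(rec.taxonomy_group)
            if rec.characterized:
                asm.ec_set.update(rec.ec_numbers)
    assemblies = sorted(
        by_canonical.values(), key=lambda a: (-a.member_count, a.canonical)
    )
    for asm in assemblies:
        asm.protein_ids.sort()
        asm.example_id = min(asm.protein_ids)
    return assemblies


def attribute_sequences(
    queries: Sequence[ProteinRecord],
    representatives: Sequence[tuple[ProteinRecord, str]],
    min_identity: float = 0.85,
) -> tuple[dict[str, Optional[str]], dict[str, float]]:
    """Attribute query sequences to known assemblies by best-hit identity.

    Each query is assigned the architecture of its best-identity
    representative (identity = identical matches / query length) when that
    identity reaches ``min_identity``; otherwise it stays unassigned. The
    returned prevalence table maps each canonical architecture string to
    the fraction of queries attributed to it, with the remainder under
    ``"unassigned"``; the fractions sum to 1.
    """
    if not representatives:
        raise ValueError("attribute_sequences requires at least one representative")
    assignments: dict[str, Optional[str]] = {}
    for query in queries:
        best_arch, best_identity = None, -1.0
        for rep, canonical in representatives:
            identity = global_identity(query.sequence, rep.sequence, mode="query")
            if identity > best_identity:
                best_arch, best_identity = canonical, identity
        assignments[query.protein_id] = (
            best_arch if best_identity >= min_identity else None
        )
    prevalence: dict[str, float] = {}
    n = len(queries)
    for assigned in assignments.values():
        key = assigned if assigned is not None else UNASSIGNED
        prevalence[key] = prevalence.get(key, 0.0) + 1.0
    for key in prevalence:
        prevalence[key] /= n
    prevalence.setdefault(UNASSIGNED, 0.0)
    return assignments, prevalence


def export_assemblies_tsv(assemblies: Sequence[Architecture], path) -> None:
    """Write assemblies as a TSV summary table.

    Columns: architecture, prevalence %, member count, taxonomy, example
    protein id, known EC numbers of characterized members.
    """
    with open(path, "w") as handle:
        handle.write(
            "architecture\tprevalence_pct\tmember_count\ttaxonomy\t"
            "example_protein_id\tknown_ecs\n"
        )
        for asm in assemblies:
            prevalence = (
                f"{100.0 * asm.prevalence:.1f}" if asm.prevalence is not None else ""
            )
            handle.write(
                f"{asm.canonical}\t{prevalence}\t{asm.member_count}\t"
                f"{','.join(sorted(asm.taxonomy_set))}\t{asm.example_id or ''}\t"
                f"{','.join(sorted(asm.ec_set))}\n"
            )
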