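"""Consolidation of redundant multi-source domain annotations.

Because several signature databases report hits for the same protein
region, a single region typically carries multiple, partially overlapping
annotations under different names. This module collapses them so that each
region is annotated by at most one curated domain call:

1. name curation (user-supplied overarching names),
2. eligibility filtering — an annotation is dropped when it has no valid
   name, marks a signal peptide, or its span falls outside the accepted
   domain-size window (10-800 AA by default),
3. outermost-edge merging of overlapping same-name calls (split detections
   of one domain by different databases),
4. iterative overlap resolution — while any retained pair overlaps by more
   than the threshold fraction (default 0.31) of the shorter span, the
   loser of the pair is deleted; the winner is decided by database
   priority, then span length, then start, then name.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import (
    ConsolidationConfig,
    CurationMap,
    DomainCall,
    MISSING_NAME_MARKERS,
    ProteinRecord,
    RawAnnotation,
)


@dataclass
class DropEntry:
    """One removed annotation with the stage and reason of its removal."""

    protein_id: str
    accession: str
    stage: str  # "eligibility" | "merge" | "overlap"
    reason: str


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of two 1-based inclusive intervals, relative to the shorter.

    ``|intersection| / min(len(a), len(b))``; 0 when disjoint.
    """
    (a1, a2), (b1, b2) = a, b
    if a1 > a2 or b1 > b2:
        raise ValueError(f"invalid interval: {a}, {b}")
    inter = min(a2, b2) - max(a1, b1) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a2 - a1 + 1, b2 - b1 + 1)


def is_eligible(
    ann: RawAnnotation, cfg: ConsolidationConfig | None = None
) -> tuple[bool, str]:
    """Apply the three retention rules to one annotation.

    (a) the annotation must carry a valid name (not missing, not the
    literal 'None'); (b) it must not mark a signal peptide — detected by a
    marker substring such as 'SIGNAL' in the name (case-sensitive) or by a
    signal-prediction source database; (c) its span length must lie within
    the configured domain-size window.

    Returns (eligible, reason); the reason names the failed rule.
    """
    cfg = cfg or ConsolidationConfig()
    if ann.name in MISSING_NAME_MARKERS:
        return False, "rule-a: missing or 'None' name"
    if ann.source_db in cfg.signal_sources or any(
        marker in ann.name for marker in cfg.signal_markers
    ):
        return False, "rule-b: signal peptide annotation"
    if not (cfg.min_domain_size <= ann.length <= cfg.max_domain_size):
        return False, (
            f"rule-c: span length {ann.length} outside "
            f"[{cfg.min_domain_size}, {cfg.max_domain_size}]"
        )
    return True, "eligible"


def apply_curation(
    anns: Sequence[RawAnnotation], curation: CurationMap
) -> list[RawAnnotation]:
    """Replace raw signature names by their curated overarching names.

    Every substitution is appended to ``curation.applied_log`` (which feeds
    the DomainCuration table); unmapped names pass through untouched.
    """
    curated = []
    for ann in anns:
        curated.append(
            RawAnnotation(
                ann.protein_id,
                ann.source_db,
                ann.accession,
                curation.curate(ann.name),
                ann.start,
                ann.end,
            )
        )
    return curated


# ---------------------------------------------------------------------------
# Merging and overlap resolution
# ---------------------------------------------------------------------------

def merge_same_name(anns: Sequence[RawAnnotation]) -> list[DomainCall]:
    """Merge overlapping same-name annotations to their outermost edges.

    When different databases each detect only part of the same domain, the
    partial calls (same protein, same curated name, chained by nonzero
    overlap) are replaced by a single call spanning the outermost
    positions, with sources and accessions unioned. Disjoint same-name
    annotations stay separate: repeated domains are real.
    """
    groups: dict[tuple[str, str], list[RawAnnotation]] = {}
    order: list[tuple[str, str]] = []
    for ann in anns:
        key = (ann.protein_id, ann.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(ann)

    calls: list[DomainCall] = []
    for key in order:
        members = sorted(groups[key], key=lambda a: (a.start, a.end))
        # sweep in start order: overlap chaining = connected components
        component: list[RawAnnotation] = []
        comp_end = -1
        for ann in members:
            if component and ann.start > comp_end:
                calls.append(_component_to_call(component))
                component = []
            component.append(ann)
            comp_end = max(comp_end, ann.end)
        if component:
            calls.append(_component_to_call(component))
    calls.sort(key=lambda c: (c.start, -c.end, c.curated_name))
    return calls


def _component_to_call(component: list[RawAnnotation]) -> DomainCall:
    return DomainCall(
        protein_id=component[0].protein_id,
        curated_name=component[0].name,
        start=min(a.start for a in component),
        end=max(a.end for a in component),
        source_dbs=frozenset(a.source_db for a in component),
        accessions=frozenset(a.accession for a in component),
    )


def _winner_key(call: DomainCall, cfg: ConsolidationConfig):
    """Strict total order deciding conflicts: smaller key wins.

    Chain: best database priority, longer span, smaller start,
    lexicographically smaller curated name. Same-name overlapping calls
    cannot reach resolution (they are merged first), so the chain never
    ties.
    """
    prio = min((cfg.priority_index(db) for db in call.source_dbs), default=10**9)
    return (prio, -call.length, call.start, call.curated_name)


def _sort_calls(calls: list[DomainCall], cfg: ConsolidationConfig) -> list[DomainCall]:
    return sorted(calls, key=lambda c: (c.start, -c.end, _winner_key(c, cfg)))


def resolve_overlaps(
    calls: Sequence[DomainCall], cfg: ConsolidationConfig | None = None
) -> tuple[list[DomainCall], list[DropEntry]]:
    """Iteratively delete losers of conflicting pairs until no conflict remains.

    Two calls conflict when their overlap fraction exceeds the threshold.
    Calls are kept sorted by (start asc, end desc); on each pass the first
    conflicting pair in scan order whose winner is itself undefeated (loses
    no conflict of its own) is resolved by deleting the loser, then the
    scan restarts. The undefeated-winner restriction makes the fixpoint
    independent of the pair-visit order: the retained set equals greedy
    retention in winner-rank order. Post-condition: no retained pair
    overlaps by more than the threshold.
    """
    cfg = cfg or ConsolidationConfig()
    current = _sort_calls(list(calls), cfg)
    dropped: list[DropEntry] = []

    def conflicting(a: DomainCall, b: DomainCall) -> bool:
        return (
            overlap_fraction((a.start, a.end), (b.start, b.end))
            > cfg.overlap_threshold
        )

    while True:
        conflicts = [
            (i, j)
            for i in range(len(current) - 1)
            for j in range(i + 1, len(current))
            if conflicting(current[i], current[j])
        ]
        if not conflicts:
            break
        # calls that lose at least one conflict; a pair may only be
        # resolved when its winner is undefeated (this is what makes the
        # fixpoint independent of the order in which pairs are visited)
        defeated = set()
        for i, j in conflicts:
            loser = i if _winner_key(current[i], cfg) > _winner_key(current[j], cfg) else j
            defeated.add(loser)
        for i, j in conflicts:
            loser_idx = (
                i if _winner_key(current[i], cfg) > _winner_key(current[j], cfg) else j
            )
            winner_idx = j if loser_idx == i else i
            if winner_idx in defeated:
                continue
            loser, winner = current[loser_idx], current[winner_idx]
            dropped.append(
                DropEntry(
                    loser.protein_id,
                    ";".join(sorted(loser.accessions)),
                    "overlap",
                    f"lost to {winner.curated_name} ({winner.start},{winner.end})",
                )
            )
            del current[loser_idx]
            break
    return current, dropped


def consolidate(
    protein: ProteinRecord | str,
    raw_anns: Sequence[RawAnnotation],
    curation: CurationMap | None = None,
    cfg: ConsolidationConfig | None = None,
) -> tuple[list[DomainCall], list[DropEntry]]:
    """Full per-protein consolidation pipeline.

    curate -> eligibility filter -> same-name merge -> overlap resolution.
    Returns the retained calls in N-to-C order and a drop log recording
    every removed annotation with its reason. Post-condition (asserted):
    no retained pair overlaps by more than the configured threshold.
    """
    protein_id = protein if isinstance(protein, str) else protein.protein_id
    cfg = cfg or ConsolidationConfig()
    curation = curation or CurationMap()
    for ann in raw_anns:
        if ann.protein_id != protein_id:
            raise ValueError(
                f"annotation for {ann.protein_id} passed to consolidate({protein_id})"
            )
    curated = apply_curation(raw_anns, curation)

    eligible: list[RawAnnotation] = []
    drop_log: list[DropEntry] = []
    for ann in curated:
        ok, reason = is_eligible(ann, cfg)
        if ok:
            eligible.append(ann)
        else:
            drop_log.append(DropEntry(ann.protein_id, ann.accession, "eligibility", reason))

    merged = merge_same_name(eligible)
    n_merged_away = len(eligible) - len(merged)
    for _ in range(n_merged_away):
        drop_log.append(
            DropEntry(
                protein_id,
                "-",
                "merge",
                "split same-name annotation absorbed into outermost-edge merge",
            )
        )

    retained, overlap_drops = resolve_overlaps(merged, cfg)
    drop_log.extend(overlap_drops)

    retained.sort(key=lambda c: (c.start, c.end))
    for i in range(len(retained) - 1):
        for j in range(i + 1, len(retained)):
            frac = overlap_fraction(
                (retained[i].start, retained[i].end),
                (retained[j].start, retained[j].end),
            )
            assert frac <= cfg.overlap_threshold, (
                f"{protein_id}: retained pair exceeds overlap threshold"
            )
    return retained, drop_log


def write_drop_log(entries: Sequence[DropEntry], path) -> None:
    """Write a drop log as TSV ``protein_id accession stage reason``."""
    with open(path, "w") as handle:
        handle.write("protein_id\taccession\tstage\treason\n")
        for e in entries:
            handle.write(f"{e.protein_id}\t{e.accession}\t{e.stage}\t{e.reason}\n")
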