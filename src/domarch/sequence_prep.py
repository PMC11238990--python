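"""Sequence filtering and homology reduction.

Deduplication, partial-protein removal, reference-presence filtering, a
greedy incremental (CD-HIT-style) clusterer, and the rule that guarantees
experimentally characterized proteins survive clustering.

Identity between two sequences is computed from an optimal global alignment
scored match=1 / mismatch=0 / gap=0 (the classical ``globalxx`` scheme):
the optimal score is the maximal number of identically aligned residue
pairs, and identity is that count divided by the length of the shorter
sequence, the longer sequence, or the query, depending on ``mode``.
"""
from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .model import CharacterizedRescueConfig, ClusterConfig, ProteinRecord

logger = logging.getLogger(__name__)

_PARTIAL_TOKEN = re.compile(r"\bpartial\b", re.IGNORECASE)

IdentityMode = str  # "shorter" | "longer" | "query"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner

_ALIGNER = _make_aligner()


def identical_matches(a: str, b: str) -> int:
    """Maximal number of identical aligned pairs over all global alignments.

    With match=1 and free mismatches/gaps this equals the optimal global
    alignment score.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    return int(_ALIGNER.score(a, b))


def global_identity(a: str, b: str, mode: IdentityMode = "longer") -> float:
    """Pairwise identity of two sequences under the chosen denominator.

    mode="shorter": matches / min length (clustering convention);
    mode="longer": matches / max length (domain-comparison convention);
    mode="query":  matches / len(a) (characterized-rescue and attribution).
    """
    matches = identical_matches(a, b)
    if mode == "shorter":
        denom = min(len(a), len(b))
    elif mode == "longer":
        denom = max(len(a), len(b))
    elif mode == "query":
        denom = len(a)
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    return matches / denom


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def deduplicate(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Drop records whose identifier OR exact sequence was seen before.

    The first occurrence wins; input order is preserved.
    """
    kept: list[ProteinRecord] = []
    dropped: list[tuple[ProteinRecord, str]] = []
    seen_ids: set[str] = set()
    seen_seqs: set[str] = set()
    for rec in records:
        if rec.protein_id in seen_ids:
            dropped.append((rec, "duplicate-identifier"))
        elif rec.sequence in seen_seqs:
            dropped.append((rec, "duplicate-sequence"))
        else:
            kept.append(rec)
            seen_ids.add(rec.protein_id)
            seen_seqs.add(rec.sequence)
    return kept, dropped


def filter_partial(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Drop records flagged as partial proteins.

    Detection is a case-insensitive, word-boundary match of the token
    ``partial`` in the description ("partially" does not match).
    """
    kept, dropped = [], []
    for rec in records:
        if _PARTIAL_TOKEN.search(rec.description or ""):
            dropped.append((rec, "partial-protein"))
        else:
            kept.append(rec)
    return kept, dropped


def filter_presence(
    records: Sequence[ProteinRecord], presence_ids: Iterable[str]
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Keep records present in a reference archive (offline UniParc stand-in).

    Sequences absent from the reference carry no domain annotations and are
    excluded from the workflow.
    """
    presence = set(presence_ids)
    if not presence:
        logger.warning("empty presence list: all %d records dropped", len(records))
    kept, dropped = [], []
    for rec in records:
        if rec.protein_id in presence:
            kept.append(rec)
        else:
            dropped.append((rec, "absent-from-reference"))
    return kept, dropped


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_greedy(
    records: Sequence[ProteinRecord], config: ClusterConfig | None = None
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy incremental clustering in CD-HIT style.

    Sequences are visited longest-first (ties keep input order). Each
    sequence joins the first existing representative it matches at
    ``identity_threshold`` identity (denominator: shorter sequence) while
    satisfying the coverage floors; otherwise it founds a new cluster.

    Returns the representatives (in creation order) and a mapping
    member id -> representative id (representatives map to themselves).
    """
    if not records:
        raise ValueError("cluster_greedy requires at least one record")
    config = config or ClusterConfig()
    order = sorted(
        range(len(records)), key=lambda i: (-len(records[i].sequence), i)
    )
    representatives: list[ProteinRecord] = []
    membership: dict[str, str] = {}
    for i in order:
        rec = records[i]
        home = None
        for rep in representatives:
            matches = identical_matches(rec.sequence, rep.sequence)
            shorter = min(len(rec.sequence), len(rep.sequence))
            longer = max(len(rec.sequence), len(rep.sequence))
            if (
                matches / shorter >= config.identity_threshold
                and matches / shorter >= config.coverage_short
                and matches / longer >= config.coverage_long
            ):
                home = rep
                break
        if home is None:
            representatives.append(rec)
            membership[rec.protein_id] = rec.protein_id
        else:
            membership[rec.protein_id] = home.protein_id
    return representatives, membership


def retain_characterized(
    representatives: Sequence[ProteinRecord],
    all_records: Sequence[ProteinRecord],
    characterized: Mapping[str, ProteinRecord] | Iterable[str],
    rescue_pool: Sequence[ProteinRecord] = (),
    config: CharacterizedRescueConfig | None = None,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Add every characterized protein back to the representative set.

    ``characterized`` may be a set of identifiers, or a mapping
    id -> record when the characterized sequences themselves are known
    (required for rescue). A characterized protein absent from
    ``all_records`` is replaced by its best ``rescue_pool`` hit iff
    identical matches divided by the query length reach
    ``config.min_similarity`` (default 0.95); otherwise it is logged as
    unrescued.

    Returns (final record list, event log of (protein_id, message) pairs).
    """
    config = config or CharacterizedRescueConfig()
    if isinstance(characterized, Mapping):
        char_records: dict[str, ProteinRecord | None] = dict(characterized)
    else:
        char_records = {pid: None for pid in characterized}

    by_id = {rec.protein_id: rec for rec in all_records}
    final: list[ProteinRecord] = list(representatives)
    present = {rec.protein_id for rec in final}
    log: list[tuple[str, str]] = []

    for pid in char_records:
        if pid in present:
            continue
        if pid in by_id:
            final.append(by_id[pid])
            present.add(pid)
            log.append((pid, "characterized-reinstated"))
            continue
        query = char_records[pid]
        if query is None:
            log.append((pid, "unrescued: sequence unavailable"))
            continue
        best, best_sim = None, -1.0
        for candidate in rescue_pool:
            sim = identical_matches(query.sequence, candidate.sequence) / len(
                query.sequence
            )
            if sim > best_sim:
                best, best_sim = candidate, sim
        if best is not None and best_sim >= config.min_similarity:
            if best.protein_id not in present:
                final.append(best)
                present.add(best.protein_id)
            log.append(
                (pid, f"rescued-by:{best.protein_id} similarity={best_sim:.3f}")
            )
        else:
            log.append((pid, f"unrescued: best similarity {max(best_sim, 0.0):.3f}"))
            logger.warning(
                "characterized protein %s could not be rescued (best %.3f < %.3f)",
                pid, max(best_sim, 0.0), config.min_similarity,
            )
    return final, log
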