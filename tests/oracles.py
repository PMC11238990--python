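"""Independent oracles used by the test suite.

These deliberately re-derive expected results by routes different from the
implementation under test: alignment identity by exhaustive recursion over
alignment moves, overlap resolution by greedy retention and by exhaustive
enumeration of deletion orders, network counts by a flat re-tally, and
Kruskal-Wallis by the textbook rank formula. iTOL files are checked by a
validator written from the published format description.
"""
from __future__ import annotations

import random
import re
from functools import lru_cache
from itertools import combinations

from domarch.consolidation import _winner_key, overlap_fraction
from domarch.model import ConsolidationConfig, DomainCall

# ---------------------------------------------------------------------------
# Alignment identity
# ---------------------------------------------------------------------------

def alignment_max_matches(a: str, b: str) -> int:
    """Maximum number of identical aligned pairs over all global alignments
    (recursion over the three alignment moves; independent of the aligner)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        options = [
            (1 if a[i] == b[j] else 0) + best(i + 1, j + 1),  # align pair
            best(i + 1, j),                                   # gap in b
            best(i, j + 1),                                   # gap in a
        ]
        return max(options)

    return best(0, 0)


# ---------------------------------------------------------------------------
# Overlap resolution
# ---------------------------------------------------------------------------

def _conflicts(calls: list[DomainCall], cfg: ConsolidationConfig) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i, j in combinations(range(len(calls)), 2)
        if overlap_fraction(
            (calls[i].start, calls[i].end), (calls[j].start, calls[j].end)
        )
        > cfg.overlap_threshold
    ]


def _call_key(c: DomainCall) -> tuple:
    return (c.start, c.end, c.curated_name, tuple(sorted(c.source_dbs)))


def greedy_retention(
    calls: list[DomainCall], cfg: ConsolidationConfig
) -> list[DomainCall]:
    """Process calls in winner-rank order; keep each call iff it conflicts
    with no already-kept call."""
    kept: list[DomainCall] = []
    for c in sorted(calls, key=lambda c: _winner_key(c, cfg)):
        if all(
            overlap_fraction((c.start, c.end), (k.start, k.end))
            <= cfg.overlap_threshold
            for k in kept
        ):
            kept.append(c)
    return sorted(kept, key=_call_key)


def exhaustive_fixpoints(
    calls: list[DomainCall], cfg: ConsolidationConfig
) -> set[frozenset]:
    """All fixpoints reachable by resolving conflicting pairs in every
    possible order, where a pair is resolvable only while its winner is
    undefeated (loses no conflict of its own). Memoized over call subsets."""
    indexed = list(enumerate(calls))

    def key_of(i: int) -> tuple:
        return _call_key(calls[i])

    @lru_cache(maxsize=None)
    def explore(alive: frozenset) -> frozenset:
        live = sorted(alive)
        pairs = [
            (i, j)
            for i, j in combinations(live, 2)
            if overlap_fraction(
                (calls[i].start, calls[i].end), (calls[j].start, calls[j].end)
            )
            > cfg.overlap_threshold
        ]
        if not pairs:
            return frozenset({frozenset(key_of(i) for i in live)})
        defeated = set()
        for i, j in pairs:
            loser = i if _winner_key(calls[i], cfg) > _winner_key(calls[j], cfg) else j
            defeated.add(loser)
        results: set[frozenset] = set()
        for i, j in pairs:
            loser = i if _winner_key(calls[i], cfg) > _winner_key(calls[j], cfg) else j
            winner = j if loser == i else i
            if winner in defeated:
                continue
            results |= explore(alive - {loser})
        return frozenset(results)

    del indexed
    return set(explore(frozenset(range(len(calls)))))


def random_calls(rng: random.Random, n: int, protein_id: str = "P") -> list[DomainCall]:
    """Random eligible, curated, distinct-name calls for oracle fuzzing."""
    dbs = ["Pfam", "CDD", "SMART", "PRINTS", "SUPERFAMILY", "CATH-Gene3D"]
    out = []
    for k in range(n):
        start = rng.randint(1, 250)
        end = start + rng.randint(9, 180)
        out.append(
            DomainCall(
                protein_id,
                f"Domain{rng.randint(1, 5)}_{k}",
                start,
                end,
                frozenset({rng.choice(dbs)}),
                frozenset({f"ACC{k}"}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Network re-tally
# ---------------------------------------------------------------------------

def recount_network(name_lists: list[list[str]]) -> tuple[dict, dict]:
    """Flat re-tally of node occurrences and consecutive-pair adjacencies."""
    nodes: dict[str, int] = {}
    edges: dict[tuple[str, str], int] = {}
    for names in name_lists:
        for name in names:
            nodes[name] = nodes.get(name, 0) + 1
        for a, b in zip(names, names[1:]):
            key = (a, b) if a <= b else (b, a)
            edges[key] = edges.get(key, 0) + 1
    return nodes, edges


# ---------------------------------------------------------------------------
# Kruskal-Wallis by the textbook formula
# ---------------------------------------------------------------------------

def kruskal_wallis_formula(groups: list[list[float]]) -> float:
    """H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N))
    with mid-rank ties; computed directly from the formula."""
    pooled = sorted(v for g in groups for v in g)
    N = len(pooled)
    # mid-ranks
    ranks: dict[float, float] = {}
    i = 0
    while i < N:
        j = i
        while j < N and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks[pooled[i]] = mid
        i = j
    rank_sums = [sum(ranks[v] for v in g) for g in groups]
    H = (12.0 / (N * (N + 1))) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3.0 * (N + 1)
    tie_counts: dict[float, int] = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in tie_counts.values()) / (N**3 - N)
    return H / correction


# ---------------------------------------------------------------------------
# iTOL format validators
# ---------------------------------------------------------------------------

_ITOL_SHAPE_VOCAB = {
    "RE", "HH", "HV", "EL", "DI", "TR", "TL", "PL", "PR", "PU", "PD", "OC", "GP",
}
_HEX_COLOR = re.compile(r"^#[0-9a-fA-F]{6}$")
_SEPARATORS = {"COMMA": ",", "SPACE": " ", "TAB": "\t"}


def validate_itol_domains(text: str) -> list[str]:
    """Validate a DATASET_DOMAINS file; returns the list of problems found."""
    problems: list[str] = []
    lines = text.splitlines()
    if not lines or lines[0] != "DATASET_DOMAINS":
        return ["first line must be DATASET_DOMAINS"]
    sep = None
    in_data = False
    keys = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not in_data:
            key = re.split(r"[,\t ]", line, maxsplit=1)[0]
            keys.add(key)
            if key == "SEPARATOR":
                sep_name = line.split(" ", 1)[1] if " " in line else ""
                if sep_name not in _SEPARATORS:
                    problems.append(f"line {lineno}: bad separator {sep_name!r}")
                else:
                    sep = _SEPARATORS[sep_name]
            elif key == "DATA":
                in_data = True
                if sep is None:
                    problems.append("DATA before SEPARATOR")
            continue
        fields = line.split(sep)
        if len(fields) < 2:
            problems.append(f"line {lineno}: need at least id and length")
            continue
        try:
            length = int(fields[1])
        except ValueError:
            problems.append(f"line {lineno}: length {fields[1]!r} not an integer")
            continue
        for shape_field in fields[2:]:
            parts = shape_field.split("|")
            if len(parts) != 5:
                problems.append(f"line {lineno}: shape field needs 5 |-parts")
                continue
            shape, start, end, color, _label = parts
            if shape not in _ITOL_SHAPE_VOCAB:
                problems.append(f"line {lineno}: unknown shape {shape!r}")
            if not _HEX_COLOR.match(color):
                problems.append(f"line {lineno}: bad colour {color!r}")
            try:
                s, e = int(start), int(end)
                if not (1 <= s <= e <= length):
                    problems.append(
                        f"line {lineno}: span ({s},{e}) outside [1,{length}]"
                    )
            except ValueError:
                problems.append(f"line {lineno}: non-integer span")
    for required in ("DATASET_LABEL", "COLOR"):
        if required not in keys:
            problems.append(f"missing mandatory header {required}")
    if not in_data:
        problems.append("missing DATA section")
    return problems


def validate_itol_treecolors(text: str) -> list[str]:
    """Validate a TREE_COLORS file; returns the list of problems found."""
    problems: list[str] = []
    lines = text.splitlines()
    if not lines or lines[0] != "TREE_COLORS":
        return ["first line must be TREE_COLORS"]
    sep = None
    in_data = False
    for lineno, line in enumerate(lines[1:], start=2):
        if not in_data:
            if line.startswith("SEPARATOR"):
                sep_name = line.split(" ", 1)[1] if " " in line else ""
                if sep_name not in _SEPARATORS:
                    problems.append(f"line {lineno}: bad separator {sep_name!r}")
                else:
                    sep = _SEPARATORS[sep_name]
            elif line == "DATA":
                in_data = True
                if sep is None:
                    problems.append("DATA before SEPARATOR")
            continue
        fields = line.split(sep)
        if len(fields) < 3:
            problems.append(f"line {lineno}: need id, type, colour")
            continue
        if fields[1] not in {"range", "clade", "branch", "label", "label_background"}:
            problems.append(f"line {lineno}: unknown type {fields[1]!r}")
        if not _HEX_COLOR.match(fields[2]):
            problems.append(f"line {lineno}: bad colour {fields[2]!r}")
        if fields[1] == "label" and len(fields) >= 4:
            if fields[3] not in {"normal", "bold", "italic", "bold-italic"}:
                problems.append(f"line {lineno}: bad label style {fields[3]!r}")
    if not in_data:
        problems.append("missing DATA section")
    return problems
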