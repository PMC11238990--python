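"""Domain-level evolution analysis.

Individual domains are excised from their parent sequences using the
stored 1-based inclusive boundaries, all within-group pairwise identities
are computed (identity = best global alignment score under match-count
scoring divided by the longer of the two sequences), and groups are
compared with a Kruskal-Wallis rank test followed by Dunn's post hoc
pairwise comparisons with tie correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DomainCall, ProteinRecord
from .sequence_prep import global_identity


@dataclass
class GroupComparison:
    """Result bundle of a multi-group domain-identity comparison."""

    groups: dict[str, list[float]]
    H: float
    H_pvalue: float
    dunn: pd.DataFrame
    adjustment: str
    summary: pd.DataFrame

    def __post_init__(self) -> None:
        for name, values in self.groups.items():
            if any(not (0.0 <= v <= 1.0) for v in values):
                raise ValueError(f"group {name!r} has identities outside [0, 1]")


def excise_domains(
    record: ProteinRecord,
    calls: Sequence[DomainCall],
    name_filter: set[str] | None = None,
) -> list[tuple[str, str]]:
    """Cut domain peptides out of a protein by stored boundaries.

    Returns (curated name, peptide) pairs in start order; a call of span
    (s, e) yields a peptide of length e - s + 1. ``name_filter`` restricts
    extraction to the named domain types.
    """
    out: list[tuple[str, str]] = []
    for call in sorted(calls, key=lambda c: (c.start, c.end)):
        if name_filter is not None and call.curated_name not in name_filter:
            continue
        if call.end > len(record.sequence):
            raise ValueError(
                f"{record.protein_id}: call {call.curated_name} "
                f"({call.start},{call.end}) exceeds sequence length "
                f"{len(record.sequence)}"
            )
        out.append((call.curated_name, record.sequence[call.start - 1 : call.end]))
    return out


def pairwise_group_identities(
    peptides_by_group: Mapping[str, Sequence[str]],
) -> dict[str, list[float]]:
    """All unordered within-group pairwise identities, per group.

    Identity uses the longer-sequence denominator; each group of n members
    yields C(n, 2) values. Groups of fewer than two members are rejected.
    """
    identities: dict[str, list[float]] = {}
    for name in peptides_by_group:
        peptides = list(peptides_by_group[name])
        if len(peptides) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
        identities[name] = [
            global_identity(a, b, mode="longer") for a, b in combinations(peptides, 2)
        ]
    return identities


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test across the groups (mid-rank tie correction).

    Degenerate input in which every pooled value is identical returns
    H = 0, p = 1 by convention.
    """
    samples = [np.asarray(groups[name], dtype=float) for name in groups]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis requires nonempty groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjustment: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post hoc pairwise comparisons on pooled mid-ranks.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j))``
    with two-sided normal p-values, adjusted by the chosen method
    (``bonferroni``, ``holm`` or ``none``). Returns a symmetric matrix of
    adjusted p-values with unit diagonal.
    """
    if adjustment not in ("bonferroni", "holm", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    names = list(groups)
    samples = [np.asarray(groups[name], dtype=float) for name in names]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("dunn_posthoc requires >= 2 nonempty groups")
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for s in samples:
        mean_ranks.append(float(np.mean(ranks[offset : offset + len(s)])))
        sizes.append(len(s))
        offset += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    pairs = list(combinations(range(len(names)), 2))
    raw_p = []
    for i, j in pairs:
        if variance_core <= 0:  # every pooled value tied
            raw_p.append(1.0)
            continue
        se = np.sqrt(variance_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw_p.append(float(2.0 * stats.norm.sf(abs(z))))
    if adjustment == "none":
        adjusted = raw_p
    else:
        adjusted = multipletests(raw_p, method=adjustment)[1].tolist()

    matrix = pd.DataFrame(1.0, index=names, columns=names)
    for (i, j), p in zip(pairs, adjusted):
        matrix.iloc[i, j] = matrix.iloc[j, i] = p
    return matrix


def compare_groups(
    peptides_by_group: Mapping[str, Sequence[str]], adjustment: str = "bonferroni"
) -> GroupComparison:
    """Full excision-identity comparison across named peptide groups.

    Computes all within-group pairwise identities, the Kruskal-Wallis H
    test over the identity distributions, and Dunn's post hoc matrix.
    The summary table reports per-group n (number of pairs), mean and
    median identity (as percentages).
    """
    identities = pairwise_group_identities(peptides_by_group)
    H, p = kruskal_wallis(identities)
    dunn = dunn_posthoc(identities, adjustment)
    summary = pd.DataFrame(
        {
            "group": list(identities),
            "n_pairs": [len(v) for v in identities.values()],
            "mean_identity_pct": [100.0 * float(np.mean(v)) for v in identities.values()],
            "median_identity_pct": [
                100.0 * float(np.median(v)) for v in identities.values()
            ],
        }
    )
    return GroupComparison(
        groups=identities, H=H, H_pvalue=p, dunn=dunn,
        adjustment=adjustment, summary=summary,
    )


def export_comparison(result: GroupComparison, report_path, pmatrix_path) -> None:
    """Write the summary table and the adjusted p-value matrix as TSV."""
    result.summary.to_csv(report_path, sep="\t", index=False, float_format="%.4f")
    result.dunn.to_csv(Path(pmatrix_path), sep="\t", float_format="%.6g")
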