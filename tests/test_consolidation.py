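import random

import pytest

from oracles import exhaustive_fixpoints, greedy_retention, random_calls, _call_key
from domarch.consolidation import (
    apply_curation,
    consolidate,
    is_eligible,
    merge_same_name,
    overlap_fraction,
    resolve_overlaps,
)
from domarch.model import (
    ConsolidationConfig,
    CurationMap,
    DomainCall,
    ProteinRecord,
    RawAnnotation,
)


def ann(name, start, end, db="Pfam", pid="P1", acc=None):
    return RawAnnotation(pid, db, acc or f"{db}:{name}:{start}", name, start, end)


class TestOverlapFraction:
    def test_partial_overlap_relative_to_shorter(self):
        # positions 50..100 shared = 51; shorter span (50,120) has 71 positions
        assert overlap_fraction((10, 100), (50, 120)) == pytest.approx(51 / 71)

    def test_disjoint_intervals(self):
        assert overlap_fraction((10, 50), (60, 100)) == 0.0

    def test_identical_intervals(self):
        assert overlap_fraction((10, 100), (10, 100)) == 1.0

    def test_containment_is_full_overlap(self):
        assert overlap_fraction((1, 500), (100, 150)) == 1.0

    def test_symmetric(self):
        assert overlap_fraction((10, 100), (50, 120)) == overlap_fraction(
            (50, 120), (10, 100)
        )


class TestIsEligible:
    def test_missing_name_fails_rule_a(self):
        ok, reason = is_eligible(ann("None", 1, 50))
        assert not ok and "rule-a" in reason

    def test_signal_marker_in_name_fails_rule_b(self):
        ok, reason = is_eligible(ann("SIGNAL_PEPTIDE_xxx", 1, 30))
        assert not ok and "rule-b" in reason

    def test_signal_source_fails_rule_b(self):
        ok, reason = is_eligible(ann("TransmembraneRegion", 1, 30, db="PHOBIUS"))
        assert not ok and "rule-b" in reason

    def test_lowercase_signal_passes_case_sensitive_match(self):
        ok, _ = is_eligible(ann("signal transduction domain", 1, 60))
        assert ok

    def test_oversized_span_fails_rule_c(self):
        ok, reason = is_eligible(ann("HugeDomain", 1, 900))
        assert not ok and "rule-c" in reason

    def test_largest_realistic_domain_is_eligible(self):
        # spans up to the configured maximum pass; 621 AA is a realistic
        # large glycosidase domain
        ok, _ = is_eligible(ann("Glyco_hydro_48", 100, 720))
        assert ok

    def test_undersized_span_fails_rule_c(self):
        ok, reason = is_eligible(ann("TinySite", 10, 15))
        assert not ok and "rule-c" in reason


class TestApplyCuration:
    def test_mapped_name_replaced_and_logged(self):
        curation = CurationMap(entries={"Glyco_hydro_48": "Catalytic domain"})
        out = apply_curation([ann("Glyco_hydro_48", 95, 719)], curation)
        assert out[0].name == "Catalytic domain"
        assert curation.applied_log == [("Glyco_hydro_48", "Catalytic domain")]

    def test_empty_map_is_identity(self):
        curation = CurationMap()
        original = [ann("Glyco_hydro_48", 95, 719)]
        assert apply_curation(original, curation) == original
        assert curation.applied_log == []

    def test_two_raw_names_to_one_curated_name(self):
        curation = CurationMap(
            entries={"GH48 domain": "Catalytic domain", "Cellulase_48": "Catalytic domain"}
        )
        out = apply_curation(
            [ann("GH48 domain", 1, 100), ann("Cellulase_48", 5, 95)], curation
        )
        assert {a.name for a in out} == {"Catalytic domain"}
        assert len(curation.applied_log) == 2


class TestMergeSameName:
    def test_split_detection_merged_to_outermost_edges(self):
        calls = merge_same_name(
            [ann("Catalytic domain", 5, 200, db="Pfam"),
             ann("Catalytic domain", 150, 350, db="CDD")]
        )
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (5, 350)
        assert calls[0].source_dbs == frozenset({"Pfam", "CDD"})

    def test_disjoint_repeats_not_merged(self):
        calls = merge_same_name(
            [ann("CBM", 10, 60), ann("CBM", 300, 350)]
        )
        assert [(c.start, c.end) for c in calls] == [(10, 60), (300, 350)]

    def test_three_chained_spans_collapse_transitively(self):
        # a-b overlap, b-c overlap, a-c disjoint: still one component
        calls = merge_same_name(
            [ann("Dom", 1, 100), ann("Dom", 90, 200), ann("Dom", 190, 300)]
        )
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (1, 300)

    def test_different_names_never_merged(self):
        calls = merge_same_name([ann("A", 1, 100), ann("B", 50, 150)])
        assert len(calls) == 2


def call(name, start, end, db="Pfam", pid="P1"):
    return DomainCall(pid, name, start, end, frozenset({db}), frozenset({f"{db}:{name}"}))


class TestResolveOverlaps:
    def test_database_preference_decides_winner(self):
        kept, dropped = resolve_overlaps(
            [call("DomA", 1, 100, db="SUPERFAMILY"), call("DomB", 11, 110, db="Pfam")]
        )
        assert [c.curated_name for c in kept] == ["DomB"]
        assert dropped[0].reason.startswith("lost to DomB")

    def test_below_threshold_pair_both_kept(self):
        # overlap 20/100 = 0.20 <= 0.31
        kept, dropped = resolve_overlaps(
            [call("DomA", 1, 100), call("DomB", 81, 180, db="CDD")]
        )
        assert len(kept) == 2 and not dropped

    def test_equal_priority_longer_span_wins(self):
        kept, _ = resolve_overlaps(
            [call("Short", 10, 60, db="Pfam"), call("Long", 10, 200, db="Pfam")]
        )
        assert [c.curated_name for c in kept] == ["Long"]

    def test_matches_exhaustive_deletion_order_oracle(self):
        rng = random.Random(987)
        cfg = ConsolidationConfig()
        for _ in range(300):
            calls = random_calls(rng, rng.randint(1, 8))
            kept, _ = resolve_overlaps(calls, cfg)
            fixpoints = exhaustive_fixpoints(calls, cfg)
            assert len(fixpoints) == 1, "resolution must be order-independent"
            assert frozenset(_call_key(c) for c in kept) in fixpoints
            assert [_call_key(c) for c in sorted(kept, key=_call_key)] == [
                _call_key(c) for c in greedy_retention(calls, cfg)
            ]


class TestConsolidate:
    def _redundant_three_domain_annotations(self):
        """One CBM + one Ig-like + one catalytic domain, each reported by 3
        databases, plus a signal peptide hit."""
        anns = []
        for db, jitter in (("Pfam", 0), ("CDD", 3), ("SMART", -2)):
            anns.append(ann("CBM", 30 + jitter, 120 + jitter, db=db, acc=f"{db}-cbm"))
            anns.append(ann("Ig-like", 140 + jitter, 230 + jitter, db=db, acc=f"{db}-ig"))
            anns.append(
                ann("Glyco_hydro_48", 250 + jitter, 700 + jitter, db=db, acc=f"{db}-cat")
            )
        anns.append(ann("SIGNAL_PEPTIDE", 1, 25, db="PHOBIUS", acc="phob-1"))
        return anns

    def test_multi_source_protein_collapses_to_three_calls(self):
        protein = ProteinRecord("P1", "M" * 720)
        curation = CurationMap(entries={"Glyco_hydro_48": "Catalytic domain"})
        calls, drops = consolidate(
            protein, self._redundant_three_domain_annotations(), curation
        )
        assert [c.curated_name for c in calls] == [
            "CBM", "Ig-like", "Catalytic domain"
        ]
        assert all(c.source_dbs == frozenset({"Pfam", "CDD", "SMART"}) for c in calls)

    def test_all_ineligible_yields_domainless_protein(self):
        anns = [ann("None", 1, 50), ann("SIGNAL_X", 1, 20), ann("Tiny", 5, 9)]
        calls, drops = consolidate("P1", anns)
        assert calls == []
        assert len(drops) == 3

    def test_single_eligible_annotation_is_identity(self):
        calls, drops = consolidate("P1", [ann("CBM", 10, 90)])
        assert len(calls) == 1 and not drops
        assert (calls[0].curated_name, calls[0].start, calls[0].end) == ("CBM", 10, 90)

    def test_foreign_annotation_rejected(self):
        with pytest.raises(ValueError, match="P2"):
            consolidate("P1", [ann("CBM", 1, 50, pid="P2")])

    def test_deterministic_repeated_runs(self):
        anns = self._redundant_three_domain_annotations()
        curation_a = CurationMap(entries={"Glyco_hydro_48": "Catalytic domain"})
        curation_b = CurationMap(entries={"Glyco_hydro_48": "Catalytic domain"})
        assert consolidate("P1", anns, curation_a)[0] == consolidate(
            "P1", anns, curation_b
        )[0]

    def test_count_conservation(self, rng):
        # |raw eligible-or-not| = |retained| + |drop-log entries|
        cfg = ConsolidationConfig()
        for _ in range(50):
            anns = []
            for k in range(rng.randint(1, 12)):
                start = rng.randint(1, 300)
                anns.append(
                    RawAnnotation(
                        "P1",
                        rng.choice(["Pfam", "CDD", "PHOBIUS", "SUPERFAMILY"]),
                        f"A{k}",
                        rng.choice(["Dom1", "Dom2", "Dom3", "None", "SIGNAL_X"]),
                        start,
                        start + rng.randint(3, 400),
                    )
                )
            calls, drops = consolidate("P1", anns, cfg=cfg)
            assert len(anns) == len(calls) + len(drops)

    def test_retained_pairs_never_exceed_threshold(self, rng):
        cfg = ConsolidationConfig()
        for _ in range(100):
            calls = random_calls(rng, rng.randint(2, 10))
            kept, _ = resolve_overlaps(calls, cfg)
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    assert (
                        overlap_fraction(
                            (kept[i].start, kept[i].end), (kept[j].start, kept[j].end)
                        )
                        <= cfg.overlap_threshold
                    )

    def test_raising_max_domain_size_admits_monotonically_more_annotations(self, rng):
        # the eligible set grows with the size window ...
        base_anns = []
        for k in range(30):
            start = rng.randint(1, 200)
            base_anns.append(
                RawAnnotation("P1", "Pfam", f"A{k}", f"Dom{k}", start,
                              start + rng.randint(50, 900))
            )
        previous_eligible: set[str] = set()
        for max_size in (100, 400, 800, 1200):
            cfg = ConsolidationConfig(max_domain_size=max_size)
            eligible = {a.accession for a in base_anns if is_eligible(a, cfg)[0]}
            assert previous_eligible <= eligible
            previous_eligible = eligible

    def test_raising_max_domain_size_monotone_retention_without_conflicts(self):
        # ... and on conflict-free inputs the retained count is monotone too
        anns = [
            ann("DomA", 1, 90),
            ann("DomB", 100, 450),
            ann("DomC", 460, 1300),
        ]
        counts = []
        for max_size in (100, 400, 800, 1200):
            cfg = ConsolidationConfig(max_domain_size=max_size)
            calls, _ = consolidate("P1", anns, cfg=cfg)
            counts.append(len(calls))
        assert counts == [1, 2, 2, 3]
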