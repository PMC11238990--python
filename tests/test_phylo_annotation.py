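import pytest

from oracles import validate_itol_domains, validate_itol_treecolors
from domarch.model import DomainCall, ProteinRecord
from domarch.phylo_annotation import (
    FastTreeAdapter,
    MafftAdapter,
    StubAligner,
    StubTreeBuilder,
    StyleMap,
    TreeBundle,
    build_style_map,
    leaf_names,
    pick_activity,
    run_msa,
    run_tree,
    select_tree_inputs,
    write_itol_domains,
    write_itol_labelcolors,
)


def rec(pid, seq="MKVAWWKLAV", **kw):
    return ProteinRecord(pid, seq, **kw)


def call(name, start, end, pid="P1"):
    return DomainCall(pid, name, start, end, frozenset({"Pfam"}), frozenset())


class TestSelectTreeInputs:
    def test_domainless_protein_excluded(self):
        records = [rec(f"P{i}") for i in range(5)]
        calls = {f"P{i}": [call("CBM", 1, 8, pid=f"P{i}")] for i in range(4)}
        kept, excluded = select_tree_inputs(records, calls)
        assert [r.protein_id for r in kept] == ["P0", "P1", "P2", "P3"]
        assert excluded == [("P4", "no detected domains")]

    def test_all_domainless_yields_empty(self):
        kept, excluded = select_tree_inputs([rec("P1"), rec("P2")], {})
        assert kept == [] and len(excluded) == 2

    def test_none_domainless_is_identity(self):
        records = [rec("P1"), rec("P2")]
        calls = {r.protein_id: [call("CBM", 1, 8, pid=r.protein_id)] for r in records}
        kept, excluded = select_tree_inputs(records, calls)
        assert kept == records and excluded == []


class TestAdapters:
    def test_stub_pipeline_two_leaves(self):
        records = [rec("A", "MKVA"), rec("B", "MKVA")]
        alignment = run_msa(records, StubAligner())
        bundle = run_tree(alignment, StubTreeBuilder())
        assert bundle.newick == "(A,B);"
        assert set(leaf_names(bundle.newick)) == {"A", "B"}

    def test_stub_identity_on_prealigned_input(self):
        records = [rec("A", "MKVA"), rec("B", "MCVA")]
        alignment = run_msa(records, StubAligner())
        assert alignment == [("A", "MKVA"), ("B", "MCVA")]

    def test_leaf_set_mismatch_rejected(self):
        class DroppingTreeBuilder:
            def infer(self, alignment):
                return "(" + ",".join(pid for pid, _ in alignment[:-1]) + ");"

        records = [rec("A"), rec("B"), rec("C")]
        alignment = run_msa(records, StubAligner())
        with pytest.raises(ValueError, match="leaf set mismatch"):
            run_tree(alignment, DroppingTreeBuilder())

    def test_ragged_alignment_rejected(self):
        class RaggedAligner:
            def align(self, records):
                return [(r.protein_id, r.sequence) for r in records]

        with pytest.raises(ValueError, match="ragged"):
            run_msa([rec("A", "MK"), rec("B", "MKVA")], RaggedAligner())

    def test_missing_binary_error_names_it(self):
        with pytest.raises(FileNotFoundError, match="definitely-not-a-real-aligner"):
            MafftAdapter("definitely-not-a-real-aligner").align([rec("A")])

    def test_real_mafft_fasttree_roundtrip(self):
        # end-to-end through the real binaries on a tiny input
        records = [
            rec("A", "MKVAWWKLAVCDEFGHIKLMNPQRST"),
            rec("B", "MKVAWWKLAVCDEFGHIKLMNPQRSA"),
            rec("C", "MKVGWWKLAVCDEFGHIKLMNPQRSA"),
            rec("D", "WWWWWWKLAVCDEFGHIKIIIPQRSA"),
        ]
        alignment = run_msa(records, MafftAdapter())
        bundle = run_tree(alignment, FastTreeAdapter())
        assert set(leaf_names(bundle.newick)) == {"A", "B", "C", "D"}


class TestPickActivity:
    def test_single_activity_no_warning(self):
        assert pick_activity(["3.2.1.4"]) == ("3.2.1.4", False)

    def test_multiple_activities_numeric_tuple_order(self):
        # (3,2,1,4) < (3,2,1,176): numeric comparison, not string order
        assert pick_activity(["3.2.1.176", "3.2.1.4"]) == ("3.2.1.4", True)

    def test_empty_list(self):
        assert pick_activity([]) == (None, False)

    def test_wildcard_sorts_after_numbers(self):
        assert pick_activity(["3.2.1.-", "3.2.1.4"]) == ("3.2.1.4", True)


class TestStyleMap:
    def test_unique_styles_and_stable_assignment(self):
        names = ["CBM", "Catalytic domain", "Dockerin"]
        style1 = build_style_map(names)
        style2 = build_style_map(list(reversed(names)))
        assert style1.domain_styles == style2.domain_styles
        assert len(set(style1.domain_styles.values())) == 3

    def test_conventional_ec_colours(self):
        style = build_style_map([], ["3.2.1.4", "3.2.1.14", "3.2.1.91", "3.2.1.176"])
        assert style.ec_colors["3.2.1.14"] == "#1f77b4"   # blue
        assert style.ec_colors["3.2.1.91"] == "#2ca02c"   # green
        assert style.ec_colors["3.2.1.176"] == "#d62728"  # red

    def test_duplicate_ec_colour_rejected(self):
        with pytest.raises(ValueError, match="share the same label colour"):
            StyleMap(ec_colors={"3.2.1.4": "#ff0000", "3.2.1.14": "#ff0000"})

    def test_duplicate_domain_style_rejected(self):
        with pytest.raises(ValueError, match="share the same"):
            StyleMap(domain_styles={"A": ("RE", "#ff0000"), "B": ("RE", "#ff0000")})


def _tree_fixture(n=6, n_characterized=2, seq_len=300):
    records, calls = {}, {}
    for i in range(n):
        pid = f"P{i:03d}"
        characterized = i < n_characterized
        records[pid] = ProteinRecord(
            pid, "M" * seq_len, taxonomy_group="Bacteria",
            characterized=characterized,
            ec_numbers=["3.2.1.176", "3.2.1.4"] if characterized else [],
        )
        calls[pid] = [
            call("CBM", 1, 100, pid=pid),
            call("Catalytic domain", 120, 290, pid=pid),
        ]
    bundle = TreeBundle(
        newick="(" + ",".join(sorted(records)) + ");",
        included_ids=set(records),
    )
    style = build_style_map(["CBM", "Catalytic domain"], ["3.2.1.4", "3.2.1.176"])
    return bundle, records, calls, style


class TestWriteItolDomains:
    def test_shapes_in_start_order_on_one_leaf(self, tmp_path):
        bundle, records, calls, style = _tree_fixture(n=1, n_characterized=0)
        out = tmp_path / "domains.txt"
        write_itol_domains(bundle, records, calls, style, out)
        data_line = out.read_text().splitlines()[-1]
        fields = data_line.split(",")
        assert fields[0] == "P000" and fields[1] == "300"
        assert [f.split("|")[4] for f in fields[2:]] == ["CBM", "Catalytic domain"]

    def test_byte_deterministic(self, tmp_path):
        bundle, records, calls, style = _tree_fixture()
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        write_itol_domains(bundle, records, calls, style, a)
        write_itol_domains(bundle, records, calls, style, b)
        assert a.read_bytes() == b.read_bytes()

    def test_passes_format_validator(self, tmp_path):
        bundle, records, calls, style = _tree_fixture()
        out = tmp_path / "domains.txt"
        write_itol_domains(bundle, records, calls, style, out)
        assert validate_itol_domains(out.read_text()) == []

    def test_one_data_line_per_leaf_and_spans_in_bounds(self, tmp_path):
        bundle, records, calls, style = _tree_fixture(n=9)
        out = tmp_path / "domains.txt"
        write_itol_domains(bundle, records, calls, style, out)
        lines = out.read_text().splitlines()
        data = lines[lines.index("DATA") + 1 :]
        assert len(data) == len(bundle.included_ids)
        for line in data:
            fields = line.split(",")
            length = int(fields[1])
            for shape_field in fields[2:]:
                _, s, e, _, _ = shape_field.split("|")
                assert 1 <= int(s) <= int(e) <= length

    def test_leaf_without_record_rejected(self, tmp_path):
        bundle, records, calls, style = _tree_fixture()
        del records["P000"]
        with pytest.raises(ValueError, match="P000"):
            write_itol_domains(bundle, records, calls, style, tmp_path / "x.txt")


class TestWriteItolLabelColors:
    def test_characterized_count_at_family_scale(self, tmp_path):
        # 216 retained sequences of which 18 are characterized
        bundle, records, calls, style = _tree_fixture(n=216, n_characterized=18)
        out = tmp_path / "colors.txt"
        write_itol_labelcolors(bundle, records, style, out)
        lines = out.read_text().splitlines()
        data = lines[lines.index("DATA") + 1 :]
        assert len(data) == 18
        assert validate_itol_treecolors(out.read_text()) == []

    def test_zero_characterized_header_only(self, tmp_path):
        bundle, records, calls, style = _tree_fixture(n=4, n_characterized=0)
        out = tmp_path / "colors.txt"
        write_itol_labelcolors(bundle, records, style, out)
        assert out.read_text().splitlines() == ["TREE_COLORS", "SEPARATOR SPACE", "DATA"]

    def test_label_lines_use_picked_activity_colour(self, tmp_path):
        bundle, records, calls, style = _tree_fixture(n=3, n_characterized=1)
        out = tmp_path / "colors.txt"
        write_itol_labelcolors(bundle, records, style, out)
        # multi-activity protein: numeric tuple order picks 3.2.1.4
        assert (
            out.read_text().splitlines()[-1]
            == f"P000 label {style.ec_colors['3.2.1.4']} normal"
        )


def test_tree_bundle_rejects_inconsistent_id_sets():
    with pytest.raises(ValueError, match="intersect"):
        TreeBundle(newick="(A,B);", included_ids={"A", "B"}, excluded_ids={"A"})
    with pytest.raises(ValueError, match="leaf set mismatch"):
        TreeBundle(newick="(A,B);", included_ids={"A", "C"})
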