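"""Phylogenetic-tree construction adapters and iTOL annotation writers.

Alignment and tree inference are delegated to external tools (MAFFT and
FastTree, both run with default settings; FastTree reports
Shimodaira-Hasegawa local supports from 1000 resamples by default) behind
small adapter classes, with in-process stub adapters for testing. The
module then produces two plain-text iTOL annotation datasets: a
DATASET_DOMAINS file drawing each leaf's domain architecture as shapes,
and a TREE_COLORS file colouring the labels of characterized proteins by
their enzymatic activity (EC number).
"""
from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

from Bio import Phylo

from .model import DomainCall, ProteinRecord

logger = logging.getLogger(__name__)

Alignment = list[tuple[str, str]]  # (protein_id, aligned sequence)

#: iTOL DATASET_DOMAINS shape vocabulary (rectangle, ellipse, diamond,
#: triangles, hexagons, pentagrams, octagon).
ITOL_SHAPES = ("RE", "EL", "DI", "TR", "TL", "HH", "HV", "PL", "PR", "PU", "PD", "OC")

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#dbdb8d",
    "#9edae5", "#393b79",
)

#: Conventional label colours for the four activities known in family GH48.
DEFAULT_EC_COLORS = {
    "3.2.1.14": "#1f77b4",   # chitinase - blue
    "3.2.1.91": "#2ca02c",   # cellobiohydrolase - green
    "3.2.1.176": "#d62728",  # reducing-end cellobiohydrolase - red
}


@dataclass
class TreeBundle:
    """A Newick tree plus bookkeeping of which proteins it includes."""

    newick: str
    included_ids: set[str]
    excluded_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.included_ids & self.excluded_ids:
            raise ValueError("included and excluded id sets intersect")
        leaves = set(leaf_names(self.newick))
        if leaves != set(self.included_ids):
            missing = set(self.included_ids) - leaves
            extra = leaves - set(self.included_ids)
            raise ValueError(
                f"tree leaf set mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )


@dataclass
class StyleMap:
    """Deterministic shape/colour assignment for domains and EC labels."""

    domain_styles: dict[str, tuple[str, str]] = field(default_factory=dict)
    ec_colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        styles = list(self.domain_styles.values())
        if len(set(styles)) != len(styles):
            raise ValueError("two domains share the same (shape, colour) pair")
        colors = list(self.ec_colors.values())
        if len(set(colors)) != len(colors):
            raise ValueError("two EC numbers share the same label colour")


def leaf_names(newick: str) -> list[str]:
    tree = Phylo.read(io.StringIO(newick), "newick")
    return [leaf.name for leaf in tree.get_terminals()]


def build_style_map(
    domain_names: Sequence[str], ec_numbers: Sequence[str] = ()
) -> StyleMap:
    """Assign a unique (shape, colour) to each domain and a colour to each EC.

    Assignment walks the shape x colour product in sorted-domain-name
    order, so it is stable across runs for the same name set. EC colours
    start from the conventional activity colours and fall back to the
    palette.
    """
    styles: dict[str, tuple[str, str]] = {}
    names = sorted(set(domain_names))
    capacity = len(ITOL_SHAPES) * len(_PALETTE)
    if len(names) > capacity:
        raise ValueError(f"more than {capacity} distinct domains; extend the palette")
    for i, name in enumerate(names):
        styles[name] = (ITOL_SHAPES[i % len(ITOL_SHAPES)], _PALETTE[i % len(_PALETTE)])
    ec_colors: dict[str, str] = {}
    used: set[str] = set()
    ordered_ecs = sorted(set(ec_numbers), key=_ec_sort_key)
    for ec in ordered_ecs:  # conventional colours claimed first
        if ec in DEFAULT_EC_COLORS:
            ec_colors[ec] = DEFAULT_EC_COLORS[ec]
            used.add(DEFAULT_EC_COLORS[ec])
    for ec in ordered_ecs:
        if ec not in ec_colors:
            color = next(c for c in _PALETTE if c not in used)
            ec_colors[ec] = color
            used.add(color)
    return StyleMap(domain_styles=styles, ec_colors=ec_colors)


# ---------------------------------------------------------------------------
# Tree-input selection and activity picking
# ---------------------------------------------------------------------------

def select_tree_inputs(
    records: Sequence[ProteinRecord],
    calls_by_protein: Mapping[str, Sequence[DomainCall]],
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Keep only proteins with at least one detected domain.

    Domainless proteins are excluded from the alignment (and therefore
    from the tree) and returned in the exclusion log.
    """
    kept, excluded = [], []
    for rec in records:
        if calls_by_protein.get(rec.protein_id):
            kept.append(rec)
        else:
            excluded.append((rec.protein_id, "no detected domains"))
    if not kept:
        logger.warning("no proteins carry domain calls; tree input set is empty")
    return kept, excluded


def _ec_sort_key(ec: str) -> tuple:
    # wildcard '-' components sort after any numeric component
    return tuple(float("inf") if part == "-" else int(part) for part in ec.split("."))


def pick_activity(ec_numbers: Sequence[str]) -> tuple[Optional[str], bool]:
    """Choose the single EC used to colour a leaf label.

    A protein with several recorded activities triggers a warning and only
    the first EC in dotted-integer-tuple order is used.
    """
    if not ec_numbers:
        return None, False
    ordered = sorted(set(ec_numbers), key=_ec_sort_key)
    if len(ordered) > 1:
        logger.warning(
            "multiple activities %s: only %s will be used for tree annotation",
            ordered, ordered[0],
        )
        return ordered[0], True
    return ordered[0], False


# ---------------------------------------------------------------------------
# External-tool adapters
# ---------------------------------------------------------------------------

class MsaAdapter(Protocol):
    def align(self, records: Sequence[ProteinRecord]) -> Alignment: ...


class TreeAdapter(Protocol):
    def infer(self, alignment: Alignment) -> str: ...


def _require_binary(binary: str) -> str:
    resolved = shutil.which(binary)
    if resolved is None:
        raise FileNotFoundError(
            f"required external tool {binary!r} not found on PATH; install it or "
            "pass a different adapter"
        )
    return resolved


class MafftAdapter:
    """Run MAFFT with default settings on a temporary FASTA file."""

    def __init__(self, binary: str = "mafft") -> None:
        self.binary = binary

    def align(self, records: Sequence[ProteinRecord]) -> Alignment:
        binary = _require_binary(self.binary)
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "input.fasta"
            with open(fasta, "w") as handle:
                for rec in records:
                    handle.write(f">{rec.protein_id}\n{rec.sequence}\n")
            result = subprocess.run(
                [binary, "--auto", str(fasta)],
                capture_output=True, text=True, check=True,
            )
        logger.info("mafft exit status 0 (%d records)", len(records))
        return _parse_fasta_text(result.stdout)


class FastTreeAdapter:
    """Run FastTree (protein mode, default settings) on an alignment."""

    def __init__(self, binary: str = "fasttree") -> None:
        self.binary = binary

    def infer(self, alignment: Alignment) -> str:
        binary = _require_binary(self.binary)
        fasta_text = "".join(f">{pid}\n{seq}\n" for pid, seq in alignment)
        result = subprocess.run(
            [binary], input=fasta_text, capture_output=True, text=True, check=True
        )
        logger.info("fasttree exit status 0 (%d leaves)", len(alignment))
        return result.stdout.strip()


class StubAligner:
    """Test aligner: pads sequences with gaps to a common length."""

    def align(self, records: Sequence[ProteinRecord]) -> Alignment:
        width = max(len(rec.sequence) for rec in records)
        return [
            (rec.protein_id, rec.sequence.ljust(width, "-")) for rec in records
        ]


class StubTreeBuilder:
    """Test tree builder: emits a star tree over the alignment ids."""

    def infer(self, alignment: Alignment) -> str:
        return "(" + ",".join(pid for pid, _ in alignment) + ");"


def _parse_fasta_text(text: str) -> Alignment:
    alignment: Alignment = []
    pid, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if pid is not None:
                alignment.append((pid, "".join(chunks)))
            pid, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if pid is not None:
        alignment.append((pid, "".join(chunks)))
    return alignment


def run_msa(records: Sequence[ProteinRecord], adapter: MsaAdapter) -> Alignment:
    """Align the records, validating the adapter's output contract."""
    if not records:
        raise ValueError("run_msa requires at least one record")
    alignment = adapter.align(records)
    widths = {len(seq) for _, seq in alignment}
    if len(widths) != 1:
        raise ValueError("adapter returned ragged alignment columns")
    if {pid for pid, _ in alignment} != {rec.protein_id for rec in records}:
        raise ValueError("adapter dropped or renamed sequences")
    return alignment


def run_tree(
    alignment: Alignment,
    adapter: TreeAdapter,
    excluded_ids: Sequence[str] = (),
) -> TreeBundle:
    """Infer a tree from the alignment and wrap it with leaf bookkeeping."""
    newick = adapter.infer(alignment)
    return TreeBundle(
        newick=newick,
        included_ids={pid for pid, _ in alignment},
        excluded_ids=set(excluded_ids),
    )


# ---------------------------------------------------------------------------
# iTOL writers
# ---------------------------------------------------------------------------

def write_itol_domains(
    tree: TreeBundle,
    records: Mapping[str, ProteinRecord],
    calls_by_protein: Mapping[str, Sequence[DomainCall]],
    style: StyleMap,
    path: str | Path,
    dataset_label: str = "Domain architectures",
) -> None:
    """Write an iTOL DATASET_DOMAINS file drawing each leaf's architecture.

    One DATA line per leaf: ``id,protein_length,SHAPE|start|end|color|label,...``
    with shapes in start order and 1-based inclusive coordinates. Output
    is byte-deterministic for identical inputs.
    """
    lines = [
        "DATASET_DOMAINS",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{dataset_label}",
        "COLOR,#7a7a7a",
        "DATA",
    ]
    for pid in sorted(tree.included_ids):
        rec = records.get(pid)
        if rec is None:
            raise ValueError(f"tree leaf {pid} has no protein record")
        fields = [pid, str(len(rec.sequence))]
        for call in sorted(calls_by_protein.get(pid, []), key=lambda c: (c.start, c.end)):
            if call.end > len(rec.sequence):
                raise ValueError(
                    f"{pid}: call {call.curated_name} ends at {call.end} beyond "
                    f"sequence length {len(rec.sequence)}"
                )
            shape, color = style.domain_styles[call.curated_name]
            fields.append(f"{shape}|{call.start}|{call.end}|{color}|{call.curated_name}")
        lines.append(",".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_itol_labelcolors(
    tree: TreeBundle,
    records: Mapping[str, ProteinRecord],
    style: StyleMap,
    path: str | Path,
) -> None:
    """Write an iTOL TREE_COLORS file colouring characterized leaf labels.

    One ``id label color normal`` line per characterized leaf, coloured by
    its picked activity (EC number). Uncharacterized leaves are omitted.
    """
    lines = ["TREE_COLORS", "SEPARATOR SPACE", "DATA"]
    for pid in sorted(tree.included_ids):
        rec = records.get(pid)
        if rec is None or not rec.characterized:
            continue
        ec, _warned = pick_activity(rec.ec_numbers)
        if ec is None or ec not in style.ec_colors:
            continue
        lines.append(f"{pid} label {style.ec_colors[ec]} normal")
    Path(path).write_text("\n".join(lines) + "\n")
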