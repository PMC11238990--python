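"""Readers/writers for every external format the pipeline touches.

Formats handled here: FASTA (with an optional ``key=value`` header
convention carrying taxonomy/characterized/EC metadata), the flat TSV and
nested-JSON annotation dialects, the two-column characterized-protein and
curation tables, one-id-per-line presence lists, and the three-table SQLite
analysis store (``ProteinSequences``, ``DomainAssemblies``,
``DomainCuration``).
"""
from __future__ import annotations

import json
import logging
import re
import sqlite3
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Architecture,
    DomainCall,
    MEMBER_DATABASES,
    ProteinRecord,
    RawAnnotation,
    TAXONOMY_GROUPS,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: DDL of the analysis store. Domain calls and EC lists are serialized as
#: JSON inside their protein's row; boundaries stay 1-based inclusive.
SCHEMA_DDL = """
CREATE TABLE ProteinSequences (
    protein_id          TEXT PRIMARY KEY,
    sequence            TEXT NOT NULL,
    description         TEXT NOT NULL DEFAULT '',
    taxonomy_group      TEXT NOT NULL,
    characterized       INTEGER NOT NULL DEFAULT 0,
    ec_numbers          TEXT NOT NULL DEFAULT '[]',
    architecture_string TEXT NOT NULL DEFAULT '',
    domain_calls        TEXT NOT NULL DEFAULT '[]'
);
CREATE TABLE DomainAssemblies (
    architecture_string TEXT PRIMARY KEY,
    member_count        INTEGER NOT NULL,
    example_protein_id  TEXT,
    taxonomy_summary    TEXT NOT NULL DEFAULT '',
    prevalence          REAL,
    ec_numbers          TEXT NOT NULL DEFAULT '[]',
    member_ids          TEXT NOT NULL DEFAULT '[]'
);
CREATE TABLE DomainCuration (
    raw_name     TEXT NOT NULL,
    curated_name TEXT NOT NULL,
    timestamp    TEXT NOT NULL
);
"""

ANNOTATION_TSV_COLUMNS = ("protein_id", "source_db", "accession", "name", "start", "end")

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

_HEADER_KEYS = ("tax", "characterized", "ec")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header_metadata(description: str) -> tuple[str, dict]:
    """Split recognized ``key=value`` tokens out of a FASTA description.

    Recognized keys: ``tax=<group>``, ``characterized=<0|1>``,
    ``ec=<ec;ec;...>``. Unrecognized tokens stay in the free-text
    description.
    """
    meta: dict = {}
    plain: list[str] = []
    for token in description.split():
        key, _, value = token.partition("=")
        if key in _HEADER_KEYS and value:
            meta[key] = value
        else:
            plain.append(token)
    return " ".join(plain), meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased; duplicate identifiers are rejected. Metadata
    may be encoded in the header via the documented ``key=value`` tokens.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaParseError(f"{path}: empty FASTA input")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected a '>' header before sequence data"
            )
        break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        pid = seq_record.id
        if pid in seen:
            raise FastaParseError(f"{path}: duplicate identifier {pid!r}")
        seen.add(pid)
        description = seq_record.description
        if description.startswith(pid):
            description = description[len(pid):].strip()
        plain, meta = _parse_header_metadata(description)
        tax = meta.get("tax", "Unclassified")
        if tax not in TAXONOMY_GROUPS:
            raise FastaParseError(
                f"{path}: {pid}: unknown taxonomy group {tax!r} in header"
            )
        ecs = [e for e in meta.get("ec", "").split(";") if e]
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=str(seq_record.seq).upper(),
                description=plain,
                taxonomy_group=tax,
                characterized=meta.get("characterized", "0") == "1" or bool(ecs),
                ec_numbers=ecs,
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrapped, metadata in header tokens."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seq_records = []
    for rec in records:
        tokens = []
        if rec.description:
            tokens.append(rec.description)
        if rec.taxonomy_group != "Unclassified":
            tokens.append(f"tax={rec.taxonomy_group}")
        if rec.characterized:
            tokens.append("characterized=1")
        if rec.ec_numbers:
            tokens.append("ec=" + ";".join(rec.ec_numbers))
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=" ".join(tokens))
        )
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")  # wraps at 60 columns


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _annotation_from_fields(
    protein_id: str,
    source_db: str,
    accession: str,
    name: str,
    start,
    end,
    origin: str,
) -> RawAnnotation | None:
    """Validate one annotation record; return None (and log) when invalid."""
    try:
        start, end = int(start), int(end)
    except (TypeError, ValueError):
        logger.warning("%s: non-integer coordinates, record skipped", origin)
        return None
    if not (1 <= start <= end):
        logger.warning(
            "%s: invalid span (%d, %d) for %s/%s, record skipped",
            origin, start, end, protein_id, accession,
        )
        return None
    if source_db not in MEMBER_DATABASES:
        logger.warning("%s: unrecognized source database %r (kept)", origin, source_db)
    return RawAnnotation(protein_id, source_db, accession, name, start, end)


def _read_annotation_tsv(path: Path) -> list[RawAnnotation]:
    anns: list[RawAnnotation] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_TSV_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(ANNOTATION_TSV_COLUMNS)}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                logger.warning("%s:%d: expected 6 fields, record skipped", path, lineno)
                continue
            ann = _annotation_from_fields(*fields, origin=f"{path}:{lineno}")
            if ann is not None:
                anns.append(ann)
    return anns


def _read_annotation_json(path: Path) -> list[RawAnnotation]:
    """Nested dialect: ``{protein_id: [{source_db, accession, name, start, end}]}``."""
    payload = json.loads(path.read_text())
    anns: list[RawAnnotation] = []
    for protein_id in payload:
        for i, entry in enumerate(payload[protein_id]):
            ann = _annotation_from_fields(
                protein_id,
                entry.get("source_db", ""),
                entry.get("accession", ""),
                entry.get("name", "None"),
                entry.get("start"),
                entry.get("end"),
                origin=f"{path}:{protein_id}[{i}]",
            )
            if ann is not None:
                anns.append(ann)
    return anns


def read_annotations(path: str | Path) -> list[RawAnnotation]:
    """Read domain annotations from a TSV file, a JSON file, or a directory.

    A directory is read as the concatenation of its files in sorted name
    order; within a file, record order follows line order. Records whose
    coordinates violate ``1 <= start <= end`` are skipped with a log
    message rather than raising.
    """
    path = Path(path)
    if path.is_dir():
        anns: list[RawAnnotation] = []
        for child in sorted(path.iterdir()):
            if child.is_file():
                anns.extend(read_annotations(child))
        return anns
    with open(path) as handle:
        head = handle.read(200).lstrip()[:1]
    if head in ("{", "["):
        return _read_annotation_json(path)
    return _read_annotation_tsv(path)


# ---------------------------------------------------------------------------
# Characterized table / curation map / presence list
# ---------------------------------------------------------------------------

def read_characterized_table(path: str | Path) -> dict[str, list[str]]:
    """Read ``protein_id<TAB>ec;ec;...`` into a mapping id -> EC list."""
    table: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            protein_id, ec_field = fields
            ecs = [e.strip() for e in ec_field.split(";") if e.strip()]
            for ec in ecs:
                if not EC_PATTERN.match(ec):
                    raise ValueError(f"{path}:{lineno}: malformed EC number {ec!r}")
            table[protein_id] = ecs
    return table


def read_curation_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``raw_name<TAB>curated_name`` mapping."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            raw, curated = fields
            if raw in mapping and mapping[raw] != curated:
                raise ValueError(f"{path}:{lineno}: conflicting curation for {raw!r}")
            mapping[raw] = curated
    return mapping


def read_presence_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line presence list (offline UniParc stand-in)."""
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


# ---------------------------------------------------------------------------
# SQLite analysis store
# ---------------------------------------------------------------------------

def _check_store_invariants(
    records: Sequence[ProteinRecord],
    calls: Mapping[str, Sequence[DomainCall]],
    assemblies: Sequence[Architecture],
) -> None:
    from .architecture import architecture_string

    known = {a.canonical for a in assemblies}
    offending = []
    n_with_calls = 0
    for rec in records:
        rec_calls = calls.get(rec.protein_id, [])
        if not rec_calls:
            continue
        n_with_calls += 1
        arch = architecture_string(rec_calls)
        if arch not in known:
            offending.append(arch)
    if offending:
        raise ValueError(
            "architecture strings present in ProteinSequences but missing from "
            f"DomainAssemblies: {sorted(set(offending))}"
        )
    total_members = sum(a.member_count for a in assemblies)
    if total_members != n_with_calls:
        raise ValueError(
            f"DomainAssemblies member counts sum to {total_members} but "
            f"{n_with_calls} proteins carry at least one domain call"
        )


def _calls_to_json(rec_calls: Sequence[DomainCall]) -> str:
    return json.dumps(
        [
            {
                "curated_name": c.curated_name,
                "start": c.start,
                "end": c.end,
                "source_dbs": sorted(c.source_dbs),
                "accessions": sorted(c.accessions),
            }
            for c in sorted(rec_calls, key=lambda c: (c.start, c.end))
        ]
    )


def save_analysis(
    store_path: str | Path,
    records: Sequence[ProteinRecord],
    calls: Mapping[str, Sequence[DomainCall]],
    assemblies: Sequence[Architecture],
    curation_log: Iterable[tuple[str, str]] = (),
) -> None:
    """Persist a full analysis into the three-table SQLite store.

    Refuses to save when the store invariants do not hold (every
    architecture present among the protein rows must exist in
    DomainAssemblies, and member counts must sum to the number of proteins
    with at least one call).
    """
    from .architecture import architecture_string

    _check_store_invariants(records, calls, assemblies)
    store_path = Path(store_path)
    if store_path.exists():
        store_path.unlink()
    con = sqlite3.connect(store_path)
    try:
        con.executescript(SCHEMA_DDL)
        con.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
        for rec in records:
            rec_calls = list(calls.get(rec.protein_id, []))
            con.execute(
                "INSERT INTO ProteinSequences VALUES (?,?,?,?,?,?,?,?)",
                (
                    rec.protein_id,
                    rec.sequence,
                    rec.description,
                    rec.taxonomy_group,
                    int(rec.characterized),
                    json.dumps(rec.ec_numbers),
                    architecture_string(rec_calls) if rec_calls else "",
                    _calls_to_json(rec_calls),
                ),
            )
        for asm in assemblies:
            con.execute(
                "INSERT INTO DomainAssemblies VALUES (?,?,?,?,?,?,?)",
                (
                    asm.canonical,
                    asm.member_count,
                    asm.example_id,
                    ";".join(sorted(asm.taxonomy_set)),
                    asm.prevalence,
                    json.dumps(sorted(asm.ec_set)),
                    json.dumps(asm.protein_ids),
                ),
            )
        stamp = datetime.now(timezone.utc).isoformat()
        for raw, curated in curation_log:
            con.execute(
                "INSERT INTO DomainCuration VALUES (?,?,?)", (raw, curated, stamp)
            )
        con.commit()
    finally:
        con.close()


def load_analysis(
    store_path: str | Path,
) -> tuple[
    list[ProteinRecord],
    dict[str, list[DomainCall]],
    list[Architecture],
    list[tuple[str, str]],
]:
    """Load the tuple persisted by :func:`save_analysis` (lossless round-trip)."""
    con = sqlite3.connect(store_path)
    try:
        records: list[ProteinRecord] = []
        calls: dict[str, list[DomainCall]] = {}
        for row in con.execute(
            "SELECT protein_id, sequence, description, taxonomy_group, characterized,"
            " ec_numbers, domain_calls FROM ProteinSequences"
        ):
            pid, seq, desc, tax, char, ecs, calls_json = row
            records.append(
                ProteinRecord(pid, seq, desc, tax, bool(char), json.loads(ecs))
            )
            rec_calls = [
                DomainCall(
                    pid,
                    c["curated_name"],
                    c["start"],
                    c["end"],
                    frozenset(c["source_dbs"]),
                    frozenset(c["accessions"]),
                )
                for c in json.loads(calls_json)
            ]
            if rec_calls:
                calls[pid] = rec_calls
        assemblies: list[Architecture] = []
        for row in con.execute(
            "SELECT architecture_string, member_count, example_protein_id,"
            " taxonomy_summary, prevalence, ec_numbers, member_ids"
            " FROM DomainAssemblies"
        ):
            canonical, _count, example, tax_summary, prevalence, ecs, members = row
            from .model import ARCHITECTURE_SEPARATOR

            assemblies.append(
                Architecture(
                    ordered_names=canonical.split(ARCHITECTURE_SEPARATOR),
                    protein_ids=json.loads(members),
                    prevalence=prevalence,
                    taxonomy_set={t for t in tax_summary.split(";") if t},
                    example_id=example,
                    ec_set=set(json.loads(ecs)),
                )
            )
        curation = [
            (raw, curated)
            for raw, curated in con.execute(
                "SELECT raw_name, curated_name FROM DomainCuration ORDER BY rowid"
            )
        ]
        return records, calls, assemblies, curation
    finally:
        con.close()
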