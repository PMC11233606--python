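"""Mature tRNA reference handling.

Loads GtRNAdb-style mature tRNA FASTA files, parses isodecoder identity
(amino acid, anticodon, gene copy) from the record names, anchors canonical
anticodon-loop positions (32-38) on the linear sequence, and groups records
with identical mature sequences into isodecoder groups for multimapper
accounting.

Coordinates are 0-based, half-open throughout; canonical position labels
("32", "34", "47d", ...) are display strings attached to linear indices.
Only anticodon-anchored labels are derived automatically; structure-dependent
positions such as the D-loop C20 or the variable-arm C47d must be supplied
through an explicit override table (tRNA id -> linear index -> label), since
assigning them correctly requires knowledge of the cloverleaf fold.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: tRNA name token, e.g. "tRNA-Ser-GCT-2-1" inside "Homo_sapiens_tRNA-Ser-GCT-2-1".
TRNA_NAME_RE = re.compile(
    r"(?P<id>tRNA-(?P<aa>[A-Za-z]{2,4})-(?P<anticodon>[ACGTUacgtu]{3})-\d+-\d+)"
)

#: Amino acids whose tRNAs carry a long variable arm (type II).
TYPE_II_AMINO_ACIDS = frozenset({"Ser", "Leu"})

#: Offsets of canonical anticodon-loop positions relative to position 34.
_ANTICODON_LOOP_OFFSETS = {
    -2: "32",
    -1: "33",
    0: "34",
    1: "35",
    2: "36",
    3: "37",
    4: "38",
}

MIN_TRNA_LEN = 60
MAX_TRNA_LEN = 110


@dataclass(frozen=True)
class TRNARecord:
    """One mature tRNA with parsed identity and canonical-position labels.

    ``sequence`` is the mature, CCA-terminated sequence in the DNA alphabet
    (A/C/G/T; references conventionally store T for U).  ``anticodon_start``
    is the 0-based linear index of canonical position 34; it is ``None``
    until :func:`assign_canonical_positions` has run.
    """

    id: str
    amino_acid: str
    anticodon: str
    sequence: str
    anticodon_start: int | None = None
    canonical_labels: Mapping[int, str] = field(default_factory=dict)

    @property
    def type_class(self) -> str:
        """"II" for long-variable-arm tRNAs (Ser/Leu), "I" otherwise."""
        return "II" if self.amino_acid in TYPE_II_AMINO_ACIDS else "I"

    def __len__(self) -> int:
        return len(self.sequence)

    def index_of_label(self, label: str) -> int | None:
        """Linear index carrying canonical ``label``, or None."""
        for idx, lab in self.canonical_labels.items():
            if lab == label:
                return idx
        return None


@dataclass(frozen=True)
class IsodecoderGroup:
    """tRNA records sharing one identical mature sequence.

    Reads cannot distinguish members, so alignment-derived quantities are
    naturally reported per group.  ``group_id`` is the lexicographically
    smallest member id, which makes grouping deterministic.
    """

    group_id: str
    member_ids: tuple[str, ...]
    sequence: str


def parse_trna_fasta(
    path: str | Path,
    override: Mapping[str, Mapping[int, str]] | None = None,
) -> list[TRNARecord]:
    """Parse a GtRNAdb-style mature tRNA FASTA into :class:`TRNARecord` s.

    U is converted to T, a CCA tail is appended when the sequence does not
    already end in CCA, and canonical positions are anchored on the
    anticodon.  Entries whose header carries no parseable
    ``tRNA-<AA>-<Anticodon>-<n>-<m>`` token, or whose sequence violates the
    basic invariants (alphabet, length), are excluded with a logged warning.

    Raises ``ValueError`` on an empty file.
    """
    records: list[TRNARecord] = []
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        header = entry.description or entry.id
        m = TRNA_NAME_RE.search(header)
        if m is None:
            log.warning("header %r has no parseable tRNA token; record excluded", header)
            continue
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq.endswith("CCA"):
            seq += "CCA"
        if set(seq) - set("ACGT"):
            log.warning("record %s contains non-ACGT characters; excluded", m.group("id"))
            continue
        if not (MIN_TRNA_LEN <= len(seq) <= MAX_TRNA_LEN):
            log.warning(
                "record %s length %d outside [%d, %d]; excluded",
                m.group("id"), len(seq), MIN_TRNA_LEN, MAX_TRNA_LEN,
            )
            continue
        rec = TRNARecord(
            id=m.group("id"),
            amino_acid=m.group("aa"),
            anticodon=m.group("anticodon").upper().replace("U", "T"),
            sequence=seq,
        )
        records.append(assign_canonical_positions(rec, override))
    if n_entries == 0:
        raise ValueError(f"empty tRNA FASTA: {path}")
    return records


def assign_canonical_positions(
    record: TRNARecord,
    override: Mapping[str, Mapping[int, str]] | None = None,
) -> TRNARecord:
    """Anchor canonical positions 32-38 on the anticodon occurrence.

    When the anticodon occurs more than once in the sequence, the occurrence
    whose start is nearest to 34% of the sequence length is chosen (the
    anticodon sits roughly a third of the way along a mature tRNA).  Labels
    beyond the anticodon loop (e.g. "20", "47d") are taken only from the
    ``override`` table; no heuristic cloverleaf numbering is attempted.

    Raises ``ValueError`` if the anticodon is absent from the sequence.
    """
    seq, ac = record.sequence, record.anticodon
    occurrences = [m.start() for m in re.finditer(f"(?={re.escape(ac)})", seq)]
    if not occurrences:
        raise ValueError(f"anticodon {ac} not found in sequence of {record.id}")
    target = 0.34 * len(seq)
    start = min(occurrences, key=lambda i: (abs(i - target), i))
    labels: dict[int, str] = {}
    for off, lab in _ANTICODON_LOOP_OFFSETS.items():
        idx = start + off
        if 0 <= idx < len(seq):
            labels[idx] = lab
    if override and record.id in override:
        for idx, lab in override[record.id].items():
            if not 0 <= int(idx) < len(seq):
                raise ValueError(
                    f"override index {idx} out of range for {record.id} (len {len(seq)})"
                )
            labels[int(idx)] = str(lab)
    return replace(record, anticodon_start=start, canonical_labels=labels)


def group_isodecoders(records: Sequence[TRNARecord]) -> list[IsodecoderGroup]:
    """Partition records into groups of identical mature sequence."""
    by_seq: dict[str, list[str]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec.id)
    groups = [
        IsodecoderGroup(group_id=min(ids), member_ids=tuple(sorted(ids)), sequence=seq)
        for seq, ids in by_seq.items()
    ]
    groups.sort(key=lambda g: g.group_id)
    return groups


def group_of(records: Sequence[TRNARecord]) -> dict[str, str]:
    """Map each record id to its isodecoder group id."""
    mapping: dict[str, str] = {}
    for grp in group_isodecoders(records):
        for member in grp.member_ids:
            mapping[member] = grp.group_id
    return mapping


def read_override_table(path: str | Path) -> dict[str, dict[int, str]]:
    """Read a canonical-label override TSV.

    Columns: ``trna_id``, ``linear_index_0based``, ``canonical_label``.
    """
    table: dict[str, dict[int, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"trna_id", "linear_index_0based", "canonical_label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"override table {path} must have columns {sorted(required)}")
        for row in reader:
            table.setdefault(row["trna_id"], {})[int(row["linear_index_0based"])] = row[
                "canonical_label"
            ]
    return table


def write_override_table(table: Mapping[str, Mapping[int, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["trna_id", "linear_index_0based", "canonical_label"])
        for trna_id in sorted(table):
            for idx in sorted(table[trna_id]):
                writer.writerow([trna_id, idx, table[trna_id][idx]])


def write_trna_fasta(records: Iterable[TRNARecord], path: str | Path) -> None:
    """Write records back out as FASTA (round-trips with parse_trna_fasta)."""
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def write_reference_manifest(
    records: Sequence[TRNARecord], path: str | Path
) -> None:
    """Write the reference manifest TSV (id, aa, anticodon, length, anchors, group)."""
    groups = group_of(records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["id", "amino_acid", "anticodon", "length", "anticodon_start", "group_id"]
        )
        for rec in records:
            writer.writerow(
                [rec.id, rec.amino_acid, rec.anticodon, len(rec), rec.anticodon_start,
                 groups[rec.id]]
            )
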