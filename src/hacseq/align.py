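"""Ungapped small-RNA alignment to mature tRNA references.

Reads are trimmed, filtered, and scanned against every reference at every
offset on the sense strand; hits with at most ``max_mismatches`` (default 2)
are kept and reduced to the minimal-mismatch stratum.  A read matching n
equally good loci receives fractional weight 1/n at each (deterministic,
unbiased across identical isodecoders), so total weighted coverage always
equals the number of mapped reads.

Indels are not modelled: tRNA-derived fragments map end-to-end, and the
2-mismatch budget is what tolerates both sequencing error and the A-to-I
editing mismatch at position 34 (read as A->G).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from .reference import TRNARecord

log = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 5, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (N and unknowns never match)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    sample_id: str = ""


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a read on a reference (0-based, half-open)."""

    read_id: str
    trna_id: str
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[tuple[int, str, str], ...]
    weight: float


@dataclass
class AlignmentSummary:
    n_reads: int = 0
    n_mapped: int = 0
    mismatch_histogram: dict[int, int] = field(default_factory=dict)
    per_reference_weight: dict[str, float] = field(default_factory=dict)

    @property
    def mapped_fraction(self) -> float | None:
        """Fraction of reads with at least one alignment; None for empty input."""
        if self.n_reads == 0:
            return None
        return self.n_mapped / self.n_reads


class ReferenceIndex:
    """Encoded reference set supporting exhaustive ungapped scans."""

    def __init__(self, records: Sequence[TRNARecord]):
        if not records:
            raise ValueError("reference set is empty")
        self.records = list(records)
        self._ids = [rec.id for rec in records]
        self._seqs = [rec.sequence for rec in records]
        self._arrays = [encode(rec.sequence) for rec in records]

    def align_sequence(
        self, sequence: str, max_mismatches: int = 2
    ) -> list[tuple[str, int, int, tuple[tuple[int, str, str], ...]]]:
        """All minimal-stratum hits of ``sequence``: (trna_id, start, mm, mm_positions)."""
        query = encode(sequence)
        L = len(query)
        hits: list[tuple[int, int, int]] = []  # (ref index, offset, mismatches)
        for ri, arr in enumerate(self._arrays):
            if L > len(arr):
                continue
            windows = sliding_window_view(arr, L)
            mm = (windows != query).sum(axis=1)
            for off in np.nonzero(mm <= max_mismatches)[0]:
                hits.append((ri, int(off), int(mm[off])))
        if not hits:
            return []
        best = min(h[2] for h in hits)
        out = []
        for ri, start, mm in hits:
            if mm != best:
                continue
            ref_seq = self._seqs[ri]
            positions = tuple(
                (start + j, ref_seq[start + j], sequence[j])
                for j in range(L)
                if ref_seq[start + j] != sequence[j]
            )
            out.append((self._ids[ri], start, mm, positions))
        return out


def trim_and_filter(
    reads: Iterable[Read],
    adapter: str = "",
    min_len: int = 15,
    max_n: int = 1,
) -> list[Read]:
    """Trim 3' adapters and drop short / N-rich reads.

    The adapter is removed at the first exact occurrence of its first 8 nt
    (or of the full adapter when shorter than 8).  Reads shorter than
    ``min_len`` after trimming, or containing more than ``max_n`` N bases,
    are discarded.
    """
    key = adapter[:8]
    kept: list[Read] = []
    n_in = n_trimmed = 0
    for read in reads:
        n_in += 1
        seq = read.sequence
        if key:
            pos = seq.find(key)
            if pos >= 0:
                seq = seq[:pos]
                n_trimmed += 1
        if len(seq) < min_len or seq.count("N") > max_n:
            continue
        kept.append(Read(read.read_id, seq, read.sample_id) if seq != read.sequence else read)
    log.info(
        "trim_and_filter: %d reads in, %d adapter-trimmed, %d kept", n_in, n_trimmed, len(kept)
    )
    if n_in and not kept:
        log.warning("trim_and_filter: all %d reads discarded", n_in)
    return kept


def align_read(
    read: Read, index: ReferenceIndex, max_mismatches: int = 2
) -> list[Alignment]:
    """Align one read; returns [] when unmapped (never raises for long reads)."""
    hits = index.align_sequence(read.sequence, max_mismatches)
    if not hits:
        return []
    w = 1.0 / len(hits)
    L = len(read.sequence)
    return [
        Alignment(read.read_id, trna_id, start, start + L, mm, positions, w)
        for trna_id, start, mm, positions in hits
    ]


def align_library(
    reads: Sequence[Read],
    index: ReferenceIndex,
    max_mismatches: int = 2,
) -> tuple[pd.DataFrame, AlignmentSummary]:
    """Align a whole library; returns (alignment table, summary).

    Identical read sequences are aligned once and the placements replicated,
    which makes fragment libraries (many duplicate sequences) cheap.  The
    table has columns read_id, trna_id, start, end, mismatches, weight.
    """
    summary = AlignmentSummary(n_reads=len(reads))
    if not reads:
        log.warning("align_library: empty input library")
        return _empty_table(), summary

    by_seq: dict[str, list[str]] = {}
    for read in reads:
        by_seq.setdefault(read.sequence, []).append(read.read_id)

    cols_read, cols_ref, cols_start, cols_end, cols_mm, cols_w = [], [], [], [], [], []
    for seq, read_ids in by_seq.items():
        hits = index.align_sequence(seq, max_mismatches)
        if not hits:
            continue
        w = 1.0 / len(hits)
        L = len(seq)
        summary.n_mapped += len(read_ids)
        mm_best = hits[0][2]
        summary.mismatch_histogram[mm_best] = (
            summary.mismatch_histogram.get(mm_best, 0) + len(read_ids)
        )
        for trna_id, start, mm, _ in hits:
            cols_read.extend(read_ids)
            cols_ref.extend([trna_id] * len(read_ids))
            cols_start.extend([start] * len(read_ids))
            cols_end.extend([start + L] * len(read_ids))
            cols_mm.extend([mm] * len(read_ids))
            cols_w.extend([w] * len(read_ids))

    table = pd.DataFrame(
        {
            "read_id": cols_read,
            "trna_id": cols_ref,
            "start": np.asarray(cols_start, dtype=np.int64),
            "end": np.asarray(cols_end, dtype=np.int64),
            "mismatches": np.asarray(cols_mm, dtype=np.int64),
            "weight": np.asarray(cols_w, dtype=float),
        }
    )
    if len(table):
        summary.per_reference_weight = (
            table.groupby("trna_id")["weight"].sum().to_dict()
        )
    return table, summary


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "trna_id": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "mismatches": pd.Series(dtype=np.int64),
            "weight": pd.Series(dtype=float),
        }
    )


def read_fastx(path: str | Path, sample_id: str = "") -> list[Read]:
    """Load a FASTQ or FASTA file (sniffed from the first byte) as Reads."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [
        Read(rec.id, str(rec.seq).upper(), sample_id)
        for rec in SeqIO.parse(str(path), fmt)
    ]


def write_alignment_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_sam(
    table: pd.DataFrame,
    records: Sequence[TRNARecord],
    reads: Sequence[Read],
    path: str | Path,
) -> None:
    """Export alignments as SAM with the tRNA set as reference sequences."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rec.id, "LN": len(rec)} for rec in records],
    }
    tid = {rec.id: i for i, rec in enumerate(records)}
    seq_of = {read.read_id: read.sequence for read in reads}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in table.itertuples(index=False):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = row.read_id
            seg.query_sequence = seq_of.get(row.read_id, "")
            seg.reference_id = tid[row.trna_id]
            seg.reference_start = int(row.start)
            length = int(row.end - row.start)
            seg.cigarstring = f"{length}M"
            seg.mapping_quality = 255
            seg.flag = 0  # multimappers all written as primary; fractional weight in XW
            seg.set_tag("NM", int(row.mismatches))
            seg.set_tag("XW", float(row.weight))
            out.write(seg)
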