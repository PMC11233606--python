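"""Ribo-Seq downstream analysis.

Covers the desk-scale core of a ribosome-profiling workflow: A-site offset
calibration from start-codon metagene signal, per-codon A-site and A+1-site
occupancy, gene-level translation efficiency TE = RPF density / RNA density,
and differential TE between conditions (Welch t on replicate log2 TE with
Benjamini-Hochberg FDR; 1.5-fold and FDR < 0.05 define TE-Up / TE-Down).

Counting operates on one canonical transcript per gene (longest CDS when
loading from files) to avoid isoform double-counting.  The first and last
annotated codons are excluded everywhere so that occupancy reflects
elongation, not initiation or termination peaks.

RPF alignments are plain tables with columns ``transcript_id``, ``start``
(0-based 5' end on the transcript) and ``length``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
OFFSET_MIN, OFFSET_MAX = 10, 16
RPF_MIN_LEN, RPF_MAX_LEN = 25, 35
DEFAULT_OFFSET = 12

TE_UP = "TE-Up"
TE_DOWN = "TE-Down"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's canonical transcript: CDS sequence plus its position."""

    gene_id: str
    transcript_id: str
    cds_sequence: str
    cds_start_in_transcript: int

    def __post_init__(self) -> None:
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    @property
    def codons(self) -> list[str]:
        s = self.cds_sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


def validate_model(model: TranscriptModel, require_start: bool = True) -> None:
    """Check start/stop invariants (CDS frame is enforced at construction)."""
    if require_start and not model.cds_sequence.startswith("ATG"):
        raise ValueError(f"{model.gene_id}: CDS does not start with ATG")
    if model.cds_sequence[-3:] not in STOP_CODONS:
        raise ValueError(f"{model.gene_id}: CDS does not end with a stop codon")


@dataclass
class ASiteOffsets:
    """Read-length -> P-site offset map (nt from read 5' end to P-site)."""

    offsets: dict[int, int] = field(default_factory=dict)
    default: int = DEFAULT_OFFSET

    def offset(self, length: int) -> int:
        return self.offsets.get(int(length), self.default)


def load_transcript_models(
    cds_fasta: str | Path, table_tsv: str | Path, require_start: bool = True
) -> list[TranscriptModel]:
    """Load models from a CDS FASTA plus a gene table.

    Table columns: gene_id, transcript_id, cds_start (0-based position of the
    CDS in the transcript).  When a gene appears with several transcripts the
    one with the longest CDS is kept.
    """
    seqs = {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    table = pd.read_csv(table_tsv, sep="\t")
    models: dict[str, TranscriptModel] = {}
    for row in table.itertuples(index=False):
        if row.transcript_id not in seqs:
            log.warning("transcript %s missing from CDS FASTA; skipped", row.transcript_id)
            continue
        model = TranscriptModel(
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            cds_sequence=seqs[row.transcript_id],
            cds_start_in_transcript=int(row.cds_start),
        )
        validate_model(model, require_start=require_start)
        prev = models.get(model.gene_id)
        if prev is None or model.n_codons > prev.n_codons:
            models[model.gene_id] = model
    return list(models.values())


def write_transcript_models(
    models: Sequence[TranscriptModel], cds_fasta: str | Path, table_tsv: str | Path
) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(m.cds_sequence), id=m.transcript_id, description="") for m in models],
        str(cds_fasta),
        "fasta",
    )
    pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "transcript_id": [m.transcript_id for m in models],
            "cds_start": [m.cds_start_in_transcript for m in models],
        }
    ).to_csv(table_tsv, sep="\t", index=False)


def calibrate_offsets(
    alignments: pd.DataFrame,
    models: Sequence[TranscriptModel],
    min_reads_per_length: int = 50,
    min_start_reads: int = 500,
) -> ASiteOffsets:
    """Calibrate per-length P-site offsets from start-codon-overlapping reads.

    For reads spanning the annotated start codon, the distance from the read
    5' end to the start codon clusters at the true offset (initiating
    ribosomes pause with the start codon in the P site).  The per-length
    offset is the mode of that distance, clamped to [10, 16]; lengths with
    fewer than ``min_reads_per_length`` such reads inherit the global mode,
    and when calibration is impossible every length falls back to 12.
    """
    start_of = {m.transcript_id: m.cds_start_in_transcript for m in models}
    result = ASiteOffsets()
    if not len(alignments):
        log.warning("calibrate_offsets: no alignments; using default offset %d", DEFAULT_OFFSET)
        return result
    cds_start = alignments["transcript_id"].map(start_of)
    starts = alignments["start"].to_numpy(dtype=float)
    lengths = alignments["length"].to_numpy(dtype=int)
    span = (
        cds_start.notna().to_numpy()
        & (starts <= cds_start.to_numpy(dtype=float))
        & (starts + lengths >= cds_start.to_numpy(dtype=float) + 3)
    )
    diffs = (cds_start.to_numpy(dtype=float) - starts)[span]
    lens = lengths[span]
    if len(diffs) < min_start_reads:
        log.warning(
            "calibrate_offsets: only %d start-overlapping reads (<%d); using defaults",
            len(diffs), min_start_reads,
        )
        return result

    def _mode(values: np.ndarray) -> int:
        uniq, cnt = np.unique(values.astype(int), return_counts=True)
        return int(uniq[np.argmax(cnt)])

    global_mode = int(np.clip(_mode(diffs), OFFSET_MIN, OFFSET_MAX))
    for L in range(RPF_MIN_LEN, RPF_MAX_LEN + 1):
        sel = lens == L
        if sel.sum() >= min_reads_per_length:
            result.offsets[L] = int(np.clip(_mode(diffs[sel]), OFFSET_MIN, OFFSET_MAX))
        else:
            result.offsets[L] = global_mode
    result.default = global_mode
    return result


def assign_a_sites(
    alignments: pd.DataFrame,
    offsets: ASiteOffsets,
    models: Sequence[TranscriptModel],
) -> tuple[dict[str, np.ndarray], int]:
    """Map RPF 5' ends to A-site codon counts per gene.

    The A-site codon index is floor((read5' + offset - cds_start)/3) + 1
    (one codon downstream of the P site).  Reads whose A site falls on the
    first or last annotated codon, or outside the CDS, are discarded; reads
    on transcripts without a model are skipped and counted.

    Returns ({gene_id: codon count vector}, n_skipped_reads).
    """
    by_tx = {m.transcript_id: m for m in models}
    counts = {m.gene_id: np.zeros(m.n_codons) for m in models}
    skipped = 0
    if not len(alignments):
        return counts, 0
    for tx_id, sub in alignments.groupby("transcript_id", sort=False):
        model = by_tx.get(tx_id)
        if model is None:
            skipped += len(sub)
            continue
        off = np.array([offsets.offset(l) for l in sub["length"].to_numpy()])
        a = (sub["start"].to_numpy() + off - model.cds_start_in_transcript) // 3 + 1
        good = (a >= 1) & (a <= model.n_codons - 2)
        skipped += int((~good).sum())
        np.add.at(counts[model.gene_id], a[good].astype(int), 1.0)
    return counts, skipped


def codon_occupancy(
    gene_codon_counts: Mapping[str, np.ndarray],
    models: Sequence[TranscriptModel],
    min_gene_reads: float = 64,
) -> pd.DataFrame:
    """Per-codon A-site and A+1-site occupancy across genes.

    Within each gene (restricted to codons 1..n-2) the count vector is
    normalised by its own mean, making genes of different depth comparable;
    the occupancy of a codon is the mean normalised density over all its
    instances in all genes passing ``min_gene_reads``.  For the A+1 site the
    same is done one codon downstream of each instance.  By construction the
    instance-weighted mean A-site occupancy over all codons is exactly 1.

    Returns a DataFrame indexed by codon with columns ``occ_A``, ``occ_A1``
    and ``n_instances``.  Raises ``ValueError`` when no gene passes.
    """
    by_gene = {m.gene_id: m for m in models}
    acc_a: dict[str, list[float]] = {}
    acc_a1: dict[str, list[float]] = {}
    n_used = 0
    for gene_id, counts in gene_codon_counts.items():
        model = by_gene.get(gene_id)
        if model is None:
            continue
        inner = counts[1 : model.n_codons - 1]
        total = inner.sum()
        if total < min_gene_reads or len(inner) == 0:
            continue
        n_used += 1
        norm = inner / inner.mean()
        codons = model.codons[1 : model.n_codons - 1]
        for j, codon in enumerate(codons):
            acc_a.setdefault(codon, []).append(norm[j])
            if j + 1 < len(norm):
                acc_a1.setdefault(codon, []).append(norm[j + 1])
    if n_used == 0:
        raise ValueError(f"no gene passes min_gene_reads={min_gene_reads}")
    codons = sorted(acc_a)
    table = pd.DataFrame(
        {
            "occ_A": [float(np.mean(acc_a[c])) for c in codons],
            "occ_A1": [float(np.mean(acc_a1[c])) if c in acc_a1 else np.nan for c in codons],
            "n_instances": [len(acc_a[c]) for c in codons],
        },
        index=pd.Index(codons, name="codon"),
    )
    return table


def compute_te(
    rpf_counts: pd.Series,
    rna_counts: pd.Series,
    models: Sequence[TranscriptModel],
    min_rna: float = 10,
) -> pd.DataFrame:
    """Gene-level TE = RPF density / RNA density (densities are CPM per CDS kb).

    TE is masked (NaN) for genes with fewer than ``min_rna`` RNA counts.
    """
    kb = pd.Series({m.gene_id: m.n_codons * 3 / 1000.0 for m in models})
    genes = kb.index.intersection(rpf_counts.index).intersection(rna_counts.index)
    rpf = rpf_counts.loc[genes].astype(float)
    rna = rna_counts.loc[genes].astype(float)
    kb = kb.loc[genes]
    rpf_density = rpf / max(rpf.sum(), 1.0) * 1e6 / kb
    rna_density = rna / max(rna.sum(), 1.0) * 1e6 / kb
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(rna >= min_rna, rpf_density / rna_density, np.nan)
    return pd.DataFrame(
        {"rpf_count": rpf, "rna_count": rna, "te": te}, index=genes
    ).rename_axis("gene_id")


def _replicate_log2_te(
    rpf: pd.DataFrame, rna: pd.DataFrame, kb: pd.Series, pseudocount: float
) -> np.ndarray:
    rpf_m = rpf.to_numpy(dtype=float) + pseudocount
    rna_m = rna.to_numpy(dtype=float) + pseudocount
    rpf_d = rpf_m / rpf_m.sum(axis=0, keepdims=True) / kb.to_numpy()[:, None]
    rna_d = rna_m / rna_m.sum(axis=0, keepdims=True) / kb.to_numpy()[:, None]
    return np.log2(rpf_d / rna_d)


def differential_te(
    rpf_a: pd.DataFrame,
    rna_a: pd.DataFrame,
    rpf_b: pd.DataFrame,
    rna_b: pd.DataFrame,
    models: Sequence[TranscriptModel],
    fold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    min_rna: float = 10,
) -> pd.DataFrame:
    """Differential translation efficiency of condition B versus A.

    Inputs are gene x replicate raw count tables (RPF and RNA for each
    condition; replicate columns pair RPF and RNA libraries from the same
    sample).  Per replicate, log2 TE is computed with a pseudocount; the
    test is a two-sided Welch t across replicates, BH-adjusted.  TE-Up means
    log2fc >= log2(fold) with fdr < alpha; TE-Down symmetric.  Genes whose
    mean RNA count falls below ``min_rna`` in either condition are reported
    untested (NaN statistics, class "unchanged").

    With a single replicate in either condition, fold changes are reported
    with empty p/fdr and classes are decided on fold change alone.
    """
    genes = rpf_a.index
    for tab in (rna_a, rpf_b, rna_b):
        genes = genes.intersection(tab.index)
    kb = pd.Series({m.gene_id: m.n_codons * 3 / 1000.0 for m in models}).reindex(genes)
    if kb.isna().any():
        missing = kb.index[kb.isna()][:3].tolist()
        raise ValueError(f"genes without transcript model, e.g. {missing}")
    rpf_a, rna_a = rpf_a.loc[genes], rna_a.loc[genes]
    rpf_b, rna_b = rpf_b.loc[genes], rna_b.loc[genes]

    la = _replicate_log2_te(rpf_a, rna_a, kb, pseudocount)
    lb = _replicate_log2_te(rpf_b, rna_b, kb, pseudocount)
    log2fc = lb.mean(axis=1) - la.mean(axis=1)

    tested = (
        (rna_a.mean(axis=1).to_numpy() >= min_rna)
        & (rna_b.mean(axis=1).to_numpy() >= min_rna)
    )
    replicated = la.shape[1] >= 2 and lb.shape[1] >= 2
    if replicated:
        _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        fdr = np.full_like(p, np.nan)
        if tested.any():
            _, fdr_t, _, _ = multipletests(p[tested], method="fdr_bh")
            fdr[tested] = fdr_t
        sig = tested & (fdr < alpha)
    else:
        log.warning("differential_te: unreplicated input; fold-change-only mode")
        p = np.full(len(genes), np.nan)
        fdr = np.full(len(genes), np.nan)
        sig = tested

    thresh = np.log2(fold)
    te_class = np.where(
        sig & (log2fc >= thresh), TE_UP, np.where(sig & (log2fc <= -thresh), TE_DOWN, UNCHANGED)
    )
    result = pd.DataFrame(
        {
            "log2fc_te": log2fc,
            "p": p,
            "fdr": fdr,
            "te_class": te_class,
            "tested": tested,
        },
        index=genes,
    )
    result.index.name = "gene_id"
    return result
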