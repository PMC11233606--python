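"""Synthetic sequencing data with ground truth.

Three generators emulate the study designs end to end so every pipeline
stage is testable without downloads:

* :func:`simulate_hac_experiment` - chemically-cleaved small-RNA libraries.
  Each tRNA molecule is cleaved independently at its configured sites with
  the genotype's probability p (treated samples) or a small background b
  (untreated controls); a cleavage at site i yields a downstream fragment
  starting at i+1.  Fragments shorter than the size-selection cutoff are
  lost.  A-to-I editing at position 34 is emitted as an A->G substitution on
  a configurable fraction of molecules.  Reverse transcription is modelled
  as full read-through (the protocol demethylates RT-blocking marks before
  library prep), so fragment 5' ends are the only modification signal.

* :func:`simulate_ribo_experiment` - ribosome footprints plus matched RNA
  counts.  Per replicate, gene abundance gets a shared biological noise draw
  (gamma, squared CV = ``dispersion``) that propagates to both the RPF and
  the RNA library of that replicate (both derive from one lysate); RPF
  totals scale with abundance x TE x CDS length and footprint positions are
  sampled proportional to per-codon dwell multipliers, with an initiation
  pause at the first elongation codon that also anchors offset calibration.

* :func:`simulate_cds_set` - coding sequences sampled codon-by-codon, with
  per-group synonymous-codon weight multipliers (enrichment factors applied
  within each amino-acid family so amino-acid composition is preserved).

Identical configuration + seed gives byte-identical output; every nonzero
cleavage probability, non-unit dwell multiplier, and non-unit TE effect is
recorded in the returned :class:`SimTruth`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Read
from .cleavage import INDEPENDENT, METTL2_DEPENDENT, METTL6_DEPENDENT, REDUNDANT
from .reference import TRNARecord, assign_canonical_positions
from .ribo import TranscriptModel

log = logging.getLogger(__name__)

GENOTYPES = ("WT", "M2KO", "M6KO", "M2_6KO")
CONDITIONS = ("ctrl", "HAC")


# --------------------------------------------------------------------------- HAC


@dataclass
class HacSimConfig:
    """Design of a simulated cleavage-sequencing experiment.

    ``site_probs[genotype][(trna_id, index)]`` is the per-molecule cleavage
    probability at that site in treated samples of that genotype; untreated
    controls use ``ctrl_background`` at the same positions.
    """

    references: list[TRNARecord]
    site_probs: dict[str, dict[tuple[str, int], float]]
    ctrl_background: float = 0.005
    molecules_per_trna: int = 5000
    editing_fraction: dict[str, float] = field(default_factory=dict)
    min_fragment_len: int = 15
    error_rate: float = 0.0
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ctrl_background <= 0.05):
            raise ValueError("ctrl_background must be in [0, 0.05]")
        if self.molecules_per_trna < 1:
            raise ValueError("molecules_per_trna must be >= 1")
        lengths = {rec.id: len(rec) for rec in self.references}
        for geno, probs in self.site_probs.items():
            for (trna_id, idx), p in probs.items():
                if trna_id not in lengths:
                    raise ValueError(f"site on unknown reference {trna_id!r}")
                if not 0 <= idx <= lengths[trna_id] - 2:
                    raise ValueError(
                        f"site index {idx} out of range for {trna_id} "
                        f"(cleavable positions are 0..{lengths[trna_id] - 2})"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"cleavage probability {p} outside [0, 1]")

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.site_probs.keys())

    def sample_ids(self) -> list[str]:
        return [
            f"{geno}_{cond}_rep{rep}"
            for geno in self.genotypes
            for cond in CONDITIONS
            for rep in range(1, self.replicates + 1)
        ]


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    cleavage_probs: pd.DataFrame | None = None
    dwell: pd.DataFrame | None = None
    te: pd.DataFrame | None = None
    expected_classes: dict[tuple[str, int], str] | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)


class HacSimResult:
    """Lazy per-sample read access for a simulated cleavage experiment.

    Reads for each sample are generated deterministically from the config
    seed and the sample's position in the design, independent of call order.
    """

    def __init__(self, config: HacSimConfig):
        self.config = config
        self.sample_ids = config.sample_ids()
        self.truth = _hac_truth(config)
        self.sample_sheet = pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "file": f"{sid}.fastq",
                    "condition": sid.split("_rep")[0].rsplit("_", 1)[1],
                    "genotype": sid.split("_rep")[0].rsplit("_", 1)[0],
                    "replicate": int(sid.rsplit("rep", 1)[1]),
                }
                for sid in self.sample_ids
            ]
        )

    def reads(self, sample_id: str) -> list[Read]:
        if sample_id not in self.sample_ids:
            raise KeyError(sample_id)
        return _simulate_hac_sample(self.config, sample_id, self.sample_ids.index(sample_id))


def simulate_hac_experiment(config: HacSimConfig) -> HacSimResult:
    """Simulate the full genotype x condition x replicate design."""
    return HacSimResult(config)


def _hac_truth(config: HacSimConfig) -> SimTruth:
    rows = [
        {"genotype": geno, "trna_id": trna_id, "index": idx, "p": p}
        for geno, probs in config.site_probs.items()
        for (trna_id, idx), p in probs.items()
    ]
    return SimTruth(
        cleavage_probs=pd.DataFrame(rows),
        seed=config.seed,
        extras={
            "ctrl_background": config.ctrl_background,
            "molecules_per_trna": config.molecules_per_trna,
            "min_fragment_len": config.min_fragment_len,
        },
    )


def _simulate_hac_sample(config: HacSimConfig, sample_id: str, sample_index: int) -> list[Read]:
    # sample ids look like "<genotype>_<condition>_rep<n>"; genotype may itself
    # contain underscores (M2_6KO), so split from the right
    geno, cond = sample_id.split("_rep")[0].rsplit("_", 1)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(sample_index,)))
    site_map = config.site_probs[geno]
    reads: list[Read] = []
    for rec in config.references:
        sites = sorted(idx for (tid, idx) in site_map if tid == rec.id)
        probs = [
            site_map[(rec.id, idx)] if cond == "HAC" else config.ctrl_background
            for idx in sites
        ]
        reads.extend(
            _simulate_molecules(rec, sites, probs, config, rng, sample_id)
        )
    return reads


def _fragments(length: int, cut_sites: Sequence[int]) -> list[tuple[int, int]]:
    """Partition [0, length) at cleavage sites: a cut at i separates i | i+1."""
    bounds = [0] + [i + 1 for i in sorted(cut_sites)] + [length]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def _simulate_molecules(
    rec: TRNARecord,
    sites: list[int],
    probs: list[float],
    config: HacSimConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> list[Read]:
    N = config.molecules_per_trna
    L = len(rec)
    edit_frac = config.editing_fraction.get(rec.id, 0.0)
    pos34 = rec.anticodon_start
    can_edit = (
        edit_frac > 0 and pos34 is not None and rec.sequence[pos34] == "A"
    )

    # Cleavage events are independent per molecule, so molecule counts per
    # cleavage pattern are multinomial - enumerate the 2^k patterns directly.
    k = len(sites)
    if k > 16:
        raise ValueError(f"{rec.id}: too many sites ({k}) for pattern enumeration")
    patterns = list(itertools.product((False, True), repeat=k))
    p_arr = np.asarray(probs)
    pattern_probs = [
        float(np.prod(np.where(np.asarray(pat), p_arr, 1 - p_arr))) if k else 1.0
        for pat in patterns
    ]
    counts = rng.multinomial(N, pattern_probs)

    reads: list[Read] = []
    serial = 0
    for pat, count in zip(patterns, counts):
        if count == 0:
            continue
        cut = [s for s, c in zip(sites, pat) if c]
        frags = [
            (a, b)
            for a, b in _fragments(L, cut)
            if b - a >= config.min_fragment_len
        ]
        n_edited = rng.binomial(count, edit_frac) if can_edit else 0
        for variant, n_var in (("e", n_edited), ("u", count - n_edited)):
            if n_var == 0:
                continue
            for a, b in frags:
                frag_seq = rec.sequence[a:b]
                if variant == "e" and a <= pos34 < b:
                    j = pos34 - a
                    frag_seq = frag_seq[:j] + "G" + frag_seq[j + 1 :]
                if config.error_rate > 0:
                    for m in range(n_var):
                        seq = _apply_errors(frag_seq, config.error_rate, rng)
                        reads.append(
                            Read(f"{sample_id}|{rec.id}|{serial}", seq, sample_id)
                        )
                        serial += 1
                else:
                    for m in range(n_var):
                        reads.append(
                            Read(f"{sample_id}|{rec.id}|{serial}", frag_seq, sample_id)
                        )
                        serial += 1
    return reads


_BASES = "ACGT"


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    """Write reads as FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


# ---------------------------------------------------------------- preset design


_PRESET_REFERENCE_SEED = 20230201  # fixed: reference sequences are the "genome"

_PRESET_LAYOUT: list[tuple[str, str, str, int]] = [
    # (name, amino acid, anticodon, length)
    ("tRNA-Arg-CCT-1-1", "Arg", "CCT", 76),
    ("tRNA-Arg-TCT-1-1", "Arg", "TCT", 76),
    ("tRNA-Thr-AGT-1-1", "Thr", "AGT", 76),
    ("tRNA-Thr-CGT-1-1", "Thr", "CGT", 76),
    ("tRNA-Thr-CGT-2-1", "Thr", "CGT", 76),
    ("tRNA-Thr-CGT-3-1", "Thr", "CGT", 76),
    ("tRNA-Thr-CGT-4-1", "Thr", "CGT", 76),
    ("tRNA-Thr-TGT-1-1", "Thr", "TGT", 76),
    ("tRNA-Ser-AGA-1-1", "Ser", "AGA", 85),
    ("tRNA-Ser-CGA-1-1", "Ser", "CGA", 85),
    ("tRNA-Ser-TGA-1-1", "Ser", "TGA", 85),
    ("tRNA-Ser-GCT-1-1", "Ser", "GCT", 85),
    ("tRNA-Ser-GCT-2-1", "Ser", "GCT", 85),  # identical sequence to GCT-1-1
    ("tRNA-Leu-CAG-1-1", "Leu", "CAG", 85),
    ("tRNA-Met-CAT-1-1", "Met", "CAT", 76),
]

#: linear index used for the variable-arm C47d on the 85-nt type II bodies
_C47D_INDEX = 60
#: linear index used for the D-loop C20 on tRNA-Met-CAT
_C20_INDEX = 19

# residual high cleavage in METTL2 knockouts persists on these isodecoders
_RESIDUAL_THR = ("tRNA-Thr-CGT-2-1", "tRNA-Thr-CGT-4-1")


def _make_preset_sequence(
    aa: str, anticodon: str, length: int, rng: np.random.Generator,
    extra_c: Sequence[int] = (),
) -> str:
    """Random tRNA-like body with fixed anticodon-loop context and CCA tail."""
    ac_start = int(round(0.34 * length))
    for _attempt in range(200):
        seq = rng.choice(list(_BASES), size=length)
        seq[ac_start - 2] = "C"  # position 32
        seq[ac_start - 1] = "T"  # universal U33
        seq[ac_start : ac_start + 3] = list(anticodon)
        seq[ac_start + 3] = "A"  # hypermodified purine 37
        seq[ac_start + 4] = "A"  # position 38 (pairs with 32)
        for idx in extra_c:
            seq[idx] = "C"
        seq[-3:] = list("CCA")
        s = "".join(seq)
        # the anticodon must anchor uniquely at the intended position
        occurrences = [i for i in range(length - 2) if s[i : i + 3] == anticodon]
        if occurrences == [ac_start]:
            return s
    raise RuntimeError("could not place anticodon uniquely")  # pragma: no cover


def paper_pattern_references() -> tuple[list[TRNARecord], dict[str, dict[int, str]]]:
    """The bundled reference set and its canonical-label override table."""
    rng = np.random.default_rng(_PRESET_REFERENCE_SEED)
    records: list[TRNARecord] = []
    override: dict[str, dict[int, str]] = {}
    gct_seq: str | None = None
    for name, aa, anticodon, length in _PRESET_LAYOUT:
        extra = []
        if aa in ("Ser", "Leu"):
            extra.append(_C47D_INDEX)
            override[name] = {_C47D_INDEX: "47d"}
        if name == "tRNA-Met-CAT-1-1":
            extra.append(_C20_INDEX)
            override[name] = {_C20_INDEX: "20"}
        if name == "tRNA-Ser-GCT-2-1":
            seq = gct_seq  # identical isodecoder pair
        else:
            seq = _make_preset_sequence(aa, anticodon, length, rng, extra)
        if name == "tRNA-Ser-GCT-1-1":
            gct_seq = seq
        rec = TRNARecord(id=name, amino_acid=aa, anticodon=anticodon, sequence=seq)
        records.append(assign_canonical_positions(rec, override))
    return records, override


def paper_pattern_config(
    seed: int = 0,
    molecules_per_trna: int = 5000,
    replicates: int = 2,
) -> tuple[HacSimConfig, SimTruth]:
    """The four-genotype study-design preset with its expected dependence map.

    Treated-sample cleavage probabilities encode the study pattern: C32 of
    all cytoplasmic Ser/Thr/Arg(CCT,TCT) tRNAs near saturation (0.97) in WT;
    METTL2 knockout ablates Arg/Thr C32 (0.02) except a ~0.80 residual on
    Thr-CGT-2-1/4-1; METTL6 knockout drops Ser-A36 C32 to 0.30 and Ser-GCT
    only slightly (0.85); the triple knockout ablates all C32 except the
    Thr-CGT residuals; variable-arm C47d and D-loop C20 sites stay at 0.90
    in every genotype.
    """
    records, override = paper_pattern_references()
    by_id = {rec.id: rec for rec in records}

    c32: dict[str, int] = {}
    for rec in records:
        if rec.amino_acid in ("Arg", "Thr", "Ser"):
            c32[rec.id] = rec.anticodon_start - 2

    site_probs: dict[str, dict[tuple[str, int], float]] = {g: {} for g in GENOTYPES}
    expected: dict[tuple[str, int], str] = {}

    for trna_id, idx in c32.items():
        rec = by_id[trna_id]
        wt = 0.97
        if rec.amino_acid in ("Arg", "Thr"):
            lost = 0.80 if trna_id in _RESIDUAL_THR else 0.02
            probs = {"WT": wt, "M2KO": lost, "M6KO": wt, "M2_6KO": lost}
            expected[(trna_id, idx)] = (
                INDEPENDENT if trna_id in _RESIDUAL_THR else METTL2_DEPENDENT
            )
        elif rec.anticodon == "GCT":
            probs = {"WT": wt, "M2KO": wt, "M6KO": 0.85, "M2_6KO": 0.02}
            expected[(trna_id, idx)] = REDUNDANT
        else:  # Ser with A36
            probs = {"WT": wt, "M2KO": wt, "M6KO": 0.30, "M2_6KO": 0.02}
            expected[(trna_id, idx)] = METTL6_DEPENDENT
        for geno, p in probs.items():
            site_probs[geno][(trna_id, idx)] = p

    for rec in records:
        if rec.amino_acid in ("Ser", "Leu"):
            for geno in GENOTYPES:
                site_probs[geno][(rec.id, _C47D_INDEX)] = 0.90
            expected[(rec.id, _C47D_INDEX)] = INDEPENDENT
    for geno in GENOTYPES:
        site_probs[geno][("tRNA-Met-CAT-1-1", _C20_INDEX)] = 0.90
    expected[("tRNA-Met-CAT-1-1", _C20_INDEX)] = INDEPENDENT

    editing = {
        rec.id: 0.25
        for rec in records
        if rec.anticodon_start is not None and rec.sequence[rec.anticodon_start] == "A"
    }

    config = HacSimConfig(
        references=records,
        site_probs=site_probs,
        molecules_per_trna=molecules_per_trna,
        editing_fraction=editing,
        replicates=replicates,
        seed=seed,
    )
    truth = _hac_truth(config)
    truth.expected_classes = expected
    truth.extras["override"] = override
    return config, truth


# --------------------------------------------------------------------------- Ribo


def default_offset_map() -> dict[int, int]:
    """Per-length P-site offsets used by the simulator (28 nt -> 12)."""
    return {L: 11 + (L - 25) // 2 for L in range(RPF_MIN_LEN_SIM, RPF_MAX_LEN_SIM + 1)}


RPF_MIN_LEN_SIM, RPF_MAX_LEN_SIM = 25, 35


@dataclass
class RiboSimConfig:
    """Design of a simulated ribosome-profiling experiment."""

    models: list[TranscriptModel]
    dwell: dict[str, float] = field(default_factory=dict)
    te: dict[str, float] = field(default_factory=dict)
    mrna_abundance: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    rpf_length_probs: dict[int, float] = field(default_factory=lambda: {28: 1.0})
    offsets: dict[int, int] = field(default_factory=default_offset_map)
    n_rpf_reads: int = 200_000
    n_rna_reads: int = 200_000
    replicates: int = 3
    start_boost: float = 2.0
    min_codons: int = 10
    emit_alignments: bool = True  # False: gene-level counts only (fast TE designs)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.dwell.values()):
            raise ValueError("dwell multipliers must be positive")
        if any(v <= 0 for v in self.te.values()):
            raise ValueError("TE multipliers must be positive")


@dataclass
class RiboSimResult:
    rna_counts: pd.DataFrame  # gene x replicate
    rpf_gene_counts: pd.DataFrame  # gene x replicate
    rpf_alignments: dict[int, pd.DataFrame]  # replicate -> alignment table
    truth: SimTruth


def simulate_ribo_experiment(config: RiboSimConfig) -> RiboSimResult:
    """Simulate matched RPF and RNA libraries for one condition."""
    models = [m for m in config.models if m.n_codons >= config.min_codons]
    dropped = len(config.models) - len(models)
    if dropped:
        log.warning("%d gene(s) with CDS < %d codons excluded", dropped, config.min_codons)
    genes = [m.gene_id for m in models]
    abundance = np.array([config.mrna_abundance.get(g, 100.0) for g in genes])
    te = np.array([config.te.get(g, 1.0) for g in genes])
    kb = np.array([m.n_codons * 3 / 1000.0 for m in models])

    # per-gene position weights over elongation codons 1..n-2
    pos_weights = []
    for m in models:
        w = np.array([config.dwell.get(c, 1.0) for c in m.codons[1 : m.n_codons - 1]])
        if len(w):
            w[0] *= config.start_boost
        pos_weights.append(w)
    gene_rpf_weight = abundance * te * np.array([w.sum() for w in pos_weights])

    lengths = np.array(sorted(config.rpf_length_probs))
    length_p = np.array([config.rpf_length_probs[L] for L in lengths], dtype=float)
    length_p = length_p / length_p.sum()
    offsets = np.array([config.offsets.get(int(L), 12) for L in lengths])

    rna_cols, rpf_cols, aligns = {}, {}, {}
    for rep in range(1, config.replicates + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1000 + rep,))
        )
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            theta = rng.gamma(shape, scale=1.0 / shape, size=len(genes))
        else:
            theta = np.ones(len(genes))
        lam_rna = abundance * theta * kb
        lam_rna = lam_rna / lam_rna.sum() * config.n_rna_reads
        rna_cols[f"rep{rep}"] = rng.poisson(lam_rna)

        w_rpf = gene_rpf_weight * theta
        gene_counts = rng.multinomial(config.n_rpf_reads, w_rpf / w_rpf.sum())
        rpf_cols[f"rep{rep}"] = gene_counts

        if not config.emit_alignments:
            aligns[rep] = pd.DataFrame(
                {"transcript_id": [], "start": [], "length": []}
            )
            continue
        tx_ids, starts, lens = [], [], []
        for m, w, n in zip(models, pos_weights, gene_counts):
            if n == 0:
                continue
            per_pos = rng.multinomial(n, w / w.sum())
            codon_idx = np.repeat(np.arange(1, m.n_codons - 1), per_pos)
            li = rng.choice(len(lengths), size=n, p=length_p)
            a_nt = m.cds_start_in_transcript + 3 * codon_idx
            starts.append(a_nt - offsets[li] - 3)
            lens.append(lengths[li])
            tx_ids.extend([m.transcript_id] * n)
        aligns[rep] = pd.DataFrame(
            {
                "transcript_id": tx_ids,
                "start": np.concatenate(starts) if starts else np.array([], dtype=int),
                "length": np.concatenate(lens) if lens else np.array([], dtype=int),
            }
        )
        if len(aligns[rep]) and aligns[rep]["start"].min() < 0:
            raise ValueError(
                "negative read start: transcript 5' UTR shorter than offset + 3"
            )

    idx = pd.Index(genes, name="gene_id")
    truth = SimTruth(
        dwell=pd.DataFrame(
            {"codon": list(config.dwell), "multiplier": list(config.dwell.values())}
        ),
        te=pd.DataFrame({"gene_id": list(config.te), "multiplier": list(config.te.values())}),
        seed=config.seed,
        extras={"dispersion": config.dispersion, "start_boost": config.start_boost},
    )
    return RiboSimResult(
        rna_counts=pd.DataFrame(rna_cols, index=idx),
        rpf_gene_counts=pd.DataFrame(rpf_cols, index=idx),
        rpf_alignments=aligns,
        truth=truth,
    )


# ---------------------------------------------------------------------------- CDS


@dataclass
class CdsSimConfig:
    """Design of a synthetic coding-sequence set.

    ``group_multipliers`` maps group name -> {codon: enrichment factor}; the
    factor scales that codon's weight and the rest of its synonymous family
    is rescaled so the family total (amino-acid composition) is unchanged.
    """

    genes_per_group: dict[str, int]
    group_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_codons: int = 150
    sd_codons: int = 30
    min_codons: int = 50
    cds_start: int = 30
    seed: int = 0


_CODON_TABLE: dict[str, str] = {}


def _codon_to_aa() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
    return _CODON_TABLE


def _group_distribution(multipliers: Mapping[str, float]) -> np.ndarray:
    """Sense-codon distribution: uniform base, multipliers applied within family."""
    from .codon import SENSE_CODONS

    aa_of = _codon_to_aa()
    weights = pd.Series(1.0, index=list(SENSE_CODONS))
    for codon, mult in multipliers.items():
        if codon not in weights.index:
            raise ValueError(f"unknown sense codon {codon!r}")
        family = [c for c in weights.index if aa_of[c] == aa_of[codon]]
        fam_total = weights[family].sum()
        new_val = weights[codon] * mult
        others = [c for c in family if c != codon]
        if new_val >= fam_total and others:
            raise ValueError(f"multiplier {mult} for {codon} exceeds its family budget")
        if others:
            scale = (fam_total - new_val) / (fam_total - weights[codon])
            weights[others] *= scale
        weights[codon] = new_val
    dist = weights.to_numpy() / weights.sum()
    return dist


def simulate_cds_set(config: CdsSimConfig) -> tuple[list[TranscriptModel], SimTruth]:
    """Sample coding sequences codon-by-codon per group distribution."""
    from .codon import SENSE_CODONS

    rng = np.random.default_rng(config.seed)
    models: list[TranscriptModel] = []
    dists = {}
    assignment = {}
    for group, n_genes in config.genes_per_group.items():
        dist = _group_distribution(config.group_multipliers.get(group, {}))
        dists[group] = dist
        for i in range(n_genes):
            n_codons = int(
                np.clip(
                    round(rng.normal(config.mean_codons, config.sd_codons)),
                    config.min_codons,
                    None,
                )
            )
            body = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=dist)
            cds = "ATG" + "".join(SENSE_CODONS[j] for j in body) + "TAA"
            gene_id = f"{group}_g{i:04d}"
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t1",
                    cds_sequence=cds,
                    cds_start_in_transcript=config.cds_start,
                )
            )
            assignment[gene_id] = group
    truth = SimTruth(
        seed=config.seed,
        extras={
            "group_of_gene": assignment,
            "distributions": {g: dict(zip(SENSE_CODONS, d)) for g, d in dists.items()},
        },
    )
    return models, truth
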