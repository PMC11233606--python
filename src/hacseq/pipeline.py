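"""End-to-end orchestration of the cleavage-calling and translation pipelines.

These functions tie the library modules together the way the command-line
interface uses them: align -> profiles -> ratios -> calls -> classification
-> exports for the cleavage pipeline, and offsets -> A-sites -> occupancy ->
TE -> differential TE -> codon comparisons for the translation pipeline.
All intermediate tables are written as TSV so runs can be resumed or
inspected without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as al
from . import cleavage as cl
from . import codon as cd
from . import expression as ex
from . import ribo
from .reference import TRNARecord, group_isodecoders, group_of

log = logging.getLogger(__name__)


@dataclass
class Sample:
    """One sequencing library of the cleavage experiment."""

    sample_id: str
    genotype: str
    condition: str  # "ctrl" or "HAC"
    replicate: int
    reads: list[al.Read] = field(default_factory=list)


@dataclass
class HacPipelineResult:
    sites: pd.DataFrame
    calls: list[cl.SiteCall]
    classes: list[cl.DependenceClass]
    tracks: dict[str, dict[str, cl.CleavageTrack]]
    expression: pd.DataFrame | None
    report: dict


def _group_labels(
    records: Sequence[TRNARecord],
) -> tuple[dict[str, tuple[str, ...]], dict[str, int], dict[str, dict[int, str]]]:
    groups = group_isodecoders(records)
    members = {g.group_id: g.member_ids for g in groups}
    lengths = {g.group_id: len(g.sequence) for g in groups}
    by_id = {rec.id: rec for rec in records}
    labels = {
        g.group_id: dict(by_id[g.group_id].canonical_labels) for g in groups
    }
    return members, lengths, labels


def sample_tracks(
    samples: Sequence[Sample],
    records: Sequence[TRNARecord],
    config: cl.CallerConfig,
    max_mismatches: int = 2,
) -> tuple[dict[str, dict[str, cl.CleavageTrack]], dict[str, al.AlignmentSummary],
           dict[str, pd.DataFrame]]:
    """Align each sample and compute per-isodecoder-group cleavage tracks."""
    index = al.ReferenceIndex(records)
    members, lengths, _ = _group_labels(records)
    tracks: dict[str, dict[str, cl.CleavageTrack]] = {}
    summaries: dict[str, al.AlignmentSummary] = {}
    tables: dict[str, pd.DataFrame] = {}
    for sample in samples:
        table, summary = al.align_library(sample.reads, index, max_mismatches)
        summaries[sample.sample_id] = summary
        tables[sample.sample_id] = table
        per_ref = {}
        for group_id, member_ids in members.items():
            profile = cl.compute_site_profile(
                table, group_id, lengths[group_id], sample.sample_id, member_ids
            )
            per_ref[group_id] = cl.cleavage_ratios(profile, config)
        tracks[sample.sample_id] = per_ref
    return tracks, summaries, tables


def run_hac_pipeline(
    samples: Sequence[Sample],
    records: Sequence[TRNARecord],
    config: cl.CallerConfig | None = None,
    outdir: str | Path | None = None,
    with_expression: bool = True,
) -> HacPipelineResult:
    """Full cleavage pipeline on in-memory samples.

    Requires a ctrl and a HAC sample for every genotype/replicate present;
    raises ``ValueError`` otherwise.  When ``outdir`` is given, bedGraph
    tracks, the sites table, the heat-map matrix, and a JSON report are
    written there.
    """
    config = config or cl.CallerConfig()
    design: dict[tuple[str, str], dict[int, Sample]] = {}
    for sample in samples:
        if not sample.reads:
            raise ValueError(f"sample {sample.sample_id} has no reads")
        design.setdefault((sample.genotype, sample.condition), {})[sample.replicate] = sample
    genotypes = sorted({g for g, _ in design})
    for geno in genotypes:
        if (geno, "HAC") not in design or (geno, "ctrl") not in design:
            raise ValueError(f"genotype {geno}: need both ctrl and HAC samples")
        if set(design[(geno, "HAC")]) != set(design[(geno, "ctrl")]):
            raise ValueError(f"genotype {geno}: ctrl/HAC replicate mismatch")

    tracks, summaries, tables = sample_tracks(samples, records, config)
    _, _, labels = _group_labels(records)

    hac_tracks = {
        geno: [tracks[design[(geno, "HAC")][rep].sample_id]
               for rep in sorted(design[(geno, "HAC")])]
        for geno in genotypes
    }
    ctrl_tracks = {
        geno: [tracks[design[(geno, "ctrl")][rep].sample_id]
               for rep in sorted(design[(geno, "ctrl")])]
        for geno in genotypes
    }
    calls = cl.call_sites(hac_tracks, ctrl_tracks, config, labels)
    classes = cl.classify_dependence(calls, config)
    sites = cl.sites_table(calls, classes)

    expression = None
    if with_expression:
        ctrl_samples = [s for s in samples if s.condition == "ctrl"]
        cols = {}
        for sample in ctrl_samples:
            counts = ex.count_expression(
                tables[sample.sample_id], list(records), sample.sample_id
            )
            cols[sample.sample_id] = counts["weighted_count"]
        expression = pd.DataFrame(cols)

    report = {
        "config": asdict(config),
        "n_samples": len(samples),
        "mapped_fraction": {
            sid: summaries[sid].mapped_fraction for sid in summaries
        },
        "n_called_sites": int(sites["is_site"].sum()),
        "classes": {c.site.trna_id + f":{c.site.index}": c.label for c in classes},
    }
    report["config_hash"] = hashlib.sha256(
        json.dumps(report["config"], sort_keys=True).encode()
    ).hexdigest()[:12]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cl.export_bedgraph(tracks, outdir / "tracks")
        sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        cl.export_heatmap_matrix(calls, outdir / "heatmap_matrix.tsv")
        if expression is not None:
            expression.to_csv(outdir / "trna_expression_counts.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)

    return HacPipelineResult(
        sites=sites, calls=calls, classes=classes, tracks=tracks,
        expression=expression, report=report,
    )


@dataclass
class RiboPipelineResult:
    offsets: ribo.ASiteOffsets
    occupancy_a: pd.DataFrame  # per condition means are columns occ_A_<cond>
    te_results: pd.DataFrame
    codon_comparison: pd.DataFrame | None
    codon_scatter: pd.DataFrame | None
    report: dict


def run_ribo_pipeline(
    models: Sequence[ribo.TranscriptModel],
    rpf_alignments: Mapping[str, Mapping[int, pd.DataFrame]],
    rna_counts: Mapping[str, pd.DataFrame],
    conditions: tuple[str, str] = ("WT", "KO"),
    outdir: str | Path | None = None,
    fold: float = 1.5,
    alpha: float = 0.05,
    min_gene_reads: float = 64,
) -> RiboPipelineResult:
    """Translation pipeline: occupancy, TE, differential TE, codon bias.

    ``rpf_alignments[condition][replicate]`` are RPF alignment tables;
    ``rna_counts[condition]`` gene x replicate RNA count tables.  The two
    conditions are compared (second versus first); TE-Up / TE-Down gene
    lists feed the codon-usage comparison automatically.
    """
    cond_a, cond_b = conditions
    for cond in conditions:
        if cond not in rpf_alignments or cond not in rna_counts:
            raise ValueError(f"condition {cond!r} missing from inputs")
        if len(rpf_alignments[cond]) != rna_counts[cond].shape[1]:
            raise ValueError(f"condition {cond!r}: RPF/RNA replicate mismatch")

    # offsets calibrated on the first condition's pooled replicates
    pooled = pd.concat(list(rpf_alignments[cond_a].values()), ignore_index=True)
    offsets = ribo.calibrate_offsets(pooled, models)

    occupancy = {}
    rpf_counts: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    for cond in conditions:
        per_gene_total: dict[str, np.ndarray] = {}
        cols = {}
        n_skip = 0
        for rep, table in sorted(rpf_alignments[cond].items()):
            counts, skip = ribo.assign_a_sites(table, offsets, models)
            n_skip += skip
            cols[f"rep{rep}"] = pd.Series(
                {g: float(v.sum()) for g, v in counts.items()}
            )
            for g, v in counts.items():
                per_gene_total[g] = per_gene_total.get(g, 0) + v
        rpf_counts[cond] = pd.DataFrame(cols).rename_axis("gene_id")
        occupancy[cond] = ribo.codon_occupancy(per_gene_total, models, min_gene_reads)
        skipped[cond] = n_skip

    occ = occupancy[cond_a].join(
        occupancy[cond_b], lsuffix=f"_{cond_a}", rsuffix=f"_{cond_b}"
    )

    te_results = ribo.differential_te(
        rpf_counts[cond_a], rna_counts[cond_a],
        rpf_counts[cond_b], rna_counts[cond_b],
        models, fold=fold, alpha=alpha,
    )

    te_up = te_results.index[te_results["te_class"] == ribo.TE_UP].tolist()
    te_down = te_results.index[te_results["te_class"] == ribo.TE_DOWN].tolist()
    comparison = scatter = None
    if te_up and te_down:
        usage = cd.codon_frequencies(models)
        comparison = cd.compare_codon_usage(te_down, te_up, usage)
        scatter = cd.codon_change_summary(te_down, te_up, usage)

    report = {
        "n_models": len(models),
        "offsets": dict(offsets.offsets),
        "n_te_up": len(te_up),
        "n_te_down": len(te_down),
        "skipped_reads": skipped,
        "fold": fold,
        "alpha": alpha,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        occ.to_csv(outdir / "codon_occupancy.tsv", sep="\t")
        te_results.to_csv(outdir / "te_results.tsv", sep="\t")
        if comparison is not None:
            comparison.to_csv(outdir / "codon_comparison.tsv", sep="\t")
            scatter.to_csv(outdir / "codon_change_scatter.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)

    return RiboPipelineResult(
        offsets=offsets, occupancy_a=occ, te_results=te_results,
        codon_comparison=comparison, codon_scatter=scatter, report=report,
    )
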