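"""Codon usage statistics linking translation-efficiency classes to codon content.

Per-gene codon frequencies (fractions of sense codons, stop codons excluded)
feed three analyses: per-codon two-sided Mann-Whitney comparisons between two
gene sets (exact, tie-aware enumeration for small sets; tie-corrected normal
approximation otherwise) with BH correction across the 61 sense codons;
a codon-frequency-change scatter of one set against another set and against
the global average; and a hypergeometric over-representation test of selected
genes against user-supplied gene sets (GMT style) - no annotation database is
fetched.
"""

from __future__ import annotations

import logging
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ribo import STOP_CODONS, TranscriptModel

log = logging.getLogger(__name__)

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

FREQ_FLOOR = 1e-6  # pseudo-frequency floor keeping log ratios finite
EXACT_MAX_GROUP = 8  # exact Mann-Whitney when min(nA, nB) <= this
EXACT_MAX_COMBINATIONS = 500_000


def codon_frequencies(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Per-gene codon usage vectors (gene x 61 sense codons, rows sum to 1).

    Codons are counted in frame from the CDS start; stop codons are excluded
    from numerator and denominator.  Internal stops trigger a warning but the
    gene is retained.  Duplicate gene ids are counted once (first occurrence).
    """
    rows: dict[str, np.ndarray] = {}
    col_index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for model in models:
        if model.gene_id in rows:
            continue
        counts = np.zeros(len(SENSE_CODONS))
        codons = model.codons
        internal_stops = sum(1 for c in codons[:-1] if c in STOP_CODONS)
        if internal_stops:
            log.warning("%s: %d internal stop codon(s); gene retained", model.gene_id,
                        internal_stops)
        for codon in codons:
            idx = col_index.get(codon)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        rows[model.gene_id] = counts / total if total > 0 else counts
    usage = pd.DataFrame.from_dict(rows, orient="index", columns=list(SENSE_CODONS))
    usage.index.name = "gene_id"
    return usage


def exact_mannwhitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p-value, tie-aware.

    Enumerates the permutation null over group assignments through a dynamic
    program on the multiset of (doubled, hence integral) midranks: the number
    of size-nx subsets attaining each rank sum is counted, and the p-value is
    the null probability of a U statistic at least as far from its mean
    nx*ny/2 as observed.  Exact for any tie pattern.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)  # doubled midranks
    # doubled U = (doubled rank sum) - nx*(nx+1)  [since U = R - nx(nx+1)/2]
    u2_obs = int(ranks2[:nx].sum()) - nx * (nx + 1)
    mu2 = nx * ny  # doubled mean of U
    dev = abs(u2_obs - mu2)

    # DP over items: ways[k][s] = #subsets of size k with doubled-rank sum s
    max_sum = int(ranks2.sum())
    ways = np.zeros((nx + 1, max_sum + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for r in ranks2:
        for k in range(nx, 0, -1):  # descending so each item is used at most once
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    sums = np.arange(max_sum + 1)
    u2_all = sums - nx * (nx + 1)
    extreme = np.abs(u2_all - mu2) >= dev
    count = ways[nx, extreme].sum()
    total = comb(nx + ny, nx)
    return float(count / total)


def _codon_p(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    small = min(nx, ny)
    if small <= EXACT_MAX_GROUP and comb(nx + ny, small) <= EXACT_MAX_COMBINATIONS:
        return exact_mannwhitney_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_codon_usage(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    usage: pd.DataFrame,
) -> pd.DataFrame:
    """Per-codon Mann-Whitney comparison of set A versus set B frequencies.

    Returns a DataFrame indexed by codon with median frequencies, two-sided
    ``mw_p`` (exact when the smaller set has <= 8 genes), BH ``fdr`` across
    codons, and log2 ratios of set-A mean frequency versus set B and versus
    the global (all-genes) average.  Raises on empty or overlapping sets.
    """
    set_a, set_b = list(genes_a), list(genes_b)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("gene sets overlap")
    ua = usage.loc[set_a]
    ub = usage.loc[set_b]
    global_mean = usage.mean(axis=0)
    rows = []
    for codon in usage.columns:
        x = ua[codon].to_numpy()
        y = ub[codon].to_numpy()
        mean_a = max(float(x.mean()), FREQ_FLOOR)
        mean_b = max(float(y.mean()), FREQ_FLOOR)
        mean_g = max(float(global_mean[codon]), FREQ_FLOOR)
        rows.append(
            {
                "codon": codon,
                "median_freq_a": float(np.median(x)),
                "median_freq_b": float(np.median(y)),
                "mw_p": _codon_p(x, y),
                "log2_mean_ratio_vs_b": float(np.log2(mean_a / mean_b)),
                "log2_mean_ratio_vs_global": float(np.log2(mean_a / mean_g)),
            }
        )
    table = pd.DataFrame(rows).set_index("codon")
    _, fdr, _, _ = multipletests(table["mw_p"].to_numpy(), method="fdr_bh")
    table.insert(3, "fdr", fdr)
    return table


def cumulative_frequency_table(
    usage: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    codons: Sequence[str],
) -> pd.DataFrame:
    """Long-format cumulative-frequency curves per codon and gene set."""
    rows = []
    for codon in codons:
        for set_name, genes in gene_sets.items():
            vals = np.sort(usage.loc[list(genes), codon].to_numpy())
            cum = np.arange(1, len(vals) + 1) / len(vals)
            for v, c in zip(vals, cum):
                rows.append(
                    {"codon": codon, "set": set_name, "frequency": v, "cumulative": c}
                )
    return pd.DataFrame(rows)


def codon_change_summary(
    te_down: Sequence[str],
    te_up: Sequence[str],
    usage: pd.DataFrame,
) -> pd.DataFrame:
    """Codon-frequency-change scatter table for the TE-Down set.

    x = log2(mean freq in TE-Down / mean freq over all genes),
    y = log2(mean freq in TE-Down / mean freq in TE-Up); codons are ranked
    by y (rank 1 = most TE-Down-enriched relative to TE-Up).
    """
    down = usage.loc[list(te_down)].mean(axis=0).clip(lower=FREQ_FLOOR)
    up = usage.loc[list(te_up)].mean(axis=0).clip(lower=FREQ_FLOOR)
    glob = usage.mean(axis=0).clip(lower=FREQ_FLOOR)
    table = pd.DataFrame(
        {
            "log2_down_vs_global": np.log2(down / glob),
            "log2_down_vs_up": np.log2(down / up),
        },
        index=usage.columns,
    )
    table.index.name = "codon"
    table["rank_down_vs_up"] = (
        table["log2_down_vs_up"].rank(ascending=False, method="first").astype(int)
    )
    return table


def rank_genes_by_codon(
    usage: pd.DataFrame, codon: str, top_fraction: float = 0.10
) -> list[str]:
    """Top ``top_fraction`` genes by frequency of ``codon`` (the codon-rich set).

    Sorting is descending by frequency with deterministic lexicographic
    tie-breaks on gene id.  Raises on an unknown codon.
    """
    if codon not in usage.columns:
        raise ValueError(f"unknown codon {codon!r}")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    order = sorted(usage.index, key=lambda g: (-usage.at[g, codon], g))
    n_top = max(1, int(len(order) * top_fraction))
    return order[:n_top]


def geneset_enrichment(
    selected: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` genes in each set.

    One-sided upper-tail p per set (probability of an overlap at least as
    large under sampling without replacement), BH-adjusted across sets.
    Set members outside the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    rows = []
    for set_id, members in gene_sets.items():
        members_in = set(members) & universe
        if len(members_in) < len(set(members)):
            log.warning(
                "gene set %s: %d member(s) outside universe dropped",
                set_id, len(set(members)) - len(members_in),
            )
        overlap = len(selected & members_in)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(members_in), len(selected))
        )
        rows.append(
            {
                "set_id": set_id,
                "overlap": overlap,
                "set_size": len(members_in),
                "universe_size": len(universe),
                "selected_size": len(selected),
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("set_id")
    _, fdr, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["fdr"] = fdr
    return table.sort_values("p")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (set_id <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
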