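"""tRNA expression quantification and differential expression.

Untreated-control libraries double as expression measurements (demethylated
RNA reads through, so read counts track abundance, as in ARM-seq-style
analyses).  Counts are aggregated per isodecoder group, CPM-normalised, and
compared between genotypes with a Welch t-test on log2(CPM) computed from
pseudocounted raw counts, with Benjamini-Hochberg FDR control.  A group is
flagged differential at a 1.5-fold difference and FDR < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import TRNARecord, group_of


def count_expression(
    alignments: pd.DataFrame,
    records: list[TRNARecord],
    sample_id: str = "",
) -> pd.DataFrame:
    """Aggregate weighted counts per isodecoder group with CPM normalisation.

    Returns a DataFrame indexed by group_id with columns ``weighted_count``
    and ``cpm`` (cpm sums to 1e6).  Groups without reads appear with zeros.
    Raises ``ValueError`` when the sample has no mapped reads at all.
    """
    mapping = group_of(records)
    groups = sorted(set(mapping.values()))
    counts = pd.Series(0.0, index=pd.Index(groups, name="group_id"))
    if len(alignments):
        per_ref = alignments.groupby("trna_id")["weight"].sum()
        for trna_id, w in per_ref.items():
            counts[mapping[trna_id]] += w
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id!r}: zero mapped reads, cannot quantify")
    out = pd.DataFrame({"weighted_count": counts, "cpm": counts / total * 1e6})
    out.attrs["sample_id"] = sample_id
    return out


def differential_trna_expression(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    fold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential expression of condition B versus condition A.

    ``counts_a``/``counts_b``: group x replicate raw weighted counts (each
    column one replicate).  The test is a two-sided Welch t on log2 CPM after
    adding ``pseudocount`` to the raw counts; p-values are BH-adjusted.
    ``is_differential`` requires |log2fc| >= log2(fold) and fdr < alpha.

    Raises ``ValueError`` with fewer than 2 replicates per condition (use
    fold-change-only comparisons explicitly in that case).
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError(
            "differential_trna_expression needs >= 2 replicates per condition; "
            "compute fold changes directly for unreplicated designs"
        )
    counts_a, counts_b = counts_a.align(counts_b, join="inner", axis=0)

    def _log2cpm(df: pd.DataFrame) -> np.ndarray:
        x = df.to_numpy(dtype=float) + pseudocount
        return np.log2(x / x.sum(axis=0, keepdims=True) * 1e6)

    la, lb = _log2cpm(counts_a), _log2cpm(counts_b)
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "is_differential": (np.abs(log2fc) >= np.log2(fold)) & (fdr < alpha),
        },
        index=counts_a.index,
    )
    result.index.name = "group_id"
    return result
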