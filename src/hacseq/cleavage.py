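"""Per-nucleotide cleavage-ratio calling of m3C sites and MTase-dependence classification.

Hydrazine-aniline chemistry cleaves RNA at N3-methylcytidine, so a fragment
produced by cleavage at site i begins at linear position i+1.  The per-site
statistic is therefore

    r_i = S_{i+1} / D_{i+1}

where S_j is the weighted count of read 5' starts at position j and D_j the
weighted read depth covering j.  r_i estimates the modification stoichiometry
at site i.  Sites are called by comparing treated (HAC) against untreated
control libraries, replicate means are averaged, and methyltransferase
dependence is classified from the fraction of the wild-type ratio retained in
each knockout genotype.

Genotype conventions follow the experimental design: "WT" (reference),
"M2KO" (METTL2A/2B knockout), "M6KO" (METTL6 knockout), and "M2_6KO"
(combined METTL2A/2B/6 knockout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

METTL2_DEPENDENT = "METTL2-dependent"
METTL6_DEPENDENT = "METTL6-dependent"
REDUNDANT = "redundant-M2/6"
INDEPENDENT = "MTase-independent"
PARTIAL = "partial/other"


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the caller and the dependence classifier.

    min_depth      weighted reads required at position i+1 for r_i to be valid
    min_ratio      minimum treated-sample ratio for a site call
    min_delta      minimum (treated - control) ratio difference for a site call
    loss_threshold retained fraction below which a knockout counts as loss
    retained_threshold  retained fraction above which the site counts as kept

    The source study reports continuous ratios without explicit call cutoffs,
    so these are package defaults, all configurable.  loss_threshold = 0.35
    places the boundary between "substantial loss" (a site dropping to ~30%
    of its wild-type ratio) and the smallest retained fraction observed for
    sites that are clearly kept (~80%).
    """

    min_depth: float = 50.0
    min_ratio: float = 0.10
    min_delta: float = 0.10
    loss_threshold: float = 0.35
    retained_threshold: float = 0.70
    reference_genotype: str = "WT"
    ko_single: tuple[str, str] = ("M2KO", "M6KO")
    ko_double: str = "M2_6KO"

    def __post_init__(self) -> None:
        if not (0.0 < self.loss_threshold < self.retained_threshold <= 1.0):
            raise ValueError("need 0 < loss_threshold < retained_threshold <= 1")


@dataclass
class SiteProfile:
    """Per-position weighted depth D and 5'-start counts S for one reference."""

    trna_id: str
    sample_id: str
    D: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.D.shape != self.S.shape:
            raise ValueError("D and S must have equal length")


@dataclass
class CleavageTrack:
    """Cleavage ratios r_i with a validity mask for one reference/sample.

    r_i = S_{i+1}/D_{i+1}; invalid wherever depth at i+1 is below min_depth,
    and by construction at position 0 and the 3'-terminal position.
    """

    trna_id: str
    sample_id: str
    r: np.ndarray
    valid: np.ndarray


@dataclass
class SiteCall:
    """A candidate site with per-genotype replicate-mean ratios."""

    trna_id: str
    index: int
    canonical_label: str
    mean_r_hac: dict[str, float]
    mean_r_ctrl: dict[str, float]
    delta: float
    is_site: bool


@dataclass
class DependenceClass:
    """MTase-dependence classification of one called site."""

    site: SiteCall
    label: str
    retained_fraction: dict[str, float]
    incomplete: bool = False


def compute_site_profile(
    alignments: pd.DataFrame,
    trna_id: str,
    length: int,
    sample_id: str = "",
    member_ids: Sequence[str] | None = None,
) -> SiteProfile:
    """Accumulate weighted depth and 5'-start counts from an alignment table.

    ``member_ids`` lets identical isodecoders be pooled into one group
    profile (default: just ``trna_id``).  All-zero profiles are allowed.
    """
    ids = list(member_ids) if member_ids is not None else [trna_id]
    sub = alignments[alignments["trna_id"].isin(ids)]
    D = np.zeros(length)
    S = np.zeros(length)
    if len(sub):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        weights = sub["weight"].to_numpy()
        if starts.min() < 0 or ends.max() > length:
            raise ValueError(f"alignment outside reference {trna_id} of length {length}")
        # depth via difference array
        diff = np.zeros(length + 1)
        np.add.at(diff, starts, weights)
        np.add.at(diff, ends, -weights)
        D = np.cumsum(diff[:-1])
        np.add.at(S, starts, weights)
    return SiteProfile(trna_id=trna_id, sample_id=sample_id, D=D, S=S)


def cleavage_ratios(profile: SiteProfile, config: CallerConfig | None = None) -> CleavageTrack:
    """Compute the cleavage-ratio track r_i = S_{i+1}/D_{i+1} with masking."""
    config = config or CallerConfig()
    L = len(profile.D)
    r = np.full(L, np.nan)
    valid = np.zeros(L, dtype=bool)
    if L >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:-1] = np.where(profile.D[1:] > 0, profile.S[1:] / np.maximum(profile.D[1:], 1e-300), np.nan)
        valid[:-1] = profile.D[1:] >= config.min_depth
    valid[0] = False
    valid[-1] = False
    return CleavageTrack(profile.trna_id, profile.sample_id, r=r, valid=valid)


TrackSet = Mapping[str, CleavageTrack]  # trna/group id -> track, one replicate


def _replicate_mean(tracks: Sequence[TrackSet], trna_id: str, i: int) -> tuple[float, bool]:
    """Mean r_i across replicates; valid only if valid in every replicate."""
    vals = []
    ok = True
    for rep in tracks:
        track = rep[trna_id]
        if not track.valid[i] or np.isnan(track.r[i]):
            ok = False
        vals.append(track.r[i])
    if not ok:
        return (float("nan"), False)
    return (float(np.mean(vals)), True)


def call_sites(
    hac_tracks: Mapping[str, Sequence[TrackSet]],
    ctrl_tracks: Mapping[str, Sequence[TrackSet]],
    config: CallerConfig | None = None,
    labels: Mapping[str, Mapping[int, str]] | None = None,
) -> list[SiteCall]:
    """Call m3C sites from HAC vs control tracks across genotypes.

    ``hac_tracks[genotype]`` is a sequence of replicate track sets (one
    ``{trna_id: CleavageTrack}`` per replicate); likewise ``ctrl_tracks``.
    Every position of every reference is reported; ``is_site`` is decided in
    the reference genotype (treated ratio >= min_ratio, treated-minus-control
    delta >= min_delta, and valid in all reference-genotype replicates).

    Raises ``ValueError`` when samples disagree on the reference set.
    """
    config = config or CallerConfig()
    ref_gen = config.reference_genotype
    if ref_gen not in hac_tracks or ref_gen not in ctrl_tracks:
        raise ValueError(f"reference genotype {ref_gen!r} missing from tracks")

    all_sets = [
        set(rep.keys())
        for source in (hac_tracks, ctrl_tracks)
        for reps in source.values()
        for rep in reps
    ]
    universe = all_sets[0]
    if any(s != universe for s in all_sets):
        raise ValueError("samples have mismatched reference sets")

    calls: list[SiteCall] = []
    for trna_id in sorted(universe):
        L = len(hac_tracks[ref_gen][0][trna_id].r)
        lab_map = labels.get(trna_id, {}) if labels else {}
        for i in range(L):
            mean_hac: dict[str, float] = {}
            mean_ctrl: dict[str, float] = {}
            valid_ref = True
            for geno, reps in hac_tracks.items():
                val, ok = _replicate_mean(reps, trna_id, i)
                mean_hac[geno] = val
                if geno == ref_gen:
                    valid_ref = valid_ref and ok
            for geno, reps in ctrl_tracks.items():
                val, ok = _replicate_mean(reps, trna_id, i)
                mean_ctrl[geno] = val
                if geno == ref_gen:
                    valid_ref = valid_ref and ok
            delta = mean_hac[ref_gen] - mean_ctrl[ref_gen]
            is_site = bool(
                valid_ref
                and mean_hac[ref_gen] >= config.min_ratio
                and delta >= config.min_delta
            )
            calls.append(
                SiteCall(
                    trna_id=trna_id,
                    index=i,
                    canonical_label=str(lab_map.get(i, "")),
                    mean_r_hac=mean_hac,
                    mean_r_ctrl=mean_ctrl,
                    delta=float(delta) if not np.isnan(delta) else float("nan"),
                    is_site=is_site,
                )
            )
    return calls


def classify_dependence(
    calls: Sequence[SiteCall],
    config: CallerConfig | None = None,
) -> list[DependenceClass]:
    """Classify MTase dependence of called sites from retained fractions.

    For each knockout genotype g, f(g) = mean_r_hac(g) / mean_r_hac(WT).
    With single knockouts (k2, k6) = config.ko_single and the double knockout
    kd = config.ko_double, and thresholds L = loss_threshold,
    K = retained_threshold:

      METTL2-dependent   f(k2) <  L and f(k6) >= K
      METTL6-dependent   f(k6) <  L and f(k2) >= K
      redundant-M2/6     f(k2) >= L and f(k6) >= L and f(kd) < L
      MTase-independent  min over all knockouts >= K
      partial/other      anything else

    Sites with missing genotypes are classified on what is available and
    flagged ``incomplete``.
    """
    config = config or CallerConfig()
    ref_gen = config.reference_genotype
    k2, k6 = config.ko_single
    kd = config.ko_double
    out: list[DependenceClass] = []
    for call in calls:
        if not call.is_site:
            continue
        wt = call.mean_r_hac.get(ref_gen, float("nan"))
        retained: dict[str, float] = {ref_gen: 1.0}
        for geno, val in call.mean_r_hac.items():
            if geno == ref_gen:
                continue
            retained[geno] = float(val / wt) if wt > 0 else float("nan")
        f = {g: retained.get(g, float("nan")) for g in (k2, k6, kd)}
        incomplete = any(np.isnan(v) for v in f.values())
        avail = {g: v for g, v in f.items() if not np.isnan(v)}

        L, K = config.loss_threshold, config.retained_threshold

        def have(*genos: str) -> bool:
            return all(g in avail for g in genos)

        if have(k2, k6) and f[k2] < L and f[k6] >= K:
            label = METTL2_DEPENDENT
        elif have(k2, k6) and f[k6] < L and f[k2] >= K:
            label = METTL6_DEPENDENT
        elif have(k2, k6, kd) and f[k2] >= L and f[k6] >= L and f[kd] < L:
            label = REDUNDANT
        elif avail and min(avail.values()) >= K:
            label = INDEPENDENT
        else:
            label = PARTIAL
        out.append(
            DependenceClass(site=call, label=label, retained_fraction=retained,
                            incomplete=incomplete)
        )
    return out


def sites_table(calls: Sequence[SiteCall], classes: Sequence[DependenceClass] | None = None) -> pd.DataFrame:
    """Flatten calls (and optional classes) into the sites TSV layout."""
    class_by_key = {}
    if classes:
        class_by_key = {(c.site.trna_id, c.site.index): c.label for c in classes}
    rows = []
    for call in calls:
        row: dict[str, object] = {
            "trna_id": call.trna_id,
            "index": call.index,
            "canonical_label": call.canonical_label,
            "delta": call.delta,
            "is_site": call.is_site,
            "class": class_by_key.get((call.trna_id, call.index), ""),
        }
        for geno, val in call.mean_r_hac.items():
            row[f"r_hac_{geno}"] = val
        for geno, val in call.mean_r_ctrl.items():
            row[f"r_ctrl_{geno}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def export_bedgraph(
    tracks: Mapping[str, Mapping[str, CleavageTrack]],
    outdir: str | Path,
) -> list[Path]:
    """Write one bedGraph per sample (tRNA id as chromosome, value = r_i).

    Masked positions are omitted.  Intervals are 0-based half-open.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sample_id, per_ref in tracks.items():
        path = outdir / f"{sample_id}.cleavage.bedGraph"
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{sample_id} cleavage ratio"\n')
            for trna_id in sorted(per_ref):
                track = per_ref[trna_id]
                for i in np.nonzero(track.valid)[0]:
                    fh.write(f"{trna_id}\t{i}\t{i + 1}\t{track.r[i]:.6g}\n")
        written.append(path)
    return written


def export_heatmap_matrix(
    calls: Sequence[SiteCall],
    path: str | Path,
    genotypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write the called-site x genotype mean-ratio matrix (heat-map layout).

    Rows are sites called in the reference genotype; columns the per-genotype
    replicate-mean treated ratios.
    """
    called = [c for c in calls if c.is_site]
    if genotypes is None:
        genotypes = sorted({g for c in called for g in c.mean_r_hac}) if called else []
    rows = {}
    for call in called:
        name = f"{call.trna_id}:{call.index}"
        if call.canonical_label:
            name += f"(C{call.canonical_label})"
        rows[name] = [call.mean_r_hac.get(g, float("nan")) for g in genotypes]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(genotypes))
    matrix.index.name = "site"
    matrix.to_csv(path, sep="\t")
    return matrix
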