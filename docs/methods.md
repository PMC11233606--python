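# Methods

This note records the models, estimators, defaults and numerical choices the
package implements, and what the simulation-based tests do and do not
establish about behaviour on real libraries.

## Cleavage model and the ratio estimator

A molecule carrying m³C at site i is cleaved by the hydrazine–aniline
chemistry between i and i+1; the downstream fragment therefore begins at
linear position i+1. Writing S_j for the weighted count of read 5′ starts at
position j and D_j for the weighted depth covering j, the cleavage ratio

    r_i = S_{i+1} / D_{i+1}

is, under the model of independent per-molecule cleavage with probability p
and no fragment loss, a binomial proportion estimator of p: every molecule
contributes one fragment covering i+1, and the fragment starts exactly at
i+1 when that molecule was cut. The estimator is reported per position with a
validity mask: positions with depth below `min_depth` (default 50 weighted
reads) are masked rather than divided, as are position 0 and the 3′-terminal
position, whose ratios are undefined by construction.

Known bias: when `min_fragment_len` (default 15 nt, the usual small-RNA size
selection) truncates a short 5′ or internal fragment, the denominator loses
those molecules and r_i no longer exactly equals the in-vivo stoichiometry.
For anticodon-loop and variable-arm sites on 76–85 nt tRNAs all fragments
exceed the cutoff and the bias vanishes; for hypothetical sites within 15 nt
of an end or of another site it does not, and the simulator reproduces this
so the effect can be quantified for any design.

## Alignment

Reads are aligned ungapped, sense strand only, against every reference at
every offset, keeping placements with at most two mismatches and then only
the minimal-mismatch stratum. This mirrors seed-free short-read mapping to a
small mature-tRNA reference; indels are not modelled because tRNA fragments
map end-to-end. A read with n equally good placements gets weight 1/n at each
— a deterministic choice that spreads multimapped coverage evenly across
identical isodecoders instead of randomly placing reads (the reporting mode
of the original mapper is not recoverable from the study text, so the
package's behaviour is documented rather than imitated). Weight conservation
(total weighted coverage = mapped reads) and equivalence to an exhaustive
Hamming scan are enforced by property tests. The two-mismatch budget is also
what tolerates the A-to-I editing mismatch at position 34 (read as A→G).

Identical mature sequences are indistinguishable to alignment, so ratios and
counts are computed per isodecoder group (a group is named by its
lexicographically smallest member id); per-record output exists but inherits
the arbitrary 1/n split.

## Site calling and dependence classification

Replicate tracks are averaged position-wise; a position is a site when, in
the reference genotype (wild type), the treated-sample mean ratio is at least
`min_ratio` (0.10), exceeds the untreated control by at least `min_delta`
(0.10), and is valid in every replicate. The study reports continuous ratios
without numeric call thresholds, so these defaults were chosen once so that
near-saturating sites pass comfortably and background (≤ ~1–2%) cannot; all
are configurable.

Dependence is classified from retained fractions f(g) = r(knockout g)/r(WT):

* METTL2-dependent: f(M2KO) < θ_loss and f(M6KO) ≥ θ_keep
* METTL6-dependent: f(M6KO) < θ_loss and f(M2KO) ≥ θ_keep
* redundant-M2/6:   f(M2KO) ≥ θ_loss, f(M6KO) ≥ θ_loss, f(M2_6KO) < θ_loss
* MTase-independent: every knockout retains ≥ θ_keep
* partial/other:    anything else

Defaults θ_loss = 0.35, θ_keep = 0.70. The loss threshold sits between the
two regimes the data exhibit: a "substantial" single-knockout loss leaves
roughly 30% of the wild-type ratio on the Ser-A36 family (0.30/0.97 ≈ 0.31),
whereas the smallest clearly-retained fraction (the residual Thr-CGT
isodecoders at ~0.80/0.97 ≈ 0.82) is far above it. θ_loss = 0.35 separates
0.31 from 0.82 with margin on both sides against replicate noise; a boundary
at 0.30 would sit exactly on the Ser-A36 retained fraction and flip its class
on sampling noise, so it was rejected. These thresholds substitute for the
qualitative language of the source analysis ("complete loss", "slight
decrease") and are printed into every report.

## tRNA expression

Untreated controls double as abundance measurements (demethylated RNA is read
through by RT). Counts are aggregated per isodecoder group and CPM
normalised; differential expression between genotypes uses a two-sided Welch
t-test on log₂ CPM after adding a 0.5 pseudocount to raw counts (zero-count
stability), with Benjamini–Hochberg correction. A group is differential at a
1.5-fold difference and FDR < 0.05. The upstream pipeline this stands in for
is not specified beyond those thresholds; the Welch/BH choice is a simple,
documented substitute. With two replicates per condition the Welch test has
~2 degrees of freedom and little tail resolution — adequate for a null check,
while power statements in the tests use three replicates.

## Ribosome profiling

**Offsets.** For reads spanning the annotated start codon, the distance from
the read 5′ end to the start codon clusters at the P-site offset (initiating
ribosomes pause with the start codon in the P site). The per-length offset is
the mode of that distance, clamped to [10, 16]; lengths with fewer than 50
such reads inherit the global mode, and with no usable signal every length
falls back to 12 nt, the canonical value for 28-mers.

**A-site assignment.** A-site codon = floor((read5′ + offset − cds_start)/3) + 1.
The first and last annotated codons are excluded everywhere so occupancy
reflects elongation rather than initiation/termination peaks; reads landing
outside the CDS are discarded and counted.

**Occupancy.** Within each gene passing `min_gene_reads` (64), the A-site
count vector over elongation codons is divided by its own mean; the occupancy
of a codon is the mean normalised density over all its instances across
genes, and the A+1-site occupancy repeats this one codon downstream of each
instance. By construction the instance-weighted mean A-site occupancy is
exactly 1. The estimator measures dwell relative to the gene-average dwell,
so a planted multiplier d on a codon of frequency q is recovered as
d/(1 + q(d−1)) — within 2% of d for the rare codons of interest.

**TE.** TE = (RPF CPM per CDS kb)/(RNA CPM per CDS kb) on one canonical
transcript per gene (longest CDS), masked below `min_rna` = 10 RNA counts.
Differential TE: per-replicate log₂ TE with a 0.5 pseudocount, two-sided
Welch t across replicates, BH correction; TE-Up/TE-Down require a 1.5-fold
difference and FDR < 0.05. With unreplicated input the module degrades to
fold-change-only classification with empty p/FDR. The original analysis was
run inside an external web toolkit whose internal statistics are
unpublished; offset calibration, the occupancy normalisation and the
Welch/BH differential test are this package's own documented choices, and
printed gene counts of the original study are not expected to be reproduced
number-for-number.

## Codon bias

Codon frequency is the per-gene fraction of sense codons (stop codons
excluded from numerator and denominator) — genes of different length stay
comparable, at the cost of ignoring absolute codon counts. Per-codon
comparisons between gene sets use a two-sided Mann–Whitney test: exact when
the smaller set has ≤ 8 genes, via a dynamic program over the multiset of
doubled midranks that counts subsets by rank sum (exact for any tie
pattern, and verified against brute-force enumeration of all C(nA+nB, nA)
assignments); a tie-corrected normal approximation otherwise. BH correction
runs across the 61 sense codons. The codon-change scatter reports, per
codon, log₂(mean TE-Down frequency / global mean) against log₂(mean TE-Down
frequency / mean TE-Up frequency), with a pseudo-frequency floor of 1e-6
keeping ratios finite; the y-axis is antisymmetric under swapping the sets.
"Global" defaults to all genes supplied in the usage table (expressed-gene
universes can be passed by subsetting). Gene-set over-representation is a
one-sided hypergeometric upper tail over a user-supplied GMT collection — no
annotation database is fetched, which trades convenience for reproducibility
across annotation versions.

## Synthetic data

The cleavage simulator draws, per molecule, independent Bernoulli cleavage at
each configured site (treated samples use the genotype's probability p,
untreated controls a background b = 0.005), partitions the molecule at the
cut points, discards fragments below the size selection, applies A34 A→G
editing per molecule at the configured fraction, and emits fragments as
reads. Because cleavage events are independent, molecule counts per cleavage
pattern are multinomial, which the implementation samples directly — exact
and fast. Reverse transcription is modelled as full read-through (the
protocol enzymatically demethylates RT-blocking marks before library prep),
and no ligation or end biases are modelled: the estimator consumes 5′ starts,
and end biases are outside the scope of what the ratio can distinguish
anyway. Passing tests on this generator therefore demonstrate estimator and
classifier correctness under the stated chemistry model, not robustness to
library-preparation artefacts.

The bundled study-design preset (15 synthetic 76/85-nt tRNA bodies with
anticodons placed at 34% of sequence length, C at every modelled site, an
identical Ser-GCT isodecoder pair, and editing on A34-containing tRNAs)
encodes the dependence pattern the experiment established: wild-type C32 at
p = 0.97 on all Ser/Thr/Arg(CCT,TCT) references; METTL2 knockout dropping
Arg/Thr C32 to 0.02 except a 0.80 residual on two Thr-CGT isodecoders;
METTL6 knockout dropping Ser-A36 C32 to 0.30 and Ser-GCT to 0.85; the triple
knockout removing all C32 except the Thr-CGT residuals; and 47d/20 sites at
0.90 everywhere. The classifier must reproduce this map exactly, and does.

The ribosome-profiling simulator gives each gene a per-replicate biological
abundance draw (gamma with squared CV = `dispersion`, default 0.1) that is
shared between the RPF and RNA libraries of that replicate — both derive
from the same lysate, so abundance noise cancels in TE, as it does in the
real paired design. RNA counts are Poisson around abundance × length;
footprint totals scale with abundance × TE × length, positions are
multinomial over elongation codons proportional to dwell multipliers, and a
2× initiation pause at the first elongation codon provides the start-codon
signal that offset calibration needs. Footprints default to 28 nt with a
12-nt offset; mixed-length designs use a built-in length→offset map. The CDS
simulator samples codons uniformly over the 61 sense codons, with per-group
enrichment factors applied within the synonymous family (the rest of the
family is rescaled, so amino-acid composition is invariant and a factor of
2 doubles the codon's frequency exactly in expectation).

Problem sizes used by the test suite and the acceptance script — 5,000
molecules per tRNA per sample for the cleavage designs; 150–1,000 genes of
~150 codons with 200k footprints for occupancy; 1,000 genes at ~2,000 mean
counts, 3 vs 3 replicates, for differential-TE operating characteristics
(100 null runs; detection power measured as FDR < 0.05 with the correct
sign, since an estimated fold sits below any threshold that equals the true
fold about half the time by symmetry) — were chosen once as the smallest
designs at which the binomial/Poisson error bounds make the checked
tolerances meaningful. All randomness descends from a single root seed per
run.

## Known limitations

* No mitochondrial tRNA handling, intron removal or secondary-structure
  numbering; positions 20/47d must come from an explicit override table.
* Ungapped alignment cannot place reads across indels or spliced references.
* The exact Mann–Whitney enumeration is quadratic in total rank sum and is
  switched to the asymptotic test beyond small sets.
* Differential tests are plain Welch/BH; no variance moderation, so power at
  2 replicates is limited.
* The codon-frequency "global average" is whatever gene universe is
  supplied; results depend on that choice.
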