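# Methods

## Scope and data model

The package models the desk half of building a capture-based SNP genotyping
panel: candidate screening from called genotypes, probe/interval design, and
the post-manufacture QC metric suite. It deliberately consumes VCF-style
output of an upstream calling pipeline; read QC, alignment and variant
calling are out of scope, as are functional annotation and wet-lab protocol
modelling.

Genotypes are held as a samples × sites matrix of dosage codes (0/1/2,
−1 = missing) with optional per-genotype depths. Only biallelic SNPs are
admitted; multiallelic and indel records are skipped at parse time with a
logged count, and any genotype containing a missing allele (including half
calls) is treated as missing — a missing call is unusable for every
downstream comparison, so no partial credit is given. All in-memory
coordinates are 1-based inclusive, matching the convention in which capture
intervals are quoted (e.g. chr1:316597–316897); conversion to 0-based
half-open happens only when writing BED.

## Screening statistics

**Hard filter.** Pass iff FS ≤ 60, HaplotypeScore ≤ 13.0, MQ ≥ 40, QD ≥ 2,
ReadPosRankSum ≥ −8.0 and MQRankSum > −12.5 (only the last bound is
strict). An absent annotation passes its criterion by default: rank-sum
annotations are undefined at sites without both genotype classes, and
HaplotypeScore is absent from modern caller output; failing on absence would
discard valid sites. A `strict` flag inverts this for callers guaranteed to
emit all six fields.

**Per-site statistics.** MAF is the folded minor-allele frequency over
non-missing calls; missing rate is missing calls over all samples; observed
heterozygosity is het calls over non-missing calls; mean depth averages over
all samples by default (the convention of the common per-site reports), with
a called-only switch.

**F<sub>ST</sub>.** The two-population per-site estimator is the Weir &
Cockerham (1984) θ̂ = a/(a+b+c) from the among-population (a),
among-individual (b) and within-individual (c) variance components, computed
from per-population sample sizes, allele frequencies and heterozygote
fractions at the site. Negative estimates are reported raw; an undefined
denominator, a population with no calls, or a mean sample size ≤ 1 yields
NaN. Screening keeps sites with θ̂ > 0.5, strictly.

For parameter recovery across many sites the package also provides the
weighted multi-site combination Σa / Σ(a+b+c). The unweighted mean of
per-site ratios is biased low (≈ 0.21 at a true F of 0.3 with 50+50
samples — a standard ratio-estimator effect, since sites where both
populations drift to similar frequencies contribute near-zero ratios); the
weighted form recovers the simulated F within ±0.02 at 5000 sites and is
what the test suite asserts.

**HWE.** The exact conditional test on genotype counts: given the observed
allele counts, the p-value sums the probabilities of all heterozygote
configurations no more probable than the observed one (standard, no mid-p —
the default of the mainstream genotype-QC tools). Computed with log-gamma
arithmetic; tests verify it against full rational-arithmetic enumeration for
totals up to 200. Monomorphic sites return p = 1.

## Panel assembly

**Dedup priority.** When a position arrives from several sources the kept
record follows RESEQ_FST > GGVD_IMMUNE > LITERATURE > RESEQ_POLY >
GGVD_POLY: differentiation-informative and trait-linked origins are rarer
and should survive collisions. Ref/alt conflicts between duplicate records
are logged and resolved in favour of the higher-priority source.

**Spaced selection.** Forced-keep sources (F<sub>ST</sub>, immune,
literature) are always retained. Remaining slots are filled round-robin over
200 kb windows (the grid on which panel density is conventionally reported),
taking each window's best remaining candidate (highest MAF, ties to the
smaller position) per round. This makes per-window occupancy as even as the
candidate support allows and is fully deterministic.

**Probes.** Sites on a chromosome group greedily left-to-right: a site joins
the open group iff it is within 100 bp of the group's *first* site, so every
within-group pairwise distance is ≤ 100 bp and one 100 bp probe, centred on
the group's span midpoint, can cover the group. Probes must have GC in
[0.20, 0.80]; be single-copy (the central 50-mer occurs exactly once in the
genome, both strands — an exact-match proxy for uniqueness that avoids a
full alignment dependency); contain no homopolymer longer than 10 and no two
disjoint 12 bp segments that are perfect reverse complements (a stem-length
proxy for hairpins and self-dimers — requiring disjoint segments matters,
since random 100-mers contain a self-palindromic 12-mer ≈ 2 % of the time
and such a 6 bp stem is not a credible failure); and cover at most 3 known
variants. The centring rule, 50-mer core, stem/homopolymer lengths and
covered-variant cap are design choices exposed as parameters. Sites whose
probe fails any screen are reported undesignable and dropped.

**Capture intervals.** Each site's window is [pos − flank_up,
pos + flank_down] with flanks constrained to 100–200 bp; the default 150 bp
is the midpoint of that range and reproduces the canonical single-site
example exactly. Flanks are per-boundary (the canonical merged example uses
140 upstream of the first site and 160 downstream of the second).
Overlapping or book-ended intervals merge into their hull — the merged
window must contain both sites plus their outer flanks, which the hull does
and a pairwise intersection would not. Merging is idempotent and every panel
site lands in exactly one merged interval.

## Validation metrics

Call rate = called sites / panel sites per sample; heterozygosity rate uses
called sites as denominator, so call rate + missing rate = 1 by
construction. A site is polymorphic if any het is observed or both
homozygote classes occur across the cohort. Concordance compares genotype
codes (no allele-level partial credit — one number per pair is the
reporting convention) over sites called in both callsets; repeatability
reports per duplicate-pair discordant counts and rates plus the unweighted
mean rate, always alongside the explicit denominator. The MAF spectrum uses
bin edges (0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5) and reports the fraction
of sites at or above a 0.01 floor. The depth experiment regenerates two
callsets from one truth at different mean depths and demonstrates the
mechanism by which low-depth callsets disagree with high-depth ones: a true
heterozygote sampled at depth d is miscalled homozygous with probability
2^(1−d).

## Clustering

QC keeps sites with call rate ≥ 0.9, MAF ≥ 0.05 and HWE exact p ≥ 10⁻⁶.
The default distance is allele sharing, d(i,j) = 1 − mean(1 − |cᵢ − cⱼ|/2)
over co-called sites. K2P distances on pseudo-sequences (homozygotes as
their allele, heterozygotes and missing as N, excluded pairwise) are offered
for fidelity to tree-building workflows that operate on linear sequences;
K2P is undefined for ambiguous bases, and how any particular workflow
encoded heterozygotes is generally unstated, so allele sharing is the
default. d = −½ ln((1−2P−Q)√(1−2Q)); out-of-domain proportions give NaN.

Neighbor joining is implemented in-package so its contract is pinned:
standard Q-criterion joins, ties broken on the lowest active index pair,
branch lengths floored at zero. It is exact on additive matrices (tested to
10⁻⁹ on random 4–8 taxon trees, and cross-checked against an independent
library implementation); site-resampling bootstrap support is available but
off by default because it multiplies runtime by the replicate count. PCA
uses Patterson standardization (centre by 2p̂, scale by √(p̂(1−p̂)), impute
missing to the site mean, drop monomorphic sites) and eigendecomposition of
the sample covariance; coordinates are eigenvectors scaled by √eigenvalue.

## Synthetic data

The generator emulates a two-reference-population design: ancestral
frequencies uniform on [maf_floor, 1 − maf_floor], population frequencies
Beta-distributed around them with variance p(1−p)F (Balding–Nichols — the
simplest model with a controllable F<sub>ST</sub>), genotypes binomial
within populations (hence in HWE), i.i.d. missingness, Poisson depths.
Defaults are 50+50 samples, 5000 sites, F = 0.3, 5 % MAF floor, mean depth
30×, 2 % missingness and a 0.1 % duplicate genotype-error rate — a
desk-scale version of a two-population reference panel with clearly
separated populations. The depth-dependent caller draws Poisson depth and
binomial allele reads, calling homozygous when one allele is seen, het when
both, missing below 2 reads.

What this does **not** emulate: linkage disequilibrium, recombination, real
site-frequency spectra, batch effects, reference bias, or capture-efficiency
variation between probes. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
performance on any particular real cohort; headline counts from real panels
depend on their private data and are not reproducible from simulation.

## Numerical and testing choices

Test problem sizes (2000–20 000 sites, 20–100 samples, 40 tree replicates)
are chosen so the full suite runs in about a minute while keeping binomial
standard errors well inside the asserted tolerances. All simulation is
seeded through `numpy.random.default_rng`; identical configurations produce
byte-identical VCF output. The HWE enumeration oracle uses exact rational
arithmetic; the F<sub>ST</sub> oracle is a separate scalar transcription of
the variance components kept independent of the vectorised implementation.
Degenerate inputs (all-missing sites, monomorphic sites, zero-depth
callsets, empty panels, pairs with no co-called sites) return NaN or empty
outputs rather than raising, except where a precondition is a genuine user
error (unknown samples, flanks outside 100–200 bp, target panel smaller
than the forced-keep set).

## Known limitations

Single-copy checking is exact-match only; near-duplicates diverged by a few
mismatches will pass. Hairpin screening is a combinatorial proxy, not a
thermodynamic ΔG model. F<sub>ST</sub> support is two populations per-site
only (no windowed or k > 2 estimators). The NJ implementation targets
hundreds of samples, not tens of thousands. X-chromosome sites are handled
like autosomes when not excluded; no dosage correction for sex chromosomes
is applied.
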