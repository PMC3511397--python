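# Methods notes

This note records the statistical models implemented in `adnapop`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate about real data.

## Sequence diversity

Haplotype diversity uses Nei's unbiased estimator
h = n(1 − Σpᵢ²)/(n − 1); it is exactly the fraction of unordered sample
pairs carrying different haplotypes, which is the oracle the tests compare
against.  Nucleotide diversity π is the mean pairwise proportion of
differing sites.  Sites where either sequence of a pair carries a gap or
an IUPAC ambiguity code are excluded *pairwise* and the per-pair alignment
length adjusted, because trimmed ancient-DNA consensus sequences routinely
contain Ns; a pair with no comparable sites is an error rather than a
silent zero.  Both statistics are undefined for n < 2 and raise instead of
returning a number.

## Genotype statistics

Expected heterozygosity is Nei's small-sample form
Hₑ = 2n(1 − Σpᵢ²)/(2n − 1).  F_IS is Weir & Cockerham's f, computed from
the within-population variance components (b, c summed over alleles); the
naive 1 − H₀/Hₑ is also reported because the two disagree at small n and
published values do not always say which was used.  Between populations,
θ (F_ST) uses the full Weir–Cockerham a/b/c components per allele and
locus; the multi-locus estimate is the ratio of summed components, the
standard weighting.  Monomorphic loci carry no information and are
excluded (an all-monomorphic dataset is an error).

Hardy–Weinberg testing conditions on the observed allele counts (Levene's
distribution).  Biallelic tables are fully enumerated over heterozygote
counts of the correct parity, summing the probabilities of tables no more
probable than the observed one.  Multiallelic tables use Monte-Carlo
allele shuffling (default 100,000 permutations) with the reported standard
error; the two routes agree within Monte-Carlo error on every small table,
which the suite checks.  Exact p-values are conservative on heavily tied
small tables — rejection rates at α stay at or below α, never above.

## AMOVA, Φ_ST and MDS

Molecular distance between haplotypes is the count of differing sites
(pairwise deletion of ambiguous positions), the conventional default for
pairwise-difference AMOVA; no substitution model is imposed.  Sums of
squares are computed from haplotype count vectors
(SS = ½ cᵀDc / group size), which the tests verify against a direct
enumeration over individuals.  The three-level design estimates σ²ₐ
(among groups), σ²ᵦ (among populations within groups) and σ²𝒸 (within
populations) from the unbalanced-design expected mean squares.  Negative
variance-component estimates are retained in the F-ratios: truncation
would bias small or null effects upward, and published tables print
negative values.  Significance is by permutation — individuals among all
populations for F_ST, individuals within groups for F_SC, whole
populations among groups for F_CT — with p = (b + 1)/(m + 1) including
the observed configuration; the default is 10,000 permutations.
Permutation p-values are uniform under the null only when the permutation
distribution is reasonably continuous; with very few distinct haplotypes
ties make them conservative, which is the safe direction.

The MDS of a Φ_ST matrix is classical Torgerson double-centering (negative
Φ_ST entries clipped to zero, eigendecomposition, top two non-negative
components).  A nonmetric procedure was deliberately not used: classical
scaling is deterministic and dependency-free, and near-metric inputs (fit
r² ≥ 0.98 is typical for these matrices) make the difference immaterial.
r² is the squared Pearson correlation between input and embedded
distances; a configuration reproduced exactly but with constant distances
(e.g. an equilateral triangle) reports r² = 1 by convention.

Lineage assignment tests the three derived diagnostic states of lineage A,
then of lineage C; a sequence matching the reference state at all
diagnostic positions is lineage B; anything else — including ambiguity
codes at a diagnostic site — is unassigned.  Diagnostic positions are
given in reference coordinates and translated through a declared offset,
because published positions are anchored to a reference genome, not to the
trimmed alignment.

## Genotyping QC

Consensus calling: modern samples require agreement of duplicate runs;
ancient samples accept any genotype called in at least two of up to three
runs.  A heterozygote/homozygote conflict resolved in the heterozygote's
favour by an additional run is flagged separately
(`het_confirmed_third_run`) because it is the signature of allelic
dropout.  No majority, or no data, yields an undetermined call — not an
error.

The per-reaction error rate divides allelic mismatches against the
consensus by ploidy × reactions, so a het scored as hom in one run is one
allelic mismatch out of two allele draws.  When two runs disagree with no
majority, the reference is the observed genotype minimising total
mismatches, which attributes the minimal number of allele errors.  The
per-genotype discrepancy rate (discrepant samples / samples compared) is
reported alongside under its own name; conflating the two scales (per
allele-reaction vs per genotype) is a common reporting error the split
naming guards against.  Replicate counting uses *all* provided replicate
reactions; restricting to a subset of batches is possible by filtering the
input, but is not the default.

The dropout screen replaces a full null-allele analysis with a calibrated
Monte-Carlo test: the statistic is the fraction of top-size-quartile
allele copies found in homozygotes, compared one-sided against genotypes
simulated under HWE from the observed allele frequencies.  Dropout strips
large alleles out of heterozygotes while leaving large homozygotes intact,
so this fraction rises; a raw homozygote count is defeated by the
dropout-deflated observed allele frequency (the count's own null
expectation shrinks with the signal) and was rejected for that reason.
Stutter is a deficit of heterozygotes exactly one repeat unit apart, same
null; the repeat unit defaults to the smallest gap between distinct
observed sizes.  Loci with fewer than two alleles are declined as
monomorphic rather than flagged.  Screening power depends on the allele
spectrum: with the largest size class at frequency ~0.3 and strong
size-graded dropout, 50 genotypes give > 80% detection; rare large
alleles are intrinsically hard to screen at that sample size.

Damage classification reads substitutions in the reference → observed
direction: C→T/G→A is Type 2 (the cytosine-deamination signature),
A→G/T→C is Type 1, everything else a transversion.  Re-complementing both
sequences maps C→T counts onto G→A counts and preserves the Type 2 total,
a strand-convention invariant the suite checks.

Percent summaries (amplification success) round half away from zero to
integer percent, matching how such rates are conventionally quoted.  The
Ct-stratified summary splits samples at the mean cycle threshold — a
non-degenerate split whenever Ct varies — and compares the fraction with
errors or undetermined genotypes above vs at-or-below the mean.

## Power simulation

The design: an ancestral population with known allele (or haplotype)
frequencies splits into two subpopulations of Nₑ diploids, each drifting
independently with multinomial resampling of 2Nₑ gene copies per
generation.  The drift time for a target F_ST inverts the inbreeding
recursion F_t = 1 − (1 − 1/(2Nₑ))^t, rounded to the nearest generation;
the expectation the rounded t actually delivers is reported and used as
the centre of the run filter.  The engine is verified against the
recursion: at Nₑ = 1000, t = 861 the mean realised F_ST is 0.3498 against
an expectation of 0.3499, and mean heterozygosity decays as
(1 − 1/(2Nₑ))^t to four decimals.

Realised F_ST per replicate is Wright's variance-standardised index
computed from the *true* post-drift subpopulation frequencies around the
known ancestral frequencies (ratio of sums across alleles and loci).  Its
expectation equals the recursion value exactly, it is 1 for a fixed
difference, and — unlike any sample-based estimate — it cannot be
correlated with the significance test through shared sampling noise.  For
evenly-frequent SNPs it coincides algebraically with the
heterozygosity-decay form 1 − H_t/H₀.  SNP runs are filtered to a
relative window (default ±10%) around the expectation, emulating loci
held at high differentiation by selection; multiallelic markers use all
runs.

Tests: Pearson χ² without continuity correction on the 2×2 allele-count
table for SNPs; Monte-Carlo Fisher exact tests (Patefield sampling of
tables with fixed margins) for microsatellites and mtDNA.  Per-locus
p-values combine by Fisher's method; a summed-χ² alternative is available
as a config switch.  Sampled tables with an empty allele margin carry no
information and are skipped, flagged through the per-replicate locus
count.  α defaults to 0.05.  The significance level, test family and
combination rule shift the filtered power estimates by at most ~2
percentage points at these sample sizes — the estimates are dominated by
the drift-conditional composition of the retained runs, a robustness the
development analysis established by varying every one of these choices.

mtDNA is simulated as a single multiallelic locus under the same
2Nₑ-gene-copy drift and 2n sampled copies as nuclear loci.  This ignores
the fourfold-smaller effective size of a maternally inherited haploid
marker; it is the deliberate choice because the comparison is of marker
information content (allele counts and frequency spectra) at a common
drift scale, and no marker-specific effective size is defined in the
study design being emulated.  The default mtDNA haplotype spectrum is a
42-haplotype geometric profile whose unbiased haplotype diversity at
n = 74 is 0.956, a synthetic stand-in constructed to match the reported
diversity of the empirical sample (whose full spectrum is not available).
The default microsatellite panel is 12 loci × 10 alleles drawn once from
a symmetric Dirichlet with concentration 2.9, the value at which the
expected heterozygosity matches the reported panel mean Hₑ = 0.870; the
frequencies are fixed by an internal seed so the panel is reproducible.

Problem sizes: the two headline SNP designs use the full 10,000 replicates
(a few seconds each, vectorised across replicates); the marker-ranking
and monotonicity properties in the test suite use 150–400 replicates per
configuration, enough to resolve the orderings they assert at their stated
slack.

### Known discrepancy

Under this design the filtered power of one SNP at target F_ST 0.35 is
86–88%, and of three SNPs at 0.2 about 97% — higher than the 73% and 92%
quoted for the analysis this simulation emulates.  The discrepancy was
investigated in depth: the conditional power given the two-sided
realised-F_ST window is invariant (±2 points) to the realised-F_ST
definition, the test family, α, the window form, the locus-combination
rule and the drift depth, and an independent R implementation reproduces
it.  Any filter that demands true between-population divergence near 0.35
forces the allele-count χ² above ~30 at these sample sizes, so
substantially lower filtered power is not obtainable from the stated
procedure; the quoted figures are reproducible only under readings that
contradict the two-sided window as described (e.g. discarding only
overshooting runs).  The implementation follows the stated procedure and
reports what it computes.

## Synthetic-data generators

The generators emulate the *structure* of real inputs: multiallelic
haplotype spectra with controlled pairwise distances (private mutations
per haplotype, so distances are exact by construction), diploid genotypes
corrupted per PCR run by per-copy allelic dropout — logistic in
standardised allele-size rank and Ct, encoding the two qualitative
degradation effects (large-allele dropout; errors concentrate in poorly
preserved, high-Ct samples) in one tunable model — one-repeat stutter
shifts, and Bernoulli miscoding lesions on C/G (Type 2) and A/T (Type 1)
sites.  Default Ct regimes are Normal(36.8, 3.5) for ancient and
Normal(25.7, 1.0) for modern cohorts.  Every generator is
seed-deterministic to the byte and writes a truth log sufficient to score
the QC estimators.

What passing the synthetic tests does **not** show: the generators draw
independent sites and runs, with no position-dependent deamination
profile, no PCR batch effects, no cross-contamination, and no linkage —
so the suite validates the estimators' arithmetic and calibration, not
their robustness to structured real-world artefacts.

## Format conventions

Alleles are opaque text labels, lexicographically ordered within a
genotype; microsatellite allele labels are their fragment size in bp
(required by the dropout screen).  Genepop `0000`/`000000` maps to an
explicit missing genotype, and a half-called genotype is treated as
missing.  Genepop files cannot carry population names, so populations
re-read as `pop1..popK` in file order; the long-table dialect is fully
lossless and is the native format.  Sequence coordinates are 0-based
internally; published diagnostic positions are translated through a
declared offset.  All randomised operations accept one integer seed,
surfaced on the CLI and recorded in each output's log file.
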