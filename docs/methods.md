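# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical conventions of `mutacc`, in the order the pipeline runs.

## Genome matrices and accessibility

The caller's only sequencing input is the *genome matrix*: per reference
position, total read coverage and counts of the six pileup symbols A, C,
G, T, deletion and N. Read trimming, alignment and duplicate removal are
upstream of this package and out of scope; a matrix TSV dialect (1-based
positions, one row per covered position) is the interchange format.

A position is **accessible** iff it is outside the repeat mask (BED,
0-based half-open), covered by ≥ 20 reads, and its focal classification is
not "undefined". "Fewer than 20 reads" is low coverage, so exactly 20
reads is analysable. Accessible-site counts are the denominator of rate
normalization; everything inaccessible is excluded from both numerator
and denominator, which keeps rate estimates unbiased even when ~25% of a
repeat-rich genome cannot be called. The definition is focal-only by
default — background-cohort conditions do not affect accessibility — since
cohort-dependent accessibility would make the denominator differ between
focal genomes of the same experiment; the cohort rules act on acceptance
instead.

## Position classification

The strongest non-reference allele among {A, C, G, T, deletion} (N is
never a mutant allele) defines the mutant-allele frequency *f* =
count/coverage. Classification intervals are left-closed/right-open
except where a strict printed bound exists: [0, 0.1) homozygous
reference, [0.1, 0.3) sequencing error, [0.3, 0.8) heterozygous,
[0.8, 0.9] undefined, (0.9, 1] homozygous mutant. The boundary choice
preserves the strict "> 0.9" and "< 0.1" semantics of the published
threshold table; boundaries are measure-zero for real data but fixed here
so tests are deterministic.

Two conventions the threshold table does not pin down:

* **Ties** between non-reference alleles break to the lexicographically
  smaller allele (column order A, C, G, T, deletion).
* **Multi-allelic positions** — two non-reference alleles each at ≥ 0.1
  frequency — are classified undefined. Genuinely multi-allelic de novo
  events are not expected in an MA design; fabricating a call would risk
  false positives.

## Cohort filtering

A focal heterozygous or homozygous-mutant call becomes an accepted novel
mutation only against its background cohort (the other genomes of the
same genotype; for generation-2/3 focal genomes the parental genome is
removed first, because a true inherited mutation is present in the
parent). Rules, evaluated in a fixed order for reproducible rejection
reasons: shared variant in any background; more than one background
undefined; any other mutation at the position; more than three
backgrounds below 20×; fewer than six backgrounds homozygous wild-type.
"Homozygous wild-type evidence" means a hom-ref classification at ≥ 20×;
error-class backgrounds count as neither wild-type nor mutant. Fewer than
six usable backgrounds after parent exclusion is a configuration error.

**Deletions.** The matrix has one deletion channel, so multi-base
deletions appear as runs of adjacent deletion-allele calls; accepted runs
are merged into a single record (1–4 bp supported — the range observed in
the data this design targets). The unification of adjacent deletion
positions is this package's convention; insertion calling is impossible
from this matrix and out of scope.

## Rates and tests

`n = ((total_genome / accessible_genome) × accepted) / generations`,
computed exactly; per-site rate is n / total_genome. Fold changes carry
the raw double and display at one decimal (half-even). Per-site rates and
percentages display at two significant digits.

Group rate comparisons use Fisher's exact test (two-sided, hypergeometric
enumeration as implemented in scipy) on the pooled table
[[mut_A, accessible_A − mut_A], [mut_B, accessible_B − mut_B]]. The table
construction behind published rate p-values is not documented anywhere we
could follow, so p-values from this contrast are indicative, not exact
reproductions. Methylation contrasts use the chi-square test with Yates
continuity correction, statistic Σ (max(|O−E|−0.5, 0))²/E with 1 d.f.;
the correction is capped so it cannot overshoot past the expected value.

## Spectra, fractions, contexts, motifs

Substitutions collapse into six strand-symmetric classes; deletions are
excluded from spectrum denominators. Genome fractions are gene, TE and
intergenic with TE taking precedence over overlapping gene models and
TE-gene features counted as TEs; "gene" includes UTRs and introns for
fraction assignment while coding effects use CDS models only (the source
analysis does not separate the two; this is our documented split).
Coding effects use the standard genetic code with strand-aware codon
lookup; stop gain/loss is non-synonymous; deletions are frameshifts and
excluded from the synonymous/non-synonymous tally.

Sequence context is the ±3 bp window with the mutated base at offset 0,
reported on the pyrimidine strand (purine-reference events are reverse
complemented), so all G:C→A:T events align in the C→T frame. Motif
matrices score each column by relative entropy against the background
A = T = 0.3, C = G = 0.2: D_j = Σ_b f_bj log2(f_bj / p_b) with
0·log 0 ≡ 0, per-base heights f_bj·D_j. This is the standard
non-uniform-background logo definition; no small-sample correction is
applied. The mutated column's *display* height is capped at 1 bit (a
figure convention); stored scores are never altered.

## Methylation calling and association

A cytosine is methylated when ≥ 2 replicates with ≥ 10 reads show a
methylation fraction ≥ 10% (both thresholds inclusive); with fewer than
two qualifying replicates it is not analysed. Only G:C→A:T mutations at
analysable cytosines enter the association test: a C→T record maps to the
plus-strand cytosine at its position, a G→A record to the minus-strand
one, so each record consults exactly one strand (in CG context both
strands carry cytosines; using the mutated strand is our convention — the
alternatives differ only through replicate noise). Per context (CG, CHG,
CHH and pooled "CNN") the methylated/unmethylated counts of mutated
positions are tested against all analysable genomic cytosines; a context
with no testable mutations is reported untestable with no p-value.

## Germline timing

In a selfing hermaphrodite, a heterozygous mutation present before the
separation of male and female cell lineages segregates 1:2:1 in the
progeny — among carriers, het:hom = 2:1 — while a post-split mutation
reaches the progeny through one gamete and is always heterozygous. With
q the post-split share of *inherited* mutations, R = (2+q)/(1−q), inverted
as q̂ = (R−2)/(R+1), clipped to [0, 1] (R < 2 maps to 0 with a flag).
Ratios are computed on normalized per-haploid-genome counts, matching the
scale on which such ratios are reported; raw counts are also emitted. q̂
has no published uncertainty; a bootstrap CI over genomes is provided and
labelled as an extra. The 2:1 expectation conditions on sequencing one
progeny per parent, which is how both the real design and the simulator
sample.

Reciprocal-cross analysis asserts that every F1 mutation is heterozygous
(a homozygous call flags that genome for self-pollination), attributes
each F1 genome's count to its irradiated parent, and compares direction
means with Welch's t-test.

## The synthetic-data generator

The generator works at pileup-count level: Poisson(λ) coverage per
position and a symmetric per-read-base error model replace read
simulation and alignment, preserving the caller's exact input contract.
Defaults are the validation conditions the pipeline is designed around:

* λ = 41 reads, per-base error ε = 2% (uniform over the three other
  bases; deletion/N error sub-rates configurable, default 0 — the error
  profile of read-level simulators is not specified at count level, so a
  symmetric substitution model is assumed and noted);
* spike-in set of 308 homozygous + 592 heterozygous substitutions;
* UV-B-like process: 88% G:C→A:T, a TC(C/T)-context weight (default 8 —
  strong enough that motif logos show the T at −1 and C/T at +1 clearly)
  and a methylated-cytosine multiplier of 2.1, which yields ≈ 27%
  methylated among mutated cytosines against a ≈ 15% genome background;
* genome: A = T = 0.3, C = G = 0.2 base composition, 30% gene / 20% TE /
  2.5% low-complexity mask (the masked share of the reference genome this
  emulates), one guaranteed gene/TE overlap so the TE-precedence rule is
  exercised;
* methylome: per-context methylation probabilities CG 0.45, CHG 0.22,
  CHH 0.03, chosen once so the overall methylated fraction of cytosines
  is ≈ 15%.

Heterozygous sites report the mutant allele per read with probability
1/2; homozygous sites on both haplotypes. Selfing segregates pre-split
heterozygous mutations 1:2:1 per progeny and transmits post-split
mutations heterozygous to every assayed progeny (the sequenced progeny
descends from the affected gamete lineage; somatic sector sizes are not
modelled). Crosses transmit homozygous parental mutations always and
heterozygous ones with probability 1/2, always heterozygous in the F1.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: alignment and mapping artefacts (the dominant
real-world false-positive source, here absorbed into the mask), PCR
duplicates, non-uniform and GC-biased coverage, correlated errors within
reads, methylation's concentration in TE-rich pericentromeric regions
(methylation is context- but not position-dependent here), and linkage
between mutations. Caller error rates measured on synthetic data are
therefore lower bounds on real-data error.

## Problem sizes and numerics

Tests run desk-scale: the spike-in validation uses a 1 Mb genome with 90
spikes (31 hom / 59 het — the published 900/308/592 design scaled by ten)
over 10 seeds; oracle-equivalence checks run 100 random cohorts of 400 bp
× 10 genomes against a literal scalar re-implementation; segregation and
recovery checks use 1e4–1e5 simulated mutations. All stage seeds derive
from one master seed via `numpy.random.SeedSequence`, making every
pipeline product bit-reproducible from its manifest. Expected behaviour
at these scales: zero false positives in every validation run, pooled
false-negative rate well under 2% (the residual misses are heterozygous
sites whose binomial frequency draw lands below the 0.3 cutoff at 41×),
and exact recovery with ε = 0 at λ = 60.

## Known limitations

* No base-quality-aware genotype likelihoods; the caller is a frequency
  thresholder by design, matching the analysis it reproduces.
* Insertions cannot be called (no insertion channel in the matrix).
* Printed Fisher p-values of the source analysis are not reproduced
  exactly (table construction unstated; see above).
* The BAM/pileup import path is untested against real alignments; the
  matrix TSV is the supported input format.
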