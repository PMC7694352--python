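# Methods

## Coordinates

All internal coordinates are 0-based half-open (BED convention); lengths
are `end − start`. Human-readable outputs (CNVR tables, scan TSVs) use
1-based inclusive coordinates, and the conversion happens only in the two
converters in `cnvpop.intervals`. The merge rule for CNVR construction is
"≥ 1 shared base": two intervals that merely abut in half-open coordinates
share zero bases and do not merge.

## Raw-call filters

Caller outputs are normalised into a TSV dialect (`sample_id, chrom,
start0, end0, svtype, caller, filter, vaf, support_reads`; "." for absent)
before filtering. Only DEL and DUP records are admitted; other SV types are
tallied and skipped. The paired-end caller's filter keeps records with
length > 50 bp and FILTER = PASS; the split-read caller's filter keeps
length > 50 bp, variant allele frequency > 0.2 and ≥ 3 supporting reads.
Both length and VAF bounds are strict; the read-count bound is inclusive.
Records with non-positive length are a hard parse error, not a filtered
record. When a VCF carries no explicit allele-frequency field, VAF is
derived from AD-style counts as `alt/(ref+alt)` (a per-call read ratio, not
a cohort frequency).

## Two-caller consensus

Per sample, a candidate pair is a paired-end call and a split-read call
with the same chromosome and SV type whose overlap is at least 50% of the
smaller call ("of a CNV size" is read as the smaller of the two, which
makes the rule symmetric; requiring the fraction of both calls is available
via the `denominator` argument). Matching is one-to-one: candidates are
accepted greedily by decreasing overlap length, ties broken toward the
leftmost partners, so a call overlapping two partners joins only its best
one. The consensus coordinates are the intersection of the pair.

## CNVR construction and unification

Consensus CNVs are clustered by the transitive closure of "≥ 1 bp shared"
irrespective of SV type (type-blind merging is what allows complex CNVRs to
exist), independently within each population and over the whole cohort; the
two levels are parallel merges of the same consensus CNVs, not nested
(cohort-level CNVRs are not built from population CNVRs). Clusters with a
single member CNV are discarded at each level independently. The envelope
is the union span of the members.

Unification with the read-depth track keeps a CNVR iff at least one
read-depth region shares ≥ 50% of the shorter of the two; the unified
envelope is the union of the CNVR span with all qualifying read-depth
spans, preserving all member evidence (the source workflow does not state
the unified coordinates; the union is the choice that loses nothing).
Regions supported by one approach only — on either side — contribute
nothing to the output, so every surviving CNVR carries both approaches.
Classification (deletion / duplication / complex) follows the member SV
types after merging.

Genome coverage in summaries is computed on the union of spans (no double
counting), verified in tests against a per-base bitmap oracle.

## Genotypes, filters, and spectra

Genotypes are biallelic per locus (reference vs SV allele) stored as
alt-allele dosage 0/1/2 with NaN for missing, read from GT fields
(0/0, 0/1, 1/1, ./.). Missing genotypes are excluded from frequency
denominators, never imputed; an all-missing locus raises a distinct error
rather than silently reporting frequency 0. The locus filters keep
MAF ≥ 0.05 and missingness ≤ 10% ("lower than 0.05" and "more than 10%"
are strict removal bounds, so both kept-side boundaries are inclusive),
computed over all samples.

The site frequency spectrum is folded (MAF-based) with left-open/
right-closed bins (0, 0.05], …, (0.45, 0.50], so the conventional rare
class "MAF ≤ 0.05" is exactly the first bin. Monomorphic loci are reported
in a separate zero class and excluded from the fractions, which sum to 1
over polymorphic loci.

## F_ST estimation and outlier calling

The per-locus estimator is the Weir–Cockerham (1984) moment estimator with
r = 2 groups (formulas in the README and the `cnvpop.fst` module
docstring). Per-group sample sizes count non-missing genotypes at that
locus. Negative θ is reported as computed, and genome-wide means and
medians average per-locus θ over defined loci including negatives — this
convention is what produces low genome-wide medians on weakly
differentiated cohorts. A multi-locus ratio-of-sums estimator
(Σa / Σ(a+b+c)) is provided separately for parameter-recovery checks; the
scan summaries use per-locus averaging.

Loci monomorphic across both groups have a + b + c = 0 and undefined θ;
they are excluded before thresholding. The outlier threshold is the
nearest-rank rule: the smallest θ among the top ⌈tail · L⌉ defined loci,
so "θ ≥ threshold" selects exactly the top 5% when values are distinct.

The implementation is cross-checked in the test suite against an
independent exact-rational (`fractions.Fraction`) implementation of the
same definitions over every dosage configuration with ≤ 3 samples per
group, including missing genotypes (≈ 6.5 × 10³ configurations), to 1e-12
on each component.

## Synthetic cohorts

The generator's defaults are the study conditions: seven populations with
sizes CB 15, JT 9, TC 14, SC 4, MD 14, MN 8, BI 21 (85 samples), a 0.9
deletion fraction, and log-normal CNV lengths with median 179 bp clipped
to [51 bp, 50 kb] (the clip keeps every simulated event above the size
filters, so length filtering is exercised by dedicated spiked calls rather
than by accident). Differentiation follows the Balding–Nichols model:
per-locus ancestral frequency p ~ Uniform(0.05, 0.95), subpopulation
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotype ~ Binomial(2, p_sub).
Balding–Nichols is used because it gives a known F_ST target for
parameter-recovery tests. Loci are placed non-overlapping, uniformly on a
toy genome (default 5 × 10 Mb), with n_loci defaulting to 2000 — the
desk-scale problem size all simulation-based checks use.

Caller emulation: each carrier (dosage ≥ 1) emits one call per caller with
endpoints jittered by independent rounded Gaussians (degenerate draws
resampled, coordinates clipped to the chromosome), dropped with probability
`fn_rate`; the paired-end caller gets FILTER = PASS with probability
`pass_prob`; the split-read caller gets VAF centred at 0.5 (heterozygotes)
or 0.95 (homozygotes) and Poisson supporting reads. Background false
positives land uniformly at `fp_per_mb` per caller per sample. The
read-depth track is the true CNVR set (loci with ≥ 2 carriers) with its own
jitter, and the genotype VCF encodes true dosages with a configurable
missing rate. A fixed spike-in list of known-fail calls (50 bp, non-PASS,
VAF = 0.2, 2 reads) is placed in a reserved 50-kb suffix of the first
chromosome so filter tests have guaranteed, collision-free coverage.

All randomness flows from one seed through named `SeedSequence` child
streams (loci, frequencies, genotypes, one per caller, read-depth,
missingness); reruns are byte-identical.

What the generator does not emulate: linkage disequilibrium between loci,
read-level artefacts (GC bias, mappability), multi-allelic copy-number
states, overlapping true events, and correlated caller errors. Passing
tests therefore demonstrate the correctness of the pipeline's logic and
estimators under the assumed statistical model, not robustness to every
failure mode of real sequencing data.

## Numerical and degenerate-input choices

- θ undefined (returned as None / NA) when a + b + c = 0 or n̄ ≤ 1; such
  loci are excluded from summaries and tail counts.
- Sorting ties broken by (chrom lexicographic, start, end) everywhere, so
  all outputs are deterministic and order-invariant.
- The ΔΔCt quad is explicit; replicate wells are aggregated by arithmetic
  mean Ct in a separate documented pre-step. Amplification-efficiency
  correction is out of scope.
- Pipeline reruns with identical inputs and config are byte-identical
  except the timestamp confined to the log header.

## Known limitations

- The FST scan is two-group; the estimator core accepts r > 2 but the scan
  interface does not expose it.
- Gene identity for cross-dataset comparison is by case-insensitive symbol
  with a logged collision report; symbol-vs-stable-ID mismatches between
  annotation releases are the caller's responsibility.
- The Manhattan plot is deliberately not produced; the ranked scan TSV is
  the normative artifact.
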