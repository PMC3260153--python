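# Methods

## Overview

`founderscan` models the classical founder-population route to recessive
disease genes: autozygosity mapping on low-density SNP arrays followed by
exome variant filtering under a mutation-homogeneity assumption. This
note records the models, the defaults and why they were chosen, the
numerical rules of the detection engine, and what the simulator does and
does not emulate.

## Data model and conventions

Genomic intervals are 1-based and fully closed everywhere inside the
package; a shared block is reported by its outermost qualifying markers,
matching the convention of delimiting mapped intervals by their flanking
SNPs. BED input/output is 0-based half-open and converted exactly once,
at the I/O boundary, in both directions.

Array genotypes are unphased biallelic calls `{AA, AB, BB, missing}`
with abstract alleles; no strand or phase information is used anywhere.
Exome genotypes are alt-allele dosages `{0, 1, 2, unknown}`. Indel
records may carry `zygosity_known = False` (callers of the emulated era
did not determine indel zygosity); their dosage then encodes presence
(1) or absence (0) only. SNV records may not carry unknown zygosity.

## Mapping statistic

For one homozygous call whose allele has control frequency `f` and a
per-call error rate `e`, the two-point LOD contribution is

    lod(f, e) = log10( [(1 − e)·f + e·f²] / f² ),

the log-likelihood ratio of observing that homozygote under autozygosity
(allowing an erroneous call to land on a chance homozygote) versus under
Hardy–Weinberg. At `e = 0` it reduces to `−log10 f`; it is strictly
decreasing in `f`, and zero information is contributed by missing or
heterozygous calls and by fixed alleles (`f → 1`). The default `e` is
0.01 and is exposed everywhere.

The location score of a block sums these contributions over all
homozygous non-missing markers in the block and over all affected
individuals, treating affecteds as independent. Summation matches the
"cumulative" construction of the statistic; because close relatives are
not independent the score overstates absolute evidence and is used only
as a *relative* ranking of intervals (ties broken by chromosome and
start position). Markers whose frequency is undefined (all control calls
missing) are skipped and the skip count is recorded on the block.

Allele frequencies come from population controls (the emulated studies
used 100 population-specific females) with a Laplace pseudocount of 0.5
per allele: `f = (n_A + ½) / (2·n_called + 1)`. The pseudocount keeps
`f` strictly inside (0, 1), so no marker can contribute infinite
evidence.

## Run and block detection

Detection is a maximal-window enumeration over per-marker status codes.
For a set of affected samples each marker is classified as

* **GOOD** — every non-missing call is the same homozygous genotype;
* **SOFT** — exactly one call deviates from an identically homozygous
  consensus carried by at least two samples (the footprint of a single
  miscalled genotype);
* **BAD** — two or more deviating samples, or no usable consensus;
* **MISS** — no non-missing calls at all.

Single-sample run detection uses the same engine with
homozygous → GOOD, heterozygous → BAD, missing → MISS (no SOFT class —
one sample cannot out-vote itself).

A window qualifies when (i) it starts and ends on GOOD markers; (ii) its
SOFT/BAD/MISS counts are within budgets; (iii) its outermost
`min(5, length)` markers on each side contain no BAD marker and at most
one SOFT/MISS marker; and (iv) it spans at least `min_markers`. Reported
runs/blocks are the qualifying windows not contained in another
qualifying window. The engine is O(n) per chromosome (sliding budgets
plus precomputed terminal-validity); the test suite checks it against an
exhaustive O(n²) enumeration of the same definition on hundreds of
random panels.

The edge-zone rule (iii) is the load-bearing numerical choice. Without
it, two failure modes ruin boundary accuracy at realistic error rates: a
single miscall just inside a true block clips one or two markers off the
reported boundary, and unspent tolerance budget drags an endpoint
outward across chance identical homozygosity beyond the block. Allowing
one SOFT (but no BAD) in a five-marker terminal zone absorbs isolated
edge miscalls while blocking budget-driven extension.

Defaults: `min_markers` 25 for 10K-like panels and 50 for 50K-like
panels; run tolerances `max_het_per_run = 0`, `max_missing_per_run = 2`;
shared-block tolerances `max_single_deviations = 6` (SOFT),
`max_conflicts = 1` (BAD), `max_missing = 2`. The SOFT budget covers the
expected number of single-sample miscalls over a block of tens of
markers and a handful of affecteds at a 0.5% call error rate (Poisson
mean ≈ 1.4 for 70 markers × 4 samples, 99.9th percentile ≈ 6). All are
caller-exposed.

With one affected sample, shared-block detection reduces exactly to run
detection with `max_conflicts` acting as the heterozygote budget.

## Exclusion mapping in nuclear families

For a family with affected children and unaffected siblings, candidate
regions are maximal intervals where all affecteds carry *identical*
genotypes (heterozygous consensus allowed — this is linkage, not
autozygosity) at every informative marker, under the same tolerance
engine. Each unaffected sibling then excludes the stretches over which
its genotypes match the affected consensus contiguously for at least
`sib_match_min_mb` (default 3 Mb): a long match is the footprint of
sharing both parental haplotypes, which an unaffected sibling cannot do
at the disease locus, while short matches are chance and are ignored.
Subtracted stretches are trimmed by two markers at each end, because a
genuine shared segment ends with a short run of coincidental
single-marker matches whose subtraction would otherwise erode a true
linkage region. Remaining intervals of at least `min_size_mb`
(default 5 Mb) are reported per family; missing sibling calls are
uninformative (they neither break nor veto a match).

## Candidate filtering

The cascade applies, in order: mapped-interval membership → novelty
(absence from every requested catalog; catalog names are validated
against a known universe) → homozygous in *all* affecteds → homozygous
in *no* unaffected → consequence class. Stage counts partition exactly
(kept + dropped = input at every stage) and the interval and novelty
stages commute. Missing affected genotypes count as "not homozygous"
and are tallied in the report rather than silently ignored.

The default potentially-pathogenic class set is {missense, nonsense,
read-through, splice site, indel}; synonymous, intronic, UTR, flanking,
miRNA and intergenic classes are not potentially pathogenic. The set is
configurable, as is retention of specific non-coding classes through the
final stage. Unknown-zygosity indels are retained through the
homozygosity stages with a warning flag when present in every affected
(strict mode drops them instead) — silently discarding a class the
caller could not genotype would risk discarding the causal variant.

The homogeneity scan is the mapping-free mode: novel, homozygous in all
affecteds, homozygous in no other studied individual, genome-wide, no
consequence filter. With at least two affected individuals it returns
the same candidate as the mapped cascade on simulated studies — the
computational expression of why mutation homogeneity makes array
genotyping dispensable.

Segregation checking expects genotyped parents of affecteds to be
heterozygous, affecteds homozygous-alternate, and no unaffected family
member homozygous-alternate; missing genotypes are reported but never
fail the check.

## Control screening and rounding

From control genotyping counts, the allele frequency is
`(n_het + 2·n_hom) / (2·n_controls) × 100` (per chromosome, printed to
two decimals) and the carrier rate is `(n_het + n_hom) / n_controls ×
100` (per individual, one decimal); for rare variants they differ by a
factor of about two and both are reported. A homozygous control is
flagged — it argues against pathogenicity of a fully penetrant
recessive allele. All printed rounding in the package (frequencies,
block sizes to 0.1 Mb, mean gene counts to integers) is half-up, as in
published tables, not banker's rounding.

## The simulator

### What it emulates

A disease allele enters through one founder couple and descends through
consanguineous lineages to study sibships. Haplotypes are tracked as
piecewise-constant maps from position to founder-haplotype index;
meioses recombine them with a Poisson crossover process at 1 crossover
per 100 Mb (configurable, no interference, sex-averaged). Identity by
descent is therefore exact and recorded, not inferred: the truth set
lists every realized autozygous segment per sample and the planted
variant's genotype in every individual, including the control cohort
(whence control carriers arise organically).

Defaults describe the emulated study conditions:

* genome: two chromosomes (100 + 80 Mb) — a chromosome-scale genome
  that keeps hundred-seed experiments fast while leaving room for
  background autozygosity;
* marker density: 17.4/Mb ("50K-like") or 3.5/Mb ("10K-like"),
  evenly spaced; allele-A frequencies uniform on (0.3, 0.7), emulating
  the high-heterozygosity ascertainment of array SNP panels;
* noise: 0.5% call-error rate (a wrong call is replaced by one of the
  other two codes) and 0.5% no-call rate, both per call;
* pedigree: four sibships whose parents descend from the founder couple
  through lineages chosen to approximate a target inbreeding coefficient
  (first cousins 1/16, first cousins once removed 1/32 — the default
  target 0.03 — second cousins 1/64); one affected child per sibship
  plus unaffected siblings, 15 genotyped family samples and 100
  population controls drawn as random founder-haplotype pairs (hence
  Hardy–Weinberg at unlinked markers);
* planted block: 4 Mb on chr1 with the pathogenic variant at its
  midpoint, missense by default;
* exomes: ~16,540 variants per sample of which ~4% are novel,
  class-weighted by the per-class averages characteristic of early
  exome cohorts; catalogued sites are shared across samples with
  Hardy–Weinberg genotypes at ascertainment frequencies; novel variants
  are private Poisson draws that are homozygous exactly when they land
  in one of the sample's realized autozygous segments — which is what
  produces the observed small number (~20) of novel homozygous variants
  per inbred exome; one "benign shared" novel confounder (homozygous in
  all affecteds *and* one unaffected) exercises the exclusion rule.

Affected children are conditioned (by gamete resampling) to inherit the
disease haplotype from both parents across the entire planted span;
unaffected relatives are resampled only if homozygous at the causal
position. Affected flanking ancestry is conditioned *not* to carry the
disease haplotype immediately outside the span, i.e. the planted
segment terminates with obligate crossovers at its edges. This makes
the truth boundary sharp and recoverable; without it, observed
identical homozygosity genuinely continues past the planted span along
the inherited haplotype, and no detector could localize the boundary to
marker resolution. The default study places affecteds in separate
sibships for the same reason: siblings share flanking parental
haplotypes, which blurs shared-block boundaries (sibling-pair designs
remain fully supported and are used in the exclusion-mapping tests).

Reproducibility: one top-level seed fans out through independent
per-stage streams (founders, gene drop, noise, exomes, annotation);
identical configuration and seed give byte-identical artifacts.

### What it does not emulate

No linkage disequilibrium between markers within founder haplotypes (all
alleles are drawn independently per marker), no real genetic map or
recombination hotspots, no deme-specific demographic history, no
ascertainment of marker clustering in subtelomeric regions, no
read-level data, and no relatedness structure at catalogued exome sites
(common variation is drawn i.i.d. per sample). Passing recovery tests
therefore demonstrate correctness of the detection and filtering logic
under the stated noise model, not performance on real LD structure; in
real data, block boundaries are fuzzier and chance identical
homozygosity is more extensive than the independent-marker model
produces.

## Test problem sizes

Simulation-backed tests use the default 180 Mb genome: shared-block
recovery at 50K-like density over 100 seeds (and a 1.6 Mb block at
10K-like density for the density contrast, where too few markers span
the block for it to qualify as a run — the reason small founder blocks
required denser arrays); cascade/homogeneity recovery over 100 seeds at
the full exome rate; exclusion mapping on single nuclear families with
two affecteds and six siblings at 10K-like density over 100 seeds.
Boundary recovery is scored at marker resolution — the reported
flanking marker must sit within one marker of the outermost marker
covered by the truth segment — because the underlying recombination
breakpoint falls between markers and is localizable only to the
flanking interval.

## Known limitations

* The location score ignores relatedness between affecteds and linkage
  disequilibrium; it is a ranking device, not a calibrated likelihood.
* Multipoint linkage (Lander–Green/Elston–Stewart), haplotype phasing,
  and pedigree-likelihood LOD with loops are out of scope.
* The exclusion-mapping sibling-match threshold (3 Mb) trades exclusion
  power against erosion of true regions; in very dense panels a lower
  threshold would be justified.
* Novel variants are private in the simulator (apart from the planted
  and confounder variants), so the homogeneity scan's discrimination
  against *shared* benign founder variants is exercised only through
  the explicit confounder mechanism.
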