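# founderscan

Autozygosity mapping and recessive candidate-variant filtering for founder
populations, together with a ground-truthed simulator of consanguineous
study cohorts.

## The problem

In endogamous founder populations (isolated demes with average inbreeding
coefficients of a few percent), nearly all patients with a recessive
disorder are homozygous for the same ancestral pathogenic allele, which
sits inside a large homozygous haplotype block shared by all affected
individuals. This makes disease-locus mapping cheap: genotype a handful of
patients on a low-density SNP array, find the genomic interval where every
affected individual is *identically homozygous*, and rank intervals by a
cumulative two-point LOD statistic. Exome sequencing then reduces the
interval to a single candidate by filtering on novelty (absence from
reference catalogs), homozygosity in all affecteds, absence of
homozygotes among unaffecteds, and consequence class. With two or more
affected individuals, the same candidate even emerges *without* mapping,
by assuming mutation homogeneity and scanning the whole exome.

`founderscan` implements this workflow as a reusable library and CLI for:

* **mapping** — per-sample runs of homozygosity, shared identically
  homozygous blocks across affecteds, per-SNP two-point LOD scores and
  cumulative *location scores*, and exclusion mapping with unaffected
  siblings in nuclear families;
* **filtering** — the candidate cascade (mapped interval → novel →
  homozygous in all affecteds → homozygous in no unaffected → pathogenic
  potential), the mapping-free homogeneity scan, and recessive
  segregation checks;
* **screening** — carrier-rate and allele-frequency arithmetic for
  population-control genotyping;
* **simulation** — a gene-drop generator that drops founder haplotypes
  through consanguineous pedigrees with Poisson recombination, plants a
  pathogenic variant inside a known autozygous block, and emits SNP
  panels, cohort exome VCFs and an exact truth set.

## The statistic

For a homozygous genotype at a marker whose observed allele has control
frequency `f`, the evidence for autozygosity relative to Hardy–Weinberg
chance homozygosity is

    lod(f, e) = log10( [(1 − e)·f + e·f²] / f² )

with `e` a per-call genotyping error rate (`e = 0` gives `−log10 f`).
The *location score* of a shared block is the sum of these contributions
over all homozygous non-missing markers in the block and over all
affected individuals; it is additive over any split of the block and
ranks candidate intervals. Allele frequencies are estimated from
population controls with a Laplace pseudocount (default 0.5 per allele)
so that a monomorphic marker can never contribute infinite evidence.

## Worked example

Run the full synthetic pipeline (simulate → map → filter → report):

```
$ founderscan run --seed 7 --outdir demo
pipeline complete: 1 candidate(s); report in demo/report.json
```

The report shows one shared block on chr1 — 70 markers, 4.0 Mb, location
score 81.5 — and the filter cascade narrowing 44,558 exome genotype calls
to a single candidate:

| stage | input | kept |
|---|---|---|
| mapped interval | 44,558 | 966 |
| novel | 966 | 200 |
| homozygous in all affecteds | 200 | 1 |
| not homozygous in any unaffected | 1 | 1 |
| potentially pathogenic | 1 | 1 |

The surviving candidate is the planted variant (`chr1:50000000 C>T`,
missense), it segregates as a recessive allele in the families, and the
simulated control screen finds 3 heterozygous carriers among 100 controls
and no homozygotes.

Control-screen arithmetic is also available directly; for 2 heterozygous
carriers among 201 genotyped controls:

```
$ founderscan screen --n-controls 201 --n-het 2
{
  "allele_frequency_pct": 0.5,   # variant alleles per chromosome (2/402)
  "carrier_rate_pct": 1.0,       # carriers per individual (2/201)
  ...
}
```

Note the factor-of-two distinction between the per-chromosome allele
frequency and the per-individual carrier rate — both are reported because
screening studies quote both.

## Layout

| module | contents |
|---|---|
| `founderscan.model` | shared data model (panels, manifests, variant tables, blocks, truth sets) |
| `founderscan.simulate` | study simulator: founders, pedigrees, gene drop, exomes |
| `founderscan.io` | TSV/PED-MAP panels, VCF 4.2 variants, BED intervals, truth files |
| `founderscan.mapping` | ROH, shared blocks, LOD/location scores, exclusion mapping |
| `founderscan.filtering` | candidate cascade, homogeneity scan, segregation checks |
| `founderscan.summary` | control-screen arithmetic, report assembly, pipeline driver |
| `founderscan.cli` | `founderscan simulate / map / filter / screen / report / run` |

Coordinates are 1-based fully closed internally (blocks are delimited by
their flanking SNPs); BED files are converted at the I/O boundary. See
`docs/methods.md` for the model, parameter defaults and limitations.
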