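# Methods

This note documents the statistical model behind each stage, the parameters
that matter, the numerical choices, and what the synthetic data do and do not
demonstrate.

## Pooled screening model

An 8-plex equal-mass pool of diploid plants contains 16 haplotypes.  A
heterozygous carrier therefore contributes an expected variant allele
frequency (VAF) of 1/16 and a homozygous carrier 2/16.  The retention rule —
keep a site when |VAF(pool) − VAF(WT)| ≥ 1/16, boundary inclusive — is the
smallest shift a single carrier can produce, and the same Δ-threshold is
applied whether the WT sample's genotype at the site is pure (VAF outside
(0.2, 0.8)) or heterozygous (inside that band).  The reason string attached
to each decision names which case applied.

At pool depth d and per-base sequencing error e, the pool VAF of a site with
one homozygous carrier is approximately Binomial(d, 0.125·(1−e) + ...)/d, so
the miss probability is the binomial tail P(X/d < 1/16) with X ~ Bin(d, 1/8).
At the default depth 2000 this is ≈ 6×10⁻¹⁹, and a false positive would need
an error allele to reach 125 of 2000 reads (P < 10⁻¹⁰⁰) — which is why the
full-scale simulated screen recovers the planted truth exactly.  The
`screen_site` power is verified against the analytic tail at small depth,
where misses are actually observable.

VAF itself is count(best-supported non-reference allele)/depth.  Ties
between non-reference alleles break by fixed order (A<C<G<T, indel alleles
last); ties at sequencing-noise level (<1 % VAF) are logged at DEBUG,
meaningful ones at WARNING.  Zero-depth sites are "missing", never errors.

Thresholds and defaults (`ScreenParams`):

| parameter | default | meaning |
|---|---|---|
| `delta_threshold` | 1/16 | minimum pool-vs-WT VAF difference |
| `het_band` | (0.2, 0.8) | WT VAF interval treated as a heterozygous parent |
| `min_depth` | 5 | below this, a site is missing rather than screened |
| `min_reads_candidate` | 50 | read support required of a final candidate |

`min_reads_candidate` has no published value ("relatively high reads"); 50
was chosen once as a conservative floor for amplicon data and is always
logged.  Candidate rows with unknown depth (the published worked-example
table, which was read-filtered upstream) skip the depth check.

## Variant annotation

Gene models are 1-based inclusive genomic intervals with explicit strand;
exon and intron indices count in transcription order.  Coding consequences
are obtained by rebuilding and translating the full mutant CDS against the
reference CDS (Biopython), so downstream premature stops are detected, not
just in-codon changes.  Indels use the dash convention of published rice
mutation tables (insertion: ref `-`, placed after the position; deletion:
deleted bases with alt `-`); VCF-anchored indels are normalised to it on
ingest.  Indel length mod 3 separates frameshift from in-frame classes, and
a deletion straddling an exon boundary is classified by the number of coding
bases it removes.  Protein changes are single-letter refPosAlt with `X` for
stop (`C55X`) and `fs`/`ins`/`del` suffixes for indels.  Exonic positions
outside the CDS are UTR; when a model carries no CDS intervals its exons are
treated as non-coding feature intervals only.

Domain overlap maps the affected residue onto the protein's domain
intervals.  Missense and in-frame changes affect only the containing domain;
truncating classes (stopgain, frameshift) additionally lose every domain at
or downstream of the residue, which is what makes an early stop in the
first domain of a negative regulator a strong allele.

## Phenotype statistics

Lines carry ≥ 2 replicate measurements per trait (default 30, the seeds
measured per plant).  Summaries use the sample SD (n−1) and CV = 100·sd/mean.
The mutant-vs-WT comparison is a two-sided Welch t-test by default — the
published analysis does not name its test, and unequal variances are
plausible — with a Monte-Carlo permutation test on the mean difference as a
selectable alternative and as the automatic fallback when the Welch
statistic is undefined (constant samples).  Significance classes are `**`
(p < 0.01), `*` (p < 0.05), `ns`; labels long/short/wide/narrow follow the
sign of the significant shift.  Percent changes round to 2 decimals at
reporting only, never internally.

## Whole-genome cascade

Genotype calling: depth < 5× → missing; VAF ≥ 0.8 or ≤ 0.2 → homozygous
(boundaries inclusive); otherwise heterozygous.  WT subtraction matches on
(chrom, pos, ref, alt) regardless of WT genotype, except that depth-masked
(missing) WT sites do not subtract, since the WT state there cannot be
asserted.  After the bulk symmetric difference, the homozygous filter keeps
by default only alt-homozygous sites (VAF ≥ 0.8): a "homozygous" call at
VAF ≤ 0.2 means the alternate allele is essentially absent.  This is
configurable (`CascadeParams.keep_hom_ref`).  The functional filter keeps
nonsynonymous, stopgain/stoploss, frameshift and in-frame indel classes;
the final filter keeps sites whose residue lies in a domain or whose
truncating consequence loses at least one downstream domain.  Stage
input/output counts are recorded and verified non-increasing on every run.

## Synthetic-data generator

The generator reproduces the study design, not the biology of mutagenesis:

- **Population**: per plant, the induced variant count is Binomial(total
  target bases, per-base rate), positions uniform over the two target
  intervals, substitutions to a uniformly random other base.  The default
  rate 5×10⁻⁶ per base per plant was set once so that 3872 plants over the
  ~8.7 kb of synthetic target intervals yield on the order of the ~179
  sites the real screen observed; no per-plant rate is published.
- **Zygosity**: induced mutations are homozygous with probability 1.0 by
  default (the pooled screen observed only homozygous mutations in M2
  material); configurable, since M2 genetics is not modelled mechanistically.
- **Pooling**: deterministic in input order (no pooling scheme is
  published); a remainder forms a short final pool with a logged warning;
  the WT reference sample is a single diploid plant.
- **Pileups**: depth ~ Poisson(mean), reads multinomial over the pool's
  haplotype frequencies; a substitution error (default 10⁻³) moves a base
  call to a uniformly random other base; indel alleles misread as the
  reference base.  No read-level FASTQ simulation, and no amplicon/PCR bias.
- **Sanger calls**: correct with probability 1 − discordance, otherwise
  reverting to the homozygous WT call — the observed failure mode in which
  unconfirmed candidates read as wild type.
- **Phenotypes**: trait mean = WT mean (9.31 mm length / 2.03 mm width) +
  additive effects looked up by (consequence class, domain); each replicate
  adds Normal(0, sd) noise with sd 0.18 mm (length) and 0.0113 mm (width,
  derived from the published CV of 0.56 % — the printed width SD of 0.01 is
  inconsistent with the printed range and was not used).  The default
  effect table encodes the observed significant shifts (OSR truncation
  +0.91 mm length; TNFR/NGFR and VWFC missense −1.25 and −0.80 mm;
  calmodulin-binding missense +0.26 mm width).  Where the real data show
  two different effects for the same (class, domain) pair, the table keeps
  one rule; effects are additive with no epistasis or line-level variance
  component.
- **WGS trio**: background variants on an off-target contig split into
  WT-shared, bulk-shared and per-bulk private sites with a het/hom VAF
  mixture and occasional sub-threshold depth; planted variants are chosen
  inside domain-covered codons and verified functional by the annotator
  before planting.

All randomness flows through a single `numpy.random.Generator`; a fixed
seed reproduces every table bit for bit (checksummed in the run manifest).

What passing tests on these data show: the decision rules, bookkeeping and
statistical calibration of every stage are correct under the study's design
parameters.  What they do not show: robustness to amplicon coverage bias,
index hopping, alignment and variant-calling artifacts, population
structure, or non-additive genotype–phenotype maps — none of which the
generator emulates.

The synthetic gene models (`mtwa.datasets.demo_gene_models`) are stand-ins:
exon layout, sequence and domain residue ranges are constructed, seeded and
deterministic, chosen only to be consistent with the published residue
placements (a stop at residue 55 truncates all three domains; residue 5
precedes them; residues 135/141 and 160–220 fall in the second and third
domains).  Reproducing the real protein-change table requires supplying the
real reference and gene models, which are not bundled.

## Problem sizes

The default test suite and the acceptance script run the full design size
where it is cheap (3872 plants, 484 pools, pool depth 2000, pileups at all
segregating plus 200 control sites; ~10⁵ simulated pileups) and reduced
sizes elsewhere (100 random cascade trios; 1000 null / 500 power phenotype
simulations), chosen to keep a complete run in the tens of seconds while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The published interval mutation frequencies (4.05×10⁻⁵ and 9.02×10⁻⁵)
  cannot be reproduced from the published site counts without the unstated
  fragment lengths; `mutation_frequency` implements the stated formula
  (mutated bases / fragment length) and the pipeline reports it per
  interval, but those two constants are not regression targets.
- Wet-lab stages (SSR authenticity assay, primer design, DNA extraction,
  image-based seed measurement) and upstream read processing / variant
  calling are out of scope; the pipeline consumes variant and phenotype
  tables.  Protein 3-D structure prediction is replaced by the
  residue-interval domain-overlap check.
- Multi-allelic pileups reduce to the single best non-reference allele.
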