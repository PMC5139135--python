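# Methods

## Study design being modelled

The package implements the analysis pipeline of an autozygosity-mapping
study of a rare recessive disorder in a small, inbred pedigree: two
affected monozygotic twin calves and their healthy parents are genotyped
on a dense SNP array; regions where both cases are homozygous with shared
alleles while neither parent is homozygous delimit the candidate IBD
intervals; the whole genome of one case is sequenced and its variant calls
are reduced to private protein-changing candidates by subtractive
filtering against the candidate regions, an in-house control cohort and a
population variant database; the surviving candidate (a 1-bp coding
deletion causing a frameshift) is then genotyped across an extended cohort
to confirm perfect segregation and estimate the carrier frequency.

## Synthetic data generator

`SimulationConfig` defaults define the study conditions:

- **Genome / panel**: 2 chromosomes x 30 Mb, 10,000 markers on a jittered
  uniform grid (~6 kb spacing) — small enough for sub-second simulation,
  dense enough that a >1 Mb tract carries >150 markers.
- **Pedigree**: sire x dam -> MZ twin cases; extended by two affected
  maternal half-siblings (one sired by the twins' sire), giving four
  obligate-carrier parents. Chip genotypes cover the quartet; the extended
  cases enter only the pedigree and the segregation cohort, as in the
  study design being emulated.
- **Haplotype model**: founder alleles are independent Bernoulli(0.5)
  draws per marker and children are produced by per-marker gene dropping.
  No linkage disequilibrium or recombination map is modelled: the mapping
  stage consumes homozygosity, not LD decay, so the IBD structure is
  imposed directly. Within each seeded tract both case chromosomes carry
  one shared founder haplotype and each parent carries it against its
  complement (heterozygous at every tract marker). Tract boundaries are
  sharp: the two markers flanking each tract are set heterozygous in
  parents and cases, representing the recombination breakpoints that end a
  real IBD segment. Without this, 1–3 chance-homozygous markers beyond the
  seeded boundary would regularly leak into the reported region and a
  single coincidentally homozygous parent call there would veto the whole
  region at the strict default parent-conflict threshold.
- **Seeded tracts**: one 8 Mb tract (chromosome 1) and one 11 Mb tract
  (chromosome 2, hosting the causal gene) — sizes in the range reported
  for case-shared tracts in small inbred pedigrees.
- **Missingness**: 0.5% of calls are set missing, uniformly at random;
  monozygotic twins share one missingness mask so their call vectors are
  byte-identical, as a chip would effectively show for one genotype run
  per animal duplicated by identity.
- **Variant cohorts**: ~500 background coding variants (SNVs plus 10%
  1-bp deletions) at uniform CDS positions of uniformly chosen
  transcripts. Each is independently present in the index genome (p=0.6;
  homozygous with p=0.5 given present), in the 106-genome control cohort
  (p=0.85, carried by 1–10 genomes) and in the 1,119-genome population
  database (p=0.7). The high control/popdb rates reflect that most real
  coding variants segregate in the species; genuinely private background
  variants are rare (~4.5%), which is what makes the funnel informative.
  The causal deletion is homozygous in all cases, heterozygous in the
  parents, and absent from both comparison cohorts.
- **Population sample**: 1,201 controls, each heterozygous with
  probability 0.0416 (the carrier fraction), never homozygous mutant;
  1,225 other-breed animals all wild type.
- **Randomness**: every stream (genotypes / fixture / cohort) derives from
  one seed through named `numpy` `SeedSequence` children; identical config
  + seed reproduces byte-identical output files.

### The two-transcript causal gene

The gene-model fixture engineers a locus with two transcripts sharing all
downstream exons but using alternative first exons whose coding
contributions differ by 99 nt (300 vs 201). The shared sequence pins a few
codons so that deleting the G that ends codon 627 of the long transcript
(c.1881, = codon 594 / c.1782 on the short one) leaves that serine intact,
changes the next residue to valine, and meets a stop at the 9th codon of
the shifted frame: `p.Ser628Valfs9*` / `p.Ser595Valfs9*`, truncating the
881-aa protein to 635 aa (246 residues, 27.9%, lost) and the 848-aa
protein to 602 aa. Three domains (AAT, MBB, MOSC) are annotated per
protein; the frameshift removes the last two. Background single-transcript
two-exon genes (24 by default, alternating strand) are laid on a fixed
grid across both chromosomes to host background coding variants inside and
outside the seeded tracts.

### What the simulator does not emulate

Real LD and recombination maps, allele-frequency spectra, genotyping-error
modes beyond uniform missingness, sequencing/calling artifacts (quality
scores, strand bias), multi-nucleotide and structural variants, and breed
demography. Passing tests therefore demonstrate the correctness of the
*algorithms* under the assumed signal structure, not robustness to every
failure mode of real chip or sequencing data.

## Homozygosity mapping

A run of homozygosity is defined window-wise: a maximal stretch of
consecutive markers on one chromosome with at most `max_het_in_run` (0)
heterozygous and `max_missing_in_run` (2) missing calls, at least
`min_markers` (20) markers and a span of at least `min_length_bp` (1 Mb).
"Maximal" means extending either end violates a budget; with non-zero
budgets maximal windows may overlap, and all of them are reported.
Detection is a two-pointer scan (a window starting at marker *l* is
maximal iff its feasible right end exceeds that of *l−1*), exactly
equivalent to brute-force enumeration of every window — the test suite
asserts this equivalence on random ≤200-marker instances.

`shared_case_regions` merges each case's runs into a union of marker-index
ranges, intersects the unions across cases, and keeps maximal sub-ranges
where every non-missing case call is homozygous for the same allele;
survivors are re-checked against `min_markers`/`min_length_bp`. Working on
the union (rather than individual runs) makes the result insensitive to
how missing calls split an underlying tract into overlapping windows.

`exclude_parental` computes, per parent, the fraction of usable markers
(parent called, shared allele known) at which the parent is homozygous for
the case-shared allele and drops the region when any parent's fraction
strictly exceeds `max_parent_hom_fraction` (default 0.0 — any full
conflict vetoes; the knob exists for genotyping-error tolerance). A parent
homozygous for the *opposite* allele is not a conflict (it is not the
carrier pattern being excluded, and the twins could not then be homozygous
for the shared allele by descent through that parent without error).

IBS between two samples is the mean over co-called markers of a per-marker
sharing score: 1 for identical genotypes, 0.5 for sharing exactly one
allele, 0 otherwise — equivalently `1 − |g1 − g2|/2` on allele-B dosages.
This definition is stated explicitly because "IBS" has variants; it is
symmetric, bounded in [0, 100] and exactly 100 for identical vectors.

Region coordinates are 0-based half-open `[first marker, last marker + 1)`
(BED convention) internally and in BED output; 1-based only at VCF
boundaries.

## Variant triage

Filters are pure set subtractions on normalized site keys and therefore
commute (verified in tests); the funnel object enforces non-increasing
stage counts. Site identity is allele-aware: (chrom, pos, ref, alt) after
removing the shared suffix then prefix (keeping one base each side).
Left-alignment against flanking reference bases is applied only where a
base lookup is available — this pipeline carries CDS FASTA, not a genome
FASTA, and all simulated cohorts emit one consistent representation, so
trimming alone suffices for cross-cohort matching. Multi-allelic VCF
records are decomposed into biallelic records on read. The dominant
branch intentionally does not use parental chip genotypes as a filter;
de novo status would be a confirmation step, not a subtraction.

Splice disruption: a variant whose reference span crosses an exon–intron
boundary is flagged (`split-span`) but not counted as non-synonymous.

## Consequence prediction

Deletions are 3'-normalized in CDS space per transcript before naming, so
one genomic event may normalize to different c. positions on different
transcripts — which is also why the two transcripts of the causal gene
carry distinct names. Normalization shifts the deletion window right while
the base entering from the right equals the base leaving on the left; it
never changes the edited nucleotide string and is idempotent.

Frameshift naming follows the convention that the first changed residue
counts as 1, so `fs9*` means the stop is the 9th codon of the new frame
and the mutant protein length is `first_changed + 9 − 2`. When the first
shifted codon is itself a stop, the call is named like a nonsense change
(`p.Xaa#*`). A shifted frame that reaches the end of the CDS without a
stop yields an explicit no-stop call, not an error. SNVs are classified
synonymous / missense / stop-gain / stop-loss by codon comparison.
Ambiguity codes are rejected at parse time. A domain is "lost" when it
lies entirely beyond the mutant protein's end, "truncated" when the mutant
ends inside it; a domain ending exactly at the mutant length is intact.
The fraction lost is computed exactly from the two lengths (the 246/881
fixture case is 27.9%).

## Segregation

Perfect recessive association requires every affected sample homozygous
mutant and zero mutant homozygotes elsewhere; missing genotypes sit in
their own column and never enter denominators. Carrier frequency is
reported with two decimals plus a rounded integer (cohort tables of this
kind are quoted as "approximately N%"). Obligate-carrier status is derived
from the pedigree (unaffected parent of an affected individual), never
taken as input; a homozygous-reference parent of a homozygous-mutant case
is flagged as a Mendelian violation.

## Numerical and design choices

- Genotypes are int8 allele-B dosages (0/1/2, −1 missing); all ROH/IBS
  computation is vectorized on this encoding.
- Abutting runs separated by more missing calls than the budget are not
  merged at detection level (the union step in region construction handles
  fragmentation explicitly).
- PED/MAP use the PLINK text dialect (whitespace-separated, alleles as
  bases, missing = 0). On read-back, per-marker allele labels are inferred
  from observed calls, so dosage polarity may flip where the original
  labelling is unrecoverable; every downstream statistic is invariant
  under that flip.
- Reports are JSON with sorted keys and no timestamps, so identical
  config + seed reproduce byte-identical artifacts.
- Problem sizes in the test suite: oracle equivalence on ≤200-marker
  instances, 1,000 fuzzed CDS/deletion cases, and 100 full replicates at
  the default 2x30 Mb / 10,000-marker / ~500-variant scale — sizes at
  which the whole suite runs in well under a minute while still exercising
  every length scale the algorithms depend on (tracts of >100 markers,
  multi-exon projection, funnel attrition).

## Known limitations

- No support for insertions longer than a few bases spanning exon
  boundaries; such events are flagged, not named.
- Left-alignment of indels requires flanking sequence and is therefore
  only exact inside annotated CDS; fully intergenic indel representation
  drift between externally produced cohorts would need a genome reference.
- The ROH caller has no LD-aware pruning or allele-frequency weighting;
  on real chip data, common long homozygous stretches (low-recombination
  regions) would need the parent-exclusion step and, ideally, frequency
  filters to stay specific.
- `perfect_association` is a deterministic criterion, not a statistical
  test; no p-value is attached (none is defined for the zero-discordance
  claim at these cohort sizes).
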