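"""Simulate a complete recessive-disease study: pedigree, chip genotypes,
variant cohorts and gene models, at desk scale."""

from mendelmap import SimulationConfig, simulate_pedigree_genotypes
from mendelmap.intervals import GenomicInterval
from mendelmap.simulate import make_transcript_fixture, simulate_variant_cohort

config = SimulationConfig(
    genome_layout=[("1", 6_000_000), ("2", 6_000_000)],
    n_markers=1_200,
    seeded_ibd_regions=[
        GenomicInterval("1", 2_000_000, 4_000_000),
        GenomicInterval("2", 1_000_000, 5_000_000),
    ],
    n_control_genomes=20,
    n_popdb_genomes=50,
    n_population_controls=150,
    n_background_coding_variants=60,
    n_background_genes=8,
    rng_seed=1,
)

pedigree, gm = simulate_pedigree_genotypes(config)
transcripts = make_transcript_fixture(config)
cohort = simulate_variant_cohort(config, transcripts)

print("pedigree:")
for ind in pedigree:
    print(f"  {ind.id:7s} sire={ind.sire or '-':7s} dam={ind.dam or '-':7s} {ind.status}")
print(f"chip: {len(gm.samples)} samples x {gm.n_markers} markers")
print(f"seeded autozygous tracts: {[str(r) for r in config.seeded_ibd_regions]}")
print(f"case VCF: {len(cohort.case_variants)} variants "
      f"(1 seeded causal deletion at {cohort.causal})")
print(f"control cohort: {len(cohort.control_samples)} genomes, "
      f"{len(cohort.control_variants)} variant sites")
print(f"population database: {len(cohort.popdb_sites)} allele sites")

# The cases are homozygous for one founder haplotype across each seeded
# tract while both parents are heterozygous carriers - the signature the
# mapping stage is built to detect.
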