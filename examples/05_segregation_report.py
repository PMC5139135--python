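"""Tabulate candidate-variant genotypes by cohort, test perfect recessive
segregation and report the carrier frequency."""

from mendelmap import SimulationConfig, build_report
from mendelmap.simulate import (
    default_pedigree,
    make_transcript_fixture,
    simulate_variant_cohort,
)

config = SimulationConfig(rng_seed=1)
cohort = simulate_variant_cohort(config, make_transcript_fixture(config))
pedigree = default_pedigree(config)

report = build_report(
    cohort.population_genotypes,
    cohort.population_groups,
    pedigree,
    carrier_groups=["population_controls"],
)
print(report.to_text())
# perfect association: every affected animal is homozygous for the
# deletion and nobody else is; the carrier percentage estimates the
# mutant-allele reservoir segregating in the healthy population.
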