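"""Name a coding deletion on both transcripts of a gene with alternative
first exons: one genomic event, two HGVS names, and the truncation it causes."""

from mendelmap import SimulationConfig, Variant, annotate_variant
from mendelmap.simulate import make_transcript_fixture

tx_a, tx_b = make_transcript_fixture(SimulationConfig(rng_seed=1))[:2]

# the seeded 1-bp deletion: the G at c.1881 of the long transcript
g = tx_a.cdna_to_genomic(1881)
anchor = tx_a.genomic_base(g - 1)
variant = Variant(tx_a.chrom, g - 1, anchor + "G", anchor)

for tx in (tx_a, tx_b):
    call = annotate_variant(variant, tx)
    print(f"{tx.id}: {call.cdna_hgvs}  {call.protein_hgvs}  [{call.category}]")
    print(f"  wild-type {call.wildtype_protein_length} aa -> mutant "
          f"{call.mutant_protein_length} aa "
          f"({100 * call.fraction_lost:.1f}% of the protein lost)")
    print(f"  domains lost: {call.lost_domains}  truncated: {call.truncated_domains}")

# The two transcripts differ by 99 coding nt in their first exons, so the
# same genomic deletion is c.1881del on one and c.1782del on the other;
# both frameshifts hit a new stop 9 codons in (fs9*), cutting off the two
# C-terminal domains.
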