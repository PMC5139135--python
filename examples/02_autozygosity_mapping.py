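"""Map case-shared autozygous regions: runs of homozygosity present in both
affected twins but absent (heterozygous) in their parents."""

from mendelmap import RohParams, compute_ibs, detect_roh, exclude_parental, shared_case_regions
from mendelmap.simulate import SimulationConfig, simulate_pedigree_genotypes

config = SimulationConfig(rng_seed=1)  # 2 x 30 Mb, 10,000 markers
pedigree, gm = simulate_pedigree_genotypes(config)

print(f"IBS CASE1/CASE2: {compute_ibs(gm, 'CASE1', 'CASE2'):.1f}%  "
      "(100% = identical at every marker, i.e. monozygotic twins)")
print(f"IBS SIRE1/CASE1: {compute_ibs(gm, 'SIRE1', 'CASE1'):.1f}%")

params = RohParams()  # runs > 1 Mb, >= 20 markers, no hets, <= 2 missing
runs = {c: detect_roh(gm, c, params) for c in ("CASE1", "CASE2")}
print(f"runs of homozygosity per case: { {c: len(r) for c, r in runs.items()} }")

regions = shared_case_regions(runs, gm, ["CASE1", "CASE2"], params)
regions = exclude_parental(regions, gm, ["SIRE1", "DAM1"])
print("case-shared autozygous regions (parents not homozygous):")
for r in regions:
    print(f"  {r.interval}  {r.interval.length / 1e6:.2f} Mb, {r.n_markers} markers, "
          f"parent conflicts {r.parent_conflicts}")
print("truth:", [str(s) for s in config.seeded_ibd_regions])
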