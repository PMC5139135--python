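"""Synthetic study generator: pedigree, chip genotypes, variant cohorts, gene models.

Emulates the structure of a recessive disease-gene discovery study in a
livestock family: a nuclear family whose two affected calves are
monozygotic twins, extended by two affected half-siblings; dense SNP-array
genotypes in which the cases share long autozygous tracts absent in their
carrier parents; a sequenced index genome carrying a seeded 1-bp coding
deletion inside one tract; an in-house control cohort and a population
variant database from which the seeded allele is absent; and a population
sample with a few percent heterozygous carriers.

Founder haplotypes are independent draws per marker (no linkage
disequilibrium is modelled — the mapping stage consumes homozygosity, not
LD decay); autozygosity is imposed directly by copying one founder
haplotype into both case chromosomes across each seeded region while
forcing both parental genotypes heterozygous there. All randomness flows
from one seed through named child generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import AFFECTED, MISSING, UNAFFECTED, GenotypeMatrix, Individual, Pedigree
from .intervals import GenomicInterval
from .transcripts import Domain, TranscriptModel
from .variants import Variant

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMP = str.maketrans("ACGT", "TGCA")

# family member ids (chip-genotyped quartet + extended half-sib cases)
SIRE, DAM, DAM2, SIRE2 = "SIRE1", "DAM1", "DAM2", "SIRE2"


def _default_regions() -> list[GenomicInterval]:
    # one 8 Mb tract and one 11 Mb tract (the latter hosts the causal gene),
    # echoing the size range of case-shared tracts in small inbred pedigrees
    return [
        GenomicInterval("1", 10_000_000, 18_000_000),
        GenomicInterval("2", 5_000_000, 16_000_000),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    genome_layout: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 30_000_000), ("2", 30_000_000)]
    )
    n_markers: int = 10_000
    marker_jitter_bp: int = 1_000
    n_cases: int = 2
    mz_twin_pair: bool = True
    n_extra_cases: int = 2
    seeded_ibd_regions: list[GenomicInterval] = field(default_factory=_default_regions)
    n_control_genomes: int = 106
    n_popdb_genomes: int = 1_119
    n_population_controls: int = 1_201
    carrier_fraction: float = 0.0416  # ~4% heterozygous carriers
    n_background_coding_variants: int = 500
    n_background_genes: int = 24
    causal_variant_spec: tuple[str, int, str, str] | None = None  # derived if None
    allele_freq: float = 0.5
    missing_rate: float = 0.005
    # cross-cohort sharing of background variants: most real variants are
    # segregating in the species, so control/popdb hit rates are high and
    # genuinely private background variants are rare
    p_case: float = 0.6
    p_hom_given_case: float = 0.5
    p_in_controls: float = 0.85
    p_in_popdb: float = 0.7
    deletion_fraction: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        layout = dict(self.genome_layout)
        for i, region in enumerate(self.seeded_ibd_regions):
            if region.chrom not in layout or region.end > layout[region.chrom]:
                raise ConfigurationError(f"seeded region {region} outside genome layout")
            for other in self.seeded_ibd_regions[i + 1 :]:
                if region.overlaps(other):
                    raise ConfigurationError(
                        f"seeded regions overlap: {region} and {other}"
                    )
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ConfigurationError("carrier_fraction must be in [0, 1]")
        if self.n_cases < 1:
            raise ConfigurationError("need at least one case")
        if self.mz_twin_pair and self.n_cases < 2:
            raise ConfigurationError("a twin pair needs n_cases >= 2")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator; independent per stream, reproducible."""
        digest = sum(ord(ch) * 31**i for i, ch in enumerate(stream)) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.rng_seed, digest]))


def default_pedigree(config: SimulationConfig) -> Pedigree:
    """Nuclear family with MZ-twin cases plus two affected half-siblings.

    The extended cases share a dam; one is sired by the twins' sire, so all
    four parents are obligate carriers.
    """
    inds = [
        Individual(SIRE, sex="male", status=UNAFFECTED),
        Individual(DAM, sex="female", status=UNAFFECTED),
    ]
    for i in range(1, config.n_cases + 1):
        inds.append(Individual(f"CASE{i}", SIRE, DAM, "female", AFFECTED))
    if config.n_extra_cases > 0:
        inds.append(Individual(DAM2, sex="female", status=UNAFFECTED))
        inds.append(Individual(SIRE2, sex="male", status=UNAFFECTED))
        sires = [SIRE, SIRE2]
        for i in range(config.n_extra_cases):
            inds.append(
                Individual(
                    f"CASE{config.n_cases + i + 1}",
                    sires[i % 2],
                    DAM2,
                    "male",
                    AFFECTED,
                )
            )
    return Pedigree(inds)


def chip_cases(config: SimulationConfig) -> list[str]:
    return [f"CASE{i}" for i in range(1, config.n_cases + 1)]


def _marker_positions(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    total = sum(length for _, length in config.genome_layout)
    rows = []
    remaining = config.n_markers
    for k, (chrom, length) in enumerate(config.genome_layout):
        n = remaining if k == len(config.genome_layout) - 1 else round(
            config.n_markers * length / total
        )
        remaining -= n
        spacing = length / (n + 1)
        jitter_max = min(config.marker_jitter_bp, int(spacing / 2) - 1)
        base = (np.arange(1, n + 1) * spacing).astype(np.int64)
        jitter = rng.integers(-jitter_max, jitter_max + 1, size=n) if jitter_max > 0 else 0
        pos = np.clip(base + jitter, 1, length - 1)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    markers = pd.concat(rows, ignore_index=True)
    bases = np.array(list("ACGT"))
    pick = rng.integers(0, 4, size=(len(markers)))
    alt = (pick + 1 + rng.integers(0, 3, size=len(markers))) % 4
    markers["a1"] = bases[pick]
    markers["a2"] = bases[alt]
    return markers


def simulate_pedigree_genotypes(config: SimulationConfig) -> tuple[Pedigree, GenotypeMatrix]:
    """Gene-drop chip genotypes for the quartet and seed autozygous tracts.

    Chip samples are the sire, the dam and the cases; within every seeded
    region all cases are homozygous for one shared founder haplotype and
    each parent is a heterozygous carrier of it. Monozygotic twins receive
    byte-identical call vectors (including the missingness mask).
    """
    config.validate()
    pedigree = default_pedigree(config)
    rng = config.rng("genotypes")
    markers = _marker_positions(config, rng)
    n = len(markers)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()

    cases = chip_cases(config)
    samples = [SIRE, DAM] + cases

    haps = {
        SIRE: rng.random((2, n)) < config.allele_freq,
        DAM: rng.random((2, n)) < config.allele_freq,
    }
    for case in cases:
        pick_s = rng.integers(0, 2, size=n)
        pick_d = rng.integers(0, 2, size=n)
        haps[case] = np.stack(
            [
                np.take_along_axis(haps[SIRE], pick_s[None, :], axis=0)[0],
                np.take_along_axis(haps[DAM], pick_d[None, :], axis=0)[0],
            ]
        )
        if config.mz_twin_pair and case == cases[1]:
            haps[case] = haps[cases[0]].copy()

    for region in config.seeded_ibd_regions:
        in_region = (chrom_arr == region.chrom) & (pos_arr >= region.start) & (
            pos_arr < region.end
        )
        if not in_region.any():
            raise ConfigurationError(f"seeded region {region} contains no marker")
        shared = rng.random(int(in_region.sum())) < config.allele_freq
        for parent in (SIRE, DAM):
            haps[parent][0, in_region] = shared
            haps[parent][1, in_region] = ~shared
        for case in cases:
            haps[case][0, in_region] = shared
            haps[case][1, in_region] = shared
        # sharp tract boundaries: the autozygous segment ends at a
        # recombination breakpoint, so the cases are heterozygous at the
        # markers flanking the tract (two per side, same chromosome)
        idx = np.nonzero(in_region)[0]
        chrom_idx = np.nonzero(chrom_arr == region.chrom)[0]
        lo, hi = chrom_idx[0], chrom_idx[-1]
        flanks = [i for i in (idx[0] - 1, idx[0] - 2, idx[-1] + 1, idx[-1] + 2)
                  if lo <= i <= hi]
        for member in (SIRE, DAM, *cases):
            haps[member][0, flanks] = False
            haps[member][1, flanks] = True

    calls = np.zeros((len(samples), n), dtype=np.int8)
    for s, sample in enumerate(samples):
        calls[s] = haps[sample].sum(axis=0)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        if config.mz_twin_pair:
            twin2 = samples.index(cases[1])
            mask[twin2] = mask[samples.index(cases[0])]
        calls[mask] = MISSING

    return pedigree, GenotypeMatrix(markers, samples, calls)


# ---------------------------------------------------------------------------
# gene-model fixture


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n)]


def make_transcript_fixture(config: SimulationConfig) -> list[TranscriptModel]:
    """Gene models: one two-transcript causal gene plus background genes.

    The causal gene mimics a molybdenum-cofactor-sulfurase-like locus: two
    transcripts share all downstream exons but use alternative first exons
    whose coding contributions differ by 99 nt, so one genomic deletion
    maps to two cDNA names 99 apart (and two protein names 33 residues
    apart). Both proteins carry three named domains (AAT, MBB, MOSC); the
    engineered frameshift truncates the protein upstream of the last two.
    Background single-transcript genes are laid on a fixed grid over both
    chromosomes, alternating strand, to host background coding variants in
    and out of the seeded autozygous regions.
    """
    config.validate()
    rng = config.rng("fixture")

    # --- causal gene: shared coding part (782 codons, terminal TAA) -------
    shared_codons = _random_codons(rng, 782)
    shared_codons[-1] = "TAA"
    pinned = {527: "TCG", 528: "AGT", 536: "CTA", 537: "AAA"}
    for k in range(529, 536):
        pinned[k] = "GCT"
    for k, codon in pinned.items():
        shared_codons[k - 1] = codon
    shared = "".join(shared_codons)
    prefix_a = "ATG" + "".join(_random_codons(rng, 99))   # 300 nt
    prefix_b = "ATG" + "".join(_random_codons(rng, 66))   # 201 nt
    cds_a = prefix_a + shared
    cds_b = prefix_b + shared

    causal_region = _causal_region(config)
    gstart = causal_region.start + (causal_region.length - 20_000) // 2
    chrom = causal_region.chrom
    exon1a = GenomicInterval(chrom, gstart, gstart + 300)
    exon1b = GenomicInterval(chrom, gstart + 1_000, gstart + 1_201)
    shared_sizes = [200] * 7 + [300, 300, 346]
    shared_exons = []
    cursor = gstart + 2_000
    for size in shared_sizes:
        shared_exons.append(GenomicInterval(chrom, cursor, cursor + size))
        cursor += size + 500  # 500 bp introns

    domains_a = [Domain("AAT", 50, 500), Domain("MBB", 640, 720), Domain("MOSC", 740, 860)]
    domains_b = [Domain(d.name, d.aa_start - 33, d.aa_end - 33) for d in domains_a]
    tx_a = TranscriptModel(
        "TX-201", "MCSU", chrom, "+", [exon1a] + shared_exons, cds_a, domains_a
    )
    tx_b = TranscriptModel(
        "TX-202", "MCSU", chrom, "+", [exon1b] + shared_exons, cds_b, domains_b
    )
    transcripts = [tx_a, tx_b]

    # --- background genes on a fixed grid ---------------------------------
    layout = config.genome_layout
    total = sum(length for _, length in layout)
    slots: list[tuple[str, int]] = []
    for bchrom, length in layout:
        count = max(1, round(config.n_background_genes * length / total))
        step = length // (count + 1)
        for i in range(1, count + 1):
            start = i * step
            if bchrom == chrom and abs(start - gstart) < 30_000:
                continue  # keep clear of the causal locus
            slots.append((bchrom, start))
    for g, (bchrom, start) in enumerate(slots[: config.n_background_genes], 1):
        codons = ["ATG"] + _random_codons(rng, 498) + ["TAA"]
        cds = "".join(codons)  # 1500 nt
        strand = "+" if g % 2 else "-"
        e1 = GenomicInterval(bchrom, start, start + 900)
        e2 = GenomicInterval(bchrom, start + 1_400, start + 2_000)
        exons = [e1, e2] if strand == "+" else [e2, e1]
        transcripts.append(
            TranscriptModel(f"BGTX{g:03d}", f"BG{g:03d}", bchrom, strand, exons, cds)
        )
    return transcripts


def _causal_region(config: SimulationConfig) -> GenomicInterval:
    """The seeded region hosting the causal gene (the last, by convention)."""
    if not config.seeded_ibd_regions:
        raise ConfigurationError("no seeded regions to host the causal variant")
    return config.seeded_ibd_regions[-1]


CAUSAL_CDS_POSITION_A = 1881  # c. position of the deleted G on transcript A


def causal_variant_site(
    config: SimulationConfig, transcripts: list[TranscriptModel]
) -> tuple[str, int, str, str]:
    """VCF-style (chrom, pos, ref, alt) of the seeded 1-bp coding deletion."""
    if config.causal_variant_spec is not None:
        return config.causal_variant_spec
    tx_a = transcripts[0]
    g = tx_a.cdna_to_genomic(CAUSAL_CDS_POSITION_A)
    anchor = tx_a.genomic_base(g - 1)
    deleted = tx_a.genomic_base(g)
    return (tx_a.chrom, g - 1, anchor + deleted, anchor)


# ---------------------------------------------------------------------------
# variant cohorts


@dataclass
class VariantCohort:
    """Everything the triage and segregation stages consume."""

    family_samples: list[str]
    case_variants: list[Variant]           # index-case VCF content (family GTs)
    control_samples: list[str]
    control_variants: list[Variant]
    popdb_sites: list[tuple[str, int, str, str]]
    population_genotypes: dict[str, int]   # causal-variant genotypes by sample
    population_groups: dict[str, str]
    causal: Variant


def simulate_variant_cohort(
    config: SimulationConfig, transcripts: list[TranscriptModel]
) -> VariantCohort:
    """Scatter background coding variants across cohorts and seed the causal one.

    Background variants (SNVs plus a fraction of 1-bp deletions) land at
    uniform CDS positions of uniformly chosen transcripts; each is
    independently present in the index genome, the control cohort and the
    population database with the configured probabilities. The causal
    deletion is homozygous in every case, heterozygous in all four parents,
    and absent from both comparison cohorts; among population controls a
    carrier fraction is heterozygous and nobody is homozygous mutant.
    """
    config.validate()
    rng = config.rng("cohort")
    layout = dict(config.genome_layout)
    for tx in transcripts:
        last = max(e.end for e in tx.exons)
        if tx.chrom not in layout or last > layout[tx.chrom]:
            raise ConfigurationError(f"transcript {tx.id} outside genome layout")

    chrom, pos, ref, alt = causal_variant_site(config, transcripts)
    hosts = [
        r for r in config.seeded_ibd_regions if r.chrom == chrom and r.contains_point(pos)
    ]
    if len(hosts) != 1:
        raise ConfigurationError(
            "causal variant must lie in exactly one seeded autozygous region"
        )
    in_cds = any(
        tx.chrom == chrom and any(e.contains_point(pos) for e in tx.exons)
        for tx in transcripts
    )
    if not in_cds:
        raise ConfigurationError("causal variant must be a coding variant (inside a CDS)")

    cases = chip_cases(config)
    extra = [f"CASE{config.n_cases + i + 1}" for i in range(config.n_extra_cases)]
    parents = [SIRE, DAM] + ([DAM2, SIRE2] if config.n_extra_cases else [])
    family = [SIRE, DAM] + cases
    causal = Variant(
        chrom, pos, ref, alt,
        {**{c: 2 for c in cases}, SIRE: 1, DAM: 1},
    )

    control_samples = [f"CTL{i:04d}" for i in range(1, config.n_control_genomes + 1)]
    case_variants: list[Variant] = [causal]
    control_variants: list[Variant] = []
    popdb_sites: list[tuple[str, int, str, str]] = []
    seen: set[tuple[str, int, str, str]] = {(chrom, pos, ref, alt)}

    made = 0
    attempts = 0
    while made < config.n_background_coding_variants and attempts < 50 * (
        config.n_background_coding_variants + 1
    ):
        attempts += 1
        tx = transcripts[int(rng.integers(0, len(transcripts)))]
        site = _random_coding_site(tx, rng, config)
        if site is None or site in seen:
            continue
        seen.add(site)
        made += 1
        vchrom, vpos, vref, valt = site

        in_case = rng.random() < config.p_case
        in_controls = rng.random() < config.p_in_controls
        in_popdb = rng.random() < config.p_in_popdb
        if in_case:
            hom = rng.random() < config.p_hom_given_case
            gts = {c: (2 if hom else 1) for c in cases}
            gts[SIRE] = 1
            gts[DAM] = 1 if hom else 0
            case_variants.append(Variant(vchrom, vpos, vref, valt, gts))
        if in_controls:
            k = int(rng.integers(1, 11))
            carriers = rng.choice(len(control_samples), size=min(k, len(control_samples)), replace=False)
            gts = {control_samples[i]: 1 for i in carriers}
            control_variants.append(Variant(vchrom, vpos, vref, valt, gts))
        if in_popdb:
            popdb_sites.append(site)
    if made < config.n_background_coding_variants:
        raise ConfigurationError("could not place the requested background variants")

    # causal-variant genotypes for the segregation stage
    genotypes: dict[str, int] = {}
    groups: dict[str, str] = {}
    for c in cases + extra:
        genotypes[c] = 2
        groups[c] = "affected"
    for p in parents:
        genotypes[p] = 1
        groups[p] = "obligate_carriers"
    carrier_draw = rng.random(config.n_population_controls) < config.carrier_fraction
    for i in range(config.n_population_controls):
        s = f"POP{i + 1:04d}"
        genotypes[s] = 1 if carrier_draw[i] else 0
        groups[s] = "population_controls"
    for i in range(config.n_control_genomes + config.n_popdb_genomes):
        s = f"OB{i + 1:04d}"
        genotypes[s] = 0
        groups[s] = "other_breeds"

    return VariantCohort(
        family_samples=family,
        case_variants=sorted(case_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)),
        control_samples=control_samples,
        control_variants=sorted(control_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)),
        popdb_sites=sorted(popdb_sites),
        population_genotypes=genotypes,
        population_groups=groups,
        causal=causal,
    )


def _random_coding_site(
    tx: TranscriptModel, rng: np.random.Generator, config: SimulationConfig
) -> tuple[str, int, str, str] | None:
    """One random SNV or 1-bp deletion inside the transcript's CDS.

    Returns a VCF-style site or None when the draw is unusable (e.g. a
    deletion whose anchor base would fall outside the exon).
    """
    c = int(rng.integers(4, tx.cds_length - 3))  # keep clear of start/stop codons
    g = tx.cdna_to_genomic(c)
    if rng.random() < config.deletion_fraction:
        # genomic deletion of the base at g, anchored one base left
        try:
            g_del = g
            anchor_c = tx.genomic_to_cdna(g_del - 1)
        except Exception:
            return None
        if abs(anchor_c - c) != 1:  # anchor must be the adjacent cDNA base
            return None
        return (tx.chrom, g_del - 1, tx.genomic_base(g_del - 1) + tx.genomic_base(g_del), tx.genomic_base(g_del - 1))
    base = tx.genomic_base(g)
    others = [b for b in "ACGT" if b != base]
    alt = others[int(rng.integers(0, 3))]
    return (tx.chrom, g, base, alt)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, rng_seed=int(seed))
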