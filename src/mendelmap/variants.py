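"""Variant records, site normalization and VCF v4.2 I/O.

Multi-allelic VCF records are decomposed into biallelic (site, allele)
pairs on read. Before any cross-cohort comparison, alleles are reduced to
a parsimonious representation (shared suffix then shared prefix removed,
at least one base kept on each side), so that the same indel written with
different anchor padding in two files still matches. Left-alignment
against flanking reference sequence is applied when a base lookup is
available; the pipeline's own writers emit one consistent representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import pysam

MISSING = -1

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class Variant:
    """A biallelic variant with per-sample allele-dosage genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref/alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        for seq in (self.ref, self.alt):
            if set(seq) - set("ACGT"):
                raise ValueError(f"non-ACGT allele {seq!r}")

    def genotype(self, sample: str) -> int:
        return self.genotypes.get(sample, MISSING)

    def site_key(self, base_at: Callable[[str, int], str | None] | None = None) -> tuple:
        """Normalized (chrom, pos, ref, alt) identity for cross-cohort matching."""
        return normalize_site(self.chrom, self.pos, self.ref, self.alt, base_at)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    base_at: Callable[[str, int], str | None] | None = None,
) -> tuple[str, int, str, str]:
    """Parsimony-trim an allele pair; left-align if flanking bases are known.

    base_at(chrom, pos) may return None where the reference is unknown, in
    which case left-alignment stops there.
    """
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if base_at is not None and len(ref) != len(alt):
        # left-align pure indels: roll left while the trailing base matches
        # the base preceding the event
        while ref[-1] == alt[-1] and pos > 1:
            prev = base_at(chrom, pos - 1)
            if prev is None:
                break
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            if ref[-1] != alt[-1]:
                break
    return chrom, pos, ref, alt


# ---------------------------------------------------------------------------
# VCF I/O (text, v4.2)


def write_vcf(
    variants: Iterable[Variant],
    samples: list[str],
    path: str | Path,
    contigs: list[tuple[str, int]] | None = None,
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs or []:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    for v in ordered:
        gts = "\t".join(_GT_STR[v.genotype(s)] for s in samples)
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[list[Variant], list[str]]:
    """Read a VCF, decomposing multi-allelic records into biallelic variants."""
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for k, alt in enumerate(rec.alts or (), start=1):
                if alt is None or set(alt.upper()) - set("ACGT"):
                    warnings.warn(f"skipping symbolic/ambiguous alt at {rec.chrom}:{rec.pos}")
                    continue
                genotypes: dict[str, int] = {}
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes[sample] = MISSING
                    else:
                        genotypes[sample] = sum(1 for a in gt if a == k)
                variants.append(
                    Variant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), genotypes)
                )
    return variants, samples


def collect_alt_sites(
    variants: Iterable[Variant],
    base_at: Callable[[str, int], str | None] | None = None,
) -> set[tuple]:
    """Normalized keys of sites where at least one sample carries the alt allele."""
    keys = set()
    for v in variants:
        if any(g in (1, 2) for g in v.genotypes.values()):
            keys.add(v.site_key(base_at))
    return keys


def write_site_list(sites: Iterable[tuple[str, int, str, str]], path: str | Path) -> None:
    """Write a population-database allele list as TSV (chrom, pos, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(sites):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_site_list(
    path: str | Path,
    base_at: Callable[[str, int], str | None] | None = None,
) -> set[tuple]:
    keys = set()
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chrom")
        for line in fh:
            chrom, pos, ref, alt = line.split()
            keys.add(normalize_site(chrom, int(pos), ref, alt, base_at))
    return keys
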