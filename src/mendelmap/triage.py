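"""Triple-step private-variant triage under recessive and dominant hypotheses.

The recessive branch starts from homozygous coding variants of the index
case and successively (I) restricts to the case-shared autozygous regions,
(II) removes every variant whose alternate allele is seen in any genome of
an in-house control cohort, (III) removes variants present in a large
population variant database, and finally keeps only variants with a
protein-changing consequence. "Private" means zero observations of the
alternate allele in any comparison genome; matching is allele-aware on the
normalized (chrom, pos, ref, alt) key, so a different alternate allele at
the same site does not mask a variant. The dominant (de novo) branch runs
the same cohort subtractions on heterozygous coding variants, without a
region restriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .consequence import (
    NON_CODING,
    NONSYNONYMOUS_CATEGORIES,
    SPLIT_SPAN,
    ConsequenceCall,
    annotate_variant,
)
from .roh import CandidateRegion
from .transcripts import TranscriptModel
from .variants import Variant

HOM_ALT = "hom-alt"
HET = "het"
_ZYGOSITY_CODE = {HOM_ALT: 2, HET: 1}


@dataclass
class TriageFunnel:
    """Ordered stages with surviving variants; counts must be non-increasing."""

    stages: list[tuple[str, list[Variant]]] = field(default_factory=list)

    def add(self, name: str, variants: list[Variant]) -> list[Variant]:
        if self.stages and len(variants) > len(self.stages[-1][1]):
            raise ValueError("funnel stage grew: filters must be subtractive")
        self.stages.append((name, list(variants)))
        return variants

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(vs) for name, vs in self.stages}

    @property
    def final(self) -> list[Variant]:
        return self.stages[-1][1] if self.stages else []


def cds_interval_tree(transcripts: list[TranscriptModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree of CDS exons (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        tree = trees.setdefault(tx.chrom, IntervalTree())
        for exon in tx.exons:
            tree.addi(exon.start, exon.end, tx.id)
    return trees


def select_coding_by_zygosity(
    variants: list[Variant],
    transcripts: list[TranscriptModel],
    zygosity: str,
    index_sample: str,
) -> list[Variant]:
    """Variants whose reference span touches a CDS exon, with the required
    genotype in the index case. Deduplicated by normalized site key."""
    if zygosity not in _ZYGOSITY_CODE:
        raise ValueError(f"zygosity must be one of {sorted(_ZYGOSITY_CODE)}")
    want = _ZYGOSITY_CODE[zygosity]
    trees = cds_interval_tree(transcripts)
    out: list[Variant] = []
    seen: set[tuple] = set()
    for v in variants:
        if v.chrom not in trees:
            warnings.warn(f"variant {v} on unknown chromosome; excluded")
            continue
        if v.genotype(index_sample) != want:
            continue
        # 0-based half-open span of the reference allele
        if not trees[v.chrom].overlap(v.pos - 1, v.pos - 1 + len(v.ref)):
            continue
        key = v.site_key()
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


def filter_step1_regions(
    variants: list[Variant], regions: list[CandidateRegion]
) -> list[Variant]:
    """Keep variants positioned inside a case-shared autozygous region."""
    intervals = [r.interval if isinstance(r, CandidateRegion) else r for r in regions]
    out = []
    for v in variants:
        pos0 = v.pos - 1
        if any(iv.chrom == v.chrom and iv.contains_point(pos0) for iv in intervals):
            out.append(v)
    return out


def filter_step2_controls(variants: list[Variant], control_sites: set[tuple]) -> list[Variant]:
    """Drop variants whose alternate allele occurs in any control genome."""
    return [v for v in variants if v.site_key() not in control_sites]


def filter_step3_popdb(variants: list[Variant], popdb_sites: set[tuple]) -> list[Variant]:
    """Drop variants present in the population variant database site list."""
    return [v for v in variants if v.site_key() not in popdb_sites]


def select_nonsynonymous(
    variants: list[Variant], transcripts: list[TranscriptModel]
) -> tuple[list[Variant], dict[str, list[ConsequenceCall]]]:
    """Keep variants with a protein-changing call on at least one transcript.

    Returns the surviving variants and every per-transcript consequence
    call (including those of dropped variants, for reporting). Variants
    whose only signal is a span across an exon-intron boundary are flagged
    via their SPLIT_SPAN calls but not counted as non-synonymous.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, []).append(tx)
    kept: list[Variant] = []
    calls: dict[str, list[ConsequenceCall]] = {}
    for v in variants:
        vcalls = []
        for tx in by_chrom.get(v.chrom, []):
            call = annotate_variant(v, tx)
            if call.category != NON_CODING:
                vcalls.append(call)
        calls[str(v)] = vcalls
        if any(c.category in NONSYNONYMOUS_CATEGORIES for c in vcalls):
            kept.append(v)
    return kept, calls


def recessive_branch(
    case_variants: list[Variant],
    index_sample: str,
    regions: list[CandidateRegion],
    control_sites: set[tuple],
    popdb_sites: set[tuple],
    transcripts: list[TranscriptModel],
) -> tuple[list[Variant], TriageFunnel, dict[str, list[ConsequenceCall]]]:
    """Homozygous funnel: coding -> autozygous regions -> controls -> popdb -> non-synonymous."""
    funnel = TriageFunnel()
    v = funnel.add(
        "coding-homozygous",
        select_coding_by_zygosity(case_variants, transcripts, HOM_ALT, index_sample),
    )
    v = funnel.add("I-autozygous-regions", filter_step1_regions(v, regions))
    v = funnel.add("II-control-genomes", filter_step2_controls(v, control_sites))
    v = funnel.add("III-population-db", filter_step3_popdb(v, popdb_sites))
    kept, calls = select_nonsynonymous(v, transcripts)
    funnel.add("non-synonymous", kept)
    return kept, funnel, calls


def dominant_branch(
    case_variants: list[Variant],
    index_sample: str,
    control_sites: set[tuple],
    popdb_sites: set[tuple],
    transcripts: list[TranscriptModel],
) -> tuple[list[Variant], TriageFunnel, dict[str, list[ConsequenceCall]]]:
    """Heterozygous (possible de novo) funnel; no region restriction."""
    funnel = TriageFunnel()
    v = funnel.add(
        "coding-heterozygous",
        select_coding_by_zygosity(case_variants, transcripts, HET, index_sample),
    )
    v = funnel.add("II-control-genomes", filter_step2_controls(v, control_sites))
    v = funnel.add("III-population-db", filter_step3_popdb(v, popdb_sites))
    kept, calls = select_nonsynonymous(v, transcripts)
    funnel.add("non-synonymous", kept)
    return kept, funnel, calls
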