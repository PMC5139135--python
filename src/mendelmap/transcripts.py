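"""Transcript models: exon chains, CDS sequences, protein domains.

Gene models in this pipeline carry no UTRs: each exon is entirely coding,
so transcript coordinates and CDS (c.) coordinates coincide. The coding
sequence itself travels in a separate FASTA keyed by transcript id, which
keeps a whole-genome reference out of the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .intervals import GenomicInterval


@dataclass(frozen=True)
class Domain:
    name: str
    aa_start: int  # 1-based inclusive
    aa_end: int    # 1-based inclusive


class ProjectionError(Exception):
    """Raised when a genomic position cannot be mapped into a CDS."""


class NonCodingPosition(ProjectionError):
    """Position falls outside every exon of the transcript."""


class SplitSpan(ProjectionError):
    """A multi-base reference span crosses an exon-intron boundary."""


@dataclass
class TranscriptModel:
    """One transcript: ordered coding exons, CDS sequence, protein domains.

    exons are genomic half-open intervals stored in 5'->3' transcript
    order (descending genomic coordinate on the minus strand).
    """

    id: str
    gene: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_seq: str
    domains: list[Domain] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        span = sum(e.length for e in self.exons)
        if span != len(self.cds_seq):
            raise ValueError(
                f"{self.id}: exon span {span} != CDS length {len(self.cds_seq)}"
            )
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        if set(self.cds_seq) - set("ACGT"):
            raise ValueError(f"{self.id}: CDS contains non-ACGT characters")
        prot = str(Seq(self.cds_seq).translate())
        if not prot.endswith("*") or "*" in prot[:-1]:
            raise ValueError(f"{self.id}: translation must have exactly one terminal stop")
        for d in self.domains:
            if not (1 <= d.aa_start <= d.aa_end <= self.protein_length):
                raise ValueError(f"{self.id}: domain {d.name} outside protein")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def protein_length(self) -> int:
        """Length of the translated protein, stop codon excluded."""
        return len(self.cds_seq) // 3 - 1

    @property
    def protein(self) -> str:
        return str(Seq(self.cds_seq).translate())[:-1]

    # -- coordinate projection ------------------------------------------------

    def genomic_to_cdna(self, gpos: int) -> int:
        """Map a 1-based genomic position to a 1-based c. position.

        Honors strand: on the minus strand the transcript runs down the
        genomic coordinate, so c.1 is the highest genomic base of the
        first exon.
        """
        offset = 0
        for exon in self.exons:
            g0 = gpos - 1
            if exon.start <= g0 < exon.end:
                if self.strand == "+":
                    return offset + (g0 - exon.start) + 1
                return offset + (exon.end - 1 - g0) + 1
            offset += exon.length
        raise NonCodingPosition(f"{self.chrom}:{gpos} outside exons of {self.id}")

    def cdna_to_genomic(self, cpos: int) -> int:
        """Inverse of genomic_to_cdna; returns a 1-based genomic position."""
        if not 1 <= cpos <= self.cds_length:
            raise ProjectionError(f"c.{cpos} outside CDS of {self.id}")
        offset = 0
        for exon in self.exons:
            if cpos <= offset + exon.length:
                within = cpos - offset - 1
                if self.strand == "+":
                    return exon.start + within + 1
                return exon.end - within
            offset += exon.length
        raise AssertionError("unreachable")

    def project_span(self, gstart: int, glen: int) -> tuple[int, int]:
        """Project a 1-based genomic span of glen bases into c. coordinates.

        Returns (c_start, c_end) with c_start <= c_end. Raises SplitSpan if
        the span crosses an exon boundary, NonCodingPosition if outside.
        """
        cpos = []
        misses = 0
        for g in (gstart, gstart + glen - 1):
            try:
                cpos.append(self.genomic_to_cdna(g))
            except NonCodingPosition:
                misses += 1
        if misses == 2:
            raise NonCodingPosition(
                f"{self.chrom}:{gstart}-{gstart + glen - 1} outside exons of {self.id}"
            )
        if misses == 1:
            raise SplitSpan(
                f"{self.chrom}:{gstart} span of {glen} crosses an exon boundary in {self.id}"
            )
        cpos.sort()
        if cpos[1] - cpos[0] != glen - 1:
            raise SplitSpan(
                f"{self.chrom}:{gstart} span of {glen} crosses an exon boundary in {self.id}"
            )
        return cpos[0], cpos[1]

    def genomic_base(self, gpos: int) -> str:
        """Reference base at a genomic position inside an exon (genomic strand)."""
        c = self.genomic_to_cdna(gpos)
        base = self.cds_seq[c - 1]
        if self.strand == "-":
            base = str(Seq(base).reverse_complement())
        return base


# ---------------------------------------------------------------------------
# GFF3 + FASTA + domain-table I/O


def write_gene_models(
    transcripts: list[TranscriptModel],
    gff_path: str | Path,
    fasta_path: str | Path,
    domains_path: str | Path,
) -> None:
    """Serialize transcripts as GFF3 (gene/mRNA/exon/CDS), CDS FASTA and a domain TSV."""
    lines = ["##gff-version 3"]
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene, []).append(tx)
    for gene_id, txs in genes.items():
        chrom = txs[0].chrom
        strand = txs[0].strand
        gstart = min(e.start for t in txs for e in t.exons)
        gend = max(e.end for t in txs for e in t.exons)
        lines.append(
            f"{chrom}\tmendelmap\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gene_id}"
        )
        for tx in txs:
            tstart = min(e.start for e in tx.exons)
            tend = max(e.end for e in tx.exons)
            lines.append(
                f"{chrom}\tmendelmap\tmRNA\t{tstart + 1}\t{tend}\t.\t{strand}\t.\t"
                f"ID={tx.id};Parent={gene_id}"
            )
            phase = 0
            for i, exon in enumerate(tx.exons, 1):
                common = f"{chrom}\tmendelmap"
                coords = f"{exon.start + 1}\t{exon.end}"
                lines.append(
                    f"{common}\texon\t{coords}\t.\t{strand}\t.\t"
                    f"ID={tx.id}.exon{i};Parent={tx.id}"
                )
                lines.append(
                    f"{common}\tCDS\t{coords}\t.\t{strand}\t{phase}\t"
                    f"ID={tx.id}.cds{i};Parent={tx.id}"
                )
                phase = (3 - ((exon.length - phase) % 3)) % 3
    Path(gff_path).write_text("\n".join(lines) + "\n")

    with open(fasta_path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.id}\n")
            for i in range(0, len(tx.cds_seq), 60):
                fh.write(tx.cds_seq[i : i + 60] + "\n")

    rows = [
        {"transcript": tx.id, "domain": d.name, "aa_start": d.aa_start, "aa_end": d.aa_end}
        for tx in transcripts
        for d in tx.domains
    ]
    pd.DataFrame(rows, columns=["transcript", "domain", "aa_start", "aa_end"]).to_csv(
        domains_path, sep="\t", index=False
    )


def read_gene_models(
    gff_path: str | Path,
    fasta_path: str | Path,
    domains_path: str | Path | None = None,
) -> list[TranscriptModel]:
    """Load transcripts from GFF3 + CDS FASTA (+ optional domain TSV)."""
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    domain_map: dict[str, list[Domain]] = {}
    if domains_path is not None:
        dom = pd.read_csv(domains_path, sep="\t")
        for row in dom.itertuples(index=False):
            domain_map.setdefault(str(row.transcript), []).append(
                Domain(str(row.domain), int(row.aa_start), int(row.aa_end))
            )

    transcripts: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = sorted(
            db.children(mrna, featuretype="CDS"),
            key=lambda f: f.start,
            reverse=(mrna.strand == "-"),
        )
        intervals = [GenomicInterval(mrna.seqid, f.start - 1, f.end) for f in exons]
        if mrna.id not in seqs:
            raise ValueError(f"no CDS sequence for transcript {mrna.id}")
        transcripts.append(
            TranscriptModel(
                id=mrna.id,
                gene=gene,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=intervals,
                cds_seq=seqs[mrna.id],
                domains=domain_map.get(mrna.id, []),
            )
        )
    return transcripts
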