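"""Protein-consequence prediction and HGVS naming for coding variants.

The central use case is the 1-bp coding deletion: shift it to its most 3'
equivalent position within the CDS (the HGVS normalization rule), apply
the edit, translate, and name the resulting frameshift as
``p.<Wt><pos><New>fs<N>*`` where the first changed residue counts as 1 and
N is the position of the new stop codon in the shifted reading frame.
Because alternative transcripts of one gene can have first exons of
different lengths, the same genomic deletion legitimately receives a
different c. (and p.) name on each transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .transcripts import NonCodingPosition, SplitSpan, TranscriptModel
from .variants import Variant

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "E": "Glu",
    "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAIN = "stop-gain"
STOP_LOSS = "stop-loss"
FRAMESHIFT = "frameshift"
INFRAME_INDEL = "inframe-indel"
NON_CODING = "non-coding"
SPLIT_SPAN = "split-span"

NONSYNONYMOUS_CATEGORIES = {MISSENSE, STOP_GAIN, STOP_LOSS, FRAMESHIFT, INFRAME_INDEL}


@dataclass(frozen=True)
class CdsDeletion:
    pos: int      # 1-based c. position of the first deleted base
    length: int = 1


@dataclass(frozen=True)
class CdsSNV:
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CdsInsertion:
    pos: int      # insertion occurs after this c. position
    seq: str


@dataclass
class ConsequenceCall:
    """Predicted effect of one variant on one transcript."""

    transcript_id: str
    category: str
    cdna_hgvs: str = ""
    protein_hgvs: str = ""
    mutant_protein_length: int = 0
    wildtype_protein_length: int = 0
    fraction_lost: float = 0.0
    stop_offset: int | None = None  # fs*N offset; first changed residue = 1
    no_stop: bool = False
    lost_domains: list[str] = field(default_factory=list)
    truncated_domains: list[str] = field(default_factory=list)


def aa3(aa: str) -> str:
    return _AA3[aa]


def normalize_3prime(cds: str, pos: int, length: int = 1) -> int:
    """Shift a CDS deletion to its most 3' equivalent placement.

    Deleting ``length`` bases at 1-based ``pos`` is equivalent to deleting
    at ``pos+1`` whenever the base entering the window from the right
    equals the base leaving it on the left. Idempotent; never changes the
    edited nucleotide string.
    """
    if not 1 <= pos <= len(cds) - length + 1:
        raise ValueError("deletion outside CDS")
    while pos + length <= len(cds) and cds[pos - 1] == cds[pos + length - 1]:
        pos += 1
    return pos


def _translate(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def predict_protein_effect(
    cds: str, edit: CdsDeletion | CdsSNV | CdsInsertion
) -> ConsequenceCall:
    """Apply a CDS edit, translate, and classify/name the protein effect.

    Deletions are 3'-normalized before naming. An edited sequence whose new
    reading frame reaches the end of the CDS without a stop codon yields an
    explicit ``no_stop`` call rather than an error.
    """
    wild = _translate(cds)          # includes the terminal '*'
    wt_len = len(wild) - 1

    if isinstance(edit, CdsSNV):
        if cds[edit.pos - 1] != edit.ref:
            raise ValueError(
                f"reference mismatch at c.{edit.pos}: CDS has {cds[edit.pos - 1]}, "
                f"variant says {edit.ref}"
            )
        edited = cds[: edit.pos - 1] + edit.alt + cds[edit.pos :]
        mut = _translate(edited)
        ci = (edit.pos - 1) // 3
        wt_aa, mut_aa = wild[ci], mut[ci]
        chgvs = f"c.{edit.pos}{edit.ref}>{edit.alt}"
        if wt_aa == mut_aa:
            return ConsequenceCall(
                "", SYNONYMOUS, chgvs, f"p.{aa3(wt_aa)}{ci + 1}=", wt_len, wt_len, 0.0
            )
        if mut_aa == "*":
            frac = (wt_len - ci) / wt_len if wt_len else 0.0
            return ConsequenceCall(
                "", STOP_GAIN, chgvs, f"p.{aa3(wt_aa)}{ci + 1}*", ci, wt_len, frac
            )
        if wt_aa == "*":
            # the stop codon itself is changed: read-through extension
            return ConsequenceCall(
                "", STOP_LOSS, chgvs, f"p.*{ci + 1}{aa3(mut_aa)}ext*?", wt_len, wt_len, 0.0
            )
        return ConsequenceCall(
            "", MISSENSE, chgvs, f"p.{aa3(wt_aa)}{ci + 1}{aa3(mut_aa)}", wt_len, wt_len, 0.0
        )

    if isinstance(edit, CdsInsertion):
        edited = cds[: edit.pos] + edit.seq + cds[edit.pos :]
        chgvs = f"c.{edit.pos}_{edit.pos + 1}ins{edit.seq}"
        if len(edit.seq) % 3 == 0:
            return _inframe_call(wild, _translate(edited), chgvs)
        return _frameshift_call(wild, _translate(edited), chgvs, wt_len)

    # deletion
    pos = normalize_3prime(cds, edit.pos, edit.length)
    deleted = cds[pos - 1 : pos - 1 + edit.length]
    edited = cds[: pos - 1] + cds[pos - 1 + edit.length :]
    if edit.length == 1:
        chgvs = f"c.{pos}del{deleted}"
    else:
        chgvs = f"c.{pos}_{pos + edit.length - 1}del"
    if edit.length % 3 == 0:
        return _inframe_call(wild, _translate(edited), chgvs)
    return _frameshift_call(wild, _translate(edited), chgvs, wt_len)


def _first_difference(wild: str, mut: str) -> int | None:
    """0-based index of the first differing residue, or None if mut is a prefix."""
    for i, aa in enumerate(mut):
        if i >= len(wild) or aa != wild[i]:
            return i
    return None


def _frameshift_call(wild: str, mut: str, chgvs: str, wt_len: int) -> ConsequenceCall:
    i = _first_difference(wild, mut)
    if i is None and len(mut) >= len(wild):
        # shifted frame happens to reproduce the wild-type translation
        return ConsequenceCall("", SYNONYMOUS, chgvs, "p.=", wt_len, wt_len, 0.0)
    if i is None:
        # frame shifted but no residue differs before the mutant sequence
        # runs out: translation continues past the CDS end with no stop
        return ConsequenceCall(
            "", FRAMESHIFT, chgvs, f"p.{aa3(wild[len(mut)])}{len(mut) + 1}fs*?",
            len(mut), wt_len, max(0.0, (wt_len - len(mut)) / wt_len), None, True,
        )
    p = i + 1  # 1-based first changed residue
    wt3 = aa3(wild[i])
    if mut[i] == "*":
        # the first shifted codon is already a stop: name it like a nonsense
        # substitution per HGVS convention
        mut_len = p - 1
        return ConsequenceCall(
            "", FRAMESHIFT, chgvs, f"p.{wt3}{p}*", mut_len, wt_len,
            (wt_len - mut_len) / wt_len, 1, False,
        )
    stop_idx = mut.find("*", i)
    if stop_idx == -1:
        return ConsequenceCall(
            "", FRAMESHIFT, chgvs, f"p.{wt3}{p}{aa3(mut[i])}fs*?",
            len(mut), wt_len, max(0.0, (wt_len - len(mut)) / wt_len), None, True,
        )
    n = stop_idx - i + 1            # stop position, first changed residue = 1
    mut_len = p + n - 2             # intact prefix + (n - 1) novel residues
    return ConsequenceCall(
        "", FRAMESHIFT, chgvs, f"p.{wt3}{p}{aa3(mut[i])}fs{n}*",
        mut_len, wt_len, (wt_len - mut_len) / wt_len, n, False,
    )


def _inframe_call(wild: str, mut: str, chgvs: str) -> ConsequenceCall:
    wt_len = len(wild) - 1
    wild_p, mut_p = wild[:-1], mut[: mut.find("*")] if "*" in mut else mut
    if mut_p == wild_p:
        return ConsequenceCall("", SYNONYMOUS, chgvs, "p.=", wt_len, wt_len, 0.0)
    a = 0
    while a < min(len(wild_p), len(mut_p)) and wild_p[a] == mut_p[a]:
        a += 1
    b = 0
    while (
        b < min(len(wild_p), len(mut_p)) - a
        and wild_p[len(wild_p) - 1 - b] == mut_p[len(mut_p) - 1 - b]
    ):
        b += 1
    lost = wild_p[a : len(wild_p) - b]
    gained = mut_p[a : len(mut_p) - b]
    if gained:
        phgvs = f"p.{aa3(wild_p[a])}{a + 1}_{aa3(wild_p[len(wild_p) - b - 1])}{len(wild_p) - b}delins{''.join(aa3(x) for x in gained)}"
    elif len(lost) == 1:
        phgvs = f"p.{aa3(lost)}{a + 1}del"
    else:
        phgvs = f"p.{aa3(lost[0])}{a + 1}_{aa3(lost[-1])}{a + len(lost)}del"
    frac = max(0.0, (wt_len - len(mut_p)) / wt_len) if wt_len else 0.0
    return ConsequenceCall("", INFRAME_INDEL, chgvs, phgvs, len(mut_p), wt_len, frac)


# ---------------------------------------------------------------------------
# genomic variant -> per-transcript call


def project_to_cdna(variant: Variant, transcript: TranscriptModel) -> tuple[int, int]:
    """c. coordinates (start, end) of the variant's changed bases on a transcript.

    For SNVs both coordinates equal the substituted base. For deletions the
    span covers the deleted bases (the anchor base is excluded). Raises
    NonCodingPosition / SplitSpan as appropriate.
    """
    if len(variant.ref) == len(variant.alt) == 1:
        c = transcript.genomic_to_cdna(variant.pos)
        return c, c
    if len(variant.ref) > len(variant.alt):
        glen = len(variant.ref) - len(variant.alt)
        return transcript.project_span(variant.pos + len(variant.alt), glen)
    c = transcript.genomic_to_cdna(variant.pos)
    return c, c


def _cds_edit(variant: Variant, tx: TranscriptModel):
    rc = lambda s: str(Seq(s).reverse_complement())
    if len(variant.ref) == len(variant.alt) == 1:
        c = tx.genomic_to_cdna(variant.pos)
        ref, alt = variant.ref, variant.alt
        if tx.strand == "-":
            ref, alt = rc(ref), rc(alt)
        return CdsSNV(c, ref, alt)
    if len(variant.ref) > len(variant.alt) and variant.ref.startswith(variant.alt):
        glen = len(variant.ref) - len(variant.alt)
        cstart, _cend = tx.project_span(variant.pos + len(variant.alt), glen)
        return CdsDeletion(cstart, glen)
    if len(variant.alt) > len(variant.ref) and variant.alt.startswith(variant.ref):
        ins = variant.alt[len(variant.ref) :]
        c = tx.genomic_to_cdna(variant.pos)
        if tx.strand == "-":
            return CdsInsertion(c - 1, rc(ins))
        return CdsInsertion(c, ins)
    raise ValueError(f"unsupported allele pair {variant.ref}>{variant.alt}")


def annotate_variant(variant: Variant, tx: TranscriptModel) -> ConsequenceCall:
    """Predict the effect of a genomic variant on one transcript.

    Returns a NON_CODING call if the variant touches no exon and a
    SPLIT_SPAN call (possible splice disruption) if its span crosses an
    exon-intron boundary.
    """
    try:
        edit = _cds_edit(variant, tx)
    except SplitSpan:
        return ConsequenceCall(tx.id, SPLIT_SPAN, wildtype_protein_length=tx.protein_length)
    except NonCodingPosition:
        return ConsequenceCall(tx.id, NON_CODING, wildtype_protein_length=tx.protein_length)
    call = predict_protein_effect(tx.cds_seq, edit)
    call.transcript_id = tx.id
    if call.category in (FRAMESHIFT, STOP_GAIN):
        _frac, lost, truncated = truncation_stats(call, tx)
        call.lost_domains = lost
        call.truncated_domains = truncated
    return call


def truncation_stats(
    call: ConsequenceCall, tx: TranscriptModel
) -> tuple[float, list[str], list[str]]:
    """Fraction of the wild-type protein lost, and the domains lost/truncated.

    A domain is lost when it lies entirely beyond the mutant protein's end,
    truncated when the mutant ends inside it; a domain ending exactly at
    the mutant length is intact.
    """
    wt_len = tx.protein_length
    mut_len = call.mutant_protein_length
    fraction_lost = (wt_len - mut_len) / wt_len if wt_len else 0.0
    fraction_lost = min(1.0, max(0.0, fraction_lost))
    lost = [d.name for d in tx.domains if d.aa_start > mut_len]
    truncated = [d.name for d in tx.domains if d.aa_start <= mut_len < d.aa_end]
    return fraction_lost, lost, truncated
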