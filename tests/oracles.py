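"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and Biopython):
translation uses a literal codon table, run detection enumerates every
marker window, and funnel filtering is plain set algebra.
"""

from __future__ import annotations

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "E": "Glu",
    "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}


def translate(seq: str) -> str:
    return "".join(
        CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def frameshift_oracle(cds: str, del_pos: int) -> dict:
    """Expected protein-level outcome of a 1-bp CDS deletion, by direct editing.

    Deletion placement within a repeat run does not change the edited
    nucleotide string, so no normalization is needed at protein level.
    """
    edited = cds[: del_pos - 1] + cds[del_pos:]
    wild = translate(cds)
    mut = translate(edited)
    first = None
    for i, aa in enumerate(mut):
        if i >= len(wild) or aa != wild[i]:
            first = i
            break
    if first is None:
        return {"protein_hgvs": None, "mutant_length": len(mut), "no_stop": True}
    p = first + 1
    if mut[first] == "*":
        return {
            "protein_hgvs": f"p.{AA3[wild[first]]}{p}*",
            "mutant_length": p - 1,
            "no_stop": False,
        }
    stop = mut.find("*", first)
    if stop == -1:
        return {
            "protein_hgvs": f"p.{AA3[wild[first]]}{p}{AA3[mut[first]]}fs*?",
            "mutant_length": len(mut),
            "no_stop": True,
        }
    n = stop - first + 1
    return {
        "protein_hgvs": f"p.{AA3[wild[first]]}{p}{AA3[mut[first]]}fs{n}*",
        "mutant_length": p + n - 2,
        "no_stop": False,
        "prefix": wild[:first],
    }


def roh_oracle(calls, positions, params):
    """Every maximal feasible window, by O(n^2) enumeration.

    Returns (start, end) marker-index pairs (inclusive) of maximal windows
    meeting the het/missing budgets and the length/marker thresholds.
    """
    n = len(calls)

    def feasible(i, j):
        window = calls[i : j + 1]
        het = sum(1 for c in window if c == 1)
        mis = sum(1 for c in window if c == -1)
        return het <= params.max_het_in_run and mis <= params.max_missing_in_run

    out = []
    for i in range(n):
        for j in range(i, n):
            if not feasible(i, j):
                continue
            if i > 0 and feasible(i - 1, j):
                continue
            if j < n - 1 and feasible(i, j + 1):
                continue
            if (
                j - i + 1 >= params.min_markers
                and positions[j] + 1 - positions[i] >= params.min_length_bp
            ):
                out.append((i, j))
    return out
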