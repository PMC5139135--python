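"""Runs of homozygosity, identity by state, and case-shared autozygous regions.

The mapping logic implements the classical autozygosity argument for a
recessive trait in a consanguineous pedigree: affected individuals are
expected to be identical by descent across the causal locus, so they are
homozygous for the same allele over an extended stretch (> ~1 Mb on a
dense SNP panel), while their carrier parents are heterozygous there.

Detection is run-based with explicit parameters (minimum physical span,
minimum marker support, allowed heterozygous/missing calls inside a run)
rather than a sliding-window scan, so the output is exactly the set of
maximal marker windows satisfying the constraints — directly checkable
against a brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UndefinedResultError
from .genotypes import MISSING, GenotypeMatrix
from .intervals import GenomicInterval


@dataclass(frozen=True)
class RohParams:
    """Constraints a marker window must satisfy to count as a run."""

    min_length_bp: int = 1_000_000
    min_markers: int = 20
    max_missing_in_run: int = 2
    max_het_in_run: int = 0

    def __post_init__(self):
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if min(self.min_markers, self.max_missing_in_run, self.max_het_in_run) < 0:
            raise ValueError("parameters must be non-negative")


@dataclass
class HomozygosityRun:
    sample: str
    interval: GenomicInterval        # [first marker pos, last marker pos + 1)
    n_markers: int
    start_idx: int                   # global marker indices, inclusive/exclusive
    end_idx: int
    alleles: np.ndarray = field(repr=False)  # genotype codes over the run


@dataclass
class CandidateRegion:
    """A region where every case is homozygous for one shared allele."""

    interval: GenomicInterval
    start_idx: int
    end_idx: int
    n_markers: int
    shared_alleles: np.ndarray = field(repr=False)  # code per marker; -1 where unknown
    parent_conflicts: dict[str, int] = field(default_factory=dict)
    parent_denominators: dict[str, int] = field(default_factory=dict)


def compute_ibs(gm: GenotypeMatrix, s1: str, s2: str) -> float:
    """Mean pairwise allele sharing between two samples, as a percentage.

    Per co-called marker the score is 1 for identical genotypes, 0.5 when
    exactly one allele is shared, 0 otherwise; with allele-B dosage codes
    g in {0,1,2} this is 1 - |g1 - g2| / 2. Symmetric; 100 for identical
    fully-called vectors (e.g. monozygotic twins).
    """
    g1 = gm.sample_calls(s1)
    g2 = gm.sample_calls(s2)
    called = (g1 != MISSING) & (g2 != MISSING)
    if not called.any():
        raise UndefinedResultError(f"no co-called markers for {s1}/{s2}")
    score = 1.0 - np.abs(g1[called].astype(float) - g2[called]) / 2.0
    return 100.0 * float(score.mean())


def detect_roh(
    gm: GenotypeMatrix, sample: str, params: RohParams = RohParams()
) -> list[HomozygosityRun]:
    """All maximal runs of homozygosity for one sample, sorted by position.

    A run is a window of consecutive markers on one chromosome containing
    at most ``max_het_in_run`` heterozygous and ``max_missing_in_run``
    missing calls, supported by at least ``min_markers`` markers and
    spanning at least ``min_length_bp``. Maximality means extending the
    window at either end would violate the het/missing budget (windows
    may overlap when the budgets are non-zero).
    """
    calls = gm.sample_calls(sample)
    pos = gm.markers["pos"].to_numpy()
    runs: list[HomozygosityRun] = []
    for chrom in gm.chroms:
        sl = gm.chrom_slice(chrom)
        c = calls[sl]
        p = pos[sl]
        n = len(c)
        het = (c == 1).astype(np.int64)
        mis = (c == MISSING).astype(np.int64)
        # two pointers: R[l] = largest r such that window [l, r] is feasible
        r = -1
        het_ct = mis_ct = 0
        prev_r = -2
        for left in range(n):
            if r < left - 1:
                r = left - 1
                het_ct = mis_ct = 0
            while r + 1 < n and (
                het_ct + het[r + 1] <= params.max_het_in_run
                and mis_ct + mis[r + 1] <= params.max_missing_in_run
            ):
                r += 1
                het_ct += het[r]
                mis_ct += mis[r]
            if r >= left and r > prev_r:  # maximal: not contained in previous window
                n_markers = r - left + 1
                span_start, span_end = int(p[left]), int(p[r]) + 1
                if n_markers >= params.min_markers and span_end - span_start >= params.min_length_bp:
                    runs.append(
                        HomozygosityRun(
                            sample=sample,
                            interval=GenomicInterval(chrom, span_start, span_end),
                            n_markers=n_markers,
                            start_idx=sl.start + left,
                            end_idx=sl.start + r + 1,
                            alleles=c[left : r + 1].copy(),
                        )
                    )
            prev_r = r
            het_ct -= het[left]
            mis_ct -= mis[left]
    return runs


def _union_index_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open index ranges into a disjoint sorted union."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(ranges):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def _intersect_unions(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo, hi = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_case_regions(
    runs_by_case: dict[str, list[HomozygosityRun]],
    gm: GenotypeMatrix,
    cases: list[str],
    params: RohParams = RohParams(),
) -> list[CandidateRegion]:
    """Regions where all cases' runs overlap and share one homozygous allele.

    Per chromosome, the (possibly overlapping) runs of each case are merged
    into a union of marker-index ranges; the unions are intersected across
    cases; within each intersection, maximal sub-ranges are retained over
    which every non-missing case call is homozygous for the same allele.
    Surviving sub-ranges are re-checked against min_length_bp/min_markers.
    """
    if not cases:
        raise ValueError("at least one case required")
    pos = gm.markers["pos"].to_numpy()
    chroms = gm.markers["chrom"].to_numpy()
    case_calls = np.stack([gm.sample_calls(c) for c in cases])

    per_case_union = []
    for case in cases:
        per_case_union.append(
            _union_index_ranges(
                [(r.start_idx, r.end_idx) for r in runs_by_case.get(case, [])]
            )
        )
    common = per_case_union[0]
    for other in per_case_union[1:]:
        common = _intersect_unions(common, other)

    regions: list[CandidateRegion] = []
    for lo, hi in common:
        block = case_calls[:, lo:hi]                       # cases x markers
        non_missing = block != MISSING
        any_het = ((block == 1) & non_missing).any(axis=0)
        # all non-missing calls agree (0 or 2) at the marker
        filled_max = np.where(non_missing, block, -10).max(axis=0)
        filled_min = np.where(non_missing, block, 10).min(axis=0)
        any_called = non_missing.any(axis=0)
        agree = ~any_called | (filled_max == filled_min)
        ok = ~any_het & agree
        # maximal True stretches of ok
        j = 0
        while j < len(ok):
            if not ok[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(ok) and ok[k + 1]:
                k += 1
            start_idx, end_idx = lo + j, lo + k + 1
            shared = np.where(
                any_called[j : k + 1], filled_max[j : k + 1], MISSING
            ).astype(np.int8)
            interval = GenomicInterval(
                str(chroms[start_idx]), int(pos[start_idx]), int(pos[end_idx - 1]) + 1
            )
            n_markers = end_idx - start_idx
            if (
                n_markers >= params.min_markers
                and interval.length >= params.min_length_bp
            ):
                regions.append(
                    CandidateRegion(interval, start_idx, end_idx, n_markers, shared)
                )
            j = k + 1
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def exclude_parental(
    regions: list[CandidateRegion],
    gm: GenotypeMatrix,
    parents: list[str],
    max_parent_hom_fraction: float = 0.0,
) -> list[CandidateRegion]:
    """Drop regions where a parent looks homozygous for the case-shared allele.

    For each parent, the conflict fraction is the share of markers (parent
    call non-missing, shared allele known) at which the parent is
    homozygous for the shared allele; a region is dropped when any parent's
    fraction is strictly greater than ``max_parent_hom_fraction``.
    Surviving regions carry per-parent conflict counts.
    """
    kept: list[CandidateRegion] = []
    for region in regions:
        drop = False
        for parent in parents:
            pcalls = gm.sample_calls(parent)[region.start_idx : region.end_idx]
            usable = (pcalls != MISSING) & (region.shared_alleles != MISSING)
            conflicts = int(((pcalls == region.shared_alleles) & usable).sum())
            denom = int(usable.sum())
            region.parent_conflicts[parent] = conflicts
            region.parent_denominators[parent] = denom
            if denom > 0 and conflicts / denom > max_parent_hom_fraction:
                drop = True
        if not drop:
            kept.append(region)
    return kept


# ---------------------------------------------------------------------------
# reporting


def write_regions_bed(regions: list[CandidateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\tregion{i}\n")


def read_regions_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, *_ = line.split()
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
    return intervals


def write_regions_tsv(regions: list[CandidateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength_bp\tn_markers\tparent_conflicts\n")
        for r in regions:
            conf = ";".join(f"{p}:{c}/{r.parent_denominators[p]}" for p, c in r.parent_conflicts.items())
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.interval.length}\t{r.n_markers}\t{conf or '.'}\n"
            )
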