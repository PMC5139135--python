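"""Pedigrees and SNP-array genotype matrices, with PLINK PED/MAP text I/O.

Genotype calls are stored as an int8 matrix of allele-B dosages:
0 = homozygous allele A, 1 = heterozygous, 2 = homozygous allele B,
-1 = missing. This makes identity-by-state and run-of-homozygosity
computations simple vector operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_PED_STATUS = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}
_PED_STATUS_INV = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PED_SEX = {"male": "1", "female": "2", "unknown": "0"}
_PED_SEX_INV = {v: k for k, v in _PED_SEX.items()}


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    status: str = UNKNOWN


@dataclass
class Pedigree:
    """An ordered set of individuals with parent links and affection status."""

    individuals: list[Individual]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in known:
                    raise ValueError(f"unknown parent {parent!r} of {ind.id!r}")
        # no individual may be its own ancestor
        by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            seen: set[str] = set()
            stack = [p for p in (ind.sire, ind.dam) if p]
            while stack:
                cur = stack.pop()
                if cur == ind.id:
                    raise ValueError(f"{ind.id!r} is its own ancestor")
                if cur in seen:
                    continue
                seen.add(cur)
                anc = by_id[cur]
                stack.extend(p for p in (anc.sire, anc.dam) if p)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def affected(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.status == AFFECTED]

    def parents_of(self, ind_id: str) -> list[str]:
        ind = self[ind_id]
        return [p for p in (ind.sire, ind.dam) if p is not None]

    def obligate_carriers(self) -> list[str]:
        """Unaffected parents of affected individuals (recessive model)."""
        carriers: list[str] = []
        for case in self.affected():
            for parent in self.parents_of(case):
                if self[parent].status != AFFECTED and parent not in carriers:
                    carriers.append(parent)
        return carriers


@dataclass
class GenotypeMatrix:
    """Biallelic marker calls for a panel of samples.

    markers: DataFrame with columns chrom, pos, a1, a2 (pos strictly
    increasing within each chromosome; chromosomes in block order).
    calls: int8 array of shape (n_samples, n_markers), allele-B dosage or -1.
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError("calls shape does not match samples x markers")
        chroms = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        start = 0
        for chrom in pd.unique(chroms):
            idx = np.nonzero(chroms == chrom)[0]
            if idx[0] != start or idx[-1] != start + len(idx) - 1:
                raise ValueError("markers of one chromosome must be contiguous")
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            self._chrom_slices[str(chrom)] = slice(start, start + len(idx))
            start += len(idx)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in genotype matrix") from None

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)


# ---------------------------------------------------------------------------
# PLINK text dialect I/O

def write_ped_map(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    ped_path: str | Path,
    map_path: str | Path,
    family_id: str = "FAM1",
) -> None:
    """Write white-space separated PED/MAP; alleles as bases, missing = 0."""
    a1 = gm.markers["a1"].to_numpy()
    a2 = gm.markers["a2"].to_numpy()
    by_id = {ind.id: ind for ind in pedigree}
    with open(ped_path, "w") as fh:
        for s, sample in enumerate(gm.samples):
            ind = by_id.get(sample, Individual(sample))
            row = [
                family_id,
                sample,
                ind.sire or "0",
                ind.dam or "0",
                _PED_SEX.get(ind.sex, "0"),
                _PED_STATUS.get(ind.status, "0"),
            ]
            calls = gm.calls[s]
            alleles = np.empty((gm.n_markers, 2), dtype=object)
            alleles[calls == 0] = np.stack([a1, a1], axis=1)[calls == 0]
            alleles[calls == 1] = np.stack([a1, a2], axis=1)[calls == 1]
            alleles[calls == 2] = np.stack([a2, a2], axis=1)[calls == 2]
            alleles[calls == MISSING] = ["0", "0"]
            row.extend(alleles.ravel())
            fh.write(" ".join(row) + "\n")
    with open(map_path, "w") as fh:
        for i, m in enumerate(gm.markers.itertuples(index=False)):
            fh.write(f"{m.chrom} m{i + 1} 0 {m.pos}\n")


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> tuple[GenotypeMatrix, Pedigree]:
    """Read the PLINK text dialect back into a GenotypeMatrix + Pedigree."""
    rows = []
    with open(map_path) as fh:
        for line in fh:
            chrom, _name, _cm, pos = line.split()
            rows.append((chrom, int(pos)))
    markers = pd.DataFrame(rows, columns=["chrom", "pos"])

    samples: list[str] = []
    individuals: list[Individual] = []
    allele_cols: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            _fam, ind_id, sire, dam, sex, status = parts[:6]
            samples.append(ind_id)
            individuals.append(
                Individual(
                    ind_id,
                    sire if sire != "0" else None,
                    dam if dam != "0" else None,
                    _PED_SEX_INV.get(sex, "unknown"),
                    _PED_STATUS_INV.get(status, UNKNOWN),
                )
            )
            allele_cols.append(np.array(parts[6:], dtype="U1").reshape(-1, 2))

    n_markers = len(markers)
    alleles = np.stack(allele_cols)  # samples x markers x 2
    if alleles.shape[1] != n_markers:
        raise ValueError("PED genotype count does not match MAP marker count")

    # infer the two alleles per marker from observed non-missing calls
    a1_col, a2_col = [], []
    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for j in range(n_markers):
        obs = alleles[:, j, :]
        present = obs[obs != "0"]
        uniq = sorted(set(present.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"marker {j} has >2 alleles: {uniq}")
        while len(uniq) < 2:
            uniq.append("N")
        a1, a2 = uniq
        a1_col.append(a1)
        a2_col.append(a2)
        called = (obs[:, 0] != "0") & (obs[:, 1] != "0")
        dosage = (obs == a2).sum(axis=1).astype(np.int8)
        calls[called, j] = dosage[called]
    markers["a1"] = a1_col
    markers["a2"] = a2_col
    return GenotypeMatrix(markers, samples, calls), Pedigree(individuals)
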