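"""Cohort genotype tabulation, segregation test, and carrier frequency.

The end point of a recessive disease-gene study: cross-tabulate candidate
genotypes by group (affected animals, obligate-carrier parents, population
controls, other breeds), test perfect co-segregation (all affected are
homozygous mutant, nobody else is), and report the carrier percentage in
the population sample. Obligate-carrier status is derived from the
pedigree, not supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import UndefinedResultError
from .genotypes import Pedigree

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPE_VALUES = (HOM_REF, HET, HOM_ALT, MISSING)

_CODE_TO_NAME = {0: HOM_REF, 1: HET, 2: HOM_ALT, -1: MISSING}


@dataclass
class SegregationReport:
    table: pd.DataFrame
    perfect_association: bool
    association_violations: list[tuple[str, str, int]]
    carrier_percent: dict[str, float]
    pedigree_violations: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "genotype_counts": {
                str(g): {c: int(row[c]) for c in GENOTYPE_VALUES}
                for g, row in self.table.iterrows()
            },
            "perfect_association": self.perfect_association,
            "association_violations": [list(v) for v in self.association_violations],
            "carrier_percent": {
                g: {"value": round(p, 2), "rounded": round(p)}
                for g, p in self.carrier_percent.items()
            },
            "pedigree_violations": [list(v) for v in self.pedigree_violations],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_text(self) -> str:
        lines = ["group\thom_ref\thet\thom_alt\tmissing"]
        for g, row in self.table.iterrows():
            lines.append(f"{g}\t{row[HOM_REF]}\t{row[HET]}\t{row[HOM_ALT]}\t{row[MISSING]}")
        lines.append(f"perfect_association\t{self.perfect_association}")
        for g, p in self.carrier_percent.items():
            lines.append(f"carrier_percent[{g}]\t{p:.2f} (~{round(p)}%)")
        return "\n".join(lines) + "\n"


def normalize_genotype(value) -> str:
    """Accept dosage codes (0/1/2/-1) or names; return the canonical name."""
    if value in _CODE_TO_NAME:
        return _CODE_TO_NAME[value]
    name = str(value).strip().lower().replace("-", "_")
    if name in GENOTYPE_VALUES:
        return name
    raise ValueError(f"unrecognized genotype {value!r}")


def genotype_counts(genotypes: dict[str, object], groups: dict[str, str]) -> pd.DataFrame:
    """Cross-tabulate genotypes by group.

    Every genotyped sample must be assigned to exactly one group. Missing
    genotypes are counted in their own column and excluded from all
    denominators downstream.
    """
    unassigned = sorted(set(genotypes) - set(groups))
    if unassigned:
        raise ValueError(f"samples without group assignment: {', '.join(unassigned)}")
    group_order: list[str] = []
    for s in genotypes:
        g = groups[s]
        if g not in group_order:
            group_order.append(g)
    for g in groups.values():  # groups may be declared empty
        if g not in group_order:
            group_order.append(g)
    table = pd.DataFrame(0, index=group_order, columns=list(GENOTYPE_VALUES))
    for sample, value in genotypes.items():
        table.loc[groups[sample], normalize_genotype(value)] += 1
    table.index.name = "group"
    return table


def counts_table(rows: dict[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Build a count table directly from (hom_ref, het, hom_alt) triples."""
    table = pd.DataFrame(
        {g: {HOM_REF: a, HET: b, HOM_ALT: c, MISSING: 0} for g, (a, b, c) in rows.items()}
    ).T
    table.index.name = "group"
    return table[list(GENOTYPE_VALUES)]


def perfect_association(
    table: pd.DataFrame, affected_group: str = "affected"
) -> tuple[bool, list[tuple[str, str, int]]]:
    """True iff every affected sample is hom-alt and no other group has any.

    Missing genotypes are ignored. Returns the offending (group, genotype
    column, count) cells when the association is imperfect.
    """
    if affected_group not in table.index:
        raise ValueError(f"table has no {affected_group!r} group")
    violations: list[tuple[str, str, int]] = []
    for col in (HOM_REF, HET):
        n = int(table.loc[affected_group, col])
        if n:
            violations.append((affected_group, col, n))
    for group in table.index:
        if group == affected_group:
            continue
        n = int(table.loc[group, HOM_ALT])
        if n:
            violations.append((group, HOM_ALT, n))
    return not violations, violations


def carrier_frequency(table: pd.DataFrame, group: str) -> float:
    """Percentage of heterozygotes among genotyped samples of a group."""
    if group not in table.index:
        raise ValueError(f"no group {group!r} in table")
    row = table.loc[group]
    total = int(row[HOM_REF] + row[HET] + row[HOM_ALT])
    if total == 0:
        raise UndefinedResultError(f"group {group!r} has no genotyped samples")
    return 100.0 * float(row[HET]) / total


def obligate_carrier_check(
    pedigree: Pedigree, genotypes: dict[str, object]
) -> list[tuple[str, str]]:
    """Parents of hom-alt affected individuals that are genotyped hom-ref.

    Under recessive inheritance such a parent is Mendelianly impossible
    without a de novo event; het and missing genotypes pass. Returns
    (parent id, affected child id) pairs.
    """
    norm = {s: normalize_genotype(g) for s, g in genotypes.items()}
    violations: list[tuple[str, str]] = []
    for case in pedigree.affected():
        if norm.get(case) != HOM_ALT:
            continue
        for parent in pedigree.parents_of(case):
            if norm.get(parent) == HOM_REF:
                violations.append((parent, case))
    return violations


def build_report(
    genotypes: dict[str, object],
    groups: dict[str, str],
    pedigree: Pedigree | None = None,
    affected_group: str = "affected",
    carrier_groups: list[str] | None = None,
) -> SegregationReport:
    table = genotype_counts(genotypes, groups)
    ok, violations = perfect_association(table, affected_group)
    if carrier_groups is None:
        carrier_groups = [g for g in table.index if g != affected_group]
    carrier = {}
    for g in carrier_groups:
        try:
            carrier[g] = carrier_frequency(table, g)
        except UndefinedResultError:
            pass
    ped_violations = obligate_carrier_check(pedigree, genotypes) if pedigree else []
    return SegregationReport(table, ok, violations, carrier, ped_violations)


def read_genotype_table(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a TSV with columns sample, group, genotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genotypes = dict(zip(df["sample"], df["genotype"]))
    groups = dict(zip(df["sample"], df["group"]))
    return genotypes, groups


def write_genotype_table(
    genotypes: dict[str, object], groups: dict[str, str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\tgenotype\n")
        for sample, value in genotypes.items():
            fh.write(f"{sample}\t{groups[sample]}\t{normalize_genotype(value)}\n")
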