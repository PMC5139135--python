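"""End-to-end orchestration: simulate -> map-roh -> triage -> annotate -> segregate.

Every stage persists its artifacts in plain-text formats (PED/MAP, BED,
VCF, GFF3, FASTA, TSV, JSON) sufficient to re-run any downstream stage in
isolation, and the final JSON/Markdown report is byte-identical across
runs with the same configuration and seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .consequence import ConsequenceCall
from .errors import StageError
from .genotypes import Individual, Pedigree, read_ped_map, write_ped_map
from .intervals import GenomicInterval, reciprocal_overlap
from .roh import (
    CandidateRegion,
    RohParams,
    compute_ibs,
    detect_roh,
    exclude_parental,
    read_regions_bed,
    shared_case_regions,
    write_regions_bed,
    write_regions_tsv,
)
from .segregation import build_report, read_genotype_table, write_genotype_table
from .simulate import (
    DAM,
    SIRE,
    SimulationConfig,
    VariantCohort,
    chip_cases,
    make_transcript_fixture,
    simulate_pedigree_genotypes,
    simulate_variant_cohort,
)
from .transcripts import read_gene_models, write_gene_models
from .triage import dominant_branch, recessive_branch
from .variants import (
    Variant,
    collect_alt_sites,
    read_site_list,
    read_vcf,
    write_site_list,
    write_vcf,
)

log = logging.getLogger("mendelmap")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    roh_params: RohParams = field(default_factory=RohParams)
    max_parent_hom_fraction: float = 0.0
    index_case: str = "CASE1"
    log_level: str = "INFO"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.sim = dataclasses.replace(self.sim, rng_seed=int(self.seed))


def _paths(out_dir: Path) -> dict[str, Path]:
    return {
        "ped": out_dir / "genotypes.ped",
        "map": out_dir / "genotypes.map",
        "pedigree": out_dir / "pedigree.tsv",
        "truth_bed": out_dir / "truth_regions.bed",
        "gff": out_dir / "genes.gff3",
        "cds_fasta": out_dir / "cds.fasta",
        "domains": out_dir / "domains.tsv",
        "case_vcf": out_dir / "case.vcf",
        "controls_vcf": out_dir / "controls.vcf",
        "popdb": out_dir / "popdb_sites.tsv",
        "genotype_table": out_dir / "causal_genotypes.tsv",
        "regions_bed": out_dir / "candidate_regions.bed",
        "regions_tsv": out_dir / "candidate_regions.tsv",
        "recessive_vcf": out_dir / "candidates_recessive.vcf",
        "dominant_vcf": out_dir / "candidates_dominant.vcf",
        "funnel_json": out_dir / "funnel.json",
        "funnel_tsv": out_dir / "funnel.tsv",
        "annotation": out_dir / "annotation.tsv",
        "segregation": out_dir / "segregation.json",
        "report_json": out_dir / "report.json",
        "report_md": out_dir / "report.md",
    }


def write_pedigree_tsv(pedigree: Pedigree, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tsex\tstatus\n")
        for ind in pedigree:
            fh.write(
                f"{ind.id}\t{ind.sire or '.'}\t{ind.dam or '.'}\t{ind.sex}\t{ind.status}\n"
            )


def read_pedigree_tsv(path: Path) -> Pedigree:
    inds = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            ind_id, sire, dam, sex, status = line.rstrip("\n").split("\t")
            inds.append(
                Individual(
                    ind_id,
                    None if sire == "." else sire,
                    None if dam == "." else dam,
                    sex,
                    status,
                )
            )
    return Pedigree(inds)


def stage_simulate(config: RunConfig) -> dict:
    """Generate and persist every synthetic input artifact."""
    p = _paths(config.out_dir)
    sim = config.sim
    pedigree, gm = simulate_pedigree_genotypes(sim)
    transcripts = make_transcript_fixture(sim)
    cohort = simulate_variant_cohort(sim, transcripts)

    write_ped_map(gm, pedigree, p["ped"], p["map"])
    write_pedigree_tsv(pedigree, p["pedigree"])
    with open(p["truth_bed"], "w") as fh:
        for i, r in enumerate(sim.seeded_ibd_regions, 1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tseeded{i}\n")
    write_gene_models(transcripts, p["gff"], p["cds_fasta"], p["domains"])
    write_vcf(cohort.case_variants, cohort.family_samples, p["case_vcf"], sim.genome_layout)
    write_vcf(
        cohort.control_variants, cohort.control_samples, p["controls_vcf"], sim.genome_layout
    )
    write_site_list(cohort.popdb_sites, p["popdb"])
    write_genotype_table(
        cohort.population_genotypes, cohort.population_groups, p["genotype_table"]
    )
    log.info(
        "simulate: %d markers, %d case variants, %d control variants, %d popdb sites",
        gm.n_markers, len(cohort.case_variants), len(cohort.control_variants),
        len(cohort.popdb_sites),
    )
    return {"pedigree": pedigree, "gm": gm, "transcripts": transcripts, "cohort": cohort}


def stage_map_roh(
    ped_path: Path,
    map_path: Path,
    params: RohParams,
    max_parent_hom_fraction: float,
    regions_bed: Path,
    regions_tsv: Path,
) -> tuple[list[CandidateRegion], dict[str, float]]:
    gm, pedigree = read_ped_map(ped_path, map_path)
    cases = [s for s in gm.samples if pedigree[s].status == "affected"]
    parents = sorted({p for c in cases for p in pedigree.parents_of(c) if p in gm.samples})
    runs = {c: detect_roh(gm, c, params) for c in cases}
    regions = shared_case_regions(runs, gm, cases, params)
    regions = exclude_parental(regions, gm, parents, max_parent_hom_fraction)
    ibs = {
        f"{a}/{b}": round(compute_ibs(gm, a, b), 4)
        for a, b in itertools.combinations(gm.samples, 2)
    }
    write_regions_bed(regions, regions_bed)
    write_regions_tsv(regions, regions_tsv)
    log.info("map-roh: %d case-shared autozygous regions", len(regions))
    return regions, ibs


def stage_triage(
    case_vcf: Path,
    controls_vcf: Path,
    popdb_path: Path,
    regions: list,
    gff: Path,
    cds_fasta: Path,
    domains: Path,
    index_case: str,
    recessive_vcf: Path,
    dominant_vcf: Path,
    funnel_json: Path,
    funnel_tsv: Path,
    contigs: list[tuple[str, int]] | None = None,
):
    case_variants, case_samples = read_vcf(case_vcf)
    control_variants, _ = read_vcf(controls_vcf)
    control_sites = collect_alt_sites(control_variants)
    popdb_sites = read_site_list(popdb_path)
    transcripts = read_gene_models(gff, cds_fasta, domains)

    rec, rec_funnel, rec_calls = recessive_branch(
        case_variants, index_case, regions, control_sites, popdb_sites, transcripts
    )
    dom, dom_funnel, dom_calls = dominant_branch(
        case_variants, index_case, control_sites, popdb_sites, transcripts
    )
    write_vcf(rec, case_samples, recessive_vcf, contigs)
    write_vcf(dom, case_samples, dominant_vcf, contigs)
    funnel = {"recessive": rec_funnel.counts, "dominant": dom_funnel.counts}
    Path(funnel_json).write_text(json.dumps(funnel, indent=2, sort_keys=True) + "\n")
    with open(funnel_tsv, "w") as fh:
        fh.write("branch\tstage\tn_variants\n")
        for branch, counts in funnel.items():
            for stage, n in counts.items():
                fh.write(f"{branch}\t{stage}\t{n}\n")
    log.info(
        "triage: recessive %s; dominant %s",
        "->".join(str(n) for n in rec_funnel.counts.values()),
        "->".join(str(n) for n in dom_funnel.counts.values()),
    )
    return rec, dom, funnel, rec_calls, dom_calls, transcripts


def annotation_rows(
    variants: list[Variant], calls: dict[str, list[ConsequenceCall]]
) -> list[dict]:
    rows = []
    for v in variants:
        for call in calls.get(str(v), []):
            rows.append(
                {
                    "variant": str(v),
                    "transcript": call.transcript_id,
                    "cdna_hgvs": call.cdna_hgvs,
                    "protein_hgvs": call.protein_hgvs,
                    "category": call.category,
                    "mutant_protein_length": call.mutant_protein_length,
                    "fraction_lost": round(call.fraction_lost, 4),
                    "lost_domains": ",".join(call.lost_domains) or ".",
                    "truncated_domains": ",".join(call.truncated_domains) or ".",
                }
            )
    return rows


def stage_annotate(variants, calls, path: Path) -> list[dict]:
    rows = annotation_rows(variants, calls)
    cols = [
        "variant", "transcript", "cdna_hgvs", "protein_hgvs", "category",
        "mutant_protein_length", "fraction_lost", "lost_domains", "truncated_domains",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return rows


def stage_segregate(genotype_table: Path, pedigree_tsv: Path, out_json: Path):
    genotypes, groups = read_genotype_table(genotype_table)
    pedigree = read_pedigree_tsv(pedigree_tsv)
    report = build_report(
        genotypes, groups, pedigree, carrier_groups=["population_controls"]
    )
    report.to_json(out_json)
    log.info(
        "segregate: perfect_association=%s carrier=%s",
        report.perfect_association,
        {g: f"{v:.2f}%" for g, v in report.carrier_percent.items()},
    )
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the final report dict.

    Any stage failure raises StageError carrying the stage name and a
    machine-readable code.
    """
    logging.basicConfig(level=config.log_level)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    p = _paths(config.out_dir)

    def _run(stage, fn, code="stage-failed"):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, code, str(exc)) from exc

    sim_out = _run("simulate", lambda: stage_simulate(config))
    regions, ibs = _run(
        "map-roh",
        lambda: stage_map_roh(
            p["ped"], p["map"], config.roh_params, config.max_parent_hom_fraction,
            p["regions_bed"], p["regions_tsv"],
        ),
    )
    rec, dom, funnel, rec_calls, dom_calls, transcripts = _run(
        "triage",
        lambda: stage_triage(
            p["case_vcf"], p["controls_vcf"], p["popdb"], regions,
            p["gff"], p["cds_fasta"], p["domains"], config.index_case,
            p["recessive_vcf"], p["dominant_vcf"], p["funnel_json"], p["funnel_tsv"],
            config.sim.genome_layout,
        ),
    )
    rec_rows = _run("annotate", lambda: stage_annotate(rec, rec_calls, p["annotation"]))
    seg = _run("segregate", lambda: stage_segregate(p["genotype_table"], p["pedigree"], p["segregation"]))

    causal = sim_out["cohort"].causal
    causal_key = causal.site_key()
    seeded = config.sim.seeded_ibd_regions
    recovered = [
        any(reciprocal_overlap(s, r.interval) >= 0.5 for r in regions) for s in seeded
    ]
    report = {
        "seed": config.seed,
        "ibs_percent": ibs,
        "candidate_regions": [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "length_bp": r.interval.length,
                "n_markers": r.n_markers,
                "parent_conflicts": r.parent_conflicts,
            }
            for r in regions
        ],
        "funnel": funnel,
        "recessive_candidates": rec_rows,
        "dominant_candidates": [str(v) for v in dom],
        "segregation": seg.to_dict(),
        "truth": {
            "causal_site": list(causal_key),
            "seeded_regions": [[s.chrom, s.start, s.end] for s in seeded],
            "seeded_regions_recovered": recovered,
            "causal_in_final_list": any(v.site_key() == causal_key for v in rec),
        },
    }
    p["report_json"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    p["report_md"].write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# mendelmap run report", ""]
    lines.append(f"Seed: {report['seed']}")
    lines.append("")
    lines.append("## Case-shared autozygous regions")
    for r in report["candidate_regions"]:
        lines.append(
            f"- {r['chrom']}:{r['start']}-{r['end']} ({r['length_bp'] / 1e6:.2f} Mb, "
            f"{r['n_markers']} markers)"
        )
    lines.append("")
    lines.append("## Variant triage funnel")
    for branch, counts in report["funnel"].items():
        chain = " -> ".join(f"{stage} {n}" for stage, n in counts.items())
        lines.append(f"- {branch}: {chain}")
    lines.append("")
    lines.append("## Final recessive candidates")
    for row in report["recessive_candidates"]:
        lines.append(
            f"- {row['variant']} {row['transcript']} {row['cdna_hgvs']} "
            f"{row['protein_hgvs']} ({row['category']}; fraction lost "
            f"{row['fraction_lost']}; domains lost {row['lost_domains']})"
        )
    seg = report["segregation"]
    lines.append("")
    lines.append("## Segregation")
    lines.append(f"- perfect association: {seg['perfect_association']}")
    for g, v in seg["carrier_percent"].items():
        lines.append(f"- carrier frequency in {g}: {v['value']}% (~{v['rounded']}%)")
    lines.append(
        f"- causal variant in final candidate list: {report['truth']['causal_in_final_list']}"
    )
    return "\n".join(lines) + "\n"
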