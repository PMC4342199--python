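"""End-to-end case processing: VCF -> triage -> report artifacts.

Mirrors the staged analysis funnel: ingest calls, run the three filtration
arms, apply the classification reporting threshold, check Sanger
confirmation, route to report sections, and assemble the Genome Report
with pharmacogenomic and blood-group results.

The assertion arm consults *prior* classifications (the laboratory's store
as it stood before this case); the classification store shipped with a
case's resources holds the assessments of the case's own findings and is
applied at the reporting-threshold stage. Passing ``prior_kb`` supplies
pre-existing classifications to the assertion arm.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .blood import type_blood
from .fixtures import annotate_variants, load_coverage, load_transcript_map
from .kb import KnowledgeBase
from .model import CoverageSummary, read_vcf
from .pgx import type_pgx
from .report import (
    GenomeReportDoc,
    build_report_model,
    render,
    write_packet,
)
from .triage import (
    Arm,
    Section,
    SectionEntry,
    TriageResources,
    TriagedVariant,
    apply_reporting_threshold,
    flag_confirmation_risk,
    route_sections,
    triage,
)

log = logging.getLogger(__name__)


@dataclass
class FunnelCounts:
    """Per-stage counts of the analysis funnel, for the structured log."""

    ingested: int = 0
    arm_assertion: int = 0
    arm_lof: int = 0
    arm_pgx: int = 0
    arm_union: int = 0
    threshold_passed: int = 0
    confirmed: int = 0
    reported: int = 0

    def check(self) -> None:
        ok = (
            self.reported
            <= self.confirmed
            <= self.threshold_passed
            <= self.arm_union
            <= self.ingested
        )
        if not ok:
            raise AssertionError(f"inconsistent funnel counts: {self}")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CaseResult:
    doc: GenomeReportDoc
    funnel: FunnelCounts
    triaged: list[TriagedVariant]
    entries: list[tuple[TriagedVariant, SectionEntry]]
    needs_assessment: list[str] = field(default_factory=list)
    exceptions: list[str] = field(default_factory=list)


def run_case(
    vcf_path: str,
    resources_dir: str,
    case_id: str = "CASE",
    study_arm: str = "primary_care",
    mean_coverage: float = 41.0,
    pct_bases_ge_8x: float = 95.5,
    min_gq: float = 30.0,
    prior_kb: Optional[KnowledgeBase] = None,
    maf_gate_mode: str = "any",
) -> CaseResult:
    """Process one case end to end and return the report model + funnel."""
    rdir = Path(resources_dir)
    variants = read_vcf(vcf_path, min_gq=min_gq)

    tmap_path = rdir / "transcript_map.tsv"
    transcript_map = load_transcript_map(str(tmap_path)) if tmap_path.exists() else {}
    resources = TriageResources.load(
        str(rdir), kb=prior_kb or KnowledgeBase(), maf_gate_mode=maf_gate_mode
    )
    # classification store for threshold/routing (this cohort's assessments)
    kb_path = rdir / "kb_state.tsv"
    kb = KnowledgeBase.load(str(kb_path)) if kb_path.exists() else KnowledgeBase()

    frequencies = resources.frequencies
    annotated = annotate_variants(variants, transcript_map, frequencies)

    cov_path = Path(vcf_path).parent / "coverage.tsv"
    coverage = load_coverage(str(cov_path)) if cov_path.exists() else {}

    triaged = triage(annotated, resources)

    funnel = FunnelCounts(ingested=len(variants), arm_union=len(triaged))
    arm_counter: Counter = Counter()
    for tv in triaged:
        for arm in tv.arms:
            arm_counter[arm] += 1
    funnel.arm_assertion = arm_counter[Arm.ASSERTION]
    funnel.arm_lof = arm_counter[Arm.LOF]
    funnel.arm_pgx = arm_counter[Arm.PGX]

    entries: list[tuple[TriagedVariant, SectionEntry]] = []
    needs_assessment: list[str] = []
    exceptions: list[str] = []
    confirmed_count = 0
    threshold_count = 0
    mendelian_genes: Counter = Counter()

    from .kb import ConfirmationStatus, key_to_str

    for tv in triaged:
        if tv.arms == {Arm.PGX}:
            continue  # pharmacogenomic sites are handled by the PGx typer
        recs = kb.get(tv.key)
        if not recs:
            needs_assessment.append(key_to_str(tv.key))
            continue
        reportable_recs = [r for r in recs if apply_reporting_threshold(tv, r)]
        if not reportable_recs:
            continue
        threshold_count += 1
        tv.confirmation_status = reportable_recs[0].confirmation_status
        if tv.confirmation_status == ConfirmationStatus.FALSE_POSITIVE:
            exceptions.append(
                f"false positive on Sanger confirmation, excluded: {key_to_str(tv.key)}"
            )
            continue
        if tv.confirmation_status.value.startswith("confirmed"):
            confirmed_count += 1
        left = right = ""
        tv.confirmation_risk = flag_confirmation_risk(
            tv.variant.variant, left, right
        )
        routed = route_sections(
            tv, reportable_recs, indication_context=study_arm,
            gene_list=resources.gene_list,
        )
        for entry in routed:
            entries.append((tv, entry))
            if entry.section == Section.CARRIER:
                mendelian_genes[entry.record.gene] += 1

    for gene, count in sorted(mendelian_genes.items()):
        if count >= 2:
            exceptions.append(
                f"co-occurring heterozygous recessive variants in {gene}: "
                "possible compound heterozygosity, manual review required"
            )

    funnel.threshold_passed = threshold_count
    funnel.confirmed = confirmed_count

    pgx_results = type_pgx(variants, coverage)
    blood_phen, blood_summary = type_blood(variants, coverage)

    coverage_summary = CoverageSummary(
        mean_coverage=mean_coverage,
        pct_bases_ge_8x=pct_bases_ge_8x,
        total_variants=len(variants),
    )
    indication_cov = None
    if study_arm == "cardiomyopathy":
        from .fixtures import INDICATION_GENES

        indication_cov = [
            {
                "gene": g,
                "mean_coverage": mean_coverage,
                "pct_bases_ge_8x": pct_bases_ge_8x,
            }
            for g in sorted(INDICATION_GENES)
        ]

    doc = build_report_model(
        case_id=case_id,
        study_arm=study_arm,
        entries=entries,
        pgx_results=pgx_results,
        blood=blood_phen,
        blood_summary=blood_summary,
        coverage=coverage_summary,
        indication_gene_coverage=indication_cov,
    )
    funnel.reported = len({tv.key for tv, _ in entries})
    funnel.check()

    return CaseResult(
        doc=doc,
        funnel=funnel,
        triaged=triaged,
        entries=entries,
        needs_assessment=needs_assessment,
        exceptions=exceptions,
    )


def write_outputs(result: CaseResult, outdir: str) -> dict[str, str]:
    """Write report.md, report.pdf, packet.json, funnel log, and exception
    report; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    md_path = out / "report.md"
    md_path.write_bytes(render(result.doc, "markdown"))
    paths["report_md"] = str(md_path)

    pdf_path = out / "report.pdf"
    pdf_path.write_bytes(render(result.doc, "pdf"))
    paths["report_pdf"] = str(pdf_path)

    packet_path = out / "packet.json"
    write_packet(result.doc, str(packet_path))
    paths["packet"] = str(packet_path)

    funnel_path = out / "funnel.jsonl"
    with open(funnel_path, "a") as fh:
        fh.write(json.dumps({"case_id": result.doc.case_id, **result.funnel.as_dict()},
                            sort_keys=True) + "\n")
    paths["funnel"] = str(funnel_path)

    exc_path = out / "exceptions.tsv"
    with open(exc_path, "w") as fh:
        fh.write("kind\tdetail\n")
        for key in result.needs_assessment:
            fh.write(f"needs_assessment\t{key}\n")
        for note in result.exceptions:
            fh.write(f"review\t{note}\n")
    paths["exceptions"] = str(exc_path)
    return paths
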