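"""Genome Report assembly and rendering.

Builds the full structured report model — single-page result summary,
detailed variant/PGx/blood sections, methodology, limitations, and a
deduplicated reference list — then renders it to deterministic Markdown
(and a simple paginated PDF) and emits a lossless machine-readable JSON
packet alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional

from .blood import AntigenPhenotype, AntigenStatus, BloodFlag, load_antigen_definitions
from .kb import REPORTABLE, ConfirmationStatus, key_to_str
from .model import CoverageSummary
from .pgx import PgxResult
from .triage import Section, SectionEntry, TriagedVariant

log = logging.getLogger(__name__)

PACKET_SCHEMA_VERSION = "1.0"

#: fixed limitations text shown on page 1 and in the limitations section
LIMITATIONS = [
    "Certain types of variation are not reliably detected by genome "
    "sequencing, including structural variants, triplet repeat expansions, "
    "copy number variants, uniparental disomy, and epigenetic changes; the "
    "definitive absence of a pathogenic variant cannot always be inferred.",
    "Coverage of disease-associated genes may be insufficient to detect all "
    "variants; per-gene coverage information is available upon request.",
    "Not all disease-associated genes have been identified, and the clinical "
    "significance of variants in many genes remains elusive.",
]

METHODOLOGY = (
    "Genome sequencing is performed to at least 30X mean coverage with >=95% "
    "of bases sequenced to at least 8X coverage. Reads are aligned to the "
    "reference sequence and variant calls are made at all positions with "
    ">=8X coverage. Annotated variants are filtered to identify (1) rare "
    "variants (MAF <5%) asserted disease-causing in mutation databases or "
    "classified pathogenic/likely pathogenic by the laboratory, (2) "
    "nonsense, frameshift, and canonical splice-site (+/-1,2) variants with "
    "MAF <1% in curated disease-associated genes, and (3) a fixed panel of "
    "pharmacogenomic variants. Variants are classified on a five-tier scale "
    "and all reported Mendelian findings are confirmed by Sanger sequencing "
    "before reporting. Red-cell and platelet antigens are predicted from "
    "genotypes over the blood-group genes."
)


class ReportBuildError(ValueError):
    """Report model cannot be built (unconfirmed finding, missing inputs)."""


@dataclass
class FindingRow:
    """One summary-table row: a reported variant-disease association."""

    disease: str
    inheritance: str
    phenotype_blurb: str
    gene: str
    transcript: str
    c_hgvs: str
    p_hgvs: str
    variant_key: str
    classification: str
    zygosity: str
    carrier_phenotype_note: Optional[str] = None
    indication: bool = False


@dataclass
class VariantDetail:
    variant_key: str
    gene: str
    transcript: str
    c_hgvs: str
    p_hgvs: str
    disease: str
    variant_frequency: str
    disease_prevalence: str
    carrier_frequency: str
    interpretation: str
    disease_summary: str
    familial_risk: str
    urls: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)


@dataclass
class GenomeReportDoc:
    case_id: str
    study_arm: str  # primary_care | cardiomyopathy
    coverage: dict
    indication_results: list[FindingRow]
    monogenic_findings: list[FindingRow]
    carrier_findings: list[FindingRow]
    pgx_results: list[dict]
    blood_statuses: dict[str, str]
    abo_rh: str
    blood_summary: str
    blood_flags: list[str]
    variant_details: list[VariantDetail]
    limitations: list[str]
    methodology: str
    references: list[str]
    indication_gene_coverage: list[dict] = field(default_factory=list)
    coverage_warnings: list[str] = field(default_factory=list)
    schema_version: str = PACKET_SCHEMA_VERSION


def coverage_gate(cov: CoverageSummary) -> tuple[str, list[str]]:
    """Check coverage against the 30X mean / 95% >=8X service thresholds.

    Returns ("pass" | "warn", warning texts). Substandard coverage warns —
    it is surfaced in the limitations section — but never fails the build.
    """
    warnings = []
    if cov.mean_coverage < 30.0:
        warnings.append(
            f"Mean coverage {cov.mean_coverage:.1f}X is below the 30X service threshold."
        )
    if cov.pct_bases_ge_8x < 95.0:
        warnings.append(
            f"Only {cov.pct_bases_ge_8x:.1f}% of bases reached 8X coverage "
            "(service threshold 95%)."
        )
    return ("warn" if warnings else "pass"), warnings


def build_report_model(
    case_id: str,
    study_arm: str,
    entries: list[tuple[TriagedVariant, SectionEntry]],
    pgx_results: list[PgxResult],
    blood: AntigenPhenotype,
    blood_summary: str,
    coverage: CoverageSummary,
    disease_info: Optional[dict[str, dict]] = None,
    indication_gene_coverage: Optional[list[dict]] = None,
) -> GenomeReportDoc:
    """Assemble the full report model from classified, confirmed findings.

    ``entries`` pairs each reportable triaged variant with one section entry
    per gene-disease association. Every Mendelian entry must be classified
    in a reportable tier and Sanger-confirmed; violations raise
    :class:`ReportBuildError` naming the variant. Ordering is deterministic:
    sections are fixed and rows sort by gene symbol.
    """
    if coverage is None:
        raise ReportBuildError("missing coverage summary")
    disease_info = disease_info or {}

    indication_rows: list[FindingRow] = []
    monogenic_rows: list[FindingRow] = []
    carrier_rows: list[FindingRow] = []
    details: dict[str, VariantDetail] = {}
    references: list[str] = []

    for tv, entry in entries:
        rec = entry.record
        if rec.classification not in REPORTABLE:
            raise ReportBuildError(
                f"variant {key_to_str(tv.key)} classified {rec.classification.value} "
                "does not meet the reporting threshold"
            )
        if rec.confirmation_status not in (
            ConfirmationStatus.CONFIRMED,
            ConfirmationStatus.CONFIRMED_ZYGOSITY_MISMATCH,
        ):
            raise ReportBuildError(
                f"variant {key_to_str(tv.key)} is not Sanger-confirmed "
                f"(status: {rec.confirmation_status.value})"
            )
        info = disease_info.get(rec.disease, {})
        row = FindingRow(
            disease=rec.disease,
            inheritance=rec.inheritance.value,
            phenotype_blurb=info.get("phenotype_blurb", ""),
            gene=rec.gene,
            transcript=rec.transcript,
            c_hgvs=rec.c_hgvs,
            p_hgvs=rec.p_hgvs,
            variant_key=key_to_str(tv.key),
            classification=rec.classification.value,
            zygosity=tv.variant.variant.zygosity.value,
            carrier_phenotype_note=rec.carrier_phenotype_note,
            indication=entry.indication,
        )
        if entry.section == Section.CARRIER:
            carrier_rows.append(row)
        else:
            monogenic_rows.append(row)
            if entry.indication:
                indication_rows.append(row)
        dkey = f"{row.variant_key}|{rec.disease}"
        freqs = tv.variant.frequencies
        details[dkey] = VariantDetail(
            variant_key=row.variant_key,
            gene=rec.gene,
            transcript=rec.transcript,
            c_hgvs=rec.c_hgvs,
            p_hgvs=rec.p_hgvs,
            disease=rec.disease,
            variant_frequency=_fmt_freq(freqs.maf_ea, freqs.maf_aa),
            disease_prevalence=info.get("prevalence", "unknown"),
            carrier_frequency=info.get("carrier_frequency", ""),
            interpretation=rec.interpretation,
            disease_summary=info.get("summary", ""),
            familial_risk=_familial_risk(rec.inheritance.value),
            urls=list(info.get("urls", [])),
            references=list(rec.references),
        )
        references.extend(rec.references)

    # deduplicated, order-preserving reference list
    seen = set()
    ref_list = []
    for r in references:
        if r not in seen:
            seen.add(r)
            ref_list.append(r)

    status, cov_warnings = coverage_gate(coverage)
    limitations = list(LIMITATIONS) + cov_warnings

    for rows in (indication_rows, monogenic_rows, carrier_rows):
        rows.sort(key=lambda r: (r.gene, r.c_hgvs, r.disease))

    return GenomeReportDoc(
        case_id=case_id,
        study_arm=study_arm,
        coverage={
            "mean_coverage": coverage.mean_coverage,
            "pct_bases_ge_8x": coverage.pct_bases_ge_8x,
            "total_variants": coverage.total_variants,
        },
        indication_results=indication_rows,
        monogenic_findings=monogenic_rows,
        carrier_findings=carrier_rows,
        pgx_results=[_pgx_dict(p) for p in pgx_results],
        blood_statuses={k: v.value for k, v in sorted(blood.statuses.items())},
        abo_rh=blood.abo_rh,
        blood_summary=blood_summary,
        blood_flags=sorted(f.value for f in blood.flags),
        variant_details=[details[k] for k in sorted(details)],
        limitations=limitations,
        methodology=METHODOLOGY,
        references=ref_list,
        indication_gene_coverage=list(indication_gene_coverage or []),
        coverage_warnings=cov_warnings,
    )


def _pgx_dict(p: PgxResult) -> dict:
    return {
        "drug": p.drug,
        "genes": list(p.genes),
        "diplotype": p.diplotype,
        "phenotype_phrase": p.phenotype_phrase,
        "detail": p.detail,
        "diplotype_frequency": p.diplotype_frequency,
        "no_call": p.no_call,
    }


def _fmt_freq(ea: Optional[float], aa: Optional[float]) -> str:
    def one(v):
        return f"{100 * v:.3g}%" if v is not None else "not observed"

    return f"EA {one(ea)}; AA {one(aa)}"


def _familial_risk(inheritance: str) -> str:
    return {
        "AD": "Autosomal dominant: each child of this individual has a 50% "
        "chance of inheriting the variant; first-degree relatives may carry it.",
        "AR": "Autosomal recessive: children are at risk only if the other "
        "parent carries a pathogenic variant in the same gene; siblings have "
        "a 50% chance of being carriers.",
        "XL": "X-linked: transmission risk depends on the sex of the carrier "
        "parent and child; maternal relatives may carry the variant.",
    }.get(inheritance, "")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _findings_table(rows: list[FindingRow], lines: list[str]) -> None:
    if not rows:
        lines.append("No findings to report in this section.")
        lines.append("")
        return
    lines.append("| Disease | Inheritance | Gene | Variant | Classification |")
    lines.append("|---|---|---|---|---|")
    for r in rows:
        variant = f"{r.c_hgvs} ({r.p_hgvs})"
        lines.append(
            f"| {r.disease} | {r.inheritance} | {r.gene} | {variant} | {r.classification} |"
        )
        if r.carrier_phenotype_note:
            lines.append(f"| | | | note: {r.carrier_phenotype_note} | |")
    lines.append("")


def render_markdown(doc: GenomeReportDoc) -> str:
    """Render the report as deterministic Markdown (same model, same bytes)."""
    L: list[str] = []
    L.append(f"# Genome Report — case {doc.case_id}")
    L.append("")
    L.append("## Result summary")
    L.append("")
    cov = doc.coverage
    L.append(
        f"Genome coverage: mean {cov['mean_coverage']:.1f}X; "
        f"{cov['pct_bases_ge_8x']:.1f}% of bases at >=8X. "
        f"{cov['total_variants']:,} variants identified versus the reference genome."
    )
    L.append("")
    if doc.study_arm == "cardiomyopathy":
        L.append("### Results related to the indication for testing")
        L.append("")
        _findings_table(doc.indication_results, L)
    L.append("### Monogenic disease risk")
    L.append("")
    _findings_table(doc.monogenic_findings, L)
    L.append("### Carrier risk")
    L.append("")
    _findings_table(doc.carrier_findings, L)

    L.append("### Pharmacogenomic associations")
    L.append("")
    L.append("| Drug | Genotype | Predicted response |")
    L.append("|---|---|---|")
    for p in doc.pgx_results:
        L.append(f"| {p['drug']} | {p['diplotype']} | {p['phenotype_phrase']} |")
    L.append("")

    L.append("### Blood group antigens")
    L.append("")
    L.append(doc.blood_summary)
    L.append("")
    L.append("Limitations of this test are listed in the Limitations section below.")
    L.append("")

    L.append("## Detailed variant information")
    L.append("")
    if not doc.variant_details:
        L.append("No reported Mendelian variants.")
        L.append("")
    for d in doc.variant_details:
        L.append(f"### {d.gene} {d.c_hgvs} ({d.p_hgvs}) — {d.disease}")
        L.append("")
        L.append(f"- Transcript: {d.transcript}")
        L.append(f"- Variant frequency: {d.variant_frequency}")
        L.append(f"- Disease prevalence: {d.disease_prevalence}")
        if d.carrier_frequency:
            L.append(f"- Carrier frequency: {d.carrier_frequency}")
        L.append(f"- Interpretation: {d.interpretation}")
        if d.disease_summary:
            L.append(f"- Disease summary: {d.disease_summary}")
        L.append(f"- Familial risk: {d.familial_risk}")
        for url in d.urls:
            L.append(f"- Resource: {url}")
        if d.references:
            L.append(f"- References: {'; '.join(d.references)}")
        L.append("")

    L.append("## Pharmacogenomic details")
    L.append("")
    for p in doc.pgx_results:
        L.append(f"### {p['drug']}")
        L.append("")
        L.append(f"- Genes: {', '.join(p['genes'])}")
        L.append(f"- Diplotype/genotype: {p['diplotype']}")
        L.append(f"- Predicted response: {p['phenotype_phrase']}")
        if p["detail"]:
            L.append(f"- Interpretation: {p['detail']}")
        if p["diplotype_frequency"] is not None:
            L.append(f"- Diplotype frequency: {p['diplotype_frequency']:.3g}")
        L.append("")

    L.append("## Blood group detail")
    L.append("")
    L.append(f"ABO Rh type: {doc.abo_rh}")
    L.append("")
    L.append("| Antigen | Predicted status |")
    L.append("|---|---|")
    for label, status in doc.blood_statuses.items():
        L.append(f"| {label} | {status} |")
    L.append("")

    if doc.study_arm == "cardiomyopathy" and doc.indication_gene_coverage:
        L.append("## Indication gene coverage")
        L.append("")
        L.append("| Gene | Mean coverage | % bases >=8X |")
        L.append("|---|---|---|")
        for row in doc.indication_gene_coverage:
            L.append(
                f"| {row['gene']} | {row['mean_coverage']:.1f}X | "
                f"{row['pct_bases_ge_8x']:.1f}% |"
            )
        L.append("")

    L.append("## Methodology")
    L.append("")
    L.append(doc.methodology)
    L.append("")
    L.append("## Limitations")
    L.append("")
    for item in doc.limitations:
        L.append(f"- {item}")
    L.append("")
    L.append("## References")
    L.append("")
    if doc.references:
        for i, r in enumerate(doc.references, 1):
            L.append(f"{i}. {r}")
    else:
        L.append("No references cited.")
    L.append("")
    return "\n".join(L)


def render(doc: GenomeReportDoc, format: str = "markdown") -> bytes:
    """Render the report model to document bytes.

    Markdown output is byte-deterministic for a fixed model. PDF output is
    a simple paginated rendering of the same text; its bytes embed no
    timestamps but page layout is a presentation concern only — the model
    and Markdown are the artifacts of record.
    """
    md = render_markdown(doc)
    if format == "markdown":
        return md.encode("utf-8")
    if format == "pdf":
        return _text_to_pdf(md)
    raise ValueError(f"unsupported format {format!r}")


def _text_to_pdf(text: str, lines_per_page: int = 60) -> bytes:
    """Minimal PDF 1.4 writer: monospaced text lines, paginated."""

    def esc(s: str) -> str:
        return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")

    lines = [ln if ln.strip() else " " for ln in text.split("\n")]
    pages = [lines[i : i + lines_per_page] for i in range(0, len(lines), lines_per_page)] or [[" "]]

    objects: list[bytes] = []

    def add(obj: bytes) -> int:
        objects.append(obj)
        return len(objects)

    font_id = add(b"<< /Type /Font /Subtype /Type1 /BaseFont /Courier >>")
    content_ids = []
    for page in pages:
        parts = ["BT /F1 9 Tf 36 756 Td 12 TL"]
        for ln in page:
            parts.append(f"({esc(ln)}) Tj T*")
        parts.append("ET")
        stream = "\n".join(parts).encode("latin-1", errors="replace")
        content_ids.append(
            add(b"<< /Length %d >>\nstream\n%s\nendstream" % (len(stream), stream))
        )
    page_ids = []
    pages_id = len(objects) + len(pages) + 1
    for cid in content_ids:
        page_ids.append(
            add(
                (
                    f"<< /Type /Page /Parent {pages_id} 0 R /MediaBox [0 0 612 792] "
                    f"/Contents {cid} 0 R /Resources << /Font << /F1 {font_id} 0 R >> >> >>"
                ).encode()
            )
        )
    kids = " ".join(f"{pid} 0 R" for pid in page_ids)
    add(f"<< /Type /Pages /Kids [{kids}] /Count {len(page_ids)} >>".encode())
    catalog_id = add(f"<< /Type /Catalog /Pages {pages_id} 0 R >>".encode())

    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, obj in enumerate(objects, 1):
        offsets.append(len(out))
        out += b"%d 0 obj\n" % i + obj + b"\nendobj\n"
    xref_at = len(out)
    out += b"xref\n0 %d\n" % (len(objects) + 1)
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += b"%010d 00000 n \n" % off
    out += (
        b"trailer\n<< /Size %d /Root %d 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(objects) + 1, catalog_id, xref_at)
    )
    return bytes(out)


# ---------------------------------------------------------------------------
# Structured packet
# ---------------------------------------------------------------------------


def emit_structured_packet(doc: GenomeReportDoc) -> dict:
    """Machine-readable twin of the report; lossless for the model."""
    packet = asdict(doc)
    packet["findings"] = [
        {
            "variant_key": r.variant_key,
            "disease": r.disease,
            "classification": r.classification,
            "section": section,
        }
        for rows, section in (
            (doc.carrier_findings, "CARRIER"),
            (doc.monogenic_findings, "MONOGENIC"),
        )
        for r in rows
    ]
    return packet


def packet_to_doc(packet: dict) -> GenomeReportDoc:
    data = {k: v for k, v in packet.items() if k != "findings"}
    data["indication_results"] = [FindingRow(**r) for r in data["indication_results"]]
    data["monogenic_findings"] = [FindingRow(**r) for r in data["monogenic_findings"]]
    data["carrier_findings"] = [FindingRow(**r) for r in data["carrier_findings"]]
    data["variant_details"] = [VariantDetail(**d) for d in data["variant_details"]]
    return GenomeReportDoc(**data)


def write_packet(doc: GenomeReportDoc, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(emit_structured_packet(doc), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_schema() -> dict:
    schema_path = importlib_resources.files("genoreport").joinpath(
        "data", "packet_schema.json"
    )
    return json.loads(Path(str(schema_path)).read_text())


def validate_packet(packet: dict, schema: Optional[dict] = None) -> None:
    """Structural validation of a packet against the shipped schema.

    Walks required keys and primitive types (a compact subset of JSON
    Schema sufficient for the packet's fixed shape); raises ValueError on
    the first violation.
    """
    schema = schema or load_schema()
    _validate_node(packet, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _validate_node(value, schema: dict, path: str) -> None:
    typ = schema.get("type")
    if typ:
        allowed = typ if isinstance(typ, list) else [typ]
        if value is None and "null" in allowed:
            return
        if not any(isinstance(value, _TYPES[t]) for t in allowed if t != "null"):
            raise ValueError(f"{path}: expected {typ}, got {type(value).__name__}")
        if isinstance(value, bool) and "boolean" not in allowed:
            raise ValueError(f"{path}: expected {typ}, got bool")
    for key in schema.get("required", []):
        if key not in value:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in value:
            _validate_node(value[key], sub, f"{path}.{key}")
    if "items" in schema and isinstance(value, list):
        for i, item in enumerate(value):
            _validate_node(item, schema["items"], f"{path}[{i}]")
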