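"""Packaged reported-findings fixture and seeded synthetic-case generator.

The packaged fixture transcribes the 49 reported findings from the first
20 study genomes (gene, HGVS, disease, classification, inheritance, report
section, and ascertainment filter). The synthetic-case generator plants
any subset of those findings — plus pharmacogenomic genotypes and
blood-group alleles — at concrete coordinates on a bundled mini-reference,
surrounded by common benign background variants that fail every filtration
arm by construction, and writes the VCF, mock resource tables, and a truth
table for oracle tests. Same seed and spec => byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kb import (
    Classification,
    ClassificationRecord,
    ConfirmationStatus,
    Inheritance,
    KnowledgeBase,
    key_to_str,
)
from .model import (
    AnnotatedVariant,
    Consequence,
    GenomicVariant,
    PopulationFrequencies,
    TranscriptAnnotation,
    Zygosity,
    classify_consequence,
    parse_c_hgvs_span,
    write_vcf,
)
from . import blood as blood_mod
from . import pgx as pgx_mod

_CLASS_MAP = {
    "P": Classification.PATHOGENIC,
    "LP": Classification.LIKELY_PATHOGENIC,
    "VUS:FP": Classification.VUS_FAVOR_PATHOGENIC,
}

#: fixed seed for the mini-reference sequence (shared by every case so that
#: planted coordinates and alleles are stable across specs)
_REFERENCE_SEED = 20141214

#: genes whose monogenic findings relate to the cardiomyopathy indication
INDICATION_GENES = frozenset({"MYH7", "MYBPC3"})

#: carrier findings annotated with a milder carrier phenotype on the report
CARRIER_PHENOTYPE_NOTES = {
    "WFS1": "Carriers may exhibit low frequency sensorineural hearing loss "
    "and/or diabetes mellitus.",
}


class DataIntegrityError(RuntimeError):
    pass


def _stable_id(text: str) -> int:
    """Process-independent small integer derived from a string."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


@dataclass(frozen=True)
class Table1Row:
    gene: str
    c_hgvs: str
    p_hgvs: str
    disease: str
    classification: str  # P | LP | VUS:FP
    inheritance: str  # AD | AR | XL
    section: str  # "Carrier Risk" | "Monogenic"
    filters: frozenset[str]  # subset of {HGMD, LOF}


def load_table1() -> list[Table1Row]:
    """Load the packaged 49-row reported-findings fixture.

    The file's SHA-256 is checked against the packaged sidecar so silent
    edits of the transcription surface as a data-integrity error.
    """
    data = importlib_resources.files("genoreport").joinpath("data")
    raw = Path(str(data / "table1.tsv")).read_bytes()
    expected = Path(str(data / "table1.sha256")).read_text().strip()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise DataIntegrityError(
            f"table1.tsv checksum mismatch: {digest} != {expected}"
        )
    df = pd.read_csv(Path(str(data / "table1.tsv")), sep="\t", dtype=str)
    rows = [
        Table1Row(
            gene=r["gene"],
            c_hgvs=r["c_hgvs"],
            p_hgvs=r["p_hgvs"],
            disease=r["disease"],
            classification=r["classification"],
            inheritance=r["inheritance"],
            section=r["section"],
            filters=frozenset(r["filters"].split(",")),
        )
        for r in df.to_dict("records")
    ]
    if len(rows) != 49:
        raise DataIntegrityError(f"expected 49 fixture rows, found {len(rows)}")
    return rows


def table1_accounting(rows: Optional[list[Table1Row]] = None) -> dict[str, int]:
    """Unique-variant and section accounting over the fixture."""
    rows = rows if rows is not None else load_table1()
    by_variant: dict[tuple[str, str], set[str]] = {}
    for r in rows:
        by_variant.setdefault((r.gene, r.c_hgvs), set()).add(r.section)
    carrier_only = sum(1 for s in by_variant.values() if s == {"Carrier Risk"})
    monogenic_only = sum(1 for s in by_variant.values() if s == {"Monogenic"})
    dual = sum(1 for s in by_variant.values() if len(s) == 2)
    return {
        "entries": len(rows),
        "unique_variants": len(by_variant),
        "carrier_only": carrier_only,
        "monogenic_only": monogenic_only,
        "dual_section": dual,
        "carrier_entries": sum(1 for r in rows if r.section == "Carrier Risk"),
        "monogenic_entries": sum(1 for r in rows if r.section == "Monogenic"),
    }


# ---------------------------------------------------------------------------
# Mini-reference and coordinate assignment
# ---------------------------------------------------------------------------

_MENDELIAN_CONTIG = "chrM1"
_PGX_CONTIG = "chrP1"
_BLOOD_CONTIG = "chrB1"
_GENE_BLOCK_START = 100_000
_GENE_BLOCK_SIZE = 10_000
_BACKGROUND_REGION = (1_000, 90_000)


def _table1_genes() -> list[str]:
    seen: list[str] = []
    for r in load_table1():
        if r.gene not in seen:
            seen.append(r.gene)
    return seen


def _span_length(c_hgvs: str) -> int:
    """Affected reference length for del/dup edits, from the c. span."""
    if c_hgvs == "c.3742-3759dup":  # printed with a dash in place of the
        return 18                    # range underscore; treat as c.3742_3759dup
    start, end, edit = parse_c_hgvs_span(c_hgvs)
    span = (end.base + end.offset) - (start.base + start.offset) + 1
    return max(span, 1)


@dataclass(frozen=True)
class PlantedCoordinate:
    chrom: str
    pos: int
    ref: str
    alt: str


class MiniReference:
    """Deterministic synthetic contigs carrying the planted variant sites."""

    def __init__(self) -> None:
        genes = _table1_genes()
        self.gene_block = {
            g: _GENE_BLOCK_START + i * _GENE_BLOCK_SIZE for i, g in enumerate(genes)
        }
        lengths = {
            _MENDELIAN_CONTIG: _GENE_BLOCK_START + (len(genes) + 1) * _GENE_BLOCK_SIZE,
            _PGX_CONTIG: 20_000,
            _BLOOD_CONTIG: 40_000,
        }
        rng = np.random.default_rng(_REFERENCE_SEED)
        bases = np.array(list("ACGT"))
        self.seqs = {
            name: bases[rng.integers(0, 4, size=length)]
            for name, length in lengths.items()
        }
        self._patch_sites()

    def _patch_sites(self) -> None:
        # panel and antigen sites must carry their declared reference alleles
        for s in pgx_mod.load_panel():
            self._set(s.chrom, s.pos, s.ref)
        for d in blood_mod.load_antigen_definitions():
            self._set(d.chrom, d.pos, d.ref)

    def _set(self, chrom: str, pos: int, ref: str) -> None:
        for i, b in enumerate(ref):
            self.seqs[chrom][pos - 1 + i] = b

    def base(self, chrom: str, pos: int, length: int = 1) -> str:
        return "".join(self.seqs[chrom][pos - 1 : pos - 1 + length])

    def flanks(self, chrom: str, pos: int, width: int = 10) -> tuple[str, str]:
        seq = self.seqs[chrom]
        left = "".join(seq[max(0, pos - 1 - width) : pos - 1])
        right = "".join(seq[pos : pos + width])
        return left, right

    def contigs(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.seqs.items()}

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                s = "".join(seq)
                for i in range(0, len(s), 70):
                    fh.write(s[i : i + 70] + "\n")

    def coordinate_for(self, row: Table1Row, index_in_gene: int) -> PlantedCoordinate:
        """Assign concrete VCF coordinates and alleles to a fixture row."""
        base_pos = self.gene_block[row.gene] + 500 + 97 * index_in_gene
        c = row.c_hgvs.replace(" ", "")
        chrom = _MENDELIAN_CONTIG
        if ">" in c:  # substitution: ref/alt bases from the HGVS edit
            ref_base, alt_base = c[-3], c[-1]
            self._set(chrom, base_pos, ref_base)
            return PlantedCoordinate(chrom, base_pos, ref_base, alt_base)
        if "dup" in c or "ins" in c:
            tail = c.split("dup")[-1] if "dup" in c else c.split("ins")[-1]
            if tail and set(tail) <= set("ACGT"):
                inserted = tail
            else:
                n = _span_length(c) if "dup" in c else 1
                inserted = self.base(chrom, base_pos + 1, n)
            anchor = self.base(chrom, base_pos)
            return PlantedCoordinate(chrom, base_pos, anchor, anchor + inserted)
        if "del" in c:
            tail = c.split("del")[-1]
            n = len(tail) if tail and set(tail) <= set("ACGT") else _span_length(c)
            if tail and set(tail) <= set("ACGT"):
                self._set(chrom, base_pos + 1, tail)
            anchor = self.base(chrom, base_pos)
            deleted = self.base(chrom, base_pos + 1, n)
            return PlantedCoordinate(chrom, base_pos, anchor + deleted, anchor)
        raise ValueError(f"cannot synthesize alleles for {row.c_hgvs!r}")


_reference_cache: Optional[MiniReference] = None


def get_reference() -> MiniReference:
    global _reference_cache
    if _reference_cache is None:
        _reference_cache = MiniReference()
    return _reference_cache


# ---------------------------------------------------------------------------
# Synthetic case specification and generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCaseSpec:
    seed: int
    n_background_variants: int = 1000
    planted: list[Table1Row] = field(default_factory=list)
    planted_zygosity: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_pgx: dict[str, str] = field(default_factory=dict)  # rsid -> het|hom_alt
    planted_blood: list[tuple[str, str]] = field(default_factory=list)  # (antigen, het|hom_alt)
    low_coverage_sites: list[tuple[str, int]] = field(default_factory=list)
    mean_coverage: float = 41.0
    pct_bases_ge_8x: float = 95.5
    study_arm: str = "primary_care"
    case_id: str = "SYN-CASE"


@dataclass
class TruthRow:
    variant_key: str
    gene: str
    c_hgvs: str
    p_hgvs: str
    disease: str
    classification: str
    inheritance: str
    section: str
    expected_arms: list[str]
    zygosity: str


@dataclass
class CaseBundle:
    spec: SyntheticCaseSpec
    vcf_path: Path
    resources_dir: Path
    fasta_path: Path
    coverage_path: Path
    truth_path: Path
    truth: list[TruthRow]
    background_keys: list[str]
    transcript_map: dict[tuple, TranscriptAnnotation]
    frequencies: dict[tuple, PopulationFrequencies]
    coverage: dict[tuple[str, int], int]


def default_zygosity(row: Table1Row) -> Zygosity:
    if row.inheritance == "XL":
        return Zygosity.HEMIZYGOUS
    return Zygosity.HETEROZYGOUS


def expected_arms(row: Table1Row, consequence: Consequence) -> list[str]:
    """Arms the triage engine is expected to record for a planted row.

    The assertion arm fires for rows carried in the assertion database
    (Filter includes HGMD); the LOF arm requires the consequence to be
    loss-of-function under the default +-1,2 splice window, so the +5
    splice-region finding ascertained by the published LOF filter is
    expected to differ (the documented exception).
    """
    arms = []
    if "HGMD" in row.filters:
        arms.append("ASSERTION")
    if "LOF" in row.filters and consequence in (
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
    ):
        arms.append("LOF")
    return arms


def generate_case(spec: SyntheticCaseSpec, outdir: str) -> CaseBundle:
    """Generate a synthetic case: VCF, mock resources, coverage, truth table.

    Background variants are drawn with MAFs in [0.05, 0.5] and no assertion
    or gene-list membership, so they fail all three arms by construction.
    Planted findings receive MAF 0.1% except where a printed arm set
    requires an intermediate frequency (between the 1% LOF and 5% assertion
    cutoffs).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    resources = out / "resources"
    resources.mkdir(exist_ok=True)
    ref = get_reference()
    rng = np.random.default_rng(spec.seed)

    variants: list[GenomicVariant] = []
    truth: list[TruthRow] = []
    transcript_map: dict[tuple, TranscriptAnnotation] = {}
    frequencies: dict[tuple, PopulationFrequencies] = {}
    assertion_rows: list[tuple[str, str]] = []
    kb = KnowledgeBase()
    today = dt.date(2014, 6, 1)

    # --- planted Mendelian findings ---------------------------------------
    per_gene_index: dict[str, dict[str, int]] = {}
    planted_positions: set[tuple[str, int]] = set()
    coords: dict[tuple[str, str], PlantedCoordinate] = {}
    for row in spec.planted:
        gene_rows = per_gene_index.setdefault(row.gene, {})
        if row.c_hgvs not in gene_rows:
            gene_rows[row.c_hgvs] = len(gene_rows)
        coord = ref.coordinate_for(row, gene_rows[row.c_hgvs])
        coords[(row.gene, row.c_hgvs)] = coord
        planted_positions.add((coord.chrom, coord.pos))

    handled: set[tuple[str, str]] = set()
    for row in spec.planted:
        coord = coords[(row.gene, row.c_hgvs)]
        key = (coord.chrom, coord.pos, coord.ref, coord.alt)
        zyg_name = spec.planted_zygosity.get(
            (row.gene, row.c_hgvs), default_zygosity(row).value
        )
        consequence = classify_consequence(row.c_hgvs, row.p_hgvs)
        if (row.gene, row.c_hgvs) not in handled:
            handled.add((row.gene, row.c_hgvs))
            variants.append(
                GenomicVariant(
                    chrom=coord.chrom,
                    pos=coord.pos,
                    ref=coord.ref,
                    alt=coord.alt,
                    zygosity=Zygosity(zyg_name),
                    genotype_quality=99,
                )
            )
            transcript_map[key] = TranscriptAnnotation(
                gene=row.gene,
                transcript=f"NM_{_stable_id(row.gene) % 100000:05d}.1",
                c_hgvs=row.c_hgvs,
                p_hgvs=row.p_hgvs,
                consequence=consequence,
            )
            # MPO-style rows: canonical splice ascertained by assertion only,
            # so the MAF must sit between the LOF and assertion cutoffs
            lof_consequence = consequence in (
                Consequence.NONSENSE,
                Consequence.FRAMESHIFT,
                Consequence.CANONICAL_SPLICE,
            )
            if lof_consequence and "LOF" not in row.filters:
                maf = 0.02
            else:
                maf = 0.001
            frequencies[key] = PopulationFrequencies(maf_ea=maf, maf_aa=maf)
            if "HGMD" in row.filters:
                assertion_rows.append((key_to_str(key), "DM"))
        kb.add(
            ClassificationRecord(
                key=key,
                classification=_CLASS_MAP[row.classification],
                disease=row.disease,
                inheritance=Inheritance(row.inheritance),
                interpretation=(
                    f"{row.gene} {row.c_hgvs} ({row.p_hgvs}) has been reported in "
                    f"association with {row.disease} and meets the "
                    f"{row.classification} evidence level."
                ),
                references=[f"PMID:{9_000_000 + (_stable_id(row.gene + row.disease) % 999_983)}"],
                last_full_assessment=today - dt.timedelta(days=30),
                confirmation_status=ConfirmationStatus.CONFIRMED,
                carrier_phenotype_note=CARRIER_PHENOTYPE_NOTES.get(row.gene),
                gene=row.gene,
                transcript=transcript_map[key].transcript,
                c_hgvs=row.c_hgvs,
                p_hgvs=row.p_hgvs,
            )
        )
        truth.append(
            TruthRow(
                variant_key=key_to_str(key),
                gene=row.gene,
                c_hgvs=row.c_hgvs,
                p_hgvs=row.p_hgvs,
                disease=row.disease,
                classification=row.classification,
                inheritance=row.inheritance,
                section=row.section,
                expected_arms=expected_arms(
                    row, transcript_map[key].consequence
                ),
                zygosity=zyg_name,
            )
        )

    # --- background variants ----------------------------------------------
    lo, hi = _BACKGROUND_REGION
    n = spec.n_background_variants
    positions = rng.choice(np.arange(lo, hi), size=n, replace=False)
    positions.sort()
    mafs = rng.uniform(0.05, 0.5, size=n)
    background_keys: list[str] = []
    bases = "ACGT"
    for i, (pos, maf) in enumerate(zip(positions, mafs)):
        pos = int(pos)
        if (_MENDELIAN_CONTIG, pos) in planted_positions:
            raise RuntimeError(f"background collides with planted site at {pos}")
        ref_base = ref.base(_MENDELIAN_CONTIG, pos)
        alt_base = bases[(bases.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
        zyg = Zygosity.HETEROZYGOUS if rng.random() < 0.6 else Zygosity.HOMOZYGOUS
        key = (_MENDELIAN_CONTIG, pos, ref_base, alt_base)
        variants.append(
            GenomicVariant(
                chrom=_MENDELIAN_CONTIG,
                pos=pos,
                ref=ref_base,
                alt=alt_base,
                zygosity=zyg,
                genotype_quality=float(int(rng.integers(40, 100))),
            )
        )
        transcript_map[key] = TranscriptAnnotation(
            gene=f"BG{i:04d}",
            transcript=f"NM_9{i:05d}.1",
            c_hgvs=f"c.{100 + i}{ref_base}>{alt_base}",
            p_hgvs="p.?",
            consequence=Consequence.MISSENSE,
        )
        frequencies[key] = PopulationFrequencies(maf_ea=float(maf), maf_aa=float(maf))
        background_keys.append(key_to_str(key))

    # --- planted PGx genotypes ---------------------------------------------
    panel = {s.rsid: s for s in pgx_mod.load_panel()}
    for rsid, gt in sorted(spec.planted_pgx.items()):
        site = panel[rsid]
        variants.append(
            GenomicVariant(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=site.alt,
                zygosity=Zygosity.HETEROZYGOUS if gt == "het" else Zygosity.HOMOZYGOUS,
                genotype_quality=99,
                rsid=rsid,
            )
        )

    # --- planted blood-group alleles ---------------------------------------
    defs = {f"{d.system} {d.antigen}": d for d in blood_mod.load_antigen_definitions()}
    seen_blood: set[tuple[str, int]] = set()
    for antigen, gt in spec.planted_blood:
        d = defs[antigen]
        if d.site in seen_blood:
            continue
        seen_blood.add(d.site)
        variants.append(
            GenomicVariant(
                chrom=d.chrom,
                pos=d.pos,
                ref=d.ref,
                alt=d.alt,
                zygosity=Zygosity.HETEROZYGOUS if gt == "het" else Zygosity.HOMOZYGOUS,
                genotype_quality=99,
            )
        )

    # --- write outputs ------------------------------------------------------
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    vcf_path = out / "case.vcf"
    write_vcf(str(vcf_path), variants, ref.contigs(), sample=spec.case_id)

    fasta_path = out / "miniref.fa"
    ref.write_fasta(str(fasta_path))

    coverage = {site: 3 for site in spec.low_coverage_sites}
    coverage_path = out / "coverage.tsv"
    with open(coverage_path, "w") as fh:
        fh.write("chrom\tpos\tdepth\n")
        for (chrom, pos), depth in sorted(coverage.items()):
            fh.write(f"{chrom}\t{pos}\t{depth}\n")

    with open(resources / "assertions.tsv", "w") as fh:
        fh.write("variant_key\tcategory\n")
        for key_str, cat in sorted(set(assertion_rows)):
            fh.write(f"{key_str}\t{cat}\n")

    genes = _table1_genes()
    table1 = load_table1()
    first_row = {}
    for r in table1:
        first_row.setdefault(r.gene, r)
    with open(resources / "genelist.tsv", "w") as fh:
        fh.write("gene\tinheritance\tdisease\tindication_gene\n")
        for g in sorted(genes):
            r = first_row[g]
            flag = "1" if g in INDICATION_GENES else "0"
            fh.write(f"{g}\t{r.inheritance}\t{r.disease}\t{flag}\n")

    with open(resources / "frequencies.tsv", "w") as fh:
        fh.write("variant_key\tmaf_ea\tmaf_aa\n")
        for key in sorted(frequencies):
            f = frequencies[key]
            fh.write(f"{key_to_str(key)}\t{f.maf_ea}\t{f.maf_aa}\n")

    kb.save(str(resources / "kb_state.tsv"))

    with open(resources / "transcript_map.tsv", "w") as fh:
        fh.write("variant_key\tgene\ttranscript\tc_hgvs\tp_hgvs\tconsequence\n")
        for key in sorted(transcript_map):
            a = transcript_map[key]
            fh.write(
                f"{key_to_str(key)}\t{a.gene}\t{a.transcript}\t{a.c_hgvs}\t"
                f"{a.p_hgvs}\t{a.consequence.value}\n"
            )

    # panel sites are part of the triage resources (PGX arm)
    src_panel = Path(str(importlib_resources.files("genoreport").joinpath("data", "pgx_panel.tsv")))
    (resources / "pgx_panel.tsv").write_text(src_panel.read_text())

    truth_path = out / "truth.json"
    payload = {
        "spec": {
            "seed": spec.seed,
            "n_background_variants": spec.n_background_variants,
            "study_arm": spec.study_arm,
            "case_id": spec.case_id,
            "mean_coverage": spec.mean_coverage,
            "pct_bases_ge_8x": spec.pct_bases_ge_8x,
        },
        "planted": [asdict(t) for t in truth],
        "background_keys": background_keys,
        "planted_pgx": spec.planted_pgx,
        "planted_blood": list(spec.planted_blood),
    }
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    return CaseBundle(
        spec=spec,
        vcf_path=vcf_path,
        resources_dir=resources,
        fasta_path=fasta_path,
        coverage_path=coverage_path,
        truth_path=truth_path,
        truth=truth,
        background_keys=background_keys,
        transcript_map=transcript_map,
        frequencies=frequencies,
        coverage=coverage,
    )


def annotate_variants(
    variants: list[GenomicVariant],
    transcript_map: dict[tuple, TranscriptAnnotation],
    frequencies: dict[tuple, PopulationFrequencies],
) -> list[AnnotatedVariant]:
    """Join raw calls to annotation and frequency resources.

    Variants outside the transcript map (pharmacogenomic and blood-group
    sites) get a placeholder annotation with consequence ``other``.
    """
    out = []
    for v in variants:
        ann = transcript_map.get(v.key) or TranscriptAnnotation(
            gene="", transcript="", c_hgvs="c.0", p_hgvs="p.?",
            consequence=Consequence.OTHER,
        )
        out.append(
            AnnotatedVariant(
                variant=v,
                annotation=ann,
                frequencies=frequencies.get(v.key, PopulationFrequencies()),
            )
        )
    return out


def load_transcript_map(path: str) -> dict[tuple, TranscriptAnnotation]:
    from .kb import key_from_str

    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        key_from_str(r["variant_key"]): TranscriptAnnotation(
            gene=r["gene"],
            transcript=r["transcript"],
            c_hgvs=r["c_hgvs"],
            p_hgvs=r["p_hgvs"],
            consequence=Consequence(r["consequence"]),
        )
        for r in df.to_dict("records")
    }


def load_coverage(path: str) -> dict[tuple[str, int], int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {(r["chrom"], int(r["pos"])): int(r["depth"]) for r in df.to_dict("records")}
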