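"""Three-arm variant filtration, reporting threshold, and section routing.

Genome-wide calls are triaged through three independent ascertainment arms:

* **ASSERTION** — rare variants (MAF < 5% in the European-American or
  African-American reference chromosomes) carried in the assertion database
  as disease-causing (DM) or possible disease-causing (DM?), or already
  classified Pathogenic/Likely pathogenic in the laboratory's own store.
* **LOF** — predicted loss-of-function variants (nonsense, frameshift,
  canonical splice +-1,2) with MAF < 1%, in a curated disease-gene list.
* **PGX** — fixed pharmacogenomic panel sites, matched by key or rsID.

Variants surviving triage pass the reporting threshold only when classified
Pathogenic, Likely pathogenic, or Uncertain significance: favor pathogenic,
and are then routed to the Carrier-Risk and/or Monogenic report sections
from the inheritance of each gene-disease association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .kb import (
    Classification,
    ClassificationRecord,
    ConfirmationStatus,
    Inheritance,
    KnowledgeBase,
    REPORTABLE,
    VariantKey,
    key_from_str,
    key_to_str,
)
from .model import (
    AnnotatedVariant,
    GenomicVariant,
    LOF_CONSEQUENCES,
    PopulationFrequencies,
    Zygosity,
)

log = logging.getLogger(__name__)


class Arm(str, Enum):
    ASSERTION = "ASSERTION"
    LOF = "LOF"
    PGX = "PGX"


class Section(str, Enum):
    INDICATION = "INDICATION"
    MONOGENIC = "MONOGENIC"
    CARRIER = "CARRIER"


class AssertionCategory(str, Enum):
    DM = "DM"
    DM_QUESTIONABLE = "DM_questionable"
    OTHER = "other"


#: categories that satisfy the assertion arm
_DISEASE_CAUSING = {AssertionCategory.DM, AssertionCategory.DM_QUESTIONABLE}
_PRIOR_PATHOGENIC = {Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC}


@dataclass
class GeneListEntry:
    gene: str
    inheritance: Inheritance
    disease: str
    indication_gene: bool = False


@dataclass
class TriagedVariant:
    variant: AnnotatedVariant
    arms: set[Arm] = field(default_factory=set)
    sections: set[Section] = field(default_factory=set)
    confirmation_risk: bool = False
    confirmation_status: ConfirmationStatus = ConfirmationStatus.PENDING

    @property
    def key(self) -> VariantKey:
        return self.variant.key


class RoutingError(ValueError):
    """Inheritance unknown for a gene-disease pairing; variant is held."""


@dataclass
class TriageResources:
    """All resource tables the triage arms consult."""

    assertions: dict[VariantKey, AssertionCategory]
    gene_list: dict[str, GeneListEntry]
    frequencies: dict[VariantKey, PopulationFrequencies]
    kb: KnowledgeBase
    pgx_sites: dict[VariantKey, str]  # key -> rsid
    pgx_rsids: set[str] = field(default_factory=set)
    assertion_maf_cutoff: float = 0.05
    lof_maf_cutoff: float = 0.01
    maf_gate_mode: str = "any"  # "any" (disjunctive, default) or "all"

    def __post_init__(self) -> None:
        if not self.pgx_rsids:
            self.pgx_rsids = {r for r in self.pgx_sites.values() if r}
        for cutoff in (self.assertion_maf_cutoff, self.lof_maf_cutoff):
            if not (0 < cutoff <= 1):
                raise ValueError(f"MAF cutoff must be in (0,1], got {cutoff}")
        if self.maf_gate_mode not in ("any", "all"):
            raise ValueError("maf_gate_mode must be 'any' or 'all'")

    @classmethod
    def load(
        cls,
        resources_dir: str,
        kb: Optional[KnowledgeBase] = None,
        **kwargs,
    ) -> "TriageResources":
        """Load assertions.tsv, genelist.tsv, frequencies.tsv (and kb_state.tsv
        plus pgx_panel.tsv if present) from a resources directory."""
        d = Path(resources_dir)
        for required in ("assertions.tsv", "genelist.tsv", "frequencies.tsv"):
            if not (d / required).exists():
                raise FileNotFoundError(f"missing resource table {d / required}")

        adf = pd.read_csv(d / "assertions.tsv", sep="\t", dtype=str)
        assertions = {
            key_from_str(row["variant_key"]): AssertionCategory(row["category"])
            for _, row in adf.iterrows()
        }

        gdf = pd.read_csv(d / "genelist.tsv", sep="\t", dtype=str)
        if gdf["gene"].duplicated().any():
            dupes = sorted(gdf.loc[gdf["gene"].duplicated(), "gene"])
            raise ValueError(f"duplicate gene symbols in gene list: {dupes}")
        gene_list = {
            row["gene"]: GeneListEntry(
                gene=row["gene"],
                inheritance=Inheritance(row["inheritance"]),
                disease=row["disease"],
                indication_gene=str(row.get("indication_gene", "0")) in ("1", "True", "true"),
            )
            for _, row in gdf.iterrows()
        }

        fdf = pd.read_csv(d / "frequencies.tsv", sep="\t", dtype=str)
        frequencies = {}
        for _, row in fdf.iterrows():
            frequencies[key_from_str(row["variant_key"])] = PopulationFrequencies(
                maf_ea=float(row["maf_ea"]) if row["maf_ea"] not in (None, "", "NA") else None,
                maf_aa=float(row["maf_aa"]) if row["maf_aa"] not in (None, "", "NA") else None,
            )

        # the store consulted here holds *prior* classifications (the lab's
        # knowledge before this case); a case's own kb_state.tsv assessments
        # belong to the reporting-threshold stage, so nothing is auto-loaded
        if kb is None:
            kb = KnowledgeBase()

        pgx_sites: dict[VariantKey, str] = {}
        panel_path = d / "pgx_panel.tsv"
        if panel_path.exists():
            pdf = pd.read_csv(panel_path, sep="\t", dtype=str)
            for _, row in pdf.iterrows():
                key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                pgx_sites[key] = row["rsid"]

        return cls(
            assertions=assertions,
            gene_list=gene_list,
            frequencies=frequencies,
            kb=kb,
            pgx_sites=pgx_sites,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Frequency gate
# ---------------------------------------------------------------------------


def maf_gate(
    freqs: Optional[PopulationFrequencies], cutoff: float, mode: str = "any"
) -> bool:
    """MAF-below-cutoff gate over the EA/AA populations.

    A population with no recorded frequency passes its own test (an
    unobserved variant is treated as rare). Default mode "any" passes when
    at least one population is below the cutoff (the disjunctive reading of
    "MAF < cutoff in EA or AA"); mode "all" requires both.
    """
    if freqs is None:
        return True
    ea_pass = freqs.maf_ea is None or freqs.maf_ea < cutoff
    aa_pass = freqs.maf_aa is None or freqs.maf_aa < cutoff
    return (ea_pass or aa_pass) if mode == "any" else (ea_pass and aa_pass)


# ---------------------------------------------------------------------------
# Filtration arms
# ---------------------------------------------------------------------------


def arm_assertion(
    v: AnnotatedVariant,
    assertions: dict[VariantKey, AssertionCategory],
    kb: KnowledgeBase,
    maf_cutoff: float = 0.05,
    maf_gate_mode: str = "any",
) -> bool:
    """Assertion-database arm: rare + (DM/DM? asserted or P/LP classified)."""
    if not maf_gate(v.frequencies, maf_cutoff, maf_gate_mode):
        return False
    category = assertions.get(v.key)
    if category in _DISEASE_CAUSING:
        return True
    return any(rec.classification in _PRIOR_PATHOGENIC for rec in kb.get(v.key))


def arm_lof(
    v: AnnotatedVariant,
    gene_list: dict[str, GeneListEntry],
    maf_cutoff: float = 0.01,
    maf_gate_mode: str = "any",
) -> bool:
    """Loss-of-function arm: LOF consequence + MAF < 1% + curated gene."""
    if v.annotation.consequence not in LOF_CONSEQUENCES:
        return False
    if not maf_gate(v.frequencies, maf_cutoff, maf_gate_mode):
        return False
    return v.annotation.gene in gene_list


def arm_pgx(
    v: GenomicVariant,
    pgx_sites: dict[VariantKey, str],
    pgx_rsids: Optional[set[str]] = None,
) -> bool:
    """Pharmacogenomic arm: panel-site match by key or rsID; frequency and
    consequence are ignored."""
    if v.key in pgx_sites:
        return True
    if pgx_rsids is None:
        pgx_rsids = {r for r in pgx_sites.values() if r}
    return v.rsid is not None and v.rsid in pgx_rsids


def triage(
    variants: Iterable[AnnotatedVariant], resources: TriageResources
) -> list[TriagedVariant]:
    """Run the three arms over all variants; keep those with >= 1 arm hit.

    Output order is deterministic: (chrom, pos, alt).
    """
    out: list[TriagedVariant] = []
    for v in variants:
        arms: set[Arm] = set()
        if arm_assertion(
            v,
            resources.assertions,
            resources.kb,
            resources.assertion_maf_cutoff,
            resources.maf_gate_mode,
        ):
            arms.add(Arm.ASSERTION)
        if arm_lof(
            v, resources.gene_list, resources.lof_maf_cutoff, resources.maf_gate_mode
        ):
            arms.add(Arm.LOF)
        if arm_pgx(v.variant, resources.pgx_sites, resources.pgx_rsids):
            arms.add(Arm.PGX)
        if arms:
            out.append(TriagedVariant(variant=v, arms=arms))
    out.sort(key=lambda tv: (tv.variant.variant.chrom, tv.variant.variant.pos,
                             tv.variant.variant.alt))
    return out


# ---------------------------------------------------------------------------
# Reporting threshold and section routing
# ---------------------------------------------------------------------------


def apply_reporting_threshold(
    tv: TriagedVariant, rec: Optional[ClassificationRecord]
) -> bool:
    """True iff the variant clears the classification threshold for return.

    Only Pathogenic, Likely pathogenic, and VUS: favor pathogenic variants
    are reported; PGX-arm-only variants bypass this gate (pharmacogenomic
    alleles are not classified on the Mendelian scale).
    """
    if tv.arms == {Arm.PGX}:
        return True
    if rec is None:
        return False
    return rec.classification in REPORTABLE


@dataclass
class SectionEntry:
    """One report-section entry: a (variant, disease association) pairing."""

    record: ClassificationRecord
    section: Section
    indication: bool = False


def route_sections(
    tv: TriagedVariant,
    records: Iterable[ClassificationRecord],
    indication_context: str = "primary_care",
    gene_list: Optional[dict[str, GeneListEntry]] = None,
) -> list[SectionEntry]:
    """Route a reportable variant to report sections, one entry per
    gene-disease association.

    AR disease + heterozygous -> Carrier Risk; AR + homozygous -> Monogenic;
    AD or XL disease -> Monogenic. A variant whose gene carries both an AR
    and an AD association yields one entry per association. Monogenic
    entries in indication genes are tagged INDICATION for cardiomyopathy
    cases.
    """
    records = list(records)
    if not records:
        raise RoutingError(
            f"no classification record (inheritance unknown) for {key_to_str(tv.key)}"
        )
    zyg = tv.variant.variant.zygosity
    entries: list[SectionEntry] = []
    for rec in sorted(records, key=lambda r: r.disease):
        if rec.inheritance is None:
            raise RoutingError(
                f"missing inheritance for {key_to_str(tv.key)} / {rec.disease}"
            )
        if rec.inheritance == Inheritance.AR and zyg == Zygosity.HETEROZYGOUS:
            section = Section.CARRIER
        else:
            # AD, XL, or biallelic AR all confer personal disease risk
            section = Section.MONOGENIC
        indication = (
            section == Section.MONOGENIC
            and indication_context == "cardiomyopathy"
            and gene_list is not None
            and rec.gene in gene_list
            and gene_list[rec.gene].indication_gene
        )
        entries.append(SectionEntry(record=rec, section=section, indication=indication))
    tv.sections = {e.section for e in entries}
    if any(e.indication for e in entries):
        tv.sections.add(Section.INDICATION)
    return entries


# ---------------------------------------------------------------------------
# Confirmation-risk flagging
# ---------------------------------------------------------------------------


def _edge_run(seq: str, from_end: bool) -> int:
    """Length of the homopolymer run at one edge of a sequence."""
    if not seq:
        return 0
    s = seq[::-1] if from_end else seq
    run, base = 0, s[0]
    for ch in s:
        if ch != base:
            break
        run += 1
    return run


def flag_confirmation_risk(
    v: GenomicVariant,
    left_context: str = "",
    right_context: str = "",
    gq_threshold: float = 30.0,
    homopolymer_min: int = 6,
) -> bool:
    """Flag calls matching the two observed false-positive failure modes:
    indels with low genotype quality, and variants abutting repetitive
    polynucleotide stretches.

    ``left_context``/``right_context`` are the flanking reference sequences
    (default 10 bp each side upstream in the pipeline); with no context
    provided only the quality rule applies.
    """
    if v.is_indel and v.genotype_quality < gq_threshold:
        return True
    if _edge_run(left_context, from_end=True) >= homopolymer_min:
        return True
    if _edge_run(right_context, from_end=False) >= homopolymer_min:
        return True
    return False
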