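"""Table-driven red-cell and platelet antigen prediction from genotypes.

Antigen presence is evaluated from genotypes at the defining sites listed
in the packaged antigen table (57 RBC antigens and all 33 human platelet
antigens). Each antigen row names the allele (reference or alternate) that
carries the antigen: the antigen is *present* when at least one copy of the
carrying allele is observed, *absent* otherwise, and *undetermined* when
any defining site is a no-call. ABO type and RhD status are composed into
the familiar "O positive"-style string; ABO is derived from an O-null site
and a B-allele site, and RhD from a deletion tag site (whole-gene RHD
deletion is not a small-variant call, so a proxy site stands in for it).

Three summary flags are derived from the phenotype alone: transfusion risk
(a high-prevalence antigen is absent), donor candidacy (a highly
immunogenic antigen is absent), and a disease-susceptibility note (an
absent antigen carries a disease association note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import GenomicVariant
from .pgx import GenotypeCall, MIN_CALLABLE_DEPTH, _ALT_COUNT

log = logging.getLogger(__name__)


class AntigenStatus(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNDETERMINED = "undetermined"


class BloodFlag(str, Enum):
    TRANSFUSION_RISK = "transfusion_risk"
    DONOR_CANDIDATE = "donor_candidate"
    DISEASE_SUSCEPTIBILITY_NOTE = "disease_susceptibility_note"


@dataclass(frozen=True)
class AntigenDefinition:
    system: str
    antigen: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    present_on: str  # "ref", "alt", or the ABO special markers "abo_A"/"abo_B"
    high_prevalence: bool = False
    immunogenic: bool = False
    disease_note: str = ""

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class AntigenPhenotype:
    statuses: dict[str, AntigenStatus]  # "<system> <antigen>" -> status
    abo_rh: str
    flags: set[BloodFlag] = field(default_factory=set)
    rare_absent: list[str] = field(default_factory=list)


def _data_path(name: str) -> Path:
    return Path(str(importlib_resources.files("genoreport").joinpath("data", name)))


def load_antigen_definitions(path: Optional[str] = None) -> list[AntigenDefinition]:
    df = pd.read_csv(path or _data_path("antigen_defs.tsv"), sep="\t", dtype=str).fillna("")
    defs = [
        AntigenDefinition(
            system=r["system"],
            antigen=r["antigen"],
            gene=r["gene"],
            chrom=r["chrom"],
            pos=int(r["pos"]),
            ref=r["ref"],
            alt=r["alt"],
            present_on=r["present_on"],
            high_prevalence=r["high_prevalence"] == "1",
            immunogenic=r["immunogenic"] == "1",
            disease_note=r["disease_note"],
        )
        for r in df.to_dict("records")
    ]
    _validate_definitions(defs)
    return defs


def _validate_definitions(defs: list[AntigenDefinition]) -> None:
    seen: dict[tuple, str] = {}
    for d in defs:
        label = f"{d.system} {d.antigen}"
        if label in seen.values():
            raise ValueError(f"duplicate antigen definition {label}")
        prior = seen.get((d.site, d.present_on))
        if prior is not None and d.present_on in ("ref", "alt"):
            raise ValueError(
                f"contradictory definitions: {prior} and {label} both claim the "
                f"{d.present_on} allele at {d.chrom}:{d.pos}"
            )
        seen[(d.site, d.present_on)] = label
        if d.present_on not in ("ref", "alt", "abo_A", "abo_B"):
            raise ValueError(f"unknown presence logic {d.present_on!r} for {label}")


def load_regions(path: Optional[str] = None) -> pd.DataFrame:
    """Region config: per-gene exon intervals (plus 10 intronic bases each
    side, already folded into the interval bounds)."""
    df = pd.read_csv(path or _data_path("blood_regions.tsv"), sep="\t", dtype=str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Genotype extraction
# ---------------------------------------------------------------------------


def extract_blood_genotypes(
    variants: Iterable[GenomicVariant],
    definitions: list[AntigenDefinition],
    regions: Optional[pd.DataFrame] = None,
    coverage: Optional[Mapping[tuple[str, int], int]] = None,
    default_depth: int = 30,
    min_depth: int = MIN_CALLABLE_DEPTH,
) -> dict[tuple[str, int], GenotypeCall]:
    """Genotype every antigen-defining site.

    Variant calls outside the configured gene regions are ignored; absent
    sites follow the same covered-implies-hom-ref / uncovered-implies-no-call
    semantics as the pharmacogenomic panel.
    """
    if regions is None:
        regions = load_regions()
    intervals = [
        (r["chrom"], int(r["start"]), int(r["end"])) for r in regions.to_dict("records")
    ]

    def in_regions(v: GenomicVariant) -> bool:
        return any(c == v.chrom and s <= v.pos <= e for c, s, e in intervals)

    by_key = {v.key: v for v in variants if in_regions(v)}
    calls: dict[tuple[str, int], GenotypeCall] = {}
    from .model import Zygosity

    for d in definitions:
        if d.site in calls:
            continue
        v = by_key.get((d.chrom, d.pos, d.ref, d.alt))
        if v is not None:
            calls[d.site] = (
                GenotypeCall.HET
                if v.zygosity == Zygosity.HETEROZYGOUS
                else GenotypeCall.HOM_ALT
            )
        elif (coverage or {}).get(d.site, default_depth) >= min_depth:
            calls[d.site] = GenotypeCall.HOM_REF
        else:
            calls[d.site] = GenotypeCall.NO_CALL
    return calls


# ---------------------------------------------------------------------------
# Antigen prediction
# ---------------------------------------------------------------------------


def _abo_type(
    defs: list[AntigenDefinition], calls: Mapping[tuple[str, int], GenotypeCall]
) -> tuple[Optional[str], AntigenStatus, AntigenStatus]:
    """Compose the ABO type from the O-null and B-allele tag sites.

    Functional (non-O) allele count is 2 minus the O-null alt count; B
    alleles are assumed to ride on functional haplotypes. Returns
    (type string or None if undetermined, A status, B status).
    """
    o_def = next(d for d in defs if d.present_on == "abo_A")
    b_def = next(d for d in defs if d.present_on == "abo_B")
    o_call = calls.get(o_def.site, GenotypeCall.NO_CALL)
    b_call = calls.get(b_def.site, GenotypeCall.NO_CALL)
    if GenotypeCall.NO_CALL in (o_call, b_call):
        return None, AntigenStatus.UNDETERMINED, AntigenStatus.UNDETERMINED
    functional = 2 - _ALT_COUNT[o_call]
    n_b = min(_ALT_COUNT[b_call], functional)
    n_a = functional - n_b
    if functional == 0:
        abo = "O"
    elif n_a and n_b:
        abo = "AB"
    elif n_b:
        abo = "B"
    else:
        abo = "A"
    a_status = AntigenStatus.PRESENT if n_a else AntigenStatus.ABSENT
    b_status = AntigenStatus.PRESENT if n_b else AntigenStatus.ABSENT
    return abo, a_status, b_status


def predict_antigens(
    calls: Mapping[tuple[str, int], GenotypeCall],
    definitions: Optional[list[AntigenDefinition]] = None,
) -> AntigenPhenotype:
    """Evaluate every antigen's presence logic against the genotype table."""
    defs = definitions if definitions is not None else load_antigen_definitions()
    statuses: dict[str, AntigenStatus] = {}

    abo_defs = [d for d in defs if d.system == "ABO"]
    abo, a_status, b_status = (None, AntigenStatus.UNDETERMINED, AntigenStatus.UNDETERMINED)
    if abo_defs:
        abo, a_status, b_status = _abo_type(abo_defs, calls)

    for d in defs:
        label = f"{d.system} {d.antigen}"
        if d.present_on == "abo_A":
            statuses[label] = a_status
            continue
        if d.present_on == "abo_B":
            statuses[label] = b_status
            continue
        call = calls.get(d.site, GenotypeCall.NO_CALL)
        if call == GenotypeCall.NO_CALL:
            statuses[label] = AntigenStatus.UNDETERMINED
        elif d.present_on == "ref":
            statuses[label] = (
                AntigenStatus.PRESENT
                if call in (GenotypeCall.HOM_REF, GenotypeCall.HET)
                else AntigenStatus.ABSENT
            )
        else:  # present on alt
            statuses[label] = (
                AntigenStatus.PRESENT
                if call in (GenotypeCall.HET, GenotypeCall.HOM_ALT)
                else AntigenStatus.ABSENT
            )

    d_status = statuses.get("RH D", AntigenStatus.UNDETERMINED)
    if abo is None or d_status == AntigenStatus.UNDETERMINED:
        abo_rh = "not determined"
    else:
        abo_rh = f"{abo} {'positive' if d_status == AntigenStatus.PRESENT else 'negative'}"
    return AntigenPhenotype(statuses=statuses, abo_rh=abo_rh)


def summarize_blood(
    phen: AntigenPhenotype,
    definitions: Optional[list[AntigenDefinition]] = None,
) -> tuple[str, set[BloodFlag]]:
    """Derive the summary line and flags from the phenotype.

    The summary lists only rare findings — antigens whose absence (for
    high-prevalence or immunogenic antigens) or presence (for low-frequency
    alt-carried antigens) is uncommon in the population.
    """
    defs = definitions if definitions is not None else load_antigen_definitions()
    flags: set[BloodFlag] = set()
    rare_absent: list[str] = []
    notes: list[str] = []
    rare_present: list[str] = []
    for d in sorted(defs, key=lambda d: (d.system, d.antigen)):
        label = f"{d.system} {d.antigen}"
        status = phen.statuses.get(label)
        if status == AntigenStatus.ABSENT and d.present_on in ("ref", "abo_A", "abo_B"):
            if d.high_prevalence:
                flags.add(BloodFlag.TRANSFUSION_RISK)
                rare_absent.append(label)
            if d.immunogenic:
                flags.add(BloodFlag.DONOR_CANDIDATE)
            if d.disease_note:
                flags.add(BloodFlag.DISEASE_SUSCEPTIBILITY_NOTE)
                notes.append(f"{label}: {d.disease_note}")
        if status == AntigenStatus.PRESENT and d.present_on == "alt":
            rare_present.append(label)

    phen.flags = flags
    phen.rare_absent = rare_absent

    parts = [f"ABO Rh blood type: {phen.abo_rh}."]
    if rare_absent:
        parts.append("Absent high-prevalence antigens: " + ", ".join(rare_absent) + ".")
        parts.append("At risk for transfusion-related events; antigen-matched blood advised.")
    if BloodFlag.DONOR_CANDIDATE in flags:
        parts.append("Lacks a highly immunogenic antigen: good candidate for whole "
                     "blood or platelet donation.")
    if rare_present:
        parts.append("Low-frequency antigens present: " + ", ".join(rare_present) + ".")
    parts.extend(notes)
    if len(parts) == 1:
        parts.append("No rare antigen findings.")
    return " ".join(parts), flags


def type_blood(
    variants: Iterable[GenomicVariant],
    coverage: Optional[Mapping[tuple[str, int], int]] = None,
    definitions: Optional[list[AntigenDefinition]] = None,
    regions: Optional[pd.DataFrame] = None,
) -> tuple[AntigenPhenotype, str]:
    """End-to-end blood typing: genotype, predict, summarize."""
    defs = definitions if definitions is not None else load_antigen_definitions()
    calls = extract_blood_genotypes(variants, defs, regions=regions, coverage=coverage)
    phen = predict_antigens(calls, defs)
    summary, _ = summarize_blood(phen, defs)
    return phen, summary
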