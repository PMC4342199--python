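"""Core domain types, VCF ingestion, and HGVS/consequence utilities.

The pipeline consumes a single-sample VCF of genome-wide variant calls.
Each call is reduced to a :class:`GenomicVariant`, paired with one primary
:class:`TranscriptAnnotation` (multi-transcript annotations are collapsed
by consequence severity), and joined to population frequencies to form the
:class:`AnnotatedVariant` that the triage arms evaluate.

Consequence classification works from HGVS strings alone: the protein
change determines nonsense/frameshift/missense/synonymous status, and the
intronic offsets parsed from the coding-DNA description determine splice
status (canonical = donor/acceptor +-1,2 by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

_VALID_BASES = re.compile(r"^[ACGT]+$")


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    DELINS = "delins"


class Consequence(str, Enum):
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: loss-of-function consequence set used by the LOF filtration arm
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)

#: severity rank used to collapse multi-transcript annotations (most severe first)
CONSEQUENCE_SEVERITY = (
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.CANONICAL_SPLICE,
    Consequence.MISSENSE,
    Consequence.SPLICE_REGION,
    Consequence.INFRAME_INDEL,
    Consequence.SYNONYMOUS,
    Consequence.OTHER,
)


class VcfParseError(ValueError):
    """Malformed or unsupported VCF input."""


def infer_variant_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt) == 1:
        return VariantClass.SNV
    if len(ref) == 1 and len(alt) > 1:
        # anchored insertion; a duplication is indistinguishable without context
        return VariantClass.INSERTION
    if len(alt) == 1 and len(ref) > 1:
        return VariantClass.DELETION
    return VariantClass.DELINS


@dataclass
class GenomicVariant:
    """One normalized variant call from a single genome.

    Positions are 1-based VCF coordinates; indels are left-trimmed so that
    the (chrom, pos, ref, alt) key matches across resource tables.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity
    genotype_quality: float
    rsid: Optional[str] = None
    variant_class: Optional[VariantClass] = None
    low_gq: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _VALID_BASES.match(allele):
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not a "
                    "plain A/C/G/T string (symbolic alleles are rejected)"
                )
        if self.genotype_quality < 0:
            raise ValueError("genotype_quality must be non-negative")
        if self.variant_class is None:
            self.variant_class = infer_variant_class(self.ref, self.alt)
        self._check_class_consistency()

    def _check_class_consistency(self) -> None:
        lr, la = len(self.ref), len(self.alt)
        vc = self.variant_class
        if lr > la and vc not in (VariantClass.DELETION, VariantClass.DELINS):
            raise ValueError(f"allele lengths imply a deletion-bearing class, got {vc}")
        if la > lr and vc not in (
            VariantClass.INSERTION,
            VariantClass.DUPLICATION,
            VariantClass.DELINS,
        ):
            raise ValueError(f"allele lengths imply an insertion-bearing class, got {vc}")
        if lr == la == 1 and vc is not VariantClass.SNV:
            raise ValueError(f"1bp substitution must be SNV, got {vc}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TranscriptAnnotation:
    gene: str
    transcript: str
    c_hgvs: str
    p_hgvs: str = "p.?"
    consequence: Optional[Consequence] = None

    def __post_init__(self) -> None:
        if not self.c_hgvs.startswith("c."):
            raise ValueError(f"coding HGVS must begin 'c.': {self.c_hgvs!r}")
        if self.p_hgvs and not self.p_hgvs.startswith("p."):
            raise ValueError(f"protein HGVS must begin 'p.': {self.p_hgvs!r}")
        if self.consequence is None:
            self.consequence = classify_consequence(self.c_hgvs, self.p_hgvs)


@dataclass
class PopulationFrequencies:
    """ESP-style minor allele frequencies for the two reference populations.

    ``None`` means the variant is absent from the frequency resource (never
    observed), which is distinct from an observed frequency of 0.0.
    """

    maf_ea: Optional[float] = None
    maf_aa: Optional[float] = None
    source_version: str = ""

    def __post_init__(self) -> None:
        for val in (self.maf_ea, self.maf_aa):
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"MAF must be a fraction in [0,1], got {val}")


@dataclass
class AnnotatedVariant:
    variant: GenomicVariant
    annotation: TranscriptAnnotation
    frequencies: PopulationFrequencies = field(default_factory=PopulationFrequencies)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


@dataclass
class CoverageSummary:
    mean_coverage: float
    pct_bases_ge_8x: float
    total_variants: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_bases_ge_8x <= 100.0):
            raise ValueError("pct_bases_ge_8x must be in [0,100]")
        if self.total_variants < 0:
            raise ValueError("total_variants must be >= 0")


# ---------------------------------------------------------------------------
# HGVS coding-DNA position parsing
# ---------------------------------------------------------------------------

# one coding position, e.g. 94, 94+2, 5563-2, *52, -14
_POS_RE = re.compile(r"(?P<utr>[*-]?)(?P<base>\d+)(?P<offset>[+-]\d+)?")
# the variant description part of a c. string
_C_BODY_RE = re.compile(
    r"^c\.(?P<start>[*-]?\d+(?:[+-]\d+)?)"
    r"(?:_(?P<end>[*-]?\d+(?:[+-]\d+)?))?"
    r"(?P<rest>.*)$"
)


@dataclass(frozen=True)
class CodingPosition:
    base: int
    offset: int  # 0 for exonic positions; +n / -n for intronic


def _parse_position(token: str) -> CodingPosition:
    m = _POS_RE.fullmatch(token)
    if m is None:
        raise ValueError(f"unparseable coding position {token!r}")
    base = int(m.group("base"))
    if m.group("utr") == "-":
        base = -base
    offset = int(m.group("offset")) if m.group("offset") else 0
    return CodingPosition(base=base, offset=offset)


def parse_c_hgvs_span(c_hgvs: str) -> tuple[CodingPosition, CodingPosition, str]:
    """Parse a coding-DNA HGVS string into (start, end, edit-description).

    Tolerates spaces inside the string (as found in typeset tables).
    Raises ValueError if the string does not follow the c.START[_END]EDIT form.
    """
    compact = c_hgvs.replace(" ", "")
    m = _C_BODY_RE.match(compact)
    if m is None:
        raise ValueError(f"unparseable coding HGVS {c_hgvs!r}")
    start = _parse_position(m.group("start"))
    end = _parse_position(m.group("end")) if m.group("end") else start
    return start, end, m.group("rest")


def intronic_offsets(c_hgvs: str) -> set[int]:
    """Signed intronic offsets touched by the variant description.

    For a range variant (e.g. a deletion ``c.841_849+19del``) every intronic
    offset between the range's endpoints on each side of an exon boundary is
    included, so a deletion sweeping through the donor +1/+2 positions reports
    them even though neither endpoint is +1 or +2.
    """
    start, end, _ = parse_c_hgvs_span(c_hgvs)
    offsets: set[int] = set()
    for p in (start, end):
        if p.offset != 0:
            offsets.add(p.offset)
    # a range running from an exonic position into a downstream intron covers
    # +1..end.offset; symmetric case for an upstream acceptor
    if start.offset == 0 and end.offset > 0:
        offsets.update(range(1, end.offset + 1))
    if end.offset == 0 and start.offset < 0:
        offsets.update(range(start.offset, 0))
    if start.offset > 0 and end.offset > start.offset and start.base == end.base:
        offsets.update(range(start.offset, end.offset + 1))
    if end.offset < 0 and start.offset < end.offset and start.base == end.base:
        offsets.update(range(start.offset, end.offset + 1))
    return offsets


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

_STOP_GAIN_RE = re.compile(r"^p\.\(?[A-Z][a-z]{2}\d+(X|Ter|\*)\)?$")
_MISSENSE_RE = re.compile(r"^p\.\(?(?P<from>[A-Z][a-z]{2})\d+(?P<to>[A-Z][a-z]{2})\)?$")
_FRAMESHIFT_RE = re.compile(r"fs")
_SYNONYMOUS_RE = re.compile(r"^p\.\(?=\)?$|^p\.\(?([A-Z][a-z]{2})(\d+)\1\)?$")


def classify_consequence(
    c_hgvs: str,
    p_hgvs: str = "p.?",
    splice_window: int = 2,
    splice_region_window: int = 8,
) -> Consequence:
    """Classify a variant's consequence from its HGVS descriptions.

    Protein-level evidence is consulted first (frameshift, then stop gain);
    splice status is decided purely from the coding-DNA intronic offsets —
    the uninformative "p.?" notation used for splice variants never
    contributes. ``splice_window`` is the canonical donor/acceptor window
    (|offset| <= window => canonical_splice); offsets beyond it but within
    ``splice_region_window`` classify as splice_region. Unparseable input
    yields OTHER with a logged warning rather than an exception.
    """
    p = (p_hgvs or "").replace(" ", "")
    p_informative = p not in ("", "p.?", "p.(?)")

    if p_informative:
        if _FRAMESHIFT_RE.search(p):
            return Consequence.FRAMESHIFT
        if _STOP_GAIN_RE.match(p):
            return Consequence.NONSENSE

    try:
        offsets = intronic_offsets(c_hgvs)
    except ValueError:
        log.warning("unparseable HGVS %r; classifying as other", c_hgvs)
        return Consequence.OTHER

    if offsets:
        min_abs = min(abs(o) for o in offsets)
        if min_abs <= splice_window:
            return Consequence.CANONICAL_SPLICE
        if min_abs <= splice_region_window:
            return Consequence.SPLICE_REGION
        # deep intronic with no informative protein change
        if not p_informative:
            return Consequence.OTHER

    if p_informative:
        m = _MISSENSE_RE.match(p)
        if m is not None:
            if m.group("from") == m.group("to"):
                return Consequence.SYNONYMOUS
            return Consequence.MISSENSE
        if _SYNONYMOUS_RE.match(p):
            return Consequence.SYNONYMOUS
        if re.search(r"(del|dup|ins)", p):
            return Consequence.INFRAME_INDEL

    _, _, edit = parse_c_hgvs_span(c_hgvs)
    if re.search(r"(del|dup|ins)", edit):
        return Consequence.INFRAME_INDEL
    return Consequence.OTHER


def collapse_annotations(
    annotations: Sequence[TranscriptAnnotation],
) -> TranscriptAnnotation:
    """Collapse multi-transcript annotations to a single primary annotation.

    The most severe consequence wins; ties break on the lexicographically
    smallest transcript identifier, so the result is order-independent.
    """
    if not annotations:
        raise ValueError("no annotations to collapse")
    rank = {c: i for i, c in enumerate(CONSEQUENCE_SEVERITY)}
    return min(annotations, key=lambda a: (rank[a.consequence], a.transcript))


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-trim shared flanking bases so indel keys are minimal.

    Shared trailing bases are removed first, then shared leading bases
    (keeping at least one base in each allele and advancing ``pos``).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _zygosity_from_gt(gt: tuple, alt_index: int) -> Optional[Zygosity]:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    hits = sum(1 for a in alleles if a == alt_index)
    if hits == 0:
        return None
    if len(alleles) == 1:
        return Zygosity.HEMIZYGOUS
    if hits == len(alleles):
        return Zygosity.HOMOZYGOUS
    return Zygosity.HETEROZYGOUS


def read_vcf(path: str, min_gq: float = 30.0) -> list[GenomicVariant]:
    """Read a single-sample VCF into a list of :class:`GenomicVariant`.

    One record is emitted per ALT allele (multi-allelic records are split)
    and indels are left-normalized. Calls below ``min_gq`` are retained but
    flagged ``low_gq`` — quality filtering is triage's decision, not I/O's.
    Genotypes carrying no copy of an ALT allele produce no record for it.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if len(samples) != 1:
        raise VcfParseError(
            f"expected a single-sample VCF, found {len(samples)} samples in {path}"
        )
    sample = samples[0]

    out: list[GenomicVariant] = []
    for rec in vcf:
        if rec.alts is None:
            continue
        call = rec.samples[sample]
        gt = call.get("GT")
        if gt is None:
            continue
        gq = call.get("GQ")
        gq = float(gq) if gq is not None else 0.0
        rsid = rec.id if rec.id not in (None, ".") else None
        for alt_index, alt in enumerate(rec.alts, start=1):
            if alt is None or not _VALID_BASES.match(alt) or not _VALID_BASES.match(rec.ref or ""):
                raise VcfParseError(
                    f"non-ACGT or symbolic allele at line for {rec.chrom}:{rec.pos}"
                )
            zyg = _zygosity_from_gt(tuple(gt), alt_index)
            if zyg is None:
                continue
            pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
            out.append(
                GenomicVariant(
                    chrom=rec.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    zygosity=zyg,
                    genotype_quality=gq,
                    rsid=rsid,
                    low_gq=gq < min_gq,
                )
            )
    return out


def write_vcf(path: str, variants: Iterable[GenomicVariant], contigs: dict[str, int],
              sample: str = "CASE") -> None:
    """Write variants back out as a minimal single-sample VCF 4.2 file."""
    gt_for = {
        Zygosity.HETEROZYGOUS: "0/1",
        Zygosity.HOMOZYGOUS: "1/1",
        Zygosity.HEMIZYGOUS: "1",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.rsid or ".",
                        v.ref,
                        v.alt,
                        ".",
                        "PASS",
                        ".",
                        "GT:GQ",
                        f"{gt_for[v.zygosity]}:{int(v.genotype_quality)}",
                    ]
                )
                + "\n"
            )
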