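"""Pharmacogenomic panel genotyping, diplotype assignment, and drug
interpretation.

The default panel holds the 18 variant sites associated with the metabolism
of five commonly administered drugs: metformin (C11orf65), clopidogrel
(CYP2C19, 8 sites), warfarin (CYP2C9, 6 sites, plus VKORC1), simvastatin
(SLCO1B1), and digoxin (ABCB1). Every panel base is genotyped: a site
absent from the VCF but adequately covered is homozygous reference; an
inadequately covered absent site is a no-call.

For the multi-site star-allele genes the unphased genotypes are resolved
into a diplotype by searching allele pairs consistent with the observed
per-site allele counts and keeping the pair with the fewest non-reference
alleles (deterministic lexicographic tie-break). Single-site genes report
the site genotype itself. Interpretation phrases are table-driven data;
warfarin combines CYP2C9 and VKORC1 into a single dose-requirement phrase.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import GenomicVariant, Zygosity

log = logging.getLogger(__name__)

#: minimum depth for calling an absent site homozygous reference
MIN_CALLABLE_DEPTH = 8

STAR_ALLELE_GENES = ("CYP2C19", "CYP2C9")
SINGLE_SITE_GENES = ("VKORC1", "SLCO1B1", "ABCB1", "C11orf65")


class GenotypeCall(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


_ALT_COUNT = {GenotypeCall.HOM_REF: 0, GenotypeCall.HET: 1, GenotypeCall.HOM_ALT: 2}


@dataclass(frozen=True)
class PanelSite:
    gene: str
    rsid: str
    drug: str
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_tag: str


@dataclass
class PgxResult:
    drug: str
    genes: list[str]
    diplotype: str
    phenotype_phrase: str
    detail: str = ""
    diplotype_frequency: Optional[float] = None
    no_call: bool = False


def _data_path(name: str) -> Path:
    return Path(str(importlib_resources.files("genoreport").joinpath("data", name)))


def load_panel(path: Optional[str] = None) -> list[PanelSite]:
    """Load the panel site definitions (default: packaged 18-site panel)."""
    df = pd.read_csv(path or _data_path("pgx_panel.tsv"), sep="\t", dtype=str)
    sites = [
        PanelSite(
            gene=r["gene"],
            rsid=r["rsid"],
            drug=r["drug"],
            chrom=r["chrom"],
            pos=int(r["pos"]),
            ref=r["ref"],
            alt=r["alt"],
            allele_tag=r["allele_tag"],
        )
        for r in df.to_dict("records")
    ]
    rsids = [s.rsid for s in sites]
    if len(set(rsids)) != len(rsids):
        raise ValueError("panel rsIDs must be unique")
    return sites


def load_allele_definitions(path: Optional[str] = None) -> dict[str, dict[str, frozenset[str]]]:
    """Star-allele definitions: gene -> allele -> set of defining rsIDs.

    The reference allele (*1) is the empty set.
    """
    df = pd.read_csv(path or _data_path("pgx_alleles.tsv"), sep="\t", dtype=str).fillna("")
    out: dict[str, dict[str, frozenset[str]]] = {}
    for r in df.to_dict("records"):
        sites = frozenset(s for s in r["sites"].split(";") if s)
        out.setdefault(r["gene"], {})[r["allele"]] = sites
    return out


def load_rules(path: Optional[str] = None) -> pd.DataFrame:
    df = pd.read_csv(path or _data_path("pgx_rules.tsv"), sep="\t", dtype=str).fillna("")
    return df


# ---------------------------------------------------------------------------
# Genotype extraction
# ---------------------------------------------------------------------------


def _site_depth(coverage: Optional[Mapping[tuple[str, int], int]], site: PanelSite,
                default_depth: int) -> int:
    if coverage is None:
        return default_depth
    return coverage.get((site.chrom, site.pos), default_depth)


def extract_panel_genotypes(
    variants: Iterable[GenomicVariant],
    panel: list[PanelSite],
    coverage: Optional[Mapping[tuple[str, int], int]] = None,
    default_depth: int = 30,
    min_depth: int = MIN_CALLABLE_DEPTH,
) -> dict[str, GenotypeCall]:
    """Genotype every panel site from the VCF calls plus coverage data.

    Returns rsid -> call. Sites with no ALT record and depth >= ``min_depth``
    are homozygous reference; with depth below the threshold they are
    no-calls.
    """
    by_key = {}
    by_rsid = {}
    for v in variants:
        by_key[v.key] = v
        if v.rsid:
            by_rsid[v.rsid] = v

    calls: dict[str, GenotypeCall] = {}
    for site in panel:
        v = by_key.get((site.chrom, site.pos, site.ref, site.alt)) or by_rsid.get(site.rsid)
        if v is not None:
            if v.zygosity == Zygosity.HETEROZYGOUS:
                calls[site.rsid] = GenotypeCall.HET
            else:  # homozygous or hemizygous alt
                calls[site.rsid] = GenotypeCall.HOM_ALT
        elif _site_depth(coverage, site, default_depth) >= min_depth:
            calls[site.rsid] = GenotypeCall.HOM_REF
        else:
            calls[site.rsid] = GenotypeCall.NO_CALL
    return calls


# ---------------------------------------------------------------------------
# Diplotype assignment
# ---------------------------------------------------------------------------


def assign_diplotype(
    gene: str,
    genotypes: Mapping[str, GenotypeCall],
    allele_defs: Mapping[str, Mapping[str, frozenset[str]]],
    panel: Optional[list[PanelSite]] = None,
) -> str:
    """Assign a diplotype label for one gene from its site genotypes.

    For star-allele genes, searches all unordered allele pairs whose summed
    per-site alt counts reproduce the observed unphased genotypes and keeps
    the pair with the fewest non-reference defining sites (parsimony),
    breaking ties lexicographically. Any defining-site no-call yields
    "no-call"; a genotype combination inconsistent with every pair yields
    "indeterminate". Single-site genes return the site genotype as an
    allele string (e.g. "G/A").
    """
    if gene in allele_defs:
        defs = allele_defs[gene]
        defining_sites = sorted(set().union(*defs.values()))
        gts = {s: genotypes.get(s, GenotypeCall.NO_CALL) for s in defining_sites}
        if any(g == GenotypeCall.NO_CALL for g in gts.values()):
            return "no-call"
        observed = {s: _ALT_COUNT[g] for s, g in gts.items()}
        candidates = []
        for a, b in itertools.combinations_with_replacement(sorted(defs), 2):
            counts = {s: 0 for s in defining_sites}
            for allele in (a, b):
                for s in defs[allele]:
                    counts[s] += 1
            if counts == observed:
                cost = len(defs[a]) + len(defs[b])
                candidates.append((cost, _star_sort_key(a), _star_sort_key(b), f"{a}/{b}"))
        if not candidates:
            log.warning(
                "genotypes for %s inconsistent with every allele pair: %s", gene, observed
            )
            return "indeterminate"
        candidates.sort()
        return candidates[0][3]

    # single-site gene: report the genotype itself
    if panel is None:
        raise ValueError(f"panel required for single-site gene {gene}")
    sites = [s for s in panel if s.gene == gene]
    if len(sites) != 1:
        raise ValueError(f"expected one panel site for {gene}, found {len(sites)}")
    site = sites[0]
    call = genotypes.get(site.rsid, GenotypeCall.NO_CALL)
    if call == GenotypeCall.NO_CALL:
        return "no-call"
    alleles = {
        GenotypeCall.HOM_REF: (site.ref, site.ref),
        GenotypeCall.HET: (site.ref, site.alt),
        GenotypeCall.HOM_ALT: (site.alt, site.alt),
    }[call]
    return "/".join(alleles)


def _star_sort_key(allele: str) -> tuple:
    # "*2" sorts numerically so *1/*2 beats *1/*17 only by cost/lexicographic rule
    if allele.startswith("*") and allele[1:].isdigit():
        return (0, int(allele[1:]))
    return (1, allele)


# ---------------------------------------------------------------------------
# Drug interpretation
# ---------------------------------------------------------------------------

DRUG_GENES = {
    "metformin": ["C11orf65"],
    "clopidogrel": ["CYP2C19"],
    "warfarin": ["CYP2C9", "VKORC1"],
    "simvastatin": ["SLCO1B1"],
    "digoxin": ["ABCB1"],
}


def _rule_key(drug: str, labels: Mapping[str, str]) -> str:
    return "|".join(f"{g} {labels[g]}" for g in DRUG_GENES[drug])


def interpret_drug(
    drug: str,
    gene_labels: Mapping[str, str],
    rules: pd.DataFrame,
) -> PgxResult:
    """Produce the qualitative drug-response result for one drug.

    ``gene_labels`` maps each gene relevant to the drug to its diplotype or
    genotype label. Warfarin's key combines CYP2C9 and VKORC1. A no-call in
    any relevant gene yields a "not determined" result; a missing rule row
    yields "interpretation unavailable".
    """
    genes = DRUG_GENES[drug]
    labels = {g: gene_labels[g] for g in genes}
    if any(lbl == "no-call" for lbl in labels.values()):
        return PgxResult(
            drug=drug,
            genes=genes,
            diplotype="; ".join(f"{g} {labels[g]}" for g in genes),
            phenotype_phrase="not determined",
            no_call=True,
        )
    key = _rule_key(drug, labels)
    hit = rules[(rules["drug"] == drug) & (rules["key"] == key)]
    diplotype = "; ".join(f"{g} {labels[g]}" for g in genes)
    if hit.empty:
        log.warning("no interpretation rule for %s / %s", drug, key)
        return PgxResult(
            drug=drug,
            genes=genes,
            diplotype=diplotype,
            phenotype_phrase="interpretation unavailable",
        )
    row = hit.iloc[0]
    freq = float(row["frequency"]) if row.get("frequency", "") else None
    return PgxResult(
        drug=drug,
        genes=genes,
        diplotype=diplotype,
        phenotype_phrase=row["phenotype"],
        detail=row["detail"],
        diplotype_frequency=freq,
    )


def type_pgx(
    variants: Iterable[GenomicVariant],
    coverage: Optional[Mapping[tuple[str, int], int]] = None,
    panel: Optional[list[PanelSite]] = None,
    allele_defs: Optional[dict] = None,
    rules: Optional[pd.DataFrame] = None,
) -> list[PgxResult]:
    """End-to-end pharmacogenomic typing: one PgxResult per panel drug."""
    panel = panel if panel is not None else load_panel()
    allele_defs = allele_defs if allele_defs is not None else load_allele_definitions()
    rules = rules if rules is not None else load_rules()
    calls = extract_panel_genotypes(variants, panel, coverage)
    genes = sorted({s.gene for s in panel})
    labels = {g: assign_diplotype(g, calls, allele_defs, panel) for g in genes}
    drugs = sorted({s.drug for s in panel})
    return [interpret_drug(drug, labels, rules) for drug in drugs]
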