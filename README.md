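# genoreport

Clinical triage of genome-wide variant calls and generation of a concise,
structured Genome Report — for clinical-bioinformatics and reporting teams
who need a reproducible desk-scale model of genome-scale incidental-finding
pipelines.

## What it does

A single genome yields millions of variant calls; only a handful belong on
a clinical report. `genoreport` ingests a single-sample VCF and triages it
through three independent filtration arms:

1. **Assertion arm** — variants with minor allele frequency (MAF) < 5% in
   European-American *or* African-American reference chromosomes that are
   asserted disease-causing (DM) or possibly disease-causing (DM?) in an
   assertion database, or already classified Pathogenic / Likely pathogenic
   in the laboratory's own store.
2. **Loss-of-function arm** — nonsense, frameshift, and canonical
   splice-site (±1,2) variants with MAF < 1% in a curated list of
   disease-associated genes. Consequences are derived from HGVS coding-DNA
   and protein descriptions.
3. **Pharmacogenomic arm** — a fixed panel of 18 variants governing the
   metabolism of five drugs (metformin, clopidogrel, warfarin, simvastatin,
   digoxin).

Triaged variants pass a reporting threshold only when classified on the
five-tier scale as Pathogenic, Likely pathogenic, or Uncertain
significance: favor pathogenic, must be Sanger-confirmed before rendering,
and are routed by inheritance and zygosity: heterozygous autosomal
recessive findings to **Carrier Risk**; dominant, X-linked, or biallelic
recessive findings to **Monogenic Disease Risk** (with an indication tag
for cardiomyopathy cases). The classification store enforces the
reassessment policy (full review on a new case after >1 year for
pathogenic, >6 months for likely pathogenic and uncertain tiers; brief
database recheck before every report for the middle tiers), exports
ClinVar-style submission rows, and emits amendment notices when a reported
variant's classification changes.

Two typing modules complete the report: star-allele diplotyping of
CYP2C19/CYP2C9 (plus four single-site pharmacogenes) with qualitative
drug-response phrases, and table-driven prediction of 57 red-cell and all
33 human platelet antigens with ABO/RhD typing and transfusion-risk /
donor-candidacy / disease-note flags.

Everything is testable without downloads: a seeded synthetic-case generator
plants reportable findings (the packaged 49-row reported-findings fixture),
pharmacogenomic genotypes, and blood-group alleles on a bundled
mini-reference, surrounded by common background variants that fail every
arm by construction.

## Worked example

```sh
genoreport simulate --seed 7 --n-background 1000 --out demo
# wrote demo/case.vcf (49 planted findings, 1000 background variants)

genoreport report --vcf demo/case.vcf --resources demo/resources \
    --case-id DEMO --out demo/report
# wrote demo/report/report.md and demo/report/packet.json
```

The funnel log (`demo/report/funnel.jsonl`) records each stage:

```json
{"arm_assertion": 27, "arm_lof": 27, "arm_pgx": 0, "arm_union": 48,
 "case_id": "DEMO", "confirmed": 48, "ingested": 1048, "reported": 48,
 "threshold_passed": 48}
```

1,048 ingested calls collapse to 48 unique reportable variants (27 hit the
assertion arm, 27 the LOF arm, 6 both); all 48 are classified in a
reportable tier, Sanger-confirmed, and reported — 40 Carrier Risk entries
and 9 Monogenic entries (one variant appears in both sections through its
dual recessive/dominant disease associations). The rendered summary begins:

```
# Genome Report — case DEMO

## Result summary

Genome coverage: mean 41.0X; 95.5% of bases at >=8X. 1,048 variants
identified versus the reference genome.

### Monogenic disease risk

| Disease | Inheritance | Gene | Variant | Classification |
|---|---|---|---|---|
| Chondrodysplasia punctata | XL | ARSE | c.410G>C (p.Gly137Ala) | VUS_favor_pathogenic |
| Romano Ward syndrome | AD | KCNQ1 | c.826delT (p.Ser276ProfsX13) | LikelyPathogenic |
...
```

Pharmacogenomic typing of the same case (all panel sites reference):

```sh
genoreport pgx --vcf demo/case.vcf --out demo/pgx
# clopidogrel: CYP2C19 *1/*1 — Typical response to clopidogrel expected
# digoxin: ABCB1 A/A — Typical serum digoxin concentrations expected
# metformin: C11orf65 A/A — Typical glycemic response to metformin expected
# simvastatin: SLCO1B1 T/T — Typical risk of simvastatin-related myopathy
# warfarin: CYP2C9 *1/*1; VKORC1 G/G — Typical warfarin dose requirement expected
```

`report.md` and `packet.json` are byte-deterministic for a fixed model;
`report.pdf` is a paginated rendering of the same text.

## Layout

- `src/genoreport/model.py` — domain types, VCF ingestion, HGVS consequence
  classification
- `src/genoreport/triage.py` — filtration arms, reporting threshold,
  section routing, confirmation-risk flags
- `src/genoreport/kb.py` — five-tier classification store, reassessment
  policy, ClinVar export, change notification
- `src/genoreport/pgx.py`, `src/genoreport/blood.py` — pharmacogenomic and
  blood-group typing
- `src/genoreport/report.py` — report model, Markdown/PDF rendering, JSON
  packet
- `src/genoreport/fixtures.py` — packaged findings fixture and the
  synthetic-case generator
- `src/genoreport/pipeline.py`, `src/genoreport/cli.py` — end-to-end case
  processing and the command line
- `docs/methods.md` — model, assumptions, parameters, and limitations
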