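# Methods

## The triage model

The pipeline models the clinical analysis of a single sequenced genome as
a staged funnel: ingest → arm ascertainment → classification threshold →
Sanger confirmation → section routing → report. Alignment and variant
calling are out of scope; the artifact consumes a finished single-sample
VCF. Annotation is a join against a transcript map (one primary transcript
per variant; multi-transcript annotations are collapsed by consequence
severity with a lexicographic transcript-ID tie-break), and consequences
are computed from HGVS strings alone:

- protein-level evidence is consulted first: a `fs` token ⇒ frameshift; a
  terminal stop token (`X`/`Ter`/`*`) on a substitution form ⇒ nonsense;
- splice status comes only from coding-DNA intronic offsets — the
  uninformative `p.?` notation never contributes. |offset| ≤ 2 ⇒ canonical
  splice (the window is configurable; an extended ±3..8 window can be
  enabled but is off by default), 3–8 ⇒ splice region. A deletion whose
  range sweeps through the +1/+2 donor positions is canonical splice even
  when its protein description is an inframe deletion;
- remaining forms classify by protein change (missense, synonymous,
  inframe indel) or fall back to `other`. Unparseable HGVS logs a warning
  and classifies `other`; it never raises.

One fixture finding (a +5 splice-region variant) is recorded in the source
table as ascertained by the loss-of-function filter even though +5 lies
outside the canonical window. The default window is kept and the replay
machinery encodes this variant as a documented exception: it is expected to
reach the report through the assertion arm only.

### Frequency gate

"MAF < cutoff in EA or AA" is read as a disjunction: the gate passes when
at least one population is below the cutoff; a population with no recorded
frequency passes its own test (unobserved ⇒ rare, the standard triage
convention — the alternative silently discards novel variants). The
conjunctive reading is available via `maf_gate_mode="all"`. Cutoffs default
to 0.05 (assertion arm) and 0.01 (LOF arm) and are configuration, not code.

### Prior knowledge vs. case assessments

The assertion arm may fire on variants previously classified
Pathogenic/Likely pathogenic by the laboratory. In a replay setting the
classification store shipped with a case holds the assessments of that
case's *own* findings, produced after filtration — feeding them back into
the assertion arm would make every loss-of-function-only finding appear
assertion-ascertained as well. `TriageResources` therefore consults an
explicitly supplied *prior* store (empty by default) at triage time, while
the case store gates the reporting threshold and routing.

### Routing

Each reportable variant routes once per gene–disease association:
heterozygous + autosomal recessive ⇒ Carrier Risk; autosomal dominant,
X-linked, or homozygous recessive ⇒ Monogenic (homozygous recessive
findings confer personal risk; the source material contains no such case,
so this is a design choice). A gene with both a recessive and a dominant
disease association yields one entry per association. Compound
heterozygosity is never inferred — no phasing is available — but
co-occurring heterozygous recessive variants in one gene are listed on the
exception report for manual review. Monogenic entries in
cardiomyopathy-associated genes are additionally tagged as
indication-related for cardiomyopathy-arm cases.

### Confirmation and classification policy

Reported Mendelian findings must be Sanger-confirmed; the report builder
refuses to render a pending or false-positive finding (false positives are
permanently excluded for the case). Confirmation-risk flagging reproduces
the two observed false-positive modes: indels with genotype quality below
30, and variants abutting a homopolymer run of ≥ 6 bases within a 10 bp
flank (all three parameters configurable).

Reassessment policy: on identification in a new case, a full reassessment
is due when the last one is > 365 days old for Pathogenic or > 182 days for
Likely pathogenic and all uncertain-significance subtiers (strict
inequalities — the source states only calendar phrases, so "over 1 year" ⇒
\> 365 d, "over 6 months" ⇒ > 182 d; the 6-month rule is applied to every
VUS subtier including favor-benign). Otherwise Likely pathogenic,
uncertain, and Likely benign records get a brief recheck whenever a report
is issued, modeled as a checklist of databases to re-query (ClinVar, HGMD,
ESP, 1000G, ExAC) rather than live queries. Benign/Likely benign records
are fully reassessed only on clinician request. "A report is being issued"
is identified with the new-case flag, since the decision function is
evaluated at report drafting.

The store is a flat current-state TSV plus an append-only JSON-lines
journal — auditable like clinical-lab practice without a database server.
ClinVar-style export emits one row per (variant, disease) with the
evidence summary and citations; rows lacking an evidence summary are
skipped with a logged warning.

## Pharmacogenomic typing

The panel is fixed data: 18 sites across C11orf65 (metformin), CYP2C19 ×8
(clopidogrel), CYP2C9 ×6 + VKORC1 (warfarin), SLCO1B1 (simvastatin), and
ABCB1 (digoxin). Every panel base is genotyped: a site absent from the VCF
with depth ≥ 8× is homozygous reference; below 8× it is a no-call, which
propagates to a "not determined" drug result. Unphased star-allele
assignment searches all allele pairs consistent with the observed per-site
alt-allele counts and keeps the pair with the fewest non-reference defining
sites (deterministic lexicographic tie-break); inconsistent combinations
return "indeterminate". Interpretation phrases, details, and diplotype
frequencies are editable rule-table data keyed on diplotype (warfarin keys
combine CYP2C9 and VKORC1); the shipped wording is implementer-supplied
and validated structurally, not clinically. No quantitative dosing
algorithms are included.

## Blood-group prediction

A fully automatic allele-table evaluator over genotypes in configured gene
regions (exons ± 10 intronic bases): each of the 57 RBC and 33 platelet
antigen rows names the allele (reference or alternate) that carries the
antigen; presence requires at least one copy, any defining-site no-call
yields "undetermined". ABO is composed from an O-null site and a B-allele
site (functional allele count = 2 − O-null alt count; B alleles assumed on
functional haplotypes); RhD uses a deletion tag site because a whole-gene
deletion is not a small-variant call. Flags derive from the phenotype
alone: transfusion risk when a high-prevalence antigen is absent, donor
candidacy when a highly immunogenic antigen is absent, and a disease note
when an absent antigen carries one. The antigen table content is curated
to the stated counts using standard blood-group nomenclature and is
validated for counts and internal consistency; it is data, not a clinical
reference. Hybrid/structural alleles and serological confirmation are out
of scope.

## Synthetic cases

The generator emulates the *logical* structure of a sequenced genome, not
its scale or biology. Planted findings take concrete coordinates on
deterministic synthetic contigs (one 10 kb block per gene; alleles
synthesized from the HGVS edit, reference patched accordingly), with the
fixture's inheritance/classification rows becoming the mock assertion
table (rows whose filter column lists the assertion database), frequency
table (MAF 0.1%, except canonical-splice rows ascertained by assertion
only, which get 2% — between the two cutoffs, as the printed arm sets
require; the true frequencies are not printed), gene list, and
classification store (all confirmed, recently assessed). Background
variants draw MAFs uniformly from [0.05, 0.5] so they fail both Mendelian
arms by construction, and carry no assertion or panel membership. Default
case size is 1,000 background variants; the oracle-equivalence suite uses
20 cases of 1,000–5,000 — sizes chosen as the smallest at which the
set-level properties are meaningful while the whole suite stays
desk-scale. Same seed + spec ⇒ byte-identical VCF, resources, and truth
table.

What passing tests therefore show: the *decision logic* (arm predicates,
thresholds, routing, policy, rendering) is correct on inputs whose truth is
known by construction. What they do not show: performance on real genomes
(3–5 million calls), annotation quality, the human curation that produces
classifications, cohort-level quantities (assessment totals, classification
distributions, confirmation rates), or detection of variant types a
short-read pipeline misses — these need real data and wet-lab work, and
are represented instead by property tests (gate monotonicity, funnel-count
consistency, confirmation gating, packet round-trip, byte-deterministic
rendering).

## Numerical and formatting choices

- Variant identity is (chrom, pos, ref, alt) after left-trimming shared
  flanking bases; rsIDs are advisory. VCF coordinates stay 1-based.
- All set iterations and output rows are deterministically sorted, so
  Markdown and packet output are byte-reproducible; the PDF is a paginated
  rendering of the Markdown text (no timestamps embedded) but layout is
  presentation only — the model and Markdown are the artifacts of record.
- Coverage below 30× mean or 95% ≥ 8× warns (surfaced in the limitations
  section) rather than fails: the report must still communicate what was
  found.
- The packet schema check is a structural walk (required keys, primitive
  types) of the shipped schema file — sufficient for the packet's fixed
  shape without a JSON-Schema dependency.

## Known limitations

Structural variants, repeat expansions, CNVs, uniparental disomy, and
epigenetic changes are undetectable by design (the report's limitations
text says so); the blood-group module cannot represent hybrid alleles; the
PGx rule wording is illustrative data; classifications are inputs, never
computed; and the synthetic mini-reference shares none of the repetitive
context of the human genome, so confirmation-risk flagging is exercised
only on constructed flanks.
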