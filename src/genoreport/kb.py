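"""Five-tier variant classification store with reassessment policy.

Classifications are curated data, not computed: the store holds one
:class:`ClassificationRecord` per (variant, disease) association, journals
every mutation to an append-only JSON-lines file, and exposes the clinical
policy surface — reassessment scheduling, Sanger-confirmation tracking,
ClinVar-style tabular export, and classification-change notification.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]


class Classification(str, Enum):
    BENIGN = "Benign"
    LIKELY_BENIGN = "LikelyBenign"
    VUS_FAVOR_BENIGN = "VUS_favor_benign"
    VUS = "VUS"
    VUS_FAVOR_PATHOGENIC = "VUS_favor_pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    PATHOGENIC = "Pathogenic"


#: the three tiers that clear the reporting threshold
REPORTABLE = frozenset(
    {
        Classification.PATHOGENIC,
        Classification.LIKELY_PATHOGENIC,
        Classification.VUS_FAVOR_PATHOGENIC,
    }
)

VUS_TIERS = frozenset(
    {
        Classification.VUS_FAVOR_BENIGN,
        Classification.VUS,
        Classification.VUS_FAVOR_PATHOGENIC,
    }
)


class ConfirmationStatus(str, Enum):
    PENDING = "pending"
    CONFIRMED = "confirmed"
    CONFIRMED_ZYGOSITY_MISMATCH = "confirmed_zygosity_mismatch"
    FALSE_POSITIVE = "false_positive"


class Inheritance(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"


class ReassessmentDecision(str, Enum):
    FULL = "full"
    BRIEF = "brief"
    NONE = "none"


#: databases re-queried during a brief pre-report recheck
BRIEF_RECHECK_DATABASES = ("ClinVar", "HGMD", "ESP", "1000G", "ExAC")

#: elapsed-day thresholds for a full reassessment on a new case
FULL_REASSESSMENT_DAYS = {
    Classification.PATHOGENIC: 365,  # "over 1 year"
    Classification.LIKELY_PATHOGENIC: 182,  # "over 6 months"
    Classification.VUS: 182,
    Classification.VUS_FAVOR_BENIGN: 182,
    Classification.VUS_FAVOR_PATHOGENIC: 182,
}

#: tiers briefly re-evaluated before each report issuance
BRIEF_RECHECK_TIERS = VUS_TIERS | {
    Classification.LIKELY_PATHOGENIC,
    Classification.LIKELY_BENIGN,
}


class StateError(RuntimeError):
    """Illegal state transition (e.g. conflicting confirmation outcomes)."""


@dataclass
class ClassificationRecord:
    key: VariantKey
    classification: Classification
    disease: str
    inheritance: Inheritance
    interpretation: str = ""
    references: list[str] = field(default_factory=list)
    last_full_assessment: Optional[dt.date] = None
    confirmation_status: ConfirmationStatus = ConfirmationStatus.PENDING
    carrier_phenotype_note: Optional[str] = None
    gene: str = ""
    c_hgvs: str = ""
    p_hgvs: str = ""
    transcript: str = ""

    @property
    def reportable(self) -> bool:
        return self.classification in REPORTABLE


def reassessment_due(
    rec: ClassificationRecord,
    today: dt.date,
    new_case: bool,
    physician_request: bool,
) -> ReassessmentDecision:
    """Decide whether a record needs a full or brief reassessment.

    A full reassessment is triggered when the variant is identified in a
    new case and the last full assessment is stale (> 365 days for
    pathogenic, > 182 days for likely pathogenic and all uncertain tiers,
    strict inequalities). Otherwise, likely pathogenic, uncertain, and
    likely benign records get a brief database recheck whenever a report
    is being issued; benign/likely benign records are only fully
    reassessed on explicit clinician request.
    """
    if rec.last_full_assessment is not None and rec.last_full_assessment > today:
        raise ValueError(
            f"last_full_assessment {rec.last_full_assessment} is in the future"
        )
    elapsed = (
        (today - rec.last_full_assessment).days
        if rec.last_full_assessment is not None
        else None
    )
    threshold = FULL_REASSESSMENT_DAYS.get(rec.classification)
    if new_case and threshold is not None:
        if elapsed is None or elapsed > threshold:
            return ReassessmentDecision.FULL
    if new_case and rec.classification in BRIEF_RECHECK_TIERS:
        return ReassessmentDecision.BRIEF
    if physician_request:
        return ReassessmentDecision.FULL
    return ReassessmentDecision.NONE


def record_confirmation(
    rec: ClassificationRecord, outcome: ConfirmationStatus
) -> ClassificationRecord:
    """Record a Sanger confirmation outcome on a pending record.

    A false-positive outcome permanently bars the variant from this case's
    report. Re-recording the same outcome is idempotent; recording a
    conflicting outcome over a settled one raises :class:`StateError`.
    """
    if outcome == ConfirmationStatus.PENDING:
        raise ValueError("cannot record a 'pending' outcome")
    if rec.confirmation_status == outcome:
        return rec
    if rec.confirmation_status != ConfirmationStatus.PENDING:
        raise StateError(
            f"confirmation already recorded as {rec.confirmation_status.value}; "
            f"refusing conflicting outcome {outcome.value}"
        )
    rec.confirmation_status = outcome
    return rec


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------


def key_to_str(key: VariantKey) -> str:
    return "{}:{}:{}:{}".format(*key)


def key_from_str(s: str) -> VariantKey:
    chrom, pos, ref, alt = s.split(":")
    return (chrom, int(pos), ref, alt)


class KnowledgeBase:
    """Versioned flat-file classification store.

    State is a plain TSV (one row per variant-disease association); every
    mutation is additionally appended to a JSON-lines journal when a
    journal path is configured, matching clinical-lab audit practice.
    """

    STATE_COLUMNS = [
        "variant_key",
        "gene",
        "transcript",
        "c_hgvs",
        "p_hgvs",
        "classification",
        "disease",
        "inheritance",
        "interpretation",
        "references",
        "last_full_assessment",
        "confirmation_status",
        "carrier_phenotype_note",
    ]

    def __init__(self, journal_path: Optional[str] = None) -> None:
        self._records: dict[VariantKey, list[ClassificationRecord]] = {}
        self.journal_path = Path(journal_path) if journal_path else None

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    def add(self, rec: ClassificationRecord) -> None:
        bucket = self._records.setdefault(rec.key, [])
        for existing in bucket:
            if existing.disease == rec.disease:
                raise StateError(
                    f"record for {key_to_str(rec.key)} / {rec.disease} already exists"
                )
        bucket.append(rec)
        self._journal("add", rec)

    def get(self, key: VariantKey) -> list[ClassificationRecord]:
        return sorted(self._records.get(key, []), key=lambda r: r.disease)

    def reclassify(
        self, key: VariantKey, disease: str, new_class: Classification, today: dt.date
    ) -> ClassificationRecord:
        for rec in self._records.get(key, []):
            if rec.disease == disease:
                rec.classification = new_class
                rec.last_full_assessment = today
                self._journal("reclassify", rec)
                return rec
        raise KeyError(f"no record for {key_to_str(key)} / {disease}")

    def all_records(self) -> list[ClassificationRecord]:
        out = []
        for key in sorted(self._records):
            out.extend(self.get(key))
        return out

    def _journal(self, action: str, rec: ClassificationRecord) -> None:
        if self.journal_path is None:
            return
        entry = asdict(rec)
        entry["key"] = key_to_str(rec.key)
        entry["classification"] = rec.classification.value
        entry["inheritance"] = rec.inheritance.value
        entry["confirmation_status"] = rec.confirmation_status.value
        entry["last_full_assessment"] = (
            rec.last_full_assessment.isoformat() if rec.last_full_assessment else None
        )
        entry["action"] = action
        with open(self.journal_path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    # -- flat-file state ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.all_records():
            rows.append(
                {
                    "variant_key": key_to_str(rec.key),
                    "gene": rec.gene,
                    "transcript": rec.transcript,
                    "c_hgvs": rec.c_hgvs,
                    "p_hgvs": rec.p_hgvs,
                    "classification": rec.classification.value,
                    "disease": rec.disease,
                    "inheritance": rec.inheritance.value,
                    "interpretation": rec.interpretation,
                    "references": ";".join(rec.references),
                    "last_full_assessment": (
                        rec.last_full_assessment.isoformat()
                        if rec.last_full_assessment
                        else ""
                    ),
                    "confirmation_status": rec.confirmation_status.value,
                    "carrier_phenotype_note": rec.carrier_phenotype_note or "",
                }
            )
        return pd.DataFrame(rows, columns=self.STATE_COLUMNS)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str, journal_path: Optional[str] = None) -> "KnowledgeBase":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        kb = cls(journal_path=None)
        for _, row in df.iterrows():
            rec = ClassificationRecord(
                key=key_from_str(row["variant_key"]),
                gene=row["gene"],
                transcript=row["transcript"],
                c_hgvs=row["c_hgvs"],
                p_hgvs=row["p_hgvs"],
                classification=Classification(row["classification"]),
                disease=row["disease"],
                inheritance=Inheritance(row["inheritance"]),
                interpretation=row["interpretation"],
                references=[r for r in row["references"].split(";") if r],
                last_full_assessment=(
                    dt.date.fromisoformat(row["last_full_assessment"])
                    if row["last_full_assessment"]
                    else None
                ),
                confirmation_status=ConfirmationStatus(row["confirmation_status"]),
                carrier_phenotype_note=row["carrier_phenotype_note"] or None,
            )
            kb.add(rec)
        kb.journal_path = Path(journal_path) if journal_path else None
        return kb


# ---------------------------------------------------------------------------
# ClinVar-style export
# ---------------------------------------------------------------------------

CLINVAR_COLUMNS = [
    "variant_key",
    "gene",
    "transcript",
    "c_hgvs",
    "p_hgvs",
    "disease",
    "classification",
    "evidence_summary",
    "citations",
]

_CLINVAR_TERM = {
    Classification.BENIGN: "Benign",
    Classification.LIKELY_BENIGN: "Likely benign",
    Classification.VUS_FAVOR_BENIGN: "Uncertain significance",
    Classification.VUS: "Uncertain significance",
    Classification.VUS_FAVOR_PATHOGENIC: "Uncertain significance",
    Classification.LIKELY_PATHOGENIC: "Likely pathogenic",
    Classification.PATHOGENIC: "Pathogenic",
}


def export_clinvar(records: Iterable[ClassificationRecord]) -> pd.DataFrame:
    """Build the ClinVar-style submission table: one row per variant-disease.

    Rows without interpretation text are skipped with a log message (the
    evidence summary is a required submission field); rows without
    references are emitted with an empty citation field and a warning.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (r.key, r.disease)):
        if not rec.interpretation:
            log.warning(
                "skipping ClinVar row for %s / %s: missing interpretation",
                key_to_str(rec.key),
                rec.disease,
            )
            continue
        if not rec.references:
            log.warning(
                "ClinVar row for %s / %s has no citations",
                key_to_str(rec.key),
                rec.disease,
            )
        rows.append(
            {
                "variant_key": key_to_str(rec.key),
                "gene": rec.gene,
                "transcript": rec.transcript,
                "c_hgvs": rec.c_hgvs,
                "p_hgvs": rec.p_hgvs,
                "disease": rec.disease,
                "classification": _CLINVAR_TERM[rec.classification],
                "evidence_summary": rec.interpretation,
                "citations": ";".join(rec.references),
            }
        )
    return pd.DataFrame(rows, columns=CLINVAR_COLUMNS)


# ---------------------------------------------------------------------------
# Classification-change notification
# ---------------------------------------------------------------------------


@dataclass
class AmendmentNotice:
    variant_key: str
    gene: str
    disease: str
    old_classification: str
    new_classification: str
    date: str


def diff_and_notify(
    previous_packet: dict, store: KnowledgeBase, today: Optional[dt.date] = None
) -> list[AmendmentNotice]:
    """Compare a previously issued report packet against the current store.

    Emits one notice per reported variant whose classification tier changed
    since the packet was issued; interpretation-text-only edits produce no
    notice. Notices are sorted by (variant key, disease).
    """
    today = today or dt.date.today()
    notices: list[AmendmentNotice] = []
    findings = previous_packet.get("findings", [])
    for finding in findings:
        key = key_from_str(finding["variant_key"])
        old = finding["classification"]
        for rec in store.get(key):
            if rec.disease != finding["disease"]:
                continue
            if rec.classification.value != old:
                notices.append(
                    AmendmentNotice(
                        variant_key=finding["variant_key"],
                        gene=rec.gene,
                        disease=rec.disease,
                        old_classification=old,
                        new_classification=rec.classification.value,
                        date=today.isoformat(),
                    )
                )
    notices.sort(key=lambda n: (n.variant_key, n.disease))
    return notices
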