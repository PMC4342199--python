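"""Classification store: reassessment policy, confirmation tracking,
ClinVar-style export, change notification."""

import datetime as dt
import itertools

import pytest

from genoreport.kb import (
    Classification,
    ClassificationRecord,
    ConfirmationStatus,
    Inheritance,
    KnowledgeBase,
    ReassessmentDecision,
    StateError,
    diff_and_notify,
    export_clinvar,
    key_to_str,
    reassessment_due,
    record_confirmation,
)

TODAY = dt.date(2014, 6, 1)


def make_record(cls=Classification.PATHOGENIC, elapsed_days=30, disease="d",
                interpretation="evidence text", references=None, key=None):
    return ClassificationRecord(
        key=key or ("chr1", 1000, "C", "T"),
        classification=cls,
        disease=disease,
        inheritance=Inheritance.AR,
        interpretation=interpretation,
        references=references if references is not None else ["PMID:1"],
        last_full_assessment=TODAY - dt.timedelta(days=elapsed_days),
        gene="GENE",
        c_hgvs="c.100C>T",
        p_hgvs="p.?",
    )


# independent restatement of the reassessment policy as an explicit oracle
_VUS = {
    Classification.VUS,
    Classification.VUS_FAVOR_BENIGN,
    Classification.VUS_FAVOR_PATHOGENIC,
}


def policy_oracle(cls, elapsed, new_case, request):
    stale = (cls is Classification.PATHOGENIC and elapsed > 365) or (
        cls in (_VUS | {Classification.LIKELY_PATHOGENIC}) and elapsed > 182
    )
    if new_case and stale:
        return ReassessmentDecision.FULL
    if new_case and cls in (_VUS | {Classification.LIKELY_PATHOGENIC,
                                    Classification.LIKELY_BENIGN}):
        return ReassessmentDecision.BRIEF
    if request:
        return ReassessmentDecision.FULL
    return ReassessmentDecision.NONE


class TestReassessmentPolicy:
    @pytest.mark.parametrize(
        "cls,elapsed,new_case,requested,expected",
        [
            (Classification.PATHOGENIC, 400, True, False, ReassessmentDecision.FULL),
            (Classification.LIKELY_PATHOGENIC, 200, True, False, ReassessmentDecision.FULL),
            (Classification.LIKELY_PATHOGENIC, 30, True, False, ReassessmentDecision.BRIEF),
            (Classification.BENIGN, 1000, False, False, ReassessmentDecision.NONE),
            (Classification.BENIGN, 1000, False, True, ReassessmentDecision.FULL),
            (Classification.PATHOGENIC, 100, True, False, ReassessmentDecision.NONE),
            (Classification.VUS, 180, True, False, ReassessmentDecision.BRIEF),
            (Classification.VUS, 183, True, False, ReassessmentDecision.FULL),
        ],
    )
    def test_policy_examples(self, cls, elapsed, new_case, requested, expected):
        rec = make_record(cls=cls, elapsed_days=elapsed)
        assert reassessment_due(rec, TODAY, new_case, requested) is expected

    def test_full_enumeration_matches_policy(self):
        """Every (classification x elapsed bucket x new-case x request) cell
        agrees with the explicit policy table."""
        for cls, elapsed, new_case, request in itertools.product(
            Classification, (0, 100, 182, 183, 300, 365, 366, 1000),
            (True, False), (True, False),
        ):
            rec = make_record(cls=cls, elapsed_days=elapsed)
            assert reassessment_due(rec, TODAY, new_case, request) is policy_oracle(
                cls, elapsed, new_case, request
            ), (cls, elapsed, new_case, request)

    def test_future_dated_assessment_rejected(self):
        rec = make_record(elapsed_days=-5)
        with pytest.raises(ValueError):
            reassessment_due(rec, TODAY, True, False)

    def test_never_assessed_variant_gets_full_on_new_case(self):
        rec = make_record()
        rec.last_full_assessment = None
        assert reassessment_due(rec, TODAY, True, False) is ReassessmentDecision.FULL


class TestConfirmation:
    def test_pending_to_confirmed(self):
        rec = make_record()
        record_confirmation(rec, ConfirmationStatus.CONFIRMED)
        assert rec.confirmation_status is ConfirmationStatus.CONFIRMED

    def test_false_positive_bars_reporting(self, replay_bundle, tmp_path):
        from genoreport.pipeline import run_case

        kb = KnowledgeBase.load(str(replay_bundle.resources_dir / "kb_state.tsv"))
        victim = kb.all_records()[0]
        victim.confirmation_status = ConfirmationStatus.PENDING
        record_confirmation(victim, ConfirmationStatus.FALSE_POSITIVE)
        kb.save(str(replay_bundle.resources_dir / "kb_state.tsv.fp"))
        # swap in the store with one false positive
        rdir = tmp_path / "resources"
        rdir.mkdir()
        for f in replay_bundle.resources_dir.iterdir():
            if f.name not in ("kb_state.tsv", "kb_state.tsv.fp"):
                (rdir / f.name).write_text(f.read_text())
        (rdir / "kb_state.tsv").write_text(
            (replay_bundle.resources_dir / "kb_state.tsv.fp").read_text()
        )
        result = run_case(str(replay_bundle.vcf_path), str(rdir))
        reported = {r.variant_key for r in result.doc.carrier_findings} | {
            r.variant_key for r in result.doc.monogenic_findings
        }
        assert key_to_str(victim.key) not in reported
        assert any("false positive" in e for e in result.exceptions)

    def test_conflicting_outcome_is_state_error(self):
        rec = make_record()
        record_confirmation(rec, ConfirmationStatus.CONFIRMED)
        record_confirmation(rec, ConfirmationStatus.CONFIRMED)  # idempotent
        with pytest.raises(StateError):
            record_confirmation(rec, ConfirmationStatus.FALSE_POSITIVE)


class TestClinvarExport:
    def test_replay_store_exports_one_row_per_association(self, replay_bundle):
        kb = KnowledgeBase.load(str(replay_bundle.resources_dir / "kb_state.tsv"))
        df = export_clinvar(kb.all_records())
        assert len(df) == 49  # dual-disease variant yields two rows
        assert df["variant_key"].nunique() == 48

    def test_export_parse_roundtrip(self, replay_bundle, tmp_path):
        kb = KnowledgeBase.load(str(replay_bundle.resources_dir / "kb_state.tsv"))
        df = export_clinvar(kb.all_records())
        path = tmp_path / "clinvar_export.tsv"
        df.to_csv(path, sep="\t", index=False)
        import pandas as pd

        back = pd.read_csv(path, sep="\t", dtype=str)
        assert list(back.columns) == list(df.columns)
        assert back["variant_key"].tolist() == df["variant_key"].tolist()
        assert back["classification"].tolist() == df["classification"].tolist()

    def test_missing_interpretation_skipped_empty_refs_warned(self, caplog):
        ok = make_record(references=[], disease="a")
        skipped = make_record(interpretation="", disease="b")
        import logging

        with caplog.at_level(logging.WARNING):
            df = export_clinvar([ok, skipped])
        assert len(df) == 1
        assert df.iloc[0]["citations"] == ""
        assert any("missing interpretation" in m for m in caplog.messages)

    def test_empty_store_yields_header_only(self, tmp_path):
        df = export_clinvar([])
        path = tmp_path / "empty.tsv"
        df.to_csv(path, sep="\t", index=False)
        assert path.read_text().strip().count("\n") == 0


class TestDiffAndNotify:
    def _store_and_packet(self, replay_bundle, replay_result):
        from genoreport.report import emit_structured_packet

        kb = KnowledgeBase.load(str(replay_bundle.resources_dir / "kb_state.tsv"))
        packet = emit_structured_packet(replay_result.doc)
        return kb, packet

    def test_no_changes_no_notices(self, replay_bundle, replay_result):
        kb, packet = self._store_and_packet(replay_bundle, replay_result)
        assert diff_and_notify(packet, kb, today=TODAY) == []

    def test_two_reclassifications_two_notices(self, replay_bundle, replay_result):
        kb, packet = self._store_and_packet(replay_bundle, replay_result)
        recs = [r for r in kb.all_records()
                if r.classification is Classification.VUS_FAVOR_PATHOGENIC][:2]
        assert len(recs) == 2
        for r in recs:
            kb.reclassify(r.key, r.disease, Classification.LIKELY_PATHOGENIC, TODAY)
        notices = diff_and_notify(packet, kb, today=TODAY)
        assert len(notices) == 2
        assert all(n.new_classification == "LikelyPathogenic" for n in notices)
        assert all(n.old_classification == "VUS_favor_pathogenic" for n in notices)

    def test_interpretation_only_edit_silent(self, replay_bundle, replay_result):
        kb, packet = self._store_and_packet(replay_bundle, replay_result)
        kb.all_records()[0].interpretation = "reworded evidence summary"
        assert diff_and_notify(packet, kb, today=TODAY) == []


class TestStorePersistence:
    def test_save_load_roundtrip_and_journal(self, tmp_path):
        journal = tmp_path / "journal.jsonl"
        kb = KnowledgeBase(journal_path=str(journal))
        kb.add(make_record(disease="a"))
        kb.add(make_record(cls=Classification.VUS, disease="b"))
        state = tmp_path / "kb_state.tsv"
        kb.save(str(state))
        again = KnowledgeBase.load(str(state))
        assert len(again) == 2
        assert [r.classification for r in again.all_records()] == [
            r.classification for r in kb.all_records()
        ]
        assert journal.read_text().count("\n") == 2

    def test_duplicate_association_rejected(self):
        kb = KnowledgeBase()
        kb.add(make_record(disease="a"))
        with pytest.raises(StateError):
            kb.add(make_record(disease="a"))
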