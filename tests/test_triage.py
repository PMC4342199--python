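"""Filtration arms, reporting threshold, routing, confirmation-risk flags."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from genoreport.kb import (
    Classification,
    ClassificationRecord,
    Inheritance,
    KnowledgeBase,
)
from genoreport.model import (
    AnnotatedVariant,
    Consequence,
    GenomicVariant,
    PopulationFrequencies,
    TranscriptAnnotation,
    Zygosity,
)
from genoreport.triage import (
    Arm,
    AssertionCategory,
    GeneListEntry,
    Section,
    TriageResources,
    TriagedVariant,
    apply_reporting_threshold,
    arm_assertion,
    arm_lof,
    arm_pgx,
    flag_confirmation_risk,
    maf_gate,
    route_sections,
    triage,
)


def make_variant(
    gene="BTD",
    consequence=Consequence.MISSENSE,
    maf=0.001,
    pos=1000,
    zygosity=Zygosity.HETEROZYGOUS,
    alt="T",
    rsid=None,
):
    v = GenomicVariant("chr1", pos, "C", alt, zygosity, 99, rsid=rsid)
    ann = TranscriptAnnotation(
        gene=gene, transcript="NM_000.1", c_hgvs="c.100C>T", p_hgvs="p.?",
        consequence=consequence,
    )
    freqs = (
        PopulationFrequencies(maf_ea=maf, maf_aa=maf)
        if maf is not None
        else PopulationFrequencies()
    )
    return AnnotatedVariant(variant=v, annotation=ann, frequencies=freqs)


class TestMafGate:
    def test_absent_frequency_passes(self):
        assert maf_gate(PopulationFrequencies(), 0.05)
        assert maf_gate(None, 0.01)

    def test_disjunctive_default_vs_conjunctive_mode(self):
        mixed = PopulationFrequencies(maf_ea=0.10, maf_aa=0.001)
        assert maf_gate(mixed, 0.05, mode="any")
        assert not maf_gate(mixed, 0.05, mode="all")

    def test_observed_zero_distinct_from_absent(self):
        assert maf_gate(PopulationFrequencies(maf_ea=0.0, maf_aa=0.0), 0.05)


class TestArms:
    def test_assertion_dm_rare_true(self):
        v = make_variant(maf=0.001)
        assertions = {v.key: AssertionCategory.DM}
        assert arm_assertion(v, assertions, KnowledgeBase())

    def test_assertion_via_prior_pathogenic_classification(self):
        v = make_variant(maf=0.001)
        kb = KnowledgeBase()
        kb.add(
            ClassificationRecord(
                key=v.key, classification=Classification.PATHOGENIC,
                disease="d", inheritance=Inheritance.AR,
            )
        )
        assert arm_assertion(v, {}, kb)

    def test_assertion_false_without_any_evidence(self):
        assert not arm_assertion(make_variant(), {}, KnowledgeBase())

    def test_assertion_fails_frequency_gate(self):
        v = make_variant(maf=0.10)
        assert not arm_assertion(v, {v.key: AssertionCategory.DM}, KnowledgeBase())

    def test_lof_true_for_rare_listed_frameshift(self):
        v = make_variant(gene="USH2A", consequence=Consequence.FRAMESHIFT, maf=0.001)
        gl = {"USH2A": GeneListEntry("USH2A", Inheritance.AR, "Usher syndrome type II")}
        assert arm_lof(v, gl)

    def test_lof_false_for_canonical_splice_above_one_percent(self):
        # assertion-arm-only ascertainment: splice variant at 2% MAF
        v = make_variant(gene="MPO", consequence=Consequence.CANONICAL_SPLICE, maf=0.02)
        gl = {"MPO": GeneListEntry("MPO", Inheritance.AR, "MPO deficiency")}
        assert not arm_lof(v, gl)
        assert arm_assertion(v, {v.key: AssertionCategory.DM}, KnowledgeBase())

    def test_lof_false_off_gene_list_or_common(self):
        v = make_variant(gene="NOTLISTED", consequence=Consequence.NONSENSE, maf=0.001)
        assert not arm_lof(v, {})
        v2 = make_variant(gene="USH2A", consequence=Consequence.NONSENSE, maf=0.03)
        gl = {"USH2A": GeneListEntry("USH2A", Inheritance.AR, "Usher")}
        assert not arm_lof(v2, gl)

    def test_pgx_matches_by_key_or_rsid(self):
        sites = {("chr10", 94781859, "G", "A"): "rs4244285"}
        hit = GenomicVariant("chr10", 94781859, "G", "A", Zygosity.HETEROZYGOUS, 99)
        assert arm_pgx(hit, sites)
        by_rsid = GenomicVariant("chrX", 5, "G", "A", Zygosity.HETEROZYGOUS, 99,
                                 rsid="rs4244285")
        assert arm_pgx(by_rsid, sites)
        miss = GenomicVariant("chr1", 7, "G", "A", Zygosity.HETEROZYGOUS, 99,
                              rsid="rs9999999")
        assert not arm_pgx(miss, sites)


def _resources(assertions=None, gene_list=None, kb=None, **kwargs):
    return TriageResources(
        assertions=assertions or {},
        gene_list=gene_list or {},
        frequencies={},
        kb=kb or KnowledgeBase(),
        pgx_sites={},
        **kwargs,
    )


class TestTriage:
    def test_empty_input_empty_output(self):
        assert triage([], _resources()) == []

    def test_multi_arm_variant_records_both_arms(self):
        # rare nonsense, asserted DM, gene on list: ascertained by both arms
        v = make_variant(gene="CFTR", consequence=Consequence.NONSENSE, maf=0.001)
        res = _resources(
            assertions={v.key: AssertionCategory.DM},
            gene_list={"CFTR": GeneListEntry("CFTR", Inheritance.AR, "Cystic fibrosis")},
        )
        (tv,) = triage([v], res)
        assert tv.arms == {Arm.ASSERTION, Arm.LOF}

    def test_output_sorted_by_position(self):
        vs = [make_variant(pos=p, maf=0.001) for p in (500, 100, 300)]
        res = _resources(assertions={v.key: AssertionCategory.DM for v in vs})
        out = triage(vs, res)
        assert [t.variant.variant.pos for t in out] == [100, 300, 500]

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_maf_cutoff_monotonicity(self, data):
        """Raising a MAF cutoff never shrinks the triaged set; lowering
        never grows it."""
        n = data.draw(st.integers(3, 12))
        variants = []
        for i in range(n):
            maf = data.draw(st.floats(0.0, 0.2), label=f"maf{i}")
            cons = data.draw(st.sampled_from(list(Consequence)), label=f"cons{i}")
            variants.append(
                make_variant(gene="G1", consequence=cons, maf=maf, pos=100 + i)
            )
        assertions = {v.key: AssertionCategory.DM for v in variants[::2]}
        gl = {"G1": GeneListEntry("G1", Inheritance.AR, "d")}
        lo_a, hi_a = sorted(
            (data.draw(st.floats(0.001, 0.3)), data.draw(st.floats(0.001, 0.3)))
        )
        lo_l, hi_l = sorted(
            (data.draw(st.floats(0.001, 0.3)), data.draw(st.floats(0.001, 0.3)))
        )
        low = triage(variants, _resources(assertions, gl,
                                          assertion_maf_cutoff=max(lo_a, 1e-6),
                                          lof_maf_cutoff=max(lo_l, 1e-6)))
        high = triage(variants, _resources(assertions, gl,
                                           assertion_maf_cutoff=max(hi_a, 1e-6),
                                           lof_maf_cutoff=max(hi_l, 1e-6)))
        assert {t.key for t in low} <= {t.key for t in high}


class TestReportingThreshold:
    def _tv(self, arms):
        return TriagedVariant(variant=make_variant(), arms=arms)

    def _rec(self, cls):
        return ClassificationRecord(
            key=("chr1", 1000, "C", "T"), classification=cls,
            disease="d", inheritance=Inheritance.AR,
        )

    @pytest.mark.parametrize(
        "cls,expected",
        [
            (Classification.PATHOGENIC, True),
            (Classification.LIKELY_PATHOGENIC, True),
            (Classification.VUS_FAVOR_PATHOGENIC, True),
            (Classification.VUS, False),
            (Classification.VUS_FAVOR_BENIGN, False),
            (Classification.LIKELY_BENIGN, False),
            (Classification.BENIGN, False),
        ],
    )
    def test_only_favor_pathogenic_tiers_pass(self, cls, expected):
        tv = self._tv({Arm.ASSERTION})
        assert apply_reporting_threshold(tv, self._rec(cls)) is expected

    def test_pgx_only_bypasses_gate(self):
        tv = self._tv({Arm.PGX})
        assert apply_reporting_threshold(tv, None)

    def test_unclassified_not_reported(self):
        assert not apply_reporting_threshold(self._tv({Arm.LOF}), None)


class TestRouting:
    def _tv(self, zygosity=Zygosity.HETEROZYGOUS, gene="GJB2"):
        return TriagedVariant(
            variant=make_variant(gene=gene, zygosity=zygosity), arms={Arm.ASSERTION}
        )

    def _rec(self, disease, inheritance, gene="GJB2"):
        return ClassificationRecord(
            key=("chr1", 1000, "C", "T"),
            classification=Classification.PATHOGENIC,
            disease=disease, inheritance=inheritance, gene=gene,
        )

    def test_het_recessive_routes_to_carrier(self):
        (entry,) = route_sections(self._tv(), [self._rec("Hearing loss", Inheritance.AR)])
        assert entry.section is Section.CARRIER

    def test_hom_recessive_routes_to_monogenic(self):
        tv = self._tv(zygosity=Zygosity.HOMOZYGOUS)
        (entry,) = route_sections(tv, [self._rec("Hearing loss", Inheritance.AR)])
        assert entry.section is Section.MONOGENIC

    def test_xl_hemizygous_routes_to_monogenic(self):
        tv = self._tv(zygosity=Zygosity.HEMIZYGOUS, gene="ARSE")
        (entry,) = route_sections(
            tv, [self._rec("Chondrodysplasia punctata", Inheritance.XL, gene="ARSE")]
        )
        assert entry.section is Section.MONOGENIC

    def test_dual_inheritance_gene_yields_one_entry_per_association(self):
        tv = self._tv(gene="KCNQ1")
        entries = route_sections(
            tv,
            [
                self._rec("Jervell and Lange-Nielsen syndrome", Inheritance.AR, "KCNQ1"),
                self._rec("Romano Ward syndrome", Inheritance.AD, "KCNQ1"),
            ],
        )
        assert {e.section for e in entries} == {Section.CARRIER, Section.MONOGENIC}
        assert len(entries) == 2
        assert tv.sections == {Section.CARRIER, Section.MONOGENIC}

    def test_indication_tag_for_cardiomyopathy_case(self):
        tv = self._tv(gene="MYH7")
        gl = {"MYH7": GeneListEntry("MYH7", Inheritance.AD, "HCM", indication_gene=True)}
        (entry,) = route_sections(
            tv,
            [self._rec("Hypertrophic cardiomyopathy", Inheritance.AD, "MYH7")],
            indication_context="cardiomyopathy",
            gene_list=gl,
        )
        assert entry.section is Section.MONOGENIC and entry.indication
        assert Section.INDICATION in tv.sections
        # same finding in a primary-care case carries no indication tag
        tv2 = self._tv(gene="MYH7")
        (entry2,) = route_sections(
            tv2, [self._rec("Hypertrophic cardiomyopathy", Inheritance.AD, "MYH7")],
            indication_context="primary_care", gene_list=gl,
        )
        assert not entry2.indication

    def test_missing_records_is_routing_error(self):
        from genoreport.triage import RoutingError

        with pytest.raises(RoutingError):
            route_sections(self._tv(), [])


class TestConfirmationRisk:
    def test_low_quality_indel_flagged(self):
        v = GenomicVariant("chr1", 100, "GA", "G", Zygosity.HETEROZYGOUS, 12)
        assert flag_confirmation_risk(v, "ACGTACGTAC", "TGCATGCATG", gq_threshold=30)

    def test_clean_snv_not_flagged(self):
        v = GenomicVariant("chr1", 100, "G", "A", Zygosity.HETEROZYGOUS, 99)
        assert not flag_confirmation_risk(v, "ACGTACGTAC", "TGCATGCATG")

    def test_homopolymer_adjacency_flagged(self):
        v = GenomicVariant("chr1", 100, "G", "A", Zygosity.HETEROZYGOUS, 99)
        assert flag_confirmation_risk(v, "GCGTAAAAAA", "TGCATGCATG")
        assert flag_confirmation_risk(v, "ACGTACGTAC", "TTTTTTGCAT")
        # run of 5 is below the default threshold of 6
        assert not flag_confirmation_risk(v, "GCGTCAAAAA", "TGCATGCATG")

    def test_quality_only_rule_without_context(self):
        v = GenomicVariant("chr1", 100, "G", "A", Zygosity.HETEROZYGOUS, 5)
        assert not flag_confirmation_risk(v)  # SNV: quality rule is indel-only
        indel = GenomicVariant("chr1", 100, "GA", "G", Zygosity.HETEROZYGOUS, 5)
        assert flag_confirmation_risk(indel)


class TestReplayArms:
    def test_replay_reproduces_filter_column(self, replay_bundle, replay_result):
        """Triage over the full replay case reproduces each fixture row's
        ascertainment arms, with the +5 splice variant as documented
        exception (assertion arm only)."""
        from genoreport.kb import key_to_str

        arms_by_key = {
            key_to_str(t.key): sorted(a.value for a in t.arms)
            for t in replay_result.triaged
        }
        for row in replay_bundle.truth:
            assert arms_by_key.get(row.variant_key) == sorted(row.expected_arms), row.gene

    def test_section_totals_match_fixture(self, replay_result):
        from genoreport.triage import Section

        sections = [e.section for _, e in replay_result.entries]
        assert sections.count(Section.CARRIER) == 40
        assert sections.count(Section.MONOGENIC) == 9
        assert len(sections) == 49
        assert len({tv.key for tv, _ in replay_result.entries}) == 48

    def test_background_never_triaged(self, replay_bundle, replay_result):
        from genoreport.kb import key_to_str

        triaged_keys = {key_to_str(t.key) for t in replay_result.triaged}
        assert triaged_keys.isdisjoint(set(replay_bundle.background_keys))
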