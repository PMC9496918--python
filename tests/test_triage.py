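import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtbfocus as m
from mtbfocus.triage import (DKTK_ORDER, ESCAT_ORDER, LABEL_ORDER,
                             EvidenceRecord, load_fusion_rules,
                             load_point_config, recommendation_sort_key,
                             variants_from_frame)


def ssv(depth=150, vaf=0.10, popfreq=0.001, gene="TP53"):
    return m.ShortSequenceVariant(gene=gene, contig="chr17", position=7_675_000,
                                  ref="C", alt="T", depth=depth, vaf=vaf,
                                  popfreq=popfreq)


class TestFilterVariants:
    def test_empty_input_gives_empty_output(self):
        passing, reasons = m.filter_variants([])
        assert passing == [] and reasons == []

    @pytest.mark.parametrize("variant, expect_pass", [
        (ssv(depth=150, vaf=0.10, popfreq=0.001), True),
        (ssv(depth=100), False),           # "over 100x" is strict
        (ssv(depth=101), True),
        (ssv(vaf=0.05), True),             # VAF cutoff inclusive
        (ssv(vaf=0.049), False),
        (ssv(popfreq=0.05), False),        # "below 5%" is strict
        (ssv(popfreq=0.0499), True),
        (ssv(popfreq=None), True),         # missing treated as rare
    ])
    def test_boundary_semantics(self, variant, expect_pass):
        passing, _ = m.filter_variants([variant])
        assert (len(passing) == 1) == expect_pass

    def test_fail_reasons_enumerate_every_violated_predicate(self):
        _, reasons = m.filter_variants([ssv(depth=50, vaf=0.01, popfreq=0.2)])
        assert len(reasons[0]) == 3

    def test_filtering_is_idempotent(self):
        table, _ = m.simulate_variant_table(200, m.SimulationConfig(seed=17))
        variants = variants_from_frame(table)
        passing, _ = m.filter_variants(variants)
        again, reasons = m.filter_variants(passing)
        assert again == passing
        assert all(r == [] for r in reasons)

    def test_agrees_with_independent_predicate_oracle(self):
        table, labels = m.simulate_variant_table(300, m.SimulationConfig(seed=23))
        _, reasons = m.filter_variants(variants_from_frame(table))
        assert [not r for r in reasons] == list(labels)


class TestPathogenicity:
    def test_no_criteria_is_vus(self):
        res = m.classify_pathogenicity([])
        assert res.total == 0 and res.category == "VUS"

    def test_known_oncogenic_combination(self):
        # OVS1 (8) + OM1 (2) = 10 -> oncogenic
        res = m.classify_pathogenicity(["OVS1", "OM1"])
        assert res.total == 10 and res.category == "oncogenic"

    def test_strong_benign_evidence(self):
        res = m.classify_pathogenicity(["SBVS1"])
        assert res.category == "benign"

    def test_unknown_code_raises_with_code_name(self):
        with pytest.raises(KeyError, match="NOPE"):
            m.classify_pathogenicity(["NOPE"])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from(sorted(load_point_config()[0])), max_size=6))
    def test_category_matches_brute_force_threshold_lookup(self, codes):
        points, cats = load_point_config()
        res = m.classify_pathogenicity(codes)
        total = sum(points[c] for c in codes)
        expected = max((c for c, t in cats.items() if t <= total),
                       key=lambda c: cats[c])
        assert res.total == total and res.category == expected

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.sampled_from(sorted(load_point_config()[0])), max_size=5),
           st.sampled_from(["OVS1", "OS1", "OM1", "OP1"]))
    def test_adding_positive_criterion_never_lowers_category(self, codes, extra):
        order = m.triage.PATHOGENICITY_CATEGORIES
        before = order.index(m.classify_pathogenicity(codes).category)
        after = order.index(m.classify_pathogenicity(codes + [extra]).category)
        assert after >= before


class TestFusionReassignment:
    def test_tmprss2_erg_reassigns_to_prostate(self):
        out = m.infer_entity_from_fusion([m.FusionCall("TMPRSS2", "ERG")])
        assert out is not None and out.entity == "prostate carcinoma"

    def test_sec31a_alk_reassigns_to_dlbcl(self):
        out = m.infer_entity_from_fusion([m.FusionCall("SEC31A", "ALK")])
        assert out.entity == "ALK-positive DLBCL"

    def test_unordered_matching_by_default(self):
        out = m.infer_entity_from_fusion([m.FusionCall("ERG", "TMPRSS2")])
        assert out.entity == "prostate carcinoma"
        assert m.infer_entity_from_fusion([m.FusionCall("ERG", "TMPRSS2")],
                                          ordered=True) is None

    def test_unlisted_fusion_gives_no_reassignment(self):
        assert m.infer_entity_from_fusion([m.FusionCall("EML4", "ALK")]) is None

    def test_rule_table_loads_with_required_columns(self):
        rules = load_fusion_rules()
        assert {"gene5", "gene3", "entity"} <= set(rules.columns)


class TestEvidenceMatching:
    def test_braf_v600e_crc_returns_tiered_record(self):
        kb = m.load_knowledge_base()
        hits = m.match_evidence("BRAF", "V600E", "CRC", kb)
        top = hits[0]
        assert top.therapy == "Encorafenib + Binimetinib + Cetuximab"
        assert top.escat == "I-A" and top.dktk == "m1a"
        assert not top.cross_entity

    def test_ret_y791f_steroid_cell_tumor(self):
        kb = m.load_knowledge_base()
        hits = m.match_evidence("RET", "Y791F", "steroid cell tumor", kb)
        assert hits[0].therapy == "Cabozantinib"
        assert hits[0].escat == "IV-A" and hits[0].dktk == "m3"

    def test_cross_entity_match_flagged_not_rewritten(self):
        kb = m.load_knowledge_base()
        hits = m.match_evidence("BRAF", "V600E", "melanoma", kb)
        assert hits and all(h.cross_entity for h in hits)
        assert {h.escat for h in hits} == {"I-A", "III-A"}  # tiers as stored

    def test_absent_alteration_gives_empty_result(self):
        assert m.match_evidence("MYC", "amplification", "CRC",
                                m.load_knowledge_base()) == []

    def test_malformed_kb_row_raises_with_line(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text("gene\talteration\tentity\ttherapy\tescat\tdktk\tlabel\n"
                        "BRAF\tV600E\tCRC\tX\tI-Z\tm1a\toff\n")
        with pytest.raises(ValueError, match="line 2"):
            m.load_knowledge_base(path)


def random_records(rng, n):
    recs = []
    for i in range(n):
        recs.append(EvidenceRecord(
            gene=f"G{i}", alteration="any", entity="E", therapy=f"T{i}",
            escat=rng.choice(ESCAT_ORDER), dktk=rng.choice(DKTK_ORDER),
            label=rng.choice(LABEL_ORDER),
            early_phase_trial=bool(rng.integers(2))))
    return recs


class TestRanking:
    def test_single_record_returns_itself(self):
        rec = EvidenceRecord("BRAF", "V600E", "CRC", "T", "I-A", "m1a", "off")
        assert m.rank_recommendations([rec]) == [rec]

    def test_strong_tier_precedes_weak_tier(self):
        weak = EvidenceRecord("A", "x", "E", "T1", "III-A", "m2a", "on")
        strong = EvidenceRecord("B", "y", "E", "T2", "I-A", "m4", "trial")
        assert m.rank_recommendations([weak, strong])[0] == strong

    def test_shuffled_records_match_brute_force_sort(self):
        rng = np.random.default_rng(2)
        recs = random_records(rng, 10)
        ranked = m.rank_recommendations(recs)
        brute = sorted(recs, key=lambda r: (
            ESCAT_ORDER.index(r.escat), DKTK_ORDER.index(r.dktk),
            LABEL_ORDER.index(r.label)))
        assert ranked == brute

    def test_timely_flag_demotes_early_phase_trials(self):
        early = EvidenceRecord("A", "x", "E", "T1", "I-A", "m1a", "trial",
                               early_phase_trial=True)
        other = EvidenceRecord("B", "y", "E", "T2", "V", "m4", "off")
        assert m.rank_recommendations([early, other])[0] == early
        assert m.rank_recommendations([early, other],
                                      timely_treatment_required=True)[0] == other

    def test_comparator_is_a_total_order(self):
        rng = np.random.default_rng(3)
        recs = random_records(rng, 12)
        keys = [recommendation_sort_key(r) for r in recs]
        for ka in keys:  # antisymmetry + transitivity hold for tuple keys;
            for kb in keys:  # check comparability explicitly
                assert (ka <= kb) or (kb <= ka)
        ranked = m.rank_recommendations(recs)
        assert sorted(ranked, key=recommendation_sort_key) == ranked
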