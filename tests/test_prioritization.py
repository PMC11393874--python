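"""The two-round cascade: rule functions, published-profile behavior on the
curated table, invariants, and brute-force oracle agreement."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from repairvar import (AfClass, FilterConfig, Group, Subcategory,
                       TranscriptAnnotation, af_class, cadd_pass, classify,
                       consequence_group, retained, revel_pass, run_relaxed,
                       run_strict, transcript_filter)
from repairvar.errors import ConfigError, InputError
from tests.oracle import oracle_retained
from tests.test_annotation_io import mk_variant

CFG = FilterConfig.published()


class TestCaddRule:
    @pytest.mark.parametrize("score,expected", [
        (42, True),        # most deleterious curated variant
        (20.0, True),      # boundary: exactly the cutoff is kept
        (19.999, False),   # "smaller than 20" excluded
        (None, True),      # unscored indels are kept
    ])
    def test_threshold_and_missing(self, score, expected):
        assert cadd_pass(score, CFG) is expected

    def test_negative_score_rejected(self):
        with pytest.raises(InputError):
            cadd_pass(-3, CFG)


class TestRevelRule:
    @pytest.mark.parametrize("score,thr,expected", [
        (0.884, 0.75, True),   # clears the strict bar
        (0.75, 0.75, False),   # strictly-greater comparison
        (0.413, 0.4, True),    # clears the relaxed bar
        (None, 0.75, True),    # unscored variants are kept
    ])
    def test_threshold_and_missing(self, score, thr, expected):
        assert revel_pass(score, thr, CFG) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            revel_pass(1.2, 0.75, CFG)


class TestAfClass:
    def test_rare_when_all_present_below(self):
        v = mk_variant(af_exome_fin=0.002491, af_genome_fin=0.003159)
        assert af_class(v, 0.01) is AfClass.RARE

    def test_ultra_rare_when_nothing_reported(self):
        assert af_class(mk_variant(), 0.01) is AfClass.ULTRA_RARE

    def test_excluded_when_any_frequency_at_threshold(self):
        v = mk_variant(af_exome_fin=0.001, af_genome_global=0.5)
        assert af_class(v, 0.01) is AfClass.EXCLUDED

    def test_zero_frequency_counts_as_reported(self):
        v = mk_variant(af_exome_fin=0.0, af_genome_fin=0.0)
        assert af_class(v, 0.01) is AfClass.RARE


class TestConsequenceGroup:
    @pytest.mark.parametrize("terms,expected", [
        ({"stop_gained"}, Group.GROUP1),
        ({"missense_variant", "splice_region_variant"}, Group.GROUP2),
        ({"synonymous_variant"}, Group.OTHER),
        ({"stop_gained", "missense_variant"}, Group.GROUP1),  # precedence
        ({"downstream_gene_variant"}, Group.GROUP2),
        ({"splice_region_variant", "splice_polypyrimidine_tract_variant",
          "intron_variant"}, Group.GROUP1),
    ])
    def test_grouping(self, terms, expected):
        assert consequence_group(terms, CFG) is expected


def ann(terms, canonical):
    return TranscriptAnnotation(gene_symbol="G",
                                consequence_terms=frozenset(terms),
                                is_canonical=canonical)


class TestTranscriptFilter:
    def test_canonical_wins(self):
        noncanon = ann({"missense_variant"}, False)
        canon = ann({"missense_variant"}, True)
        assert transcript_filter([noncanon, canon]) is canon

    def test_non_transcript_only_survives(self):
        down = ann({"downstream_gene_variant"}, False)
        assert transcript_filter([down]) is down

    def test_non_canonical_transcript_only_dropped(self):
        assert transcript_filter([ann({"missense_variant"}, False)]) is None

    def test_empty_list(self):
        assert transcript_filter([]) is None


def cv(gene="WRN", terms=("missense_variant",), canonical=True, pos=100, **kw):
    v = mk_variant(gene=gene, pos=pos, rsid=f"rs{pos}", **kw)
    object.__setattr__(v.annotation, "consequence_terms", frozenset(terms))
    object.__setattr__(v.annotation, "is_canonical", canonical)
    return v


class TestRounds:
    def test_strict_retains_high_revel_rare_missense(self, panel):
        v = cv(gene="MSH3", revel=0.884, cadd_phred=32,
               af_exome_fin=0.001294, af_genome_fin=0.001415)
        calls, genes = run_strict([v], panel, CFG)
        assert [c.subcategory for c in calls] == [Subcategory.SUB1]
        assert genes == {"MSH3"}

    def test_strict_excludes_af_above_cutoff(self, panel):
        v = cv(gene="POLQ", revel=0.84, cadd_phred=33,
               af_exome_fin=0.01381, af_genome_fin=0.01208)
        calls, genes = run_strict([v], panel, CFG)
        assert calls == [] and genes == set()

    def test_relaxed_recovers_it_with_gene_anchor(self, panel):
        v = cv(gene="POLQ", revel=0.84, cadd_phred=33,
               af_exome_fin=0.01381, af_genome_fin=0.01208)
        calls = run_relaxed([v], {"POLQ"}, CFG, panel)
        assert [c.subcategory for c in calls] == [Subcategory.SUB2]

    def test_relaxed_skips_unaffected_genes(self, panel):
        v = cv(gene="POLQ", revel=0.84, cadd_phred=33, af_exome_fin=0.015)
        assert run_relaxed([v], {"WRN"}, CFG, panel) == []

    def test_empty_input(self, panel):
        assert run_strict([], panel, CFG) == ([], set())


class TestClassify:
    def test_common_panel_variant_rejected_as_excluded(self, panel):
        v = cv(gene="WRN", revel=0.9, cadd_phred=30, af_exome_fin=0.3)
        (call,) = classify([v], panel, CFG)
        assert not call.retained and call.af_class is AfClass.EXCLUDED

    def test_single_group1_ultra_rare_retained_without_subcategory(self, panel):
        v = cv(gene="CHEK2", terms=("splice_acceptor_variant",), cadd_phred=34)
        (call,) = classify([v], panel, CFG)
        assert call.retained and call.group is Group.GROUP1
        assert call.subcategory is Subcategory.NONE

    def test_mid_revel_needs_same_gene_anchor_under_strict_scope(self, panel):
        anchor = cv(gene="POLG", pos=1, revel=0.967, cadd_phred=25,
                    af_exome_fin=0.004)
        mid = cv(gene="POLG", pos=2, revel=0.571, cadd_phred=28,
                 af_exome_fin=0.007)
        lone = cv(gene="TREX1", pos=3, revel=0.571, cadd_phred=28,
                  af_exome_fin=0.007)
        cfg = dataclasses.replace(CFG, relaxed_gene_source="strict_retained")
        calls = {c.uid: c for c in classify([anchor, mid, lone], panel, cfg)}
        assert calls["rs2"].retained and calls["rs2"].subcategory is Subcategory.SUB2
        assert not calls["rs3"].retained

    def test_rule_trace_nonempty_for_every_variant(self, table1, panel):
        assert all(c.rule_trace for c in classify(table1, panel, CFG))

    def test_permutation_invariance(self, table1, panel):
        fwd = classify(table1, panel, CFG)
        rev = classify(list(reversed(table1)), panel, CFG)
        as_set = lambda calls: {(c.uid, c.retained, c.group, c.subcategory)
                                for c in calls}
        assert as_set(fwd) == as_set(rev)

    def test_duplicate_records_evaluated_once(self, table1, panel):
        calls = classify(list(table1) + list(table1), panel, CFG)
        assert len(calls) == len(table1)


class TestPublishedProfileOnCuratedTable:
    def test_all_curated_variants_retained(self, table1, panel):
        assert len(retained(classify(table1, panel, CFG))) == len(table1)

    def test_five_polq_variants_and_cadd_max_42(self, table1, panel):
        keep = retained(classify(table1, panel, CFG))
        assert sum(1 for c in keep if c.gene == "POLQ") == 5
        uids = {c.uid for c in keep}
        cadds = [v.cadd_phred for v in table1
                 if v.uid in uids and v.cadd_phred is not None]
        assert max(cadds) == 42

    def test_pinned_subcategories(self, table1, panel):
        by = {c.uid: c for c in classify(table1, panel, CFG)}
        assert by["rs199791286"].subcategory is Subcategory.SUB1
        assert by["rs41540016"].subcategory is Subcategory.SUB2
        assert by["rs2306211"].subcategory is Subcategory.SUB2
        # Group 1 rows with AF in [0.01, 0.02) come back in round 2, no subcategory
        assert by["rs11571833"].retained
        assert by["rs11571833"].subcategory is Subcategory.NONE


class TestInvariants:
    def test_strict_retainees_also_satisfy_relaxed_rules(self, table1, panel):
        strict_calls, _ = run_strict(table1, panel, CFG)
        strict_uids = {c.uid for c in strict_calls}
        relaxed_all = run_relaxed(
            table1, {v.gene for v in table1}, CFG, panel,
            already_retained=[(c.key, c.gene) for c in strict_calls])
        # SUB1/SUB2 disjoint by construction; strict set within relaxed criteria
        relaxed_uids = {c.uid for c in relaxed_all}
        assert strict_uids.isdisjoint(relaxed_uids)
        relaxed_keep, _ = run_strict(
            table1, panel,
            dataclasses.replace(CFG, af_strict=CFG.af_relaxed,
                                revel_strict=CFG.revel_relaxed))
        assert strict_uids <= {c.uid for c in relaxed_keep}

    @pytest.mark.parametrize("harder", [
        dict(cadd_min=25.0), dict(af_strict=0.005, af_relaxed=0.005),
        dict(af_strict=0.001, af_relaxed=0.01),
    ])
    def test_monotonicity_tightening_never_adds_retainees(
            self, table1, panel, harder):
        base = {c.uid for c in retained(classify(table1, panel, CFG))}
        tight = {c.uid for c in retained(classify(
            table1, panel, dataclasses.replace(CFG, **harder)))}
        assert tight <= base

    def test_oracle_agreement_on_curated_table(self, table1, panel):
        mine = {c.uid for c in retained(classify(table1, panel, CFG))}
        assert mine == oracle_retained(table1, panel, CFG)

    @settings(max_examples=30, deadline=None)
    @given(af_strict=st.floats(0.0005, 0.01), af_gap=st.floats(0, 0.02),
           revel_relaxed=st.floats(0.1, 0.75), revel_gap=st.floats(0, 0.25),
           scope=st.sampled_from(["general_filter", "strict_retained"]))
    def test_oracle_agreement_under_threshold_sweeps(
            self, table1, panel, af_strict, af_gap, revel_relaxed, revel_gap,
            scope):
        cfg = dataclasses.replace(
            CFG, af_strict=af_strict, af_relaxed=min(af_strict + af_gap, 1.0),
            revel_relaxed=revel_relaxed,
            revel_strict=min(revel_relaxed + revel_gap, 1.0),
            relaxed_gene_source=scope)
        mine = {c.uid for c in retained(classify(table1, panel, cfg))}
        assert mine == oracle_retained(table1, panel, cfg)


class TestConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            FilterConfig(af_strict=0.05, af_relaxed=0.01)
        with pytest.raises(ConfigError):
            FilterConfig(revel_strict=0.2, revel_relaxed=0.6)

    def test_overlapping_group_terms_rejected(self):
        with pytest.raises(ConfigError):
            FilterConfig(group1_terms=frozenset({"missense_variant"}))

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = dataclasses.replace(CFG, cadd_min=25.0)
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert FilterConfig.from_yaml(p) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("bogus_threshold: 3\n")
        with pytest.raises(ConfigError):
            FilterConfig.from_yaml(p)
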