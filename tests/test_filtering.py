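"""The nine-rule filter cascade."""

import pytest

from chipcall.calling import VariantCall
from chipcall.filtering import (
    Annotation,
    AnnotationTable,
    FilterConfig,
    FLAG_POP_MAF,
    FLAG_RECURRENCE,
    FLAG_SET_GAP,
    FLAG_VAF_WINDOW,
    filter_annotation,
    filter_cohort_recurrence,
    filter_dual_set,
    filter_population_maf,
    filter_vaf_window,
    run_cascade,
)
from chipcall.panel import SET_A, SET_B, Amplicon, AmpliconPanel


def make_call(
    contig="G1",
    position=150,
    ref="A",
    alt="C",
    alt_reads=None,
    set_counts=None,
    mean_mapq=60.0,
    patient_id="P1",
    vaf=None,
    effect="HIGH",
    pop_mafs=None,
    dbsnp_common=False,
):
    set_counts = set_counts or {SET_A: (10, 300), SET_B: (9, 290)}
    alt_total = set_counts[SET_A][0] + set_counts[SET_B][0]
    depth_total = set_counts[SET_A][1] + set_counts[SET_B][1]
    if vaf is None:
        vaf = alt_total / depth_total
    ref_reads = round(alt_total / vaf) - alt_total if vaf > 0 else depth_total
    return VariantCall(
        contig=contig, position=position, ref=ref, alt=alt, gene=contig,
        alt_reads=alt_total, ref_reads=ref_reads, vaf=vaf, set_counts=set_counts,
        mean_mapq=mean_mapq, patient_id=patient_id, effect=effect,
        pop_mafs=pop_mafs or {}, dbsnp_common=dbsnp_common,
    )


CFG = FilterConfig()


class TestConfigValidation:
    def test_defaults_valid(self):
        FilterConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"vaf_min": 0.004},             # below the low floor
            {"pop_maf_max": 1.5},
            {"germline_band": (0.55, 0.45)},
            {"excluded_effects": frozenset({"BOGUS"})},
            {"min_coverage_per_set": 0},
        ],
    )
    def test_bad_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)


class TestPopulationMaf:
    def test_five_percent_in_any_source_fails(self):
        v = make_call(pop_mafs={"KG1000": 0.06, "EVS": 0.0, "ExAC": 0.0})
        assert not filter_population_maf(v, CFG)

    def test_below_threshold_in_all_sources_passes(self):
        v = make_call(pop_mafs={"KG1000": 0.049, "EVS": 0.049, "ExAC": 0.049})
        assert filter_population_maf(v, CFG)

    def test_unannotated_passes(self):
        assert filter_population_maf(make_call(pop_mafs={}), CFG)


class TestCohortRecurrence:
    def _calls_for(self, n_carriers, n_other=0):
        calls = [make_call(patient_id=f"P{i}") for i in range(n_carriers)]
        calls += [
            make_call(position=10 + i, patient_id=f"P{i}") for i in range(n_other)
        ]
        return calls

    def test_sixteen_of_two_hundred_fails(self):
        calls = self._calls_for(16)
        status = filter_cohort_recurrence(calls, CFG, cohort_size=200)
        assert not status[calls[0].key]

    def test_fifteen_of_two_hundred_passes(self):
        calls = self._calls_for(15)
        status = filter_cohort_recurrence(calls, CFG, cohort_size=200)
        assert status[calls[0].key]

    def test_singleton_passes(self):
        calls = self._calls_for(1)
        assert filter_cohort_recurrence(calls, CFG, cohort_size=200)[calls[0].key]

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            filter_cohort_recurrence(self._calls_for(1), CFG, cohort_size=0)


class TestDualSet:
    def test_low_coverage_in_one_set_fails(self):
        v = make_call(set_counts={SET_A: (8, 150), SET_B: (8, 99)})
        assert not filter_dual_set(v, CFG)

    def test_support_in_one_set_only_fails(self):
        v = make_call(set_counts={SET_A: (8, 500), SET_B: (0, 500)})
        assert not filter_dual_set(v, CFG)

    def test_concordant_support_passes(self):
        v = make_call(set_counts={SET_A: (5, 300), SET_B: (4, 280)})
        assert filter_dual_set(v, CFG)

    def test_single_set_panel_gap_has_distinct_flag(self):
        panel = AmpliconPanel(
            [Amplicon("G1_A", "G1", "G1", 100, 240, SET_A)], {"G1": "A" * 400}
        )
        v = make_call(position=150)
        survivors, _ = run_cascade([v], AnnotationTable(), CFG, cohort_size=50,
                                   panel=panel)
        assert survivors == []
        assert v.filters == [FLAG_SET_GAP]


class TestAnnotationRule:
    def test_modifier_effect_fails(self):
        assert not filter_annotation(make_call(effect="MODIFIER"), CFG)

    def test_clean_high_effect_passes(self):
        assert filter_annotation(make_call(effect="HIGH", mean_mapq=60.0), CFG)

    def test_low_mapping_quality_fails(self):
        assert not filter_annotation(make_call(mean_mapq=19.5), CFG)

    def test_dbsnp_common_fails(self):
        assert not filter_annotation(make_call(dbsnp_common=True), CFG)


class TestVafWindow:
    @pytest.mark.parametrize(
        "vaf,floor,expected",
        [
            (0.02, None, True),    # at least 0.02 passes
            (0.50, None, False),   # germline band
            (0.45, None, False),   # band endpoints inclusive
            (0.55, None, False),
            (0.019, None, False),  # below default floor
            (0.019, 0.005, True),  # low-clone-size floor
            (0.56, None, True),
        ],
    )
    def test_window(self, vaf, floor, expected):
        assert filter_vaf_window(make_call(vaf=vaf), CFG, vaf_floor=floor) is expected


class TestCascade:
    def test_all_pass_toy_set_survives_whole(self):
        calls = [make_call(position=100 + i, patient_id=f"P{i}") for i in range(5)]
        survivors, audit = run_cascade(calls, AnnotationTable(), CFG, cohort_size=50)
        assert survivors == calls
        assert audit.loc[audit["rule"] == "PASS", "removed"].item() == 5

    def test_removal_counts_conserve_input(self):
        calls = [
            make_call(position=100, patient_id="P1"),
            make_call(position=101, patient_id="P1", vaf=0.5),
            make_call(position=102, patient_id="P2", set_counts={SET_A: (5, 80), SET_B: (5, 300)}),
            make_call(position=103, patient_id="P2", effect="LOW"),
        ]
        survivors, audit = run_cascade(calls, AnnotationTable(), CFG, cohort_size=10)
        removed = audit.loc[audit["rule"] != "PASS", "removed"].sum()
        assert removed + len(survivors) == len(calls)

    def test_first_failing_rule_stamped(self):
        # fails both the population rule and the VAF window: first rule wins
        ann = AnnotationTable({
            ("G1", 150, "A", "C"): Annotation(pop_mafs={"KG1000": 0.3}, effect="HIGH"),
        })
        v = make_call(vaf=0.5)
        run_cascade([v], ann, CFG, cohort_size=10)
        assert v.filters == [FLAG_POP_MAF]

    def test_idempotent_on_survivors(self):
        calls = [
            make_call(position=100 + i, patient_id=f"P{i}", vaf=0.03 + 0.01 * i)
            for i in range(6)
        ] + [make_call(position=200, vaf=0.5), make_call(position=201, vaf=0.01)]
        survivors, _ = run_cascade(calls, AnnotationTable(), CFG, cohort_size=40)
        again, audit = run_cascade(list(survivors), AnnotationTable(), CFG, cohort_size=40)
        assert again == survivors
        assert audit.loc[audit["rule"] != "PASS", "removed"].sum() == 0

    def test_lowering_floor_never_removes_a_survivor(self):
        calls = [
            make_call(position=100 + i, patient_id=f"P{i}", vaf=v)
            for i, v in enumerate([0.006, 0.015, 0.03, 0.2, 0.5])
        ]
        high, _ = run_cascade(calls, AnnotationTable(), CFG, cohort_size=50, vaf_floor=0.02)
        low, _ = run_cascade(calls, AnnotationTable(), CFG, cohort_size=50, vaf_floor=0.005)
        assert {v.key for v in high} <= {v.key for v in low}

    def test_recurrent_contaminant_removed_only_by_recurrence_rule(self):
        # contaminant in 20% of patients, private clones elsewhere
        contaminant = [make_call(position=150, patient_id=f"P{i}") for i in range(10)]
        private = [make_call(position=160 + i, patient_id=f"P{i}") for i in range(10)]
        survivors, audit = run_cascade(
            contaminant + private, AnnotationTable(), CFG, cohort_size=50
        )
        assert {v.key for v in survivors} == {p.key for p in private}
        assert all(v.filters == [FLAG_RECURRENCE] for v in contaminant)
        assert audit.loc[audit["rule"] == FLAG_RECURRENCE, "removed"].item() == 10

    def test_germline_band_calls_removed_by_vaf_window(self):
        calls = [make_call(position=100 + i, patient_id=f"P{i}", vaf=0.45 + 0.02 * i)
                 for i in range(5)]
        survivors, _ = run_cascade(calls, AnnotationTable(), CFG, cohort_size=50)
        removed = [v for v in calls if v.vaf <= 0.55]
        assert survivors == [v for v in calls if v.vaf > 0.55]
        assert all(v.filters == [FLAG_VAF_WINDOW] for v in removed)
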