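"""Variant stratification: frequency framework, DS ensemble, joint filter
and uATG detection."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synostat._errors import ConfigError, DataError, DomainError
from synostat.stratify import (
    ConsequenceClass,
    DiseaseModel,
    FrequencyRecord,
    PopulationFrequency,
    PredictorCall,
    PredictorPanel,
    StratificationConfig,
    assign_af_max,
    classify_damaging,
    classify_lof,
    classify_rare,
    compute_ds,
    detect_upstream_atg,
    max_credible_af,
    stratify_cohort,
)

from conftest import make_panel, make_variant
from oracles import uatg_oracle


class TestMaxCredibleAF:
    def test_reproduces_published_threshold(self):
        # contribution product 0.036 back-solves the printed 4.5e-5 ceiling
        model = DiseaseModel(
            prevalence=0.0005,
            genetic_contribution=0.06,
            allelic_contribution=0.6,
            inheritance_factor=0.5,
            penetrance=0.2,
        )
        assert max_credible_af(model) == pytest.approx(0.000045, rel=1e-12)

    def test_identity_factors(self):
        model = DiseaseModel(
            prevalence=0.001,
            genetic_contribution=1.0,
            allelic_contribution=1.0,
            inheritance_factor=0.5,
            penetrance=1.0,
        )
        assert max_credible_af(model) == pytest.approx(0.0005)

    def test_doubling_penetrance_halves_output(self):
        base = DiseaseModel(penetrance=0.2)
        doubled = DiseaseModel(penetrance=0.4)
        assert max_credible_af(doubled) == pytest.approx(
            max_credible_af(base) / 2, rel=1e-12
        )

    @given(k=st.floats(min_value=0.01, max_value=1.0))
    def test_multiplicative_in_prevalence(self, k):
        base = DiseaseModel(prevalence=0.0005)
        scaled = DiseaseModel(prevalence=0.0005 * k)
        assert max_credible_af(scaled) == pytest.approx(
            max_credible_af(base) * k, rel=1e-9
        )

    @pytest.mark.parametrize("field,value", [
        ("prevalence", 0.0), ("penetrance", -0.1), ("inheritance_factor", 1.5),
    ])
    def test_out_of_domain_fields_rejected(self, field, value):
        with pytest.raises(DomainError, match=field):
            DiseaseModel(**{field: value})


class TestAssignAfMax:
    def test_qualifying_population_beats_overall(self, default_config):
        freq = FrequencyRecord(
            overall_allele_count=4,
            overall_allele_number=250000,
            populations=(
                PopulationFrequency("NFE", 3, 100000),
                PopulationFrequency("AFR", 1, 20000),  # AC=1: excluded
            ),
        )
        assert assign_af_max(freq, default_config) == pytest.approx(0.00003)

    def test_falls_back_to_overall_af(self, default_config):
        freq = FrequencyRecord(
            overall_allele_count=1,
            overall_allele_number=50000,
            populations=(PopulationFrequency("NFE", 1, 40000),),
        )
        assert assign_af_max(freq, default_config) == pytest.approx(0.00002)

    def test_absent_variant_gives_zero(self, default_config):
        freq = FrequencyRecord(
            overall_allele_count=0,
            overall_allele_number=250000,
            populations=(PopulationFrequency("NFE", 0, 100000),),
        )
        assert assign_af_max(freq, default_config) == 0.0

    def test_excluded_population_ignored(self, default_config):
        freq = FrequencyRecord(
            overall_allele_count=5,
            overall_allele_number=250000,
            populations=(PopulationFrequency("OTH", 5, 1000),),
        )
        # OTH would give 5e-3 but is excluded; falls back to overall
        assert assign_af_max(freq, default_config) == pytest.approx(2e-5)

    @given(
        overall_ac=st.integers(min_value=0, max_value=50),
        pops=st.lists(
            st.tuples(
                st.sampled_from(["NFE", "AFR", "EAS", "SAS", "OTH"]),
                st.integers(min_value=0, max_value=50),
                st.integers(min_value=50, max_value=100000),
            ),
            max_size=5,
            unique_by=lambda t: t[0],
        ),
    )
    def test_af_max_at_least_overall_af(self, overall_ac, pops):
        freq = FrequencyRecord(
            overall_allele_count=overall_ac,
            overall_allele_number=200000,
            populations=tuple(PopulationFrequency(*p) for p in pops),
        )
        assert assign_af_max(freq, StratificationConfig()) >= freq.overall_af

    def test_zero_allele_number_rejected(self):
        with pytest.raises(DataError):
            PopulationFrequency("NFE", 0, 0)


class TestClassifyRare:
    @pytest.mark.parametrize("af_max,expected", [
        (0.000044, True),
        (0.000045, False),  # strict inequality at the boundary
        (0.0, True),
        (0.5, False),
    ])
    def test_strict_threshold(self, af_max, expected, default_config):
        assert classify_rare(af_max, default_config) is expected

    def test_out_of_range_rejected(self, default_config):
        with pytest.raises(DomainError):
            classify_rare(1.5, default_config)


class TestComputeDS:
    @pytest.mark.parametrize("n_exceed", range(7))
    def test_counts_exceedances(self, n_exceed):
        ds, n_avail = compute_ds(make_panel(n_exceed))
        assert ds == n_exceed
        assert n_avail == 6

    def test_all_unavailable_scores_zero(self):
        calls = tuple(
            PredictorCall(f"p{i}", raw_score=None, available=False)
            for i in range(6)
        )
        ds, n_avail = compute_ds(PredictorPanel(calls=calls))
        assert ds == 0
        assert n_avail == 0

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError, match="duplicated"):
            PredictorPanel(calls=(PredictorCall("x"), PredictorCall("x")))

    def test_more_than_six_calls_rejected(self):
        with pytest.raises(ConfigError):
            PredictorPanel(calls=tuple(PredictorCall(f"p{i}") for i in range(7)))

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False),
                st.floats(-5, 5, allow_nan=False),
                st.booleans(),
                st.booleans(),
            ),
            max_size=6,
        )
    )
    def test_matches_brute_force_recount(self, data):
        calls = tuple(
            PredictorCall(f"p{i}", raw_score=score, threshold=thr,
                          higher_is_deleterious=hi, available=avail)
            for i, (score, thr, hi, avail) in enumerate(data)
        )
        ds, _ = compute_ds(PredictorPanel(calls=calls))
        expected = 0
        for score, thr, hi, avail in data:
            if avail and ((score > thr) if hi else (score < thr)):
                expected += 1
        assert ds == expected


class TestClassifyLofAndDamaging:
    @pytest.mark.parametrize("consequence,expected", [
        (ConsequenceClass.FRAMESHIFT, True),
        (ConsequenceClass.STOP_GAIN, True),
        (ConsequenceClass.SPLICE_DONOR, True),
        (ConsequenceClass.SPLICE_ACCEPTOR, True),
        (ConsequenceClass.MISSENSE, False),
        (ConsequenceClass.UTR5, False),
        (ConsequenceClass.SYNONYMOUS, False),
        (ConsequenceClass.INFRAME_INDEL, False),
    ])
    def test_lof_classes(self, consequence, expected):
        assert classify_lof(consequence) is expected

    def test_unknown_consequence_lists_accepted_values(self):
        with pytest.raises(DataError, match="frameshift"):
            ConsequenceClass.parse("nonsense_mediated_decay")

    def test_lof_damaging_regardless_of_ds(self, default_config):
        v = make_variant(consequence=ConsequenceClass.STOP_GAIN, n_exceed=0)
        assert classify_damaging(v, default_config) is True

    @pytest.mark.parametrize("ds,expected", [(4, True), (3, False), (6, True)])
    def test_missense_at_ds_threshold(self, ds, expected, default_config):
        v = make_variant(n_exceed=ds)
        assert classify_damaging(v, default_config) is expected


class TestStratifyCohort:
    def test_rare_lof_kept(self, default_config):
        kept, report = stratify_cohort([make_variant(
            consequence=ConsequenceClass.FRAMESHIFT)], default_config)
        assert len(kept) == 1
        assert report[0].kept and not report[0].failed_rules

    def test_frequent_damaging_excluded_on_frequency(self, default_config):
        # an AF_max of 7e-4 (a recurrent in-frame deletion's frequency)
        # fails the rarity rule however damaging the prediction
        v = make_variant(
            consequence=ConsequenceClass.INFRAME_INDEL,
            overall_ac=175, overall_an=250000,
            populations=(("NFE", 70, 100000),),
            n_exceed=6,
        )
        kept, report = stratify_cohort([v], default_config)
        assert kept == []
        assert report[0].failed_rules == ("frequency",)
        assert report[0].af_max == pytest.approx(0.0007)

    def test_empty_input(self, default_config):
        kept, report = stratify_cohort([], default_config)
        assert kept == [] and report == []

    def test_unevaluable_missense_flagged_and_excluded(self, default_config):
        calls = tuple(
            PredictorCall(f"p{i}", raw_score=None, available=False)
            for i in range(6)
        )
        v = make_variant()
        v.predictors = PredictorPanel(calls=calls)
        kept, report = stratify_cohort([v], default_config)
        assert kept == []
        assert report[0].unevaluable

    def test_idempotent(self, default_config):
        variants = [
            make_variant("a", ConsequenceClass.FRAMESHIFT),
            make_variant("b", n_exceed=5),
            make_variant("c", n_exceed=2),
            make_variant("d", overall_ac=100, overall_an=1000, n_exceed=6),
        ]
        kept, _ = stratify_cohort(variants, default_config)
        kept_again, _ = stratify_cohort(kept, default_config)
        assert [v.variant_id for v in kept_again] == [v.variant_id for v in kept]

    def test_membership_order_invariant(self, default_config):
        variants = [
            make_variant("a", ConsequenceClass.FRAMESHIFT),
            make_variant("b", n_exceed=3),
            make_variant("c", n_exceed=6),
        ]
        forward, _ = stratify_cohort(variants, default_config)
        backward, _ = stratify_cohort(variants[::-1], default_config)
        assert {v.variant_id for v in forward} == {v.variant_id for v in backward}

    @given(
        ds_lo=st.integers(0, 6), ds_hi=st.integers(0, 6),
        af_lo=st.floats(1e-6, 1e-2), af_hi=st.floats(1e-6, 1e-2),
    )
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity(self, ds_lo, ds_hi, af_lo, af_hi):
        """Raising af_threshold never shrinks, and raising ds_threshold
        never grows, the kept set."""
        if ds_lo > ds_hi:
            ds_lo, ds_hi = ds_hi, ds_lo
        if af_lo > af_hi:
            af_lo, af_hi = af_hi, af_lo
        variants = [
            make_variant(f"v{i}", ConsequenceClass.MISSENSE,
                         overall_ac=i * 7, overall_an=100000, n_exceed=i % 7)
            for i in range(12)
        ]
        def kept_ids(af_t, ds_t):
            cfg = StratificationConfig(af_threshold=af_t, ds_threshold=ds_t)
            kept, _ = stratify_cohort(variants, cfg)
            return {v.variant_id for v in kept}

        assert kept_ids(af_lo, 4) <= kept_ids(af_hi, 4)
        assert kept_ids(1e-4, ds_hi) <= kept_ids(1e-4, ds_lo)


class TestDetectUpstreamAtg:
    def test_edit_without_atg(self):
        # G->T at offset 4 of CCGTGCC gives CCGTTCC: no ATG anywhere
        creates, frame = detect_upstream_atg("CCGTGCC", (4, "G", "T"), 7)
        assert creates is False and frame is None

    def test_preexisting_atg_not_counted(self):
        # edit elsewhere leaves the existing ATG untouched
        creates, frame = detect_upstream_atg("CCATGCC", (0, "C", "G"), 6)
        assert creates is False

    def test_out_of_frame_uatg_mirrors_minus9_variant(self):
        # a G>T edit creates "ATG" whose A sits 8 bases upstream of the
        # main ORF's A: 8 is not a multiple of 3, so out of frame
        sequence = "CAGGCCCCCATG"
        creates, frame = detect_upstream_atg(sequence, (2, "G", "T"), 9)
        assert creates is True and frame is False
        assert uatg_oracle(sequence, 2, "T", 9) == (True, False)

    def test_in_frame_uatg(self):
        sequence = "CCAGGCCCATG"
        # A-G-G at 2..4: edit G->T? construct: positions 2,3,4 = A,G,G;
        # edit position 3 G->T gives ATG at 2; cds_offset 8 -> (8-2)%3==0
        creates, frame = detect_upstream_atg(sequence, (3, "G", "T"), 8)
        assert creates is True and frame is True

    def test_ref_mismatch_rejected(self):
        with pytest.raises(DataError, match="mismatch"):
            detect_upstream_atg("ACGT", (1, "G", "T"), 3)

    def test_non_acgt_rejected(self):
        with pytest.raises(DataError):
            detect_upstream_atg("ACNT", (1, "C", "T"), 3)

    def test_edit_not_upstream_rejected(self):
        with pytest.raises(DataError, match="5'"):
            detect_upstream_atg("ACGTACGT", (5, "C", "T"), 4)

    @given(
        sequence=st.text(alphabet="ACGT", min_size=4, max_size=30),
        position=st.integers(0, 28),
        alt=st.sampled_from("ACGT"),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_scanning_oracle(self, sequence, position, alt):
        if position >= len(sequence) - 1:
            position = len(sequence) - 2
        cds_offset = len(sequence)
        ref = sequence[position]
        result = detect_upstream_atg(sequence, (position, ref, alt), cds_offset)
        assert result == uatg_oracle(sequence, position, alt, cds_offset)
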