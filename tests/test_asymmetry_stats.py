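"""Asymmetry index, cohort statistics, and agreement scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fdgasym.asymmetry_stats import (
    AIRecord,
    RatingPair,
    ai_records_from_suvmeans,
    asymmetry_index,
    classify_ai,
    cohen_kappa,
    delta_ai,
    kappa_band,
    paired_t_test,
    ratings_contingency,
    simulate_observers,
    summarize_cohort,
)


def make_record(pid, ai1, ai2, mri="positive"):
    """AIRecord with prescribed AI values via synthetic SUV pairs."""
    # choose contra = 6, solve ez from AI = 200 (c - e)/(c + e)
    def suv_pair(ai):
        c = 6.0
        e = c * (200.0 - ai) / (200.0 + ai)
        return e, c

    e1, c1 = suv_pair(ai1)
    e2, c2 = suv_pair(ai2)
    return AIRecord(
        patient_id=pid,
        suv_ez_early=e1, suv_contra_early=c1,
        suv_ez_delayed=e2, suv_contra_delayed=c2,
        mri_status=mri,
    )


class TestAsymmetryIndex:
    def test_printed_early_group_means(self):
        # group-mean SUVs 5.21 (EZ) and 5.94 (contralateral)
        assert asymmetry_index(5.21, 5.94) == pytest.approx(100 * 2 * 0.73 / 11.15, rel=1e-12)
        assert asymmetry_index(5.21, 5.94) == pytest.approx(13.0942, abs=5e-5)

    def test_printed_delayed_group_means(self):
        assert asymmetry_index(5.61, 6.58) == pytest.approx(15.9147, abs=5e-5)

    def test_symmetry_gives_zero(self):
        for x in (0.5, 1.0, 7.3):
            assert asymmetry_index(x, x) == 0.0

    @given(
        a=st.floats(0.1, 50), b=st.floats(0.1, 50), c=st.floats(0.01, 100)
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_antisymmetry(self, a, b, c):
        assert asymmetry_index(c * a, c * b) == pytest.approx(asymmetry_index(a, b), abs=1e-9)
        assert asymmetry_index(a, b) == pytest.approx(-asymmetry_index(b, a), abs=1e-12)

    @pytest.mark.parametrize("a", [0.0, 0.05, 0.127, 0.3])
    def test_proportional_hypometabolism_identity(self, a):
        # ez = (1 - a) * contra  =>  AI = 200 a / (2 - a), exactly
        contra = 5.94
        assert asymmetry_index((1 - a) * contra, contra) == pytest.approx(
            200 * a / (2 - a), rel=1e-13
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            asymmetry_index(-1.0, 5.0)
        with pytest.raises(ValueError):
            asymmetry_index(0.0, 0.0)

    def test_bounded_open_interval(self):
        assert -200 < asymmetry_index(0.0, 5.0) <= 200
        assert asymmetry_index(0.0, 5.0) == pytest.approx(200.0)


class TestDeltaAI:
    def test_worked_case_a(self):
        assert delta_ai(14.92, 23.64) == pytest.approx(8.72)

    def test_worked_case_d(self):
        assert delta_ai(10.7, 18.87) == pytest.approx(8.17)

    def test_equal_inputs_zero(self):
        assert delta_ai(13.5, 13.5) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_ai(float("nan"), 1.0)


class TestClassifyAI:
    @pytest.mark.parametrize(
        "ai,band",
        [
            (0.0, "sub_threshold"),
            (9.99, "sub_threshold"),
            (10.0, "suggestive"),
            (14.92, "suggestive"),
            (15.0, "suggestive"),
            (15.01, "diagnostic"),
            (23.64, "diagnostic"),
            (-5.0, "sub_threshold"),
        ],
    )
    def test_bands_with_closed_suggestive_interval(self, ai, band):
        assert classify_ai(ai) == band


class TestPairedT:
    def test_identical_samples_give_null(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computed_example(self):
        t, df, p = paired_t_test([1, 2, 3, 4], [2, 3, 5, 5])
        # d = [1,1,2,1], mean 1.25, sd 0.5, t = 1.25/(0.5/2) = 5
        assert t == pytest.approx(5.0, rel=1e-12)
        assert df == 3
        assert p == pytest.approx(0.0154, abs=5e-4)

    def test_matches_reference_oracle_on_random_data(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(3, 60)
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 1.0, size=n)
            t, df, p = paired_t_test(x, y)
            ref = sps.ttest_rel(y, x)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_type_one_error_near_nominal(self):
        # null differences: rejection rate at alpha = .05 stays near .05
        rng = np.random.default_rng(7)
        n, reps = 50, 2000
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        rejections = sum(paired_t_test(x[i], y[i])[2] < 0.05 for i in range(reps))
        assert 0.035 <= rejections / reps <= 0.065

    def test_degenerate_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            paired_t_test([1.0, 2.0], [2.0, 3.0])  # constant nonzero shift

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(np.diag([10, 5, 3]))
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "very good agreement"

    def test_hand_computed_two_by_two(self):
        table = [[20, 5, 0], [10, 15, 0], [0, 0, 0]]
        res = cohen_kappa(table)
        assert res.p_observed == pytest.approx(0.7)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.4)

    def test_independent_marginals_give_zero(self):
        row = np.array([0.5, 0.3, 0.2])
        col = np.array([0.4, 0.4, 0.2])
        table = np.outer(row, col) * 1000
        assert cohen_kappa(table).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        cats = ("early_better", "same", "delayed_better")
        for _ in range(20):
            obs1 = rng.choice(cats, size=40)
            obs2 = rng.choice(cats, size=40)
            pairs = [RatingPair(str(i), a, b) for i, (a, b) in enumerate(zip(obs1, obs2))]
            table = ratings_contingency(pairs)
            # brute force: count agreements and category frequencies directly
            p_o = np.mean(obs1 == obs2)
            p_e = sum(np.mean(obs1 == c) * np.mean(obs2 == c) for c in cats)
            expected = (p_o - p_e) / (1 - p_e)
            assert cohen_kappa(table).kappa == pytest.approx(expected, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cohen_kappa([[5, 0, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((3, 3)))

    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.71, "good agreement"),
            (1.0, "very good agreement"),
            (0.40, "moderate agreement"),
            (0.20, "fair agreement"),
            (0.19, "poor consistency"),
            (-0.3, "poor consistency"),
            (0.80, "very good agreement"),
        ],
    )
    def test_band_conventions(self, kappa, band):
        assert kappa_band(kappa) == band


class TestSummarizeCohort:
    def test_opposite_shifts_counted_separately(self):
        records = [make_record("a", 10.0, 11.0), make_record("b", 10.0, 9.0, "negative")]
        s = summarize_cohort(records)
        assert s.n_increased == 1
        assert s.n_decreased == 1
        assert s.n_unchanged == 0
        assert s.strata["all"].dai_mean == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_flags_degenerate_t(self):
        # identical SUV pairs shifted in time give dAI constant per record
        records = [
            AIRecord(f"p{i}", 5.0, 6.0, 4.8, 6.2, "positive") for i in range(5)
        ]
        s = summarize_cohort(records)
        assert s.strata["all"].dai_sd == pytest.approx(0.0)
        assert s.strata["all"].t is None
        assert "degenerate" in s.strata["all"].note

    def test_matches_spreadsheet_style_recomputation(self):
        rng = np.random.default_rng(3)
        records = [
            make_record(f"p{i}", rng.uniform(5, 20), rng.uniform(8, 25),
                        "positive" if i % 3 else "negative")
            for i in range(52)
        ]
        s = summarize_cohort(records)
        df = pd.DataFrame(
            dict(ai1=[r.ai1 for r in records], ai2=[r.ai2 for r in records],
                 mri=[r.mri_status for r in records])
        )
        df["dai"] = df.ai2 - df.ai1
        assert s.strata["all"].ai1_mean == pytest.approx(df.ai1.mean())
        assert s.strata["all"].dai_sd == pytest.approx(df.dai.std(ddof=1))
        pos = df[df.mri == "positive"]
        assert s.strata["mri_positive"].n == len(pos)
        assert s.strata["mri_positive"].ai2_mean == pytest.approx(pos.ai2.mean())
        ref = sps.ttest_rel(pos.ai2, pos.ai1)
        assert s.strata["mri_positive"].p == pytest.approx(ref.pvalue, abs=1e-8)
        assert s.n_increased + s.n_decreased + s.n_unchanged == 52
        assert s.pct_increased() == pytest.approx(100 * s.n_increased / 52)

    def test_single_record_stratum_flagged_not_fabricated(self):
        records = [
            make_record("a", 10, 12, "positive"),
            make_record("b", 9, 13, "positive"),
            make_record("c", 8, 10, "negative"),
        ]
        s = summarize_cohort(records)
        neg = s.strata["mri_negative"]
        assert neg.n == 1
        assert neg.ai1_sd is None and neg.p is None
        assert "unavailable" in neg.note


class TestObservers:
    def test_noiseless_large_shifts_agree_perfectly(self):
        records = [make_record(f"p{i}", 10.0, 15.0 + i) for i in range(10)]
        pairs = simulate_observers(records, noise_sd=0.0, same_threshold=1.0, seed=0)
        assert all(p.obs1 == p.obs2 == "delayed_better" for p in pairs)
        assert cohen_kappa(ratings_contingency(pairs) + np.diag([1, 1, 0])).kappa == 1.0

    def test_zero_change_reads_same(self):
        records = [make_record("p", 12.0, 12.0)]
        pairs = simulate_observers(records, noise_sd=0.0, same_threshold=1.0, seed=0)
        assert pairs[0].obs1 == pairs[0].obs2 == "same"

    def test_agreement_decays_with_perception_noise(self):
        rng = np.random.default_rng(5)
        records = [make_record(f"p{i}", 10 + rng.normal(0, 3), 13 + rng.normal(0, 3))
                   for i in range(52)]
        kappas = []
        for sd in (0.5, 1.5, 4.0, 8.0):
            vals = []
            for rep in range(40):
                pairs = simulate_observers(records, sd, 1.0, seed=100 * rep + int(sd * 10))
                table = ratings_contingency(pairs)
                try:
                    vals.append(cohen_kappa(table).kappa)
                except ZeroDivisionError:
                    vals.append(1.0)
            kappas.append(np.mean(vals))
        assert 0 < kappas[-1] < 1 or kappas[0] > kappas[-1]
        assert np.all(np.diff(kappas) < 0)

    def test_deterministic_given_seed(self):
        records = [make_record(f"p{i}", 10, 12) for i in range(10)]
        a = simulate_observers(records, 1.5, 1.0, seed=9)
        b = simulate_observers(records, 1.5, 1.0, seed=9)
        assert a == b


def test_ai_records_from_suvmeans_roundtrip():
    df = pd.DataFrame(
        dict(
            patient_id=["a", "b"],
            suv_ez_early=[5.21, 5.0], suv_contra_early=[5.94, 5.5],
            suv_ez_delayed=[5.61, 5.2], suv_contra_delayed=[6.58, 6.0],
            mri_status=["positive", "negative"],
        )
    )
    records = ai_records_from_suvmeans(df)
    assert records[0].ai1 == pytest.approx(asymmetry_index(5.21, 5.94))
    assert records[0].dai == pytest.approx(records[0].ai2 - records[0].ai1)
    with pytest.raises(ValueError, match="missing columns"):
        ai_records_from_suvmeans(df.drop(columns=["mri_status"]))
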