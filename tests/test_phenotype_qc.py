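"""Depression classifier, family-history derivation, HWE test and QC cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalmr.phenotype import (
    QuestionnaireAnswers,
    classify_depression,
    classify_depression_frame,
    derive_family_history,
)
from causalmr.qc import QCThresholds, hwe_test, qc_filter


class TestClassifyDepression:
    @pytest.mark.parametrize("kwargs, expected", [
        # GP but no psychiatrist, all core criteria met -> moderate
        (dict(ever_depressed_week=True, longest_weeks=3, n_periods=2,
              seen_gp=True, seen_psychiatrist=False), "moderate"),
        # anhedonia route with psychiatrist -> severe (GP not required)
        (dict(ever_depressed_week=False, ever_anhedonia_week=True, longest_weeks=2,
              n_periods=5, seen_gp=False, seen_psychiatrist=True), "severe"),
        # longest episode only one week: core fails despite everything else
        (dict(ever_depressed_week=True, ever_anhedonia_week=True, longest_weeks=1,
              n_periods=9, seen_gp=True, seen_psychiatrist=True), "none"),
        # single episode fails the recurrence criterion
        (dict(ever_depressed_week=True, longest_weeks=10, n_periods=1,
              seen_gp=True, seen_psychiatrist=True), "none"),
        # core met but no professional consulted
        (dict(ever_depressed_week=True, longest_weeks=4, n_periods=3,
              seen_gp=False, seen_psychiatrist=False), "none"),
        # everything missing -> conservative control
        (dict(), "none"),
    ])
    def test_classification_paths(self, kwargs, expected):
        assert classify_depression(QuestionnaireAnswers(**kwargs)) == expected

    def test_severe_takes_precedence_over_moderate(self):
        a = QuestionnaireAnswers(ever_depressed_week=True, longest_weeks=3, n_periods=3,
                                 seen_gp=True, seen_psychiatrist=True)
        assert classify_depression(a) == "severe"

    @settings(max_examples=200, deadline=None)
    @given(
        dep=st.sampled_from([True, False, None]),
        anh=st.sampled_from([True, False, None]),
        weeks=st.one_of(st.none(), st.integers(0, 60)),
        periods=st.one_of(st.none(), st.integers(0, 20)),
        gp=st.sampled_from([True, False, None]),
        psych=st.sampled_from([True, False, None]),
    )
    def test_core_criteria_gate_both_levels(self, dep, anh, weeks, periods, gp, psych):
        """No classification as a case without every core criterion; levels disjoint."""
        a = QuestionnaireAnswers(ever_depressed_week=dep, ever_anhedonia_week=anh,
                                 longest_weeks=weeks, n_periods=periods,
                                 seen_gp=gp, seen_psychiatrist=psych)
        status = classify_depression(a)
        core = (dep is True or anh is True) and (weeks or 0) >= 2 and (periods or 0) >= 2
        if not core:
            assert status == "none"
        if status == "severe":
            assert psych is True
        if status == "moderate":
            assert gp is True and psych is not True

    def test_frame_classifier_agrees_with_scalar(self):
        df = pd.DataFrame({
            "ever_depressed_week": ["yes", "no", "yes", "NA"],
            "ever_anhedonia_week": ["no", "yes", "no", "NA"],
            "longest_weeks": [3, 2, 1, np.nan],
            "n_periods": [2, 5, 9, np.nan],
            "seen_gp": ["yes", "no", "yes", "NA"],
            "seen_psychiatrist": ["no", "yes", "yes", "NA"],
        })
        assert list(classify_depression_frame(df)) == ["moderate", "severe", "none", "none"]


class TestFamilyHistory:
    @pytest.mark.parametrize("father, mother, expected", [
        ({"heart disease"}, set(), True),
        (set(), set(), False),
        ({"diabetes"}, {"heart disease"}, True),
        ({"stroke"}, {"diabetes"}, False),
    ])
    def test_either_parent_counts(self, father, mother, expected):
        a = QuestionnaireAnswers(father_conditions=father, mother_conditions=mother)
        assert derive_family_history(a) is expected


class TestHWE:
    def test_exact_proportions_give_p_one(self):
        # p(A)=0.9 -> expected 810/180/10 at n=1000: chi-square 0
        assert hwe_test(810, 180, 10) == pytest.approx(1.0)

    def test_extreme_het_deficit(self):
        # expected 25/50/25; chi2 = 25 + 50 + 25 = 100
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(1.52e-23, rel=0.01)
        assert p < 1e-12

    def test_monomorphic_returns_one(self):
        assert hwe_test(0, 0, 10) == 1.0
        assert hwe_test(10, 0, 0) == 1.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
           .filter(lambda t: sum(t) > 0))
    def test_exchangeable_under_homozygote_relabeling(self, counts):
        a, b, c = counts
        assert hwe_test(a, b, c) == pytest.approx(hwe_test(c, b, a), rel=1e-9)


def _clean_genotypes(n=60, m=4, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    ids = [f"id{i:03d}" for i in range(n)]
    return pd.DataFrame(g, index=ids, columns=[f"rs{j}" for j in range(m)])


class TestQCFilter:
    def test_clean_matrix_retains_everything(self):
        G = _clean_genotypes()
        res = qc_filter(G)
        assert res.retained_variants == list(G.columns)
        assert res.retained_individuals == list(G.index)
        assert res.log.empty

    def test_kinship_chain_keeps_single_lexicographic_survivor(self):
        G = _clean_genotypes()
        a, b, c = G.index[0], G.index[1], G.index[2]
        res = qc_filter(G, kinship_pairs=[(a, b), (b, c)])
        kept = {a, b, c} & set(res.retained_individuals)
        assert kept == {min(a, b, c)}
        assert (res.log["rule"] == "relatedness").sum() == 2

    def test_hwe_threshold_is_maf_stratified(self):
        # common variant (MAF 0.30) with HWE p ~ 6.7e-7 -> dropped at 1e-6;
        # rare variant (MAF ~ 0.0055) with p ~ 2.1e-8 -> retained at 1e-12.
        def expand(counts):
            n_aa, n_ab, n_bb = counts
            return np.array([0.0] * n_aa + [1.0] * n_ab + [2.0] * n_bb)

        common = expand((523, 354, 123))
        rare = expand((990, 9, 1))
        rng = np.random.default_rng(1)
        clean = rng.binomial(2, 0.4, 1000).astype(float)
        G = pd.DataFrame({"rs_clean": clean, "rs_common": common, "rs_rare": rare},
                         index=[f"id{i:04d}" for i in range(1000)])
        res = qc_filter(G)
        assert "rs_common" not in res.retained_variants
        assert "rs_rare" in res.retained_variants
        row = res.log[res.log["id"] == "rs_common"].iloc[0]
        assert row["rule"] == "hwe_failure"

    def test_sex_mismatch_dropped(self):
        G = _clean_genotypes(n=20)
        sex = pd.DataFrame({"reported_sex": ["male"] * 20, "genetic_sex": ["male"] * 20},
                           index=G.index)
        sex.iloc[3, 0] = "female"
        res = qc_filter(G, sex=sex)
        assert G.index[3] not in res.retained_individuals
        assert (res.log["rule"] == "sex_mismatch").sum() == 1

    def test_low_call_rate_variant_dropped(self):
        G = _clean_genotypes(n=200, m=30)
        G.iloc[:150, 0] = np.nan  # 25% call rate vs ~100% elsewhere
        res = qc_filter(G)
        assert G.columns[0] not in res.retained_variants
        assert (res.log.query("entity == 'variant'")["rule"] == "low_call_rate").any()

    def test_output_invariant_to_input_order(self):
        G = _clean_genotypes(n=80, m=5, seed=3)
        G.iloc[:40, 1] = np.nan
        res1 = qc_filter(G)
        shuffled = G.sample(frac=1, random_state=7)[list(G.columns[::-1])]
        res2 = qc_filter(shuffled)
        assert set(res1.retained_variants) == set(res2.retained_variants)
        assert set(res1.retained_individuals) == set(res2.retained_individuals)

    def test_empty_matrix_is_hard_error(self):
        with pytest.raises(ValueError):
            qc_filter(pd.DataFrame())
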