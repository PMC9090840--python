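"""Normalization and male-bias cascade tests.

Size factors carry frozen closed-form expectations (geometric-mean algebra);
the cascade is traced by hand on constructed genes and checked for its
counting/monotonicity invariants on random matrices.  The median-of-ratios
estimator is additionally cross-checked against pydeseq2 on a random matrix.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germscan.expression import (
    ClassifierParams,
    classify_male_biased,
    embryo_classify,
    group_summary,
    log2_mf,
    normalize_counts,
    size_factors,
)

GONAD_SHEET = pd.Series(
    {
        "PM_1": "PM", "PM_2": "PM",
        "MM_1": "MM", "MM_2": "MM",
        "EF_1": "EF", "EF_2": "EF",
        "MF_1": "MF",
        "UD_1": "UD",
    },
    name="group",
)


def _counts(rows: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=samples).T


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20], "s2": [10, 20]}, index=["g1", "g2"])
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_column_closed_form(self):
        # column 2 = 2 x column 1 -> factors (1/sqrt(2), sqrt(2))
        counts = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]}, index=["g1", "g2"])
        np.testing.assert_allclose(
            size_factors(counts), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12
        )

    def test_three_sample_scaling_exact(self):
        # counts mu_i * c_j with c = (1,2,4) -> factors (0.5, 1, 2)
        mu = np.array([5.0, 11.0, 23.0, 47.0])
        counts = pd.DataFrame(
            {"s1": mu * 1, "s2": mu * 2, "s3": mu * 4},
            index=[f"g{i}" for i in range(4)],
        )
        np.testing.assert_allclose(size_factors(counts), [0.5, 1.0, 2.0], rtol=1e-12)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="positive"):
            size_factors(counts)

    @settings(max_examples=20, deadline=None)
    @given(
        lam=st.floats(0.25, 4.0),
        col=st.integers(0, 2),
        seed=st.integers(0, 10_000),
    )
    def test_scale_invariance_up_to_global_factor(self, lam, col, seed):
        """Scaling one sample by lambda changes the normalized matrix only by
        one global constant (lambda^(1/m), from that sample's contribution to
        every gene's geometric mean): all between-sample structure is
        preserved and the scaled sample's factor absorbs the rest of lambda."""
        gen = np.random.default_rng(seed)
        m = 3
        counts = pd.DataFrame(
            gen.integers(1, 200, size=(30, m)).astype(float),
            index=[f"g{i}" for i in range(30)],
            columns=["a", "b", "c"],
        )
        scaled = counts.copy()
        scaled.iloc[:, col] *= lam
        ratio = normalize_counts(scaled).to_numpy() / normalize_counts(counts).to_numpy()
        np.testing.assert_allclose(ratio, lam ** (1 / m), rtol=1e-9)
        sf, sf0 = size_factors(scaled), size_factors(counts)
        assert sf.iloc[col] / sf0.iloc[col] == pytest.approx(lam ** (1 - 1 / m))

    def test_matches_pydeseq2_reference(self):
        """Independent cross-check of the median-of-ratios estimator."""
        pytest.importorskip("pydeseq2")
        from pydeseq2.preprocessing import deseq2_norm

        gen = np.random.default_rng(7)
        counts = pd.DataFrame(
            gen.negative_binomial(5, 0.05, size=(80, 6)),
            index=[f"g{i}" for i in range(80)],
            columns=[f"s{i}" for i in range(6)],
        )
        _, ref_sf = deseq2_norm(counts.T)  # pydeseq2 uses samples x genes
        np.testing.assert_allclose(size_factors(counts), np.asarray(ref_sf), rtol=1e-8)


class TestGroupSummary:
    def test_median_and_low_flag_boundaries(self):
        counts = _counts(
            {"g1": [10, 20, 30, 4.9, 4.9, 5.0, 5.0, 0]},
            list(GONAD_SHEET.index),
        )
        out = group_summary(counts, GONAD_SHEET)
        assert out.loc["g1", "median_PM"] == 15.0  # midpoint convention
        assert out.loc["g1", "median_EF"] == pytest.approx(4.95)
        assert bool(out.loc["g1", "low_EF"]) is True
        assert bool(out.loc["g1", "low_MF"]) is False  # median exactly 5.0
        assert bool(out.loc["g1", "low_UD"]) is True  # all-zero

    def test_pooled_groups(self):
        counts = _counts({"g1": [1, 3, 5, 7, 0, 0, 0, 0]}, list(GONAD_SHEET.index))
        out = group_summary(counts, GONAD_SHEET, pooled={"male": ("PM", "MM")})
        assert out.loc["g1", "median_male"] == 4.0

    def test_empty_group_errors(self):
        counts = _counts({"g1": [1, 2]}, ["PM_1", "PM_2"])
        sheet = pd.Series({"PM_1": "PM", "PM_2": "PM"})
        with pytest.raises(ValueError, match="pooled group"):
            group_summary(counts, sheet, pooled={"x": ("LM",)})


class TestLog2MF:
    def test_equal_means_zero(self):
        counts = _counts({"g1": [8, 8, 8, 8, 8, 8, 8, 0]}, list(GONAD_SHEET.index))
        assert log2_mf(counts, GONAD_SHEET).loc["g1"] == pytest.approx(0.0)

    def test_silent_in_females_closed_form(self):
        # male mean 15, female mean 0, c1=1 -> log2(16) = 4
        counts = _counts({"g1": [15, 15, 15, 15, 0, 0, 0, 0]}, list(GONAD_SHEET.index))
        assert log2_mf(counts, GONAD_SHEET, c1=1.0).loc["g1"] == pytest.approx(4.0)

    def test_all_zero_degenerate(self):
        counts = _counts({"g1": [0] * 8}, list(GONAD_SHEET.index))
        assert log2_mf(counts, GONAD_SHEET).loc["g1"] == pytest.approx(0.0)


class TestCascade:
    def test_hand_traced_example(self):
        """One gene high in males (candidate, passes, sole -> strong), one
        filtered by male total, one below the logFC threshold."""
        sheet = pd.Series(
            {"PM_1": "PM", "PM_2": "PM", "EF_1": "EF", "EF_2": "EF"}, name="group"
        )
        norm = pd.DataFrame(
            {
                "PM_1": [1000.0, 400.0, 20.0],
                "PM_2": [1200.0, 100.0, 20.0],
                "EF_1": [10.0, 30.0, 10.0],
                "EF_2": [10.0, 32.0, 10.0],
            },
            index=["gA", "gB", "gC"],
        )
        params = ClassifierParams(male_groups=("PM",), female_groups=("EF",))
        res = classify_male_biased(norm, sheet, params)
        # gA: A = log2(1101/11) ~ 6.65 > 2; male total 2200 > 1000
        assert res.loc["gA", "logfc_a"] == pytest.approx(np.log2(1101 / 11))
        assert bool(res.loc["gA", "strong"]) is True
        # gB: logFC ~ 3 but male total 500 -> candidate, filtered out
        assert bool(res.loc["gB", "candidate"]) is True
        assert bool(res.loc["gB", "passes_filter"]) is False
        assert bool(res.loc["gB", "strong"]) is False
        # gC: logFC ~ 0.9 -> not a candidate
        assert bool(res.loc["gC", "candidate"]) is False
        assert res["strong"].sum() == 1  # ceil(0.2 * 1)

    def test_shrunken_estimator_can_rescue_candidates(self):
        """A high-count gene slightly under L on the light estimator can pass
        on the shrunken one only when shrinkage moves it less."""
        sheet = pd.Series({"PM_1": "PM", "EF_1": "EF"}, name="group")
        norm = pd.DataFrame({"PM_1": [3.9], "EF_1": [0.0]}, index=["g"])
        params = ClassifierParams(male_groups=("PM",), female_groups=("EF",), L=2.0)
        res = classify_male_biased(norm, sheet, params)
        # A = log2(4.9/1) ~ 2.29 > 2; B = log2(11.9/8) ~ 0.57
        assert bool(res.loc["g", "candidate"]) is True

    def test_strong_count_is_ceiling_rule(self):
        gen = np.random.default_rng(0)
        sheet = pd.Series(
            {"PM_1": "PM", "PM_2": "PM", "EF_1": "EF", "EF_2": "EF"}, name="group"
        )
        n = 37
        norm = pd.DataFrame(
            {
                "PM_1": gen.uniform(900, 1100, n),
                "PM_2": gen.uniform(900, 1100, n),
                "EF_1": gen.uniform(0, 5, n),
                "EF_2": gen.uniform(0, 5, n),
            },
            index=[f"g{i:03d}" for i in range(n)],
        )
        params = ClassifierParams(male_groups=("PM",), female_groups=("EF",))
        res = classify_male_biased(norm, sheet, params)
        n_pass = int(res["passes_filter"].sum())
        assert res["strong"].sum() == math.ceil(0.2 * n_pass)

    @settings(max_examples=15, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        bump_t=st.floats(0, 4000),
        bump_l=st.floats(0, 3),
    )
    def test_monotone_in_thresholds(self, seed, bump_t, bump_l):
        """Raising T or L never enlarges the strong set."""
        gen = np.random.default_rng(seed)
        sheet = pd.Series(
            {"PM_1": "PM", "PM_2": "PM", "EF_1": "EF", "EF_2": "EF"}, name="group"
        )
        norm = pd.DataFrame(
            gen.uniform(0, 2000, size=(40, 4)),
            index=[f"g{i:03d}" for i in range(40)],
            columns=sheet.index,
        )
        base = ClassifierParams(male_groups=("PM",), female_groups=("EF",))
        stricter = ClassifierParams(
            L=base.L + bump_l, T=base.T + bump_t,
            male_groups=("PM",), female_groups=("EF",),
        )
        s_base = classify_male_biased(norm, sheet, base)["strong"]
        s_strict = classify_male_biased(norm, sheet, stricter)["strong"]
        assert s_strict.sum() <= s_base.sum()

    def test_empty_strong_set_not_error(self):
        sheet = pd.Series({"PM_1": "PM", "EF_1": "EF"}, name="group")
        norm = pd.DataFrame({"PM_1": [5.0], "EF_1": [5.0]}, index=["g"])
        params = ClassifierParams(male_groups=("PM",), female_groups=("EF",))
        res = classify_male_biased(norm, sheet, params)
        assert res["strong"].sum() == 0


class TestEmbryo:
    SHEET = pd.Series(
        {"pre_1": "pre_pgr", "pre_2": "pre_pgr", "pre_3": "pre_pgr",
         "post_1": "post_pgr", "post_2": "post_pgr", "post_3": "post_pgr"},
        name="group",
    )

    def test_high_flag(self):
        counts = pd.DataFrame(
            {"pre_1": [60], "pre_2": [55], "pre_3": [70],
             "post_1": [0], "post_2": [1], "post_3": [2]},
            index=["g"],
        )
        res = embryo_classify(counts, self.SHEET)
        assert bool(res.loc["g", "high_pre"]) is True
        assert bool(res.loc["g", "expressed_post"]) is True  # mean 1.0 >= 1
        assert bool(res.loc["g", "high_post"]) is False

    def test_all_zero_not_expressed(self):
        counts = pd.DataFrame(
            np.zeros((1, 6)), index=["g"], columns=self.SHEET.index
        )
        res = embryo_classify(counts, self.SHEET)
        assert not res.loc["g", ["expressed_pre", "expressed_post"]].any()

    def test_mean_point_nine_not_expressed(self):
        counts = pd.DataFrame(
            {"pre_1": [0.9], "pre_2": [0.9], "pre_3": [0.9],
             "post_1": [0], "post_2": [0], "post_3": [0]},
            index=["g"],
        )
        res = embryo_classify(counts, self.SHEET)
        assert bool(res.loc["g", "expressed_pre"]) is False

    def test_high_implies_expressed_property(self, small_bundle):
        res = embryo_classify(small_bundle.embryo_counts, small_bundle.embryo_sheet)
        assert (res["high_pre"] <= res["expressed_pre"]).all()
        assert (res["high_post"] <= res["expressed_post"]).all()
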