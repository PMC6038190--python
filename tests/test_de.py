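import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirsig.de import (
    DECall,
    DesignSpec,
    bh_adjust,
    build_design_matrix,
    call_deregulated,
    estimate_dispersions,
    log_transform,
    nb_wald,
    size_factors,
    top_abundant_de,
    top_de,
    top_variable,
)


def nb_counts(rng, mean, alpha, size):
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


def two_group_sheet(n=8, extra=None):
    ids = [f"C{i}" for i in range(n)] + [f"P{i}" for i in range(n)]
    sheet = pd.DataFrame(
        {"group": ["CTRL"] * n + ["PD"] * n,
         "sex": (["F", "M"] * n)[: 2 * n]},
        index=ids,
    )
    if extra is not None:
        for k, v in extra.items():
            sheet[k] = v
    return sheet


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        df = pd.DataFrame([[10, 20], [30, 60]], columns=["s1", "s2"])
        sf = size_factors(df)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(50, size=30) + 1
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(size_factors(df), 1.0)

    def test_column_scaling_equivariance_of_factor_ratios(self, rng):
        # median-of-ratios factors are defined up to the geometric-mean
        # reference, so scaling column b by 3 scales sf_b *relative to the
        # others* by exactly 3 (all factors also absorb a common 3^(1/n))
        df = pd.DataFrame(rng.poisson(40, size=(50, 4)) + 1,
                          columns=list("abcd"))
        sf = size_factors(df)
        df3 = df.copy()
        df3["b"] = df3["b"] * 3
        sf3 = size_factors(df3)
        assert sf3["b"] / sf3["a"] == pytest.approx(3 * sf["b"] / sf["a"])
        assert sf3["c"] / sf3["a"] == pytest.approx(sf["c"] / sf["a"])

    def test_requires_a_feature_expressed_everywhere(self):
        df = pd.DataFrame([[0, 5], [3, 0]], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            size_factors(df)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.001, 0.5, 1.0], [0.003, 0.75, 1.0]),
            ([0.5], [0.5]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_nan_passthrough_and_range_check(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_pointwise_dominance_and_rank_preservation(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # step-up adjustment is monotone in the ranks of the raw p-values
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDispersions:
    def test_poisson_data_gets_near_zero_dispersion(self, rng):
        y = pd.DataFrame(rng.poisson(100, size=(300, 16)))
        y.columns = [f"s{i}" for i in range(16)]
        sf = pd.Series(1.0, index=y.columns)
        alpha = estimate_dispersions(y, sf)
        assert alpha.median() <= 0.01

    def test_nb_dispersion_recovered_to_right_order(self, rng):
        y = pd.DataFrame(nb_counts(rng, 100.0, 0.2, (300, 16)))
        y.columns = [f"s{i}" for i in range(16)]
        sf = pd.Series(1.0, index=y.columns)
        alpha = estimate_dispersions(y, sf)
        assert 0.1 <= alpha.median() <= 0.4

    def test_single_feature_skips_trend(self, rng):
        y = pd.DataFrame(nb_counts(rng, 80.0, 0.3, (1, 12)))
        y.columns = [f"s{i}" for i in range(12)]
        alpha = estimate_dispersions(y, pd.Series(1.0, index=y.columns))
        assert len(alpha) == 1 and alpha.iloc[0] >= 1e-8


class TestDesignMatrix:
    def test_contrast_and_dummy_coding(self):
        sheet = two_group_sheet(3)
        X, ccol = build_design_matrix(sheet, DesignSpec("group", ("sex",)))
        assert ccol == "group[PD]"
        assert X["group[PD]"].tolist() == [0, 0, 0, 1, 1, 1]
        assert "sex[M]" in X.columns  # F is first in sheet order -> reference

    def test_three_level_contrast_rejected(self):
        sheet = two_group_sheet(4)
        sheet.loc[sheet.index[0], "group"] = "ESC"
        with pytest.raises(ValueError, match="2 observed levels"):
            build_design_matrix(sheet, DesignSpec("group"))

    def test_single_sample_level_rejected(self):
        sheet = pd.DataFrame({"group": ["CTRL", "CTRL", "PD"]},
                             index=["a", "b", "c"])
        with pytest.raises(ValueError, match="at least 2"):
            build_design_matrix(sheet, DesignSpec("group"))

    def test_rank_deficient_design_rejected(self):
        sheet = two_group_sheet(3)
        sheet["copy"] = sheet["group"]  # perfectly confounded covariate
        with pytest.raises(ValueError, match="rank"):
            build_design_matrix(sheet, DesignSpec("group", ("copy",)))


class TestNBWald:
    def test_label_swap_flips_log2fc_and_keeps_p(self, rng):
        sheet = two_group_sheet(5)
        mu = np.where(sheet["group"] == "PD", 200.0, 100.0)
        y = pd.DataFrame(nb_counts(rng, mu, 0.1, (80, 10)), columns=sheet.index)
        res_a = nb_wald(y, sheet, DesignSpec("group", reference_level="CTRL"))
        res_b = nb_wald(y, sheet, DesignSpec("group", reference_level="PD"))
        ok = res_a["tested"] & res_b["tested"]
        assert np.allclose(res_a.loc[ok, "log2fc"], -res_b.loc[ok, "log2fc"], atol=1e-5)
        assert np.allclose(res_a.loc[ok, "p"], res_b.loc[ok, "p"], atol=1e-6)

    def test_all_zero_feature_flagged_untested(self, rng):
        sheet = two_group_sheet(4)
        y = pd.DataFrame(rng.poisson(50, size=(30, 8)), columns=sheet.index)
        y.iloc[7] = 0
        res = nb_wald(y, sheet, DesignSpec("group"))
        row = res.iloc[7]
        assert not row["tested"] and np.isnan(row["p"]) and np.isnan(row["padj"])
        assert row["base_mean"] == 0.0

    def test_null_data_centered_and_calibrated(self, rng):
        sheet = two_group_sheet(8)
        y = pd.DataFrame(nb_counts(rng, 100.0, 0.1, (600, 16)), columns=sheet.index)
        res = nb_wald(y, sheet, DesignSpec("group"))
        t = res[res["tested"]]
        assert abs(t["log2fc"].median()) < 0.1
        frac = (t["p"] < 0.05).mean()
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(t))

    def test_planted_effect_recovered(self, rng):
        # balanced up/down plant so median-of-ratios normalization stays centered
        sheet = two_group_sheet(8)
        n_feat, n_up, n_down = 1000, 50, 50
        lfc = np.zeros(n_feat)
        lfc[:n_up] = 1.5
        lfc[n_up:n_up + n_down] = -1.5
        mu = 100.0 * 2.0 ** (lfc[:, None] * (sheet["group"] == "PD").to_numpy()[None, :])
        y = pd.DataFrame(nb_counts(rng, mu, 0.1, (n_feat, 16)), columns=sheet.index)
        res = nb_wald(y, sheet, DesignSpec("group"))
        assert res.iloc[:n_up]["log2fc"].mean() == pytest.approx(1.5, abs=0.15)
        assert res.iloc[n_up:n_up + n_down]["log2fc"].mean() == pytest.approx(
            -1.5, abs=0.15
        )


class TestCallRule:
    @pytest.fixture
    def res_frame(self):
        return pd.DataFrame(
            {
                "log2fc": [0.59, -0.7, 1.2, 0.6, -0.6],
                "padj": [0.01, 0.09, 0.10, 0.099, 0.0999],
                "base_mean": 1.0,
                "p": 0.01,
                "tested": True,
            },
            index=list("abcde"),
        )

    def test_threshold_semantics(self, res_frame):
        call = call_deregulated(res_frame)
        assert "a" not in call.all_ids  # |lfc| 0.59 below inclusive 0.6
        assert "b" in call.down  # -0.7 at padj 0.09
        assert "c" not in call.all_ids  # padj 0.10 fails the strict < 0.1
        assert "d" in call.up and "e" in call.down  # boundaries inclusive on lfc

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValueError):
            DECall(up=frozenset("a"), down=frozenset("a"))


class TestTransformsAndRankings:
    def test_log_transform_values(self):
        df = pd.DataFrame({"s": [0, 15]}, index=["a", "b"])
        sf = pd.Series({"s": 1.0})
        out = log_transform(df, sf)
        assert out.loc["a", "s"] == 0.0 and out.loc["b", "s"] == 4.0

    def test_log_transform_halves_with_doubled_size_factor(self):
        df = pd.DataFrame({"s": [32]}, index=["a"])
        v1 = log_transform(df, pd.Series({"s": 1.0})).iloc[0, 0]
        v2 = log_transform(df, pd.Series({"s": 2.0})).iloc[0, 0]
        assert v1 == np.log2(33) and v2 == np.log2(17)

    def test_top_variable_ordering_and_ties(self, rng):
        m = pd.DataFrame(np.ones((4, 6)), index=["w", "z", "a", "b"])
        m.loc["z"] = np.arange(6)
        assert top_variable(m, 1) == ["z"]
        assert top_variable(m, 10) == ["z", "a", "b", "w"]  # ties by id

    def test_top_de_sorting(self):
        res = pd.DataFrame(
            {
                "padj": [0.5, 0.01, 0.01, np.nan],
                "p": [0.2, 0.004, 0.001, np.nan],
                "tested": [True, True, True, False],
            },
            index=["a", "b", "c", "d"],
        )
        assert top_de(res, 2) == ["c", "b"]
        assert top_de(res, 10) == ["c", "b", "a"]  # untested excluded

    def test_top_abundant_de_and_count_share(self):
        res = pd.DataFrame(
            {"base_mean": [10.0, 5.0, 1.0, 100.0]}, index=["a", "b", "c", "d"]
        )
        call = DECall(up=frozenset(["a", "b"]), down=frozenset(["c"]))
        norm = pd.DataFrame(
            {"s1": [20.0, 0.0, 0.0, 80.0], "s2": [10.0, 5.0, 0.0, 85.0]},
            index=["a", "b", "c", "d"],
        )
        ids, share = top_abundant_de(res, call, N=2, normalized=norm)
        assert ids == ["a", "b"]  # d is not called despite largest base mean
        assert share["s1"] == pytest.approx(0.20)
        assert share["s2"] == pytest.approx(0.15)

    def test_top_abundant_de_empty_call(self):
        res = pd.DataFrame({"base_mean": [1.0]}, index=["a"])
        ids, share = top_abundant_de(
            res, DECall(frozenset(), frozenset()), N=5,
            normalized=pd.DataFrame({"s": [4.0]}, index=["a"]),
        )
        assert ids == [] and (share == 0).all()
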