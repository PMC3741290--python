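"""Unit and property tests for the methylation inference chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methlink.methylation import (
    DataError,
    EBayesPrior,
    InferenceError,
    MaValues,
    TwoColorArray,
    bh_adjust,
    call_unmethylated,
    compute_ma,
    estimate_ebayes_prior,
    filter_dmrs,
    fit_probe_models,
    moderate_statistics,
    normalize_within_control_loess,
    qc_exclude_low_iqr,
    quantile_normalize,
)


def _array(aid, group, treated, untreated, ctrl=None, probes=None):
    n = len(treated)
    return TwoColorArray(
        array_id=aid,
        group=group,
        probe_ids=np.array(probes if probes is not None else [f"p{i}" for i in range(n)]),
        treated=np.asarray(treated, dtype=float),
        untreated=np.asarray(untreated, dtype=float),
        is_control=np.asarray(ctrl if ctrl is not None else [False] * n),
    )


def _ma(M: pd.DataFrame, groups=None, controls=None) -> MaValues:
    groups = groups or {c: "normal" for c in M.columns}
    ctrl = pd.Series(
        controls if controls is not None else [False] * len(M), index=M.index
    )
    return MaValues(M=M, A=M * 0 + 10.0, groups=pd.Series(groups), is_control=ctrl)


class TestComputeMa:
    @pytest.mark.parametrize(
        "untreated,treated,m,a",
        [(1024, 1024, 0.0, 10.0), (4, 1, 2.0, 1.0), (1, 4, -2.0, 1.0)],
    )
    def test_hand_arithmetic(self, untreated, treated, m, a):
        ma = compute_ma([_array("a1", "normal", [treated], [untreated])])
        assert ma.M.iloc[0, 0] == pytest.approx(m)
        assert ma.A.iloc[0, 0] == pytest.approx(a)

    def test_flooring_keeps_values_finite(self):
        ma = compute_ma([_array("a1", "normal", [0.2], [512.0])])
        assert np.isfinite(ma.M.iloc[0, 0])
        assert ma.M.iloc[0, 0] == pytest.approx(9.0)  # log2(512) - log2(1)

    def test_mismatched_probe_lists_rejected(self):
        a1 = _array("a1", "normal", [1, 2], [1, 2], probes=["x", "y"])
        a2 = _array("a2", "normal", [1, 2], [1, 2], probes=["x", "z"])
        with pytest.raises(DataError, match="probe list"):
            compute_ma([a1, a2])


class TestQcLowIqr:
    def test_identical_distributions_keep_everything(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame({f"a{i}": rng.normal(0, 1, 200) for i in range(6)})
        kept, report = qc_exclude_low_iqr(_ma(M))
        assert not report.table["excluded"].any()
        assert kept.M.shape[1] == 6

    def test_degenerate_zero_iqr_array_excluded(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame({f"a{i}": rng.normal(0, 1, 200) for i in range(5)})
        M["dead"] = 0.0
        kept, report = qc_exclude_low_iqr(_ma(M), min_iqr_ratio=1e-6)
        assert "dead" not in kept.M.columns
        row = report.table.set_index("array_id").loc["dead"]
        assert row["excluded"] and row["iqr"] == 0.0

    def test_needs_three_arrays(self):
        M = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        with pytest.raises(InferenceError):
            qc_exclude_low_iqr(_ma(M))


class TestControlLoess:
    def _ma_with_trend(self, slope, n=400, n_ctrl=120):
        rng = np.random.default_rng(2)
        A = rng.uniform(6, 14, n)
        ctrl = np.zeros(n, dtype=bool)
        ctrl[:n_ctrl] = True
        M = slope * A
        M[~ctrl] += rng.normal(1.0, 0.01, n - n_ctrl)  # signal on non-controls
        df = pd.DataFrame({"a1": M})
        ma = MaValues(
            M=df,
            A=pd.DataFrame({"a1": A}),
            groups=pd.Series({"a1": "normal"}),
            is_control=pd.Series(ctrl),
        )
        return ma

    def test_controls_on_zero_line_is_identity(self):
        ma = self._ma_with_trend(0.0)
        out = normalize_within_control_loess(ma, min_controls=50)
        ctrl = ma.is_control.values
        np.testing.assert_allclose(out.M.values[ctrl], 0.0, atol=1e-9)
        np.testing.assert_allclose(out.M.values, ma.M.values - 0.0, atol=1e-6)

    def test_constant_control_offset_subtracted(self):
        rng = np.random.default_rng(3)
        n = 300
        A = rng.uniform(6, 14, n)
        ctrl = np.zeros(n, dtype=bool)
        ctrl[:100] = True
        M = np.full(n, 0.7)
        ma = MaValues(
            M=pd.DataFrame({"a1": M}),
            A=pd.DataFrame({"a1": A}),
            groups=pd.Series({"a1": "normal"}),
            is_control=pd.Series(ctrl),
        )
        out = normalize_within_control_loess(ma, min_controls=50)
        np.testing.assert_allclose(out.M["a1"].values, M - 0.7, atol=1e-9)

    def test_linear_trend_removed_at_interior_a(self):
        # controls lie on M = 0.1*A: a probe at A=10, M=2 maps to ~1
        rng = np.random.default_rng(4)
        n_ctrl = 200
        A_ctrl = rng.uniform(6, 14, n_ctrl)
        A = np.concatenate([A_ctrl, [10.0]])
        M = np.concatenate([0.1 * A_ctrl, [2.0]])
        ctrl = np.array([True] * n_ctrl + [False])
        ma = MaValues(
            M=pd.DataFrame({"a1": M}),
            A=pd.DataFrame({"a1": A}),
            groups=pd.Series({"a1": "normal"}),
            is_control=pd.Series(ctrl),
        )
        out = normalize_within_control_loess(ma, min_controls=50)
        assert out.M["a1"].iloc[-1] == pytest.approx(1.0, abs=0.05)

    def test_too_few_controls_suggests_fallback(self):
        ma = self._ma_with_trend(0.0, n_ctrl=10)
        with pytest.raises(DataError, match="fallback_global"):
            normalize_within_control_loess(ma, min_controls=50)


class TestQuantileNormalize:
    def test_hand_example(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(X)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        X = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        np.testing.assert_allclose(quantile_normalize(X).values, X.values)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.floats(-100, 100, allow_nan=False), min_size=5, max_size=5,
                unique=True,
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_columns_share_sorted_values_and_ranks_preserved(self, cols):
        X = np.array(cols, dtype=float).T
        out = quantile_normalize(X)
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)
            # rank preservation: sorting the input column sorts the output column
            order = np.argsort(X[:, j], kind="stable")
            assert (np.diff(out[order, j]) >= -1e-12).all()

    def test_ties_receive_mean_of_spanned_reference_values(self):
        # tied 1.0s span the two smallest order statistics of the target
        X = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(X)
        target = np.sort(X.values, axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out["a"].iloc[0] == pytest.approx((target[0] + target[1]) / 2)
        assert out["a"].iloc[1] == pytest.approx((target[0] + target[1]) / 2)
        assert out["a"].iloc[2] == pytest.approx(target[2])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (50, 4))
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_rejects_missing_values(self):
        with pytest.raises(DataError):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestFitProbeModels:
    def _fit(self, normal, asthma):
        M = pd.DataFrame(
            [list(normal) + list(asthma)],
            index=["p0"],
            columns=[f"n{i}" for i in range(len(normal))]
            + [f"a{i}" for i in range(len(asthma))],
        )
        groups = pd.Series(
            ["normal"] * len(normal) + ["asthma"] * len(asthma), index=M.columns
        )
        return fit_probe_models(M, groups)

    def test_constant_probe(self):
        fit = self._fit([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
        assert fit.means.loc["p0", "normal"] == pytest.approx(0.4)
        assert fit.means.loc["p0", "asthma"] == pytest.approx(0.4)
        assert fit.sigma_sq["p0"] == pytest.approx(0.0)

    def test_noiseless_split(self):
        fit = self._fit([1, 1, 1, 1], [0, 0, 0, 0])
        assert fit.means.loc["p0", "normal"] == pytest.approx(1.0)
        assert fit.means.loc["p0", "asthma"] == pytest.approx(0.0)
        assert fit.sigma_sq["p0"] == pytest.approx(0.0)
        assert fit.residual_df == 6

    def test_hand_pooled_variance(self):
        fit = self._fit([0.9, 1.1], [0.1, -0.1])
        assert fit.means.loc["p0", "normal"] == pytest.approx(1.0)
        assert fit.means.loc["p0", "asthma"] == pytest.approx(0.0)
        assert fit.sigma_sq["p0"] == pytest.approx(0.02)
        assert fit.residual_df == 2

    def test_single_array_group_rejected(self):
        with pytest.raises(InferenceError):
            self._fit([1.0], [0.0, 0.0])


class TestModeration:
    def _toy_fit(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        M = pd.DataFrame(
            rng.normal(0, 1, (n, 8)) * rng.uniform(0.5, 2.0, n)[:, None],
            index=[f"p{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["normal"] * 4 + ["asthma"] * 4, index=M.columns)
        return fit_probe_models(M, groups)

    def test_closed_form_posterior_variance(self):
        # s^2 = 1, df = 4, prior (d0=4, s0^2=2) -> posterior variance 1.5
        d0, s0, df, s2 = 4.0, 2.0, 4.0, 1.0
        assert (d0 * s0 + df * s2) / (d0 + df) == pytest.approx(1.5)
        # and the same number flows through the implementation
        M = pd.DataFrame(
            [[0.0, 1.0, 2.0, 1.0, 2.0, 3.0]], index=["p0"],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["normal"] * 3 + ["asthma"] * 3, index=M.columns)
        fit = fit_probe_models(M, groups)
        assert fit.sigma_sq["p0"] == pytest.approx(1.0)
        res, _ = moderate_statistics(fit, prior=EBayesPrior(d0=4.0, s0_sq=2.0))
        row = res[res["contrast"] == "meth_normal"].iloc[0]
        # moderated t = estimate / (sqrt(1.5) * sqrt(1/3))
        assert row["moderated_t"] == pytest.approx(1.0 / (np.sqrt(1.5) * np.sqrt(1 / 3)))

    def test_no_shrinkage_limit_matches_ordinary_t(self):
        fit = self._toy_fit()
        res, _ = moderate_statistics(fit, prior=EBayesPrior(d0=1e-8, s0_sq=1.0))
        sub = res[res["contrast"] == "difference"]
        diff = fit.means["normal"] - fit.means["asthma"]
        se = np.sqrt(fit.sigma_sq * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(sub["moderated_t"].values, (diff / se).values, rtol=1e-5)

    def test_full_shrinkage_limit_uses_prior_variance_only(self):
        fit = self._toy_fit()
        res, _ = moderate_statistics(fit, prior=EBayesPrior(d0=1e8, s0_sq=0.7))
        sub = res[res["contrast"] == "difference"]
        diff = fit.means["normal"] - fit.means["asthma"]
        expected = diff / (np.sqrt(0.7) * np.sqrt(0.5))
        np.testing.assert_allclose(sub["moderated_t"].values, expected.values, rtol=1e-6)

    def test_all_zero_variances_fall_back_with_warning(self):
        M = pd.DataFrame(
            np.tile([1.0, 1.0, 0.0, 0.0], (5, 1)),
            index=[f"p{i}" for i in range(5)],
            columns=["s0", "s1", "s2", "s3"],
        )
        groups = pd.Series(["normal", "normal", "asthma", "asthma"], index=M.columns)
        fit = fit_probe_models(M, groups)
        with pytest.warns(RuntimeWarning, match="variances"):
            res, prior = moderate_statistics(fit)
        assert np.isinf(prior.d0)
        assert (res["p_raw"] <= 1).all()

    def test_prior_estimation_recovers_moments(self):
        rng = np.random.default_rng(7)
        d0_true, s0_true, df = 6.0, 0.5, 10
        n = 20_000
        true_var = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = true_var * rng.chisquare(df, n) / df
        prior = estimate_ebayes_prior(s2, df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.1)


def bh_oracle(p):
    """Independent restatement of step-up: adj_i = min over tail of p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos, i in enumerate(order):
        adj[i] = min(min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0)
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_dominates_raw_and_stays_in_unit_interval(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallsAndFilter:
    def test_unmethylated_call_thresholds(self, results_builder):
        res = results_builder(
            [
                ("p1", "meth_normal", 0.9, 0.01),   # called
                ("p2", "meth_normal", 0.9, 0.06),   # fails FDR
                ("p3", "meth_normal", 0.45, 0.001),  # fails log2FC
                ("p1", "meth_asthma", 0.0, 0.9),
                ("p2", "meth_asthma", 0.0, 0.9),
                ("p3", "meth_asthma", 0.0, 0.9),
            ]
        )
        calls = call_unmethylated(res)
        assert calls["normal_only"] == {"p1"}
        assert calls["asthma_only"] == set()

    def test_both_group_calls_are_not_single_group(self, results_builder):
        res = results_builder(
            [("p1", "meth_normal", 1.0, 0.01), ("p1", "meth_asthma", 1.0, 0.01)]
        )
        calls = call_unmethylated(res)
        assert calls["both"] == {"p1"}
        assert calls["normal_only"] == set()

    @pytest.mark.parametrize(
        "lfc_normal,lfc_asthma,kept",
        [
            (0.9, 0.4, True),    # methylated group < 0.5 and |delta| > 0.3
            (0.8, 0.55, False),  # methylated group >= 0.5
            (0.6, 0.4, False),   # |delta| <= 0.3
        ],
    )
    def test_two_stage_filter(self, results_builder, lfc_normal, lfc_asthma, kept):
        res = results_builder(
            [
                ("p1", "meth_normal", lfc_normal, 0.01),
                ("p1", "meth_asthma", lfc_asthma, 0.9),
                ("p1", "difference", lfc_normal - lfc_asthma, 0.01),
            ]
        )
        calls = {"normal_only": {"p1"}, "asthma_only": set(), "both": set()}
        hyper, hypo = filter_dmrs(calls, res)
        assert (("p1" in hyper.probe_ids) is kept)
        assert hypo.table.empty
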