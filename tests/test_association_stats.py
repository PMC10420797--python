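"""Tests for stepwise regression, logistic models and tertile ANCOVA,
including brute-force oracles for the effect-size arithmetic."""

import numpy as np
import pandas as pd
import pytest

from chronodiet.association_stats import (
    ModelSpec,
    ancova_by_tertile,
    bonferroni_adjust,
    fit_ols_structure,
    hosmer_lemeshow,
    stepwise_logistic,
    stepwise_ols,
)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected", [(0.01, 3, 0.03), (0.5, 4, 1.0), (0.2, 1, 0.2)]
    )
    def test_definition_cap_and_identity(self, p, m, expected):
        assert bonferroni_adjust([p], m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], 2)


def _signal_noise_frame(rng, n=150, beta=0.5):
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = beta * x1 + rng.standard_normal(n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


class TestStepwiseOls:
    def test_signal_selected_noise_mostly_not(self):
        rng = np.random.default_rng(5)
        only_signal = 0
        reps = 200
        for _ in range(reps):
            df = _signal_noise_frame(rng)
            res = stepwise_ols(df, ModelSpec("y", ["x1", "x2"]))
            sel = list(res.table["predictor"])
            if sel == ["x1"]:
                only_signal += 1
        # x1 virtually always enters; x2 only at the 5% entry level, so
        # "x1 alone" should hold in at least ~90% of replicates
        assert only_signal / reps >= 0.90

    def test_exact_duplicate_excluded_by_vif(self, rng):
        df = _signal_noise_frame(rng, n=200)
        df["x3"] = df["x1"]
        res = stepwise_ols(df, ModelSpec("y", ["x1", "x2", "x3"]))
        assert "x3" in res.excluded_collinear or "x1" in res.excluded_collinear
        assert not {"x1", "x3"} <= set(res.table["predictor"])
        assert (res.table["VIF"] < 5).all()

    def test_delta_r2_decomposition(self, rng):
        n = 300
        x1 = rng.standard_normal(n)
        x2 = 0.4 * x1 + rng.standard_normal(n)
        y = 0.6 * x1 + 0.3 * x2 + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = fit_ols_structure(df, "y", ["x1", "x2"])
        r2_first = fit_ols_structure(df, "y", ["x1"]).r2
        assert res.table["dR2"].iloc[1] == pytest.approx(
            res.r2 - r2_first, abs=1e-10
        )
        assert res.table["dR2"].sum() == pytest.approx(res.r2, abs=1e-10)
        assert res.table["R2_cum"].iloc[-1] == pytest.approx(res.r2, abs=1e-12)

    def test_standardized_beta_invariant_to_affine_rescaling(self, rng):
        df = _signal_noise_frame(rng, n=250)
        res1 = fit_ols_structure(df, "y", ["x1", "x2"])
        df2 = df.assign(x1=df.x1 * 1000 - 7.5, x2=df.x2 / 300 + 2)
        res2 = fit_ols_structure(df2, "y", ["x1", "x2"])
        assert np.allclose(
            res1.table["beta"], res2.table["beta"], atol=1e-8
        )

    def test_no_candidate_passing_entry_returns_flagged_empty_model(self, rng):
        n = 200
        df = pd.DataFrame(
            {"y": rng.standard_normal(n), "x1": rng.standard_normal(n)}
        )
        res = stepwise_ols(df, ModelSpec("y", ["x1"], entry_p=1e-6))
        assert res.empty and len(res.table) == 0


class TestStepwiseLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # counts: exposed cases a=30, exposed controls b=20,
        #          unexposed cases c=15, unexposed controls d=60
        a, b, c, d = 30, 20, 15, 60
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        df = pd.DataFrame({"y": y, "x": x})
        res = stepwise_logistic(df, ModelSpec("y", ["x"]))
        assert res.table["OR"].iloc[0] == pytest.approx(
            (a * d) / (b * c), rel=1e-8
        )
        assert res.table["ci_low"].iloc[0] < res.table["OR"].iloc[0] \
            < res.table["ci_high"].iloc[0]

    def test_null_outcome_gives_empty_model(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "y": (rng.random(n) < 0.3).astype(float),
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
            }
        )
        res = stepwise_logistic(df, ModelSpec("y", ["x1", "x2"], entry_p=1e-4))
        assert res.empty

    def test_separated_predictor_dropped_with_flag(self, rng):
        n = 200
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        sep = np.r_[np.ones(n // 2), np.zeros(n // 2)] * 10 + 5  # perfect
        df = pd.DataFrame({"y": y, "sep": sep, "x": rng.standard_normal(n)})
        res = stepwise_logistic(df, ModelSpec("y", ["sep", "x"]))
        assert "sep" in res.separated
        assert "sep" not in list(res.table["predictor"])

    def test_omnibus_matches_likelihood_ratio(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + x)))).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        res = stepwise_logistic(df, ModelSpec("y", ["x"]))
        import statsmodels.api as sm

        full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        assert res.omnibus_chi2 == pytest.approx(
            2 * (full.llf - null.llf), rel=1e-6
        )
        assert res.omnibus_df == 1

    def test_hosmer_lemeshow_degrees_of_freedom(self, rng):
        n = 1000
        p = rng.uniform(0.1, 0.9, n)
        y = (rng.random(n) < p).astype(float)
        chi2, df, pval = hosmer_lemeshow(y, p)
        assert df == 8  # ten groups minus two
        assert 0 <= pval <= 1


def _ancova_frame(rng, n=240, shift=0.0):
    tert = np.repeat([1, 2, 3], n // 3)
    cov = rng.standard_normal(n)
    y = 0.5 * cov + shift * (tert - 2) + rng.standard_normal(n)
    return pd.DataFrame({"y": y, "tert": tert, "cov": cov})


class TestAncova:
    def test_null_effect_eta_squared_near_zero(self):
        rng = np.random.default_rng(3)
        etas, fs = [], []
        for _ in range(100):
            res = ancova_by_tertile(_ancova_frame(rng), "y", "tert", ["cov"])
            etas.append(res.eta_sq)
            fs.append(res.f)
        assert np.mean(etas) < 0.02
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(4)
        sig = sum(
            ancova_by_tertile(
                _ancova_frame(rng, shift=0.5), "y", "tert", ["cov"]
            ).p < 0.05
            for _ in range(25)
        )
        assert sig >= 24

    def test_eta_squared_matches_hand_sums_of_squares(self):
        # 12-row fixture, hand-decomposable
        df = pd.DataFrame(
            {
                "y": [1.0, 2.0, 1.5, 2.5, 3.0, 4.0, 3.5, 4.5, 6.0, 7.0, 6.5, 7.5],
                "tert": [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3],
                "cov": [0.1, -0.2, 0.0, 0.3, -0.1, 0.2, 0.1, 0.0, -0.3, 0.1,
                        0.2, -0.1],
            }
        )
        res = ancova_by_tertile(df, "y", "tert", ["cov"])
        # oracle: explicit least-squares projections
        y = df["y"].to_numpy()
        d2 = (df["tert"] == 2).astype(float)
        d3 = (df["tert"] == 3).astype(float)
        X_full = np.column_stack([np.ones(12), d2, d3, df["cov"]])
        X_red = np.column_stack([np.ones(12), df["cov"]])

        def ssr(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ beta) ** 2))

        ss_factor = ssr(X_red) - ssr(X_full)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        f_oracle = (ss_factor / 2) / (ssr(X_full) / (12 - 4))
        assert res.eta_sq == pytest.approx(ss_factor / ss_total, abs=1e-8)
        assert res.f == pytest.approx(f_oracle, abs=1e-8)
        assert 0 <= res.eta_sq <= 1

    def test_adjusted_means_in_tertile_order_and_posthoc_tiers(self):
        rng = np.random.default_rng(6)
        res = ancova_by_tertile(
            _ancova_frame(rng, n=600, shift=1.0), "y", "tert", ["cov"]
        )
        assert list(res.groups["tertile"]) == [1, 2, 3]
        means = res.groups["adj_mean"].to_numpy()
        assert means[0] < means[1] < means[2]
        extreme = res.posthoc.set_index("pair").loc["1-3"]
        assert extreme["tier"] == "<0.0001"

    def test_empty_tertile_rejected(self, rng):
        df = _ancova_frame(rng)
        df.loc[df["tert"] == 3, "tert"] = 2
        with pytest.raises(ValueError, match="3 non-empty levels"):
            ancova_by_tertile(df, "y", "tert", ["cov"])

    def test_factor_collinear_covariate_flagged(self, rng):
        df = _ancova_frame(rng)
        df["bad"] = df["tert"].map({1: 0.0, 2: 1.0, 3: 2.0})
        with pytest.raises(ValueError, match="collinear"):
            ancova_by_tertile(df, "y", "tert", ["cov", "bad"])
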