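"""Environmental distances, residualization, and permutation regressions."""

import numpy as np
import pandas as pd
import pytest

import phyloturn as pt
from phyloturn.env import (
    env_distance,
    perm_regression,
    residualize_on_space,
    spatial_distance,
    stagewise_association,
    subsample_association,
)


def _env_frame(values: np.ndarray, names=None) -> pd.DataFrame:
    n, p = values.shape
    names = names or [f"v{j}" for j in range(p)]
    df = pd.DataFrame(values, columns=names,
                      index=[f"P{i:02d}" for i in range(n)])
    rng = np.random.default_rng(0)
    df["x"] = rng.uniform(0, 100, n)
    df["y"] = rng.uniform(0, 100, n)
    return df


class TestEnvDistance:
    def test_two_plots_full_space_distance(self):
        vals = np.array([[1.0, 10.0, 3.0], [2.0, 20.0, 5.0]])
        df = _env_frame(vals)
        d, meta = env_distance(df, variance_target=0.90)
        # with 2 plots every variable z-scores to +-1/sqrt(2) after logging;
        # one PC carries all variance
        assert len(d) == 1
        zz = np.log(vals)
        zz = (zz - zz.mean(0)) / zz.std(0, ddof=1)
        expected = np.linalg.norm(zz[0] - zz[1])
        assert d.iloc[0] == pytest.approx(expected)

    def test_duplicated_variable_near_invariance(self):
        # a perfectly collinear copy adds no PCA rank; the retained-PC
        # distances stay nearly unchanged (duplication only reweights the
        # shared axis)
        rng = np.random.default_rng(1)
        base = np.exp(rng.standard_normal((15, 8)))
        d1, m1 = env_distance(_env_frame(base), variance_target=0.999)
        dup = np.hstack([base, base[:, :1]])
        d2, m2 = env_distance(_env_frame(dup), variance_target=0.999)
        assert m2["n_pc"] <= m1["n_pc"] + 1  # no new dimensions beyond rank
        r = np.corrcoef(d1, d2)[0, 1]
        assert r > 0.97

    @pytest.mark.parametrize("seed", [4, 5, 6, 7, 8])
    def test_six_latent_factors_need_about_six_pcs(self, seed):
        # 27 plots x 11 variables driven by 6 comparable latent factors:
        # about six PCs reach the 90% variance target
        rng = np.random.default_rng(seed)
        n, q, p = 27, 6, 11
        factors = rng.standard_normal((n, q))
        Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
        loadings = Q[:q] * np.sqrt(p / q)
        vals = np.exp(0.5 * (factors @ loadings)
                      + 0.18 * rng.standard_normal((n, p)))
        _, meta = env_distance(_env_frame(vals), variance_target=0.90)
        assert 5 <= meta["n_pc"] <= 7

    def test_constant_variable_dropped(self, caplog):
        vals = np.exp(np.random.default_rng(3).standard_normal((10, 3)))
        vals[:, 1] = 2.0
        _, meta = env_distance(_env_frame(vals))
        assert meta["dropped"] == ["v1"]

    def test_signed_variables_pass_untransformed(self):
        rng = np.random.default_rng(4)
        vals = np.column_stack([
            np.exp(rng.standard_normal(10)),
            rng.uniform(-1, 1, 10),
        ])
        _, meta = env_distance(_env_frame(vals, names=["pH", "northness"]))
        assert meta["log_transformed"] == ["pH"]
        assert meta["untransformed"] == ["northness"]


class TestResidualize:
    def test_exact_linear_function_gives_zero_residuals(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")]
        )
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        y = 2.0 + 0.5 * x
        resid, info = residualize_on_space(y, x)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        assert info["slope"] == pytest.approx(0.5)

    def test_closed_form_four_pairs(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")]
        )
        x = pd.Series([0.0, 1.0, 2.0, 3.0], index=idx)
        y = pd.Series([1.0, 3.0, 2.0, 6.0], index=idx)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        expected = y.to_numpy() - X @ beta
        resid, info = residualize_on_space(y, x)
        np.testing.assert_allclose(resid, expected, atol=1e-12)
        assert info["slope"] == pytest.approx(beta[1])

    def test_zero_variance_space_centers(self, caplog):
        idx = pd.MultiIndex.from_tuples([("a", "b"), ("a", "c"), ("b", "c")])
        y = pd.Series([1.0, 2.0, 6.0], index=idx)
        x = pd.Series([5.0, 5.0, 5.0], index=idx)
        resid, _ = residualize_on_space(y, x)
        np.testing.assert_allclose(resid, y - y.mean())


class TestPermRegression:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = perm_regression(x, x, n_perm=499, rng=np.random.default_rng(5))
        assert res.r2 == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 500)

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_sets = 400
        for _ in range(n_sets):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            res = perm_regression(y, x, n_perm=99, rng=rng)
            rejections += res.p <= 0.05
        rate = rejections / n_sets
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sets)
        assert abs(rate - 0.05) < ci + 0.01

    def test_zero_variance_flagged(self):
        res = perm_regression(np.ones(5), np.arange(5.0), n_perm=99)
        assert np.isnan(res.p)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 60)
        signal_sd = 0.5 * np.std(2.0 * x)
        y = 2.0 * x + rng.normal(0, signal_sd, 60)
        slopes = []
        for _ in range(50):
            y = 2.0 * x + rng.normal(0, signal_sd, 60)
            slopes.append(perm_regression(y, x, n_perm=19, rng=rng).slope)
        assert np.mean(slopes) == pytest.approx(2.0, rel=0.1)


class TestStagewise:
    def test_deep_scenario_late_stage_association(self, pool410):
        """Across several deep-filtering datasets, the turnover-environment
        association is positive in the late stages and the late-only pattern
        holds in the majority of runs (per-run power at ~0.2 R-squared and
        <= 21 pairs is intrinsically limited)."""
        rng = np.random.default_rng(8)
        late_slopes, pattern = [], []
        for i in range(16):
            b = pt.generate_bundle(
                pt.ScenarioConfig(scenario="deep_filtering_late", seed=900 + i),
                pool=pool410, with_traits=False,
            )
            a = stagewise_association(b, n_perm=499, rng=rng).set_index("scope")
            late_slopes += [a.loc["stage 4", "slope"], a.loc["stage 5", "slope"]]
            late_sig = (a.loc["stage 4", "p"] <= 0.05) or (a.loc["stage 5", "p"] <= 0.05)
            early_sig = any(a.loc[f"stage {s}", "p"] <= 0.05 for s in "123")
            pattern.append(late_sig and not early_sig)
        assert np.mean(np.array(late_slopes) > 0) >= 0.75
        assert np.mean(pattern) >= 0.5

    def test_scopes_present(self, neutral_bundle):
        assoc = stagewise_association(
            neutral_bundle, n_perm=99, rng=np.random.default_rng(9)
        )
        scopes = set(assoc["scope"])
        assert {"overall", "within-stage", "between-stage"} <= scopes
        assert sum(s.startswith("stage ") for s in scopes) == 5


class TestSubsample:
    def test_subset_counts(self, neutral_bundle):
        out = subsample_association(
            neutral_bundle, k=4, n_perm=19, rng=np.random.default_rng(10)
        )
        by_stage = out.set_index("stage")
        assert by_stage.loc["1", "n_subsets"] == 5    # C(5,4)
        assert by_stage.loc["2", "n_subsets"] == 1    # C(4,4)
        assert by_stage.loc["4", "n_subsets"] == 15   # C(6,4)
        assert by_stage.loc["5", "n_subsets"] == 35   # C(7,4)

    def test_stage_of_exactly_k_equals_stagewise(self, neutral_bundle):
        rng = np.random.default_rng(11)
        out = subsample_association(neutral_bundle, k=4, n_perm=199, rng=rng)
        assoc = stagewise_association(
            neutral_bundle, n_perm=199, rng=np.random.default_rng(11)
        )
        r2_sub = out.set_index("stage").loc["2", "mean_r2"]
        r2_full = assoc.set_index("scope").loc["stage 2", "r2"]
        assert r2_sub == pytest.approx(r2_full, rel=1e-9)

    def test_small_stage_skipped(self, four_tip_bundle):
        b = four_tip_bundle
        # graft an env table onto the 2-plot bundle
        rng = np.random.default_rng(12)
        b.env = pd.DataFrame(
            {"pH": [4.0, 5.0], "moisture": [0.2, 0.3],
             "x": [0.0, 1.0], "y": [0.0, 1.0]},
            index=b.plots,
        )
        out = subsample_association(b, k=4, n_perm=19, rng=rng)
        assert (out["n_subsets"] == 0).all()

    def test_deep_scenario_late_subsets_stay_positive(self, deep_bundle):
        out = subsample_association(
            deep_bundle, k=4, n_perm=99, rng=np.random.default_rng(13)
        )
        by_stage = out.set_index("stage")
        assert by_stage.loc["5", "mean_slope"] > 0
        assert by_stage.loc["5", "mean_r2"] > 0.05
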