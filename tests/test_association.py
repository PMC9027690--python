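"""Regression screen, BH correction, adjusted-R2 accounting and ROC AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopress.association import (
    bh_adjust,
    combined_fit,
    cumulative_r2,
    ols_fit,
    roc_auc,
    screen_features,
)
from metabopress.datasets import ckd_bp_metabolite_table


def normal_equations(X: np.ndarray, y: np.ndarray):
    """Independent OLS oracle: closed-form slopes, SEs and t-test p-values."""
    from scipy import stats

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    p = 2 * stats.t.sf(np.abs(beta / se), dof)
    return beta, se, p


class TestOlsFit:
    def test_matches_normal_equations_on_random_designs(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 31))
            p = int(rng.integers(1, 6))
            data = pd.DataFrame(
                rng.standard_normal((n, p)), columns=[f"x{k}" for k in range(p)]
            )
            data["y"] = rng.standard_normal(n)
            res = ols_fit(data, "y", [f"x{k}" for k in range(p)])
            X = np.column_stack([np.ones(n), data.iloc[:, :p].to_numpy()])
            beta, se, pvals = normal_equations(X, data["y"].to_numpy())
            np.testing.assert_allclose(res.estimate.to_numpy(), beta, atol=1e-8)
            np.testing.assert_allclose(res.stderr.to_numpy(), se, atol=1e-8)
            np.testing.assert_allclose(res.p.to_numpy(), pvals, atol=1e-8)
            assert res.adj_r2 <= res.r2

    def test_three_point_closed_form(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        res = ols_fit(data, "y", ["x"])
        assert res.estimate["x"] == pytest.approx(1.0)
        assert res.estimate["const"] == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_perfect_fit_recovers_slope(self, rng):
        x = rng.standard_normal(40)
        data = pd.DataFrame({"x": x, "y": 2.5 * x - 1.0})
        res = ols_fit(data, "y", ["x"])
        assert res.estimate["x"] == pytest.approx(2.5)
        assert res.p["x"] < 1e-30

    def test_type_one_error_calibrated(self, rng):
        """Outcome independent of the predictor: p is uniform, ~5% below 0.05."""
        hits = 0
        reps = 400
        for _ in range(reps):
            data = pd.DataFrame(
                {"x": rng.standard_normal(25), "y": rng.standard_normal(25)}
            )
            hits += ols_fit(data, "y", ["x"]).p["x"] < 0.05
        assert 0.03 <= hits / reps <= 0.08  # ~3 binomial SDs around 0.05

    def test_singular_design_names_columns(self, rng):
        x = rng.standard_normal(30)
        data = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.standard_normal(30)})
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            ols_fit(data, "y", ["x", "x2"])

    def test_insufficient_n(self):
        data = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="samples"):
            ols_fit(data, "y", ["x"])


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: adjusted_i = min over {j : p_j >= p_i} of
    m * p_j / rank_j, capped at 1."""
    m = len(p)
    ranks = {}
    for rank, idx in enumerate(np.argsort(p, kind="mergesort"), start=1):
        ranks[idx] = rank
    out = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


class TestBHAdjust:
    def test_published_worked_example(self):
        """BH with m = 31 on the published combined p column reproduces the
        published adjusted column to 3 significant figures."""
        table = ckd_bp_metabolite_table()
        adjusted = bh_adjust(table["p_combined"])
        np.testing.assert_allclose(
            adjusted, table["p_adjusted_published"], rtol=5e-3
        )

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_oracle_and_statsmodels(self, p_list):
        p = np.asarray(p_list)
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, bh_oracle(p), atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, sm_adj, atol=1e-12)

    def test_degenerate_cases(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])  # m = 1
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)  # ties
        assert (np.diff(bh_adjust(np.linspace(0.001, 0.9, 12))) >= 0).all()

    def test_invalid_p_rejected(self):
        for bad in ([], [0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


def _cohort_frame(rng, n=150, effect=0.0):
    ckd = rng.integers(0, 6, n).astype(float)
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    y = np.clip(np.round(2.5 + 0.2 * ckd + effect * x + noise), 1, 5)
    return pd.DataFrame({"bp_code5": y, "ckd_stage": ckd, "feat": x,
                         "null": rng.standard_normal(n)})


class TestScreenAndCombine:
    def test_alpha_zero_replicates_nothing(self, rng):
        disc = _cohort_frame(rng, effect=2.0)
        val = _cohort_frame(rng, effect=2.0)
        assoc = screen_features(disc, val, ["feat", "null"], alpha=0.0)
        assert not assoc["replicated"].any()
        assert assoc["p_validation"].isna().all()

    def test_strong_effect_replicates_and_null_does_not(self, rng):
        disc = _cohort_frame(rng, n=400, effect=1.0)
        val = _cohort_frame(rng, n=400, effect=1.0)
        assoc = screen_features(disc, val, ["feat", "null"])
        row = assoc.set_index("feature")
        assert row.loc["feat", "replicated"]
        assert row.loc["feat", "p_discovery"] < 0.05 and row.loc["feat", "p_validation"] < 0.05

    def test_replication_symmetric_for_identical_cohorts(self, rng):
        frame = _cohort_frame(rng, n=300, effect=0.8)
        a = screen_features(frame, frame.copy(), ["feat", "null"])
        b = screen_features(frame.copy(), frame, ["feat", "null"])
        pd.testing.assert_frame_equal(a, b)
        assert (a["p_discovery"].to_numpy() == a["p_validation"].to_numpy())[
            a["replicated"]
        ].all()

    def test_missing_feature_rejected(self, rng):
        disc = _cohort_frame(rng)
        with pytest.raises(ValueError, match="missing"):
            screen_features(disc, disc.drop(columns=["null"]), ["feat", "null"])

    def test_combined_fit_duplicate_feature_identical(self, rng):
        disc = _cohort_frame(rng, n=400, effect=1.0)
        val = _cohort_frame(rng, n=400, effect=1.0)
        for frame in (disc, val):
            frame["feat_dup"] = frame["feat"]
            frame["egfr"] = 100 - 10 * frame["ckd_stage"] + rng.standard_normal(len(frame))
            frame["age"] = 55 + rng.standard_normal(len(frame))
            frame["weight"] = 70 + rng.standard_normal(len(frame))
            frame["bmi"] = 24 + rng.standard_normal(len(frame))
        assoc = screen_features(disc, val, ["feat", "feat_dup"])
        pooled = pd.concat([disc, val])
        out = combined_fit(assoc, pooled).set_index("feature")
        assert out.loc["feat", "estimate_combined"] == pytest.approx(
            out.loc["feat_dup", "estimate_combined"]
        )
        # BH applied within the replicated set only
        assert out.loc[out["replicated"], "p_adjusted"].notna().all()
        assert (
            out.loc[out["replicated"], "p_adjusted"]
            >= out.loc[out["replicated"], "p_combined"] - 1e-15
        ).all()


class TestCumulativeR2:
    def test_trajectory_length_and_noise_feature(self, rng):
        n = 500
        data = pd.DataFrame({
            "ckd_stage": rng.integers(0, 6, n).astype(float),
            "egfr": rng.normal(60, 20, n),
            "age": rng.normal(57, 10, n),
            "weight": rng.normal(72, 10, n),
            "bmi": rng.normal(24, 3, n),
        })
        data["bp_code5"] = np.clip(
            np.round(2.5 + 0.15 * data["ckd_stage"] + rng.standard_normal(n)), 1, 5
        )
        deltas = []
        for rep in range(20):
            data[f"noise{rep}"] = rng.standard_normal(n)
            traj = cumulative_r2(data, [f"noise{rep}"])
            assert len(traj) == 2
            deltas.append(traj[1] - traj[0])
        # adding pure noise does not raise adjusted R2 on average
        assert np.mean(deltas) <= 0.002

    def test_collinear_feature_raises(self, rng):
        n = 100
        data = pd.DataFrame({
            "ckd_stage": rng.integers(0, 6, n).astype(float),
            "egfr": rng.normal(60, 20, n),
            "age": rng.normal(57, 10, n),
            "weight": rng.normal(72, 10, n),
            "bmi": rng.normal(24, 3, n),
            "bp_code5": rng.integers(1, 6, n).astype(float),
        })
        data["dup_age"] = data["age"]
        with pytest.raises(np.linalg.LinAlgError):
            cumulative_r2(data, ["dup_age"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1])) == 1.0

    def test_four_point_worked_cases(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        assert roc_auc(values, np.array([0, 0, 1, 1])) == pytest.approx(1.0)
        assert roc_auc(values, np.array([0, 1, 0, 1])) == pytest.approx(0.75)

    def test_all_four_point_patterns_match_pair_enumeration(self):
        """Pairwise-enumeration oracle over every 4-point label pattern with
        both classes present, including tied values."""
        for values in ([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 2.0, 3.0], [5.0, 5.0, 5.0, 5.0]):
            v = np.array(values)
            for labels in itertools.product([0, 1], repeat=4):
                y = np.array(labels)
                if y.min() == y.max():
                    continue
                pos = v[y == 1]
                neg = v[y == 0]
                pairs = [(0.5 if a == b else float(a > b)) for a in pos for b in neg]
                assert roc_auc(v, y) == pytest.approx(np.mean(pairs))

    def test_null_auc_near_half(self, rng):
        values = rng.standard_normal(2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc(values, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.standard_normal(300)
        labels = (values + rng.standard_normal(300) > 0).astype(int)
        assert roc_auc(values, labels) == pytest.approx(roc_auc_score(labels, values))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))
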