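"""Penalized logistic models, Pclass scores, nomograms, structure analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorph.classify import (
    PclassModel,
    ScoreSet,
    bootstrap_validate,
    build_nomogram,
    calibration_curve,
    compare_model_structure,
    fit_penalized_lr,
    fit_tiv_augmented,
    pairwise_difference_summary,
    pclass_scores,
    score_battery,
    select_reference_category,
    significant_predictor_intersections,
)
from dimorph.effects import cliff_delta_inference, derive_rng


def _make_xy(n=300, p=4, beta=None, seed=0):
    g = np.random.default_rng(seed)
    X = pd.DataFrame(g.standard_normal((n, p)), columns=[f"x{j}" for j in range(p)])
    eta = X.to_numpy() @ (beta if beta is not None else np.zeros(p))
    prob = 1 / (1 + np.exp(-eta))
    y = np.where(g.uniform(size=n) < prob, "F", "M")
    # ensure both classes present
    y[0], y[1] = "F", "M"
    return X, pd.Series(y)


def _mock_model(names, sig, reference_sex="F"):
    """Minimal PclassModel carrying only a Wald table and coefficients."""
    coefs = pd.Series(np.linspace(1, 2, len(names)), index=names)
    wald = pd.DataFrame(
        {"coef": coefs, "se": 1.0, "z": 1.0,
         "p": [0.001 if n in sig else 0.8 for n in names],
         "fdr_p": [0.001 if n in sig else 0.9 for n in names]},
        index=names,
    )
    wald["significant"] = wald["fdr_p"] < 0.05
    return PclassModel(
        reference_sex=reference_sex, predictors=tuple(names), intercept=0.0,
        coefficients=coefs, penalty=1.0, cov=np.eye(len(names) + 1),
        apparent={"nagelkerke_r2": 0, "c_index": 0.5, "somers_dxy": 0}, wald=wald,
    )


class TestReferenceSelection:
    def _uni_with_deltas(self, deltas):
        from dimorph.univariate import UnivariateTable

        dom = pd.DataFrame({"delta": deltas}, index=[f"r{i}" for i in range(len(deltas))])
        return UnivariateTable(kind="raw", global_test=dom, overlap=dom, deciles=dom,
                               dominance=dom, shape=dom, direction=pd.Series(dtype=object))

    def test_unanimous_directions(self):
        assert select_reference_category(self._uni_with_deltas([-0.5] * 5)) == "M"
        assert select_reference_category(self._uni_with_deltas([0.3] * 5)) == "F"

    def test_exact_tie_defaults_to_f(self):
        assert select_reference_category(self._uni_with_deltas([-0.2, 0.2])) == "F"


class TestPenalizedFit:
    def test_null_signal_corrected_c_near_half(self):
        X, y = _make_xy(n=250, p=6, seed=1)
        model = fit_penalized_lr(X, y, "F")
        bootstrap_validate(model, X, y, n_reps=60, rng=derive_rng(1, "v"))
        assert 0.4 < model.corrected["c_index"] < 0.62
        assert model.apparent["c_index"] >= model.corrected["c_index"] - 0.02

    def test_single_strong_predictor_monotone_scores(self):
        X, y = _make_xy(n=400, p=1, beta=np.array([2.0]), seed=2)
        model = fit_penalized_lr(X, y, "F")
        order = np.argsort(X["x0"].to_numpy())
        scores = model.predict_proba(X)
        assert np.all(np.diff(scores[order]) >= 0)
        assert model.apparent["c_index"] > 0.8

    def test_huge_penalty_shrinks_slopes_to_prevalence(self):
        X, y = _make_xy(n=200, p=3, beta=np.array([1.0, -1.0, 0.5]), seed=3)
        model = fit_penalized_lr(X, y, "F", penalty_grid=[1e8])
        assert np.max(np.abs(model.coefficients)) < 1e-3
        prevalence = np.mean(np.asarray(y) == "F")
        assert np.allclose(model.predict_proba(X), prevalence, atol=0.01)

    def test_separation_without_penalty_raises(self):
        X = pd.DataFrame({"x0": np.concatenate([np.ones(20), -np.ones(20)])
                          + np.random.default_rng(0).normal(0, 0.01, 40)})
        y = pd.Series(["F"] * 20 + ["M"] * 20)
        with pytest.raises(ValueError, match="penalty|separation"):
            fit_penalized_lr(X, y, "F", penalty_grid=[0.0])

    def test_dxy_identity_and_c_against_pair_counting(self):
        X, y = _make_xy(n=150, p=3, beta=np.array([1.0, 0.5, 0.0]), seed=4)
        model = fit_penalized_lr(X, y, "F")
        scores = model.predict_proba(X)
        yb = (np.asarray(y) == "F")
        pos, neg = scores[yb], scores[~yb]
        conc = sum(np.sum(p > neg) + 0.5 * np.sum(p == neg) for p in pos)
        c_oracle = conc / (len(pos) * len(neg))
        assert model.apparent["c_index"] == pytest.approx(c_oracle, abs=1e-12)
        assert model.apparent["somers_dxy"] == pytest.approx(2 * (c_oracle - 0.5), abs=1e-9)

    def test_missing_values_rejected(self):
        X, y = _make_xy(n=50, p=2)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_penalized_lr(X, y, "F")


class TestValidation:
    def test_overfitting_detected_on_null_with_many_predictors(self):
        X, y = _make_xy(n=60, p=15, seed=5)
        model = fit_penalized_lr(X, y, "F", penalty_grid=[0.5])
        res = bootstrap_validate(model, X, y, n_reps=50, rng=derive_rng(5, "v"))
        assert model.apparent["c_index"] > 0.6
        assert res["c_index"] < model.apparent["c_index"] - 0.03

    def test_deterministic_given_seed(self):
        X, y = _make_xy(n=120, p=4, beta=np.array([1, 0, 0, 0.0]), seed=6)
        model = fit_penalized_lr(X, y, "F")
        r1 = bootstrap_validate(model, X, y, n_reps=30, rng=derive_rng(7, "v"))
        r2 = bootstrap_validate(model, X, y, n_reps=30, rng=derive_rng(7, "v"))
        assert r1 == r2


class TestCalibration:
    def test_single_bin_is_mean_vs_prevalence(self):
        X, y = _make_xy(n=100, p=2, beta=np.array([1.0, 0.0]), seed=8)
        model = fit_penalized_lr(X, y, "F")
        curve = calibration_curve(model, X, y, n_bins=1)
        assert len(curve) == 1
        assert curve["observed_fraction"][0] == pytest.approx(np.mean(np.asarray(y) == "F"))
        assert curve["mean_predicted"][0] == pytest.approx(model.predict_proba(X).mean())

    def test_generative_model_well_calibrated(self):
        beta = np.array([1.0, -0.7, 0.4])
        X, y = _make_xy(n=2000, p=3, beta=beta, seed=9)
        model = fit_penalized_lr(X, y, "F")
        curve = calibration_curve(model, X, y, n_bins=10)
        assert np.max(np.abs(curve["mean_predicted"] - curve["observed_fraction"])) < 0.08

    def test_too_many_bins_rejected(self):
        X, y = _make_xy(n=30, p=2)
        model = fit_penalized_lr(X, y, "F")
        with pytest.raises(ValueError):
            calibration_curve(model, X, y, n_bins=50)


class TestScoreBattery:
    def test_perfect_separation(self, fast_cfg):
        g = np.random.default_rng(1)
        scores = ScoreSet(
            scores=pd.Series(np.concatenate([0.9 + 0.05 * g.uniform(size=30),
                                             0.05 * g.uniform(size=30)])),
            sex=pd.Series(["F"] * 30 + ["M"] * 30),
            score_kind="pclass",
            reference_sex="F",
        )
        out = score_battery(scores, fast_cfg)
        assert out["accuracy"]["balanced_pct"] == 100.0
        assert out["dominance"].delta.value == 1.0
        assert out["overlap"].value < 0.05

    def test_delta_matches_direct_cliff_inference(self, fast_cfg):
        g = np.random.default_rng(2)
        vals = np.clip(g.beta(2, 2, size=80), 0, 1)
        scores = ScoreSet(scores=pd.Series(vals), sex=pd.Series(["F", "M"] * 40),
                          score_kind="pclass", reference_sex="F")
        out = score_battery(scores, fast_cfg)
        direct = cliff_delta_inference(scores.group("F"), scores.group("M"), fast_cfg)
        assert out["dominance"].delta.value == pytest.approx(direct.delta.value, abs=1e-12)

    def test_pclass_range_enforced(self):
        with pytest.raises(ValueError):
            ScoreSet(scores=pd.Series([0.5, 1.5]), sex=pd.Series(["F", "M"]),
                     score_kind="pclass")


class TestPairwiseDifferences:
    def test_total_dominance(self, fast_cfg):
        s = ScoreSet(scores=pd.Series([1.0, 1.0, 0.0, 0.0]),
                     sex=pd.Series(["F", "F", "M", "M"]), score_kind="pclass",
                     reference_sex="F")
        res = pairwise_difference_summary(s, fast_cfg, n_boot=20)
        assert res.percent_favoring_reference == 100.0
        assert res.n_pairs == 4

    def test_tie_exclusion_enumeration(self, fast_cfg):
        # F=[1,0], M=[0,1] -> differences {1,0,0,-1}: ties excluded, 50%
        s = ScoreSet(scores=pd.Series([1.0, 0.0, 0.0, 1.0]),
                     sex=pd.Series(["F", "F", "M", "M"]), score_kind="pclass",
                     reference_sex="F")
        res = pairwise_difference_summary(s, fast_cfg, n_boot=20)
        assert res.percent_favoring_reference == 50.0
        assert res.n_ties == 2

    def test_identical_groups_near_half(self, fast_cfg):
        g = np.random.default_rng(3)
        vals = g.uniform(size=400)
        s = ScoreSet(scores=pd.Series(vals), sex=pd.Series(["F", "M"] * 200),
                     score_kind="pclass", reference_sex="F")
        res = pairwise_difference_summary(s, fast_cfg, n_boot=50)
        assert res.percent_favoring_reference == pytest.approx(50.0, abs=8.0)
        assert res.deciles[4] == pytest.approx(0.0, abs=0.05)

    def test_cap_without_subsampling_raises(self, fast_cfg):
        g = np.random.default_rng(4)
        s = ScoreSet(scores=pd.Series(g.uniform(size=200)),
                     sex=pd.Series(["F", "M"] * 100), score_kind="pclass")
        with pytest.raises(ValueError, match="cap"):
            pairwise_difference_summary(s, fast_cfg, n_boot=5, pair_cap=100, subsample=False)


class TestNomogram:
    def test_single_predictor_spans_full_scale(self):
        X, y = _make_xy(n=200, p=1, beta=np.array([1.5]), seed=10)
        model = fit_penalized_lr(X, y, "F")
        nom = build_nomogram(model, X)
        assert nom["table"]["max_points"].iloc[0] == pytest.approx(100.0)

    def test_importance_ratio_scaling(self):
        model = _mock_model(["a", "b"], sig=set())
        model.coefficients = pd.Series([2.0, 1.0], index=["a", "b"])
        model.predictors = ("a", "b")
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        nom = build_nomogram(model, X)
        assert nom["table"].loc["a", "max_points"] == pytest.approx(100.0)
        assert nom["table"].loc["b", "max_points"] == pytest.approx(50.0)

    def test_zero_coefficient_gives_flat_scale(self):
        model = _mock_model(["a", "b"], sig=set())
        model.coefficients = pd.Series([1.0, 0.0], index=["a", "b"])
        model.predictors = ("a", "b")
        X = pd.DataFrame({"a": [0.0, 2.0], "b": [0.0, 2.0]})
        nom = build_nomogram(model, X)
        assert nom["table"].loc["b", "max_points"] == 0.0

    def test_all_zero_model_rejected(self):
        model = _mock_model(["a"], sig=set())
        model.coefficients = pd.Series([0.0], index=["a"])
        model.predictors = ("a",)
        with pytest.raises(ValueError):
            build_nomogram(model, pd.DataFrame({"a": [0.0, 1.0]}))

    def test_points_map_recovers_probabilities(self):
        X, y = _make_xy(n=150, p=3, beta=np.array([1.0, -0.5, 0.2]), seed=11)
        model = fit_penalized_lr(X, y, "F")
        nom = build_nomogram(model, X)
        # total points of each subject map back to its Pclass score
        beta = model.coefficients.to_numpy()
        anchor = np.where(beta >= 0, X.min().to_numpy(), X.max().to_numpy())
        top = (np.abs(beta) * (X.max() - X.min()).to_numpy()).max()
        pts = (100 * np.abs(beta) * np.abs(X.to_numpy() - anchor) / top).sum(axis=1)
        assert np.allclose(nom["total_points_to_pclass"](pts), model.predict_proba(X), atol=1e-9)


class TestStructureAndIntersections:
    def test_identical_and_negated_vectors(self):
        m1 = _mock_model(["a", "b", "c", "d"], sig=set())
        m2 = _mock_model(["a", "b", "c", "d"], sig=set())
        m2.coefficients = -m1.coefficients
        res = compare_model_structure([m1, m2])
        assert res["rho_abs"].iloc[0, 1] == pytest.approx(1.0)
        assert res["rho_signed"].iloc[0, 1] == pytest.approx(-1.0)

    def test_mismatched_predictors_rejected(self):
        m1 = _mock_model(["a", "b", "c"], sig=set())
        m2 = _mock_model(["x", "y", "z"], sig=set())
        with pytest.raises(ValueError):
            compare_model_structure([m1, m2])

    def test_intersection_set_arithmetic(self):
        m1 = _mock_model(["A", "B", "C"], sig={"A", "B"})
        m2 = _mock_model(["A", "B", "C"], sig={"B", "C"})
        res = significant_predictor_intersections([m1, m2], model_names=["one", "two"])
        assert res["exclusive_intersections"][("one", "two")] == ["B"]
        assert res["exclusive_intersections"][("one",)] == ["A"]
        assert res["exclusive_intersections"][("two",)] == ["C"]
        assert res["counts"]["B"] == 2

    def test_random_vectors_have_low_abs_rho(self):
        g = np.random.default_rng(12)
        rhos = []
        for _ in range(300):
            rhos.append(abs(stats.spearmanr(g.standard_normal(18), g.standard_normal(18)).statistic))
        assert np.quantile(rhos, 0.95) < 0.52


class TestTivAugmented:
    def test_constant_tiv_rejected(self):
        X, y = _make_xy(n=60, p=2)
        with pytest.raises(ValueError, match="constant"):
            fit_tiv_augmented(X, pd.Series(np.full(60, 1450.0)), y, "F")

    def test_tiv_column_added(self, small_datasets):
        raw, _ = small_datasets
        model = fit_tiv_augmented(raw.zscores, raw.tiv, raw.sex, "M")
        assert "TIV" in model.predictors
        assert model.includes_tiv
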