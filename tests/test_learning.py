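"""Model selection, fitting, assessment, persistence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from pathdyn.exceptions import ConfigurationError
from pathdyn.learning import (
    Candidate,
    MetabolicDynamics,
    MetabolicDynamicsResults,
    SearchSpace,
    assess_derivative_fit,
    fit_dynamics,
    select_model,
)
from pathdyn.preprocess import DerivativeTrainingSet, build_training_set


def _exact_linear(seed):
    return Pipeline([("reg", Ridge(alpha=1e-12))])


def _knn(seed):
    return Pipeline([("scale", StandardScaler()),
                     ("reg", KNeighborsRegressor(n_neighbors=3))])


def _linear_training_set(n_strains=4, rows_per=30, noise=0.0, seed=0):
    """Synthetic linear dynamics: targets = features @ W.T (+ noise)."""
    rng = np.random.default_rng(seed)
    W = np.array([[0.5, -0.2, 1.0], [0.0, 0.3, -0.5]])  # 2 mets x 3 features
    feats, targs, strain, time = [], [], [], []
    for i in range(n_strains):
        X = rng.uniform(0, 2, size=(rows_per, 3))
        feats.append(X)
        targs.append(X @ W.T + noise * rng.normal(size=(rows_per, 2)))
        strain.extend([f"s{i}"] * rows_per)
        time.extend(np.linspace(0, 72, rows_per))
    return DerivativeTrainingSet(
        features=np.vstack(feats), targets=np.vstack(targs),
        metabolite_names=("mA", "mB"), protein_names=("pX",),
        provenance=pd.DataFrame({"strain": strain, "time": time}),
    )


class TestSelectModel:
    def test_single_candidate_space_returns_it_refit(self):
        ts = _linear_training_set()
        space = SearchSpace.single(Candidate("lin", _exact_linear, 1, 1))
        fitted, table = select_model(ts, "mA", space, seed=0)
        assert list(table["candidate"]) == ["lin"]
        # refit on all rows: near-exact on the training features
        pred = fitted.predict(ts.features)
        np.testing.assert_allclose(pred, ts.target_for("mA"), atol=1e-6)

    def test_linear_dynamics_recovered_with_tiny_cv_rmse(self):
        """Noise-free linear system: the linear candidate's CV RMSE ~ 0."""
        ts = _linear_training_set(noise=0.0)
        space = SearchSpace.single(Candidate("lin", _exact_linear, 1, 1))
        _, table = select_model(ts, "mA", space, seed=0)
        assert table.loc[0, "cv_rmse"] < 1e-6

    def test_true_family_wins_model_recovery(self):
        """Linear truth vs. kNN: the generative family wins across seeds."""
        space = SearchSpace((
            Candidate("lin", _exact_linear, 1, 1),
            Candidate("knn", _knn, 2, 1),
        ))
        wins = 0
        for seed in range(10):
            ts = _linear_training_set(noise=0.01, seed=seed)
            _, table = select_model(ts, "mA", space, seed=seed)
            wins += table.loc[0, "candidate"] == "lin"
        assert wins >= 9

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigurationError):
            SearchSpace(candidates=())

    def test_no_row_in_both_fold_sides(self):
        from pathdyn.learning import _cv_splits
        ts = _linear_training_set(n_strains=12, rows_per=10)
        for tr, te in _cv_splits(ts, 10, seed=0):
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == ts.n_rows

    def test_folds_group_whole_strains(self):
        from pathdyn.learning import _cv_splits
        ts = _linear_training_set(n_strains=5, rows_per=10)
        labels = ts.strain_labels
        for _, te in _cv_splits(ts, 10, seed=3):
            held_strains = set(labels[te])
            # every row of a held-out strain is in the test side
            for s in held_strains:
                assert np.all(np.isin(np.where(labels == s)[0], te))


class TestFitDynamics:
    def test_one_sub_model_per_pathway_metabolite(self, small_pool):
        ts = build_training_set(small_pool.series[:2], target_points=60)
        res = fit_dynamics(ts, seed=0)
        assert len(res.sub_models) == 10
        assert set(res.sub_models) == set(ts.metabolite_names)

    def test_zero_targets_give_zero_predictions(self):
        ts = _linear_training_set()
        zero = DerivativeTrainingSet(
            features=ts.features, targets=np.zeros_like(ts.targets),
            metabolite_names=ts.metabolite_names,
            protein_names=ts.protein_names, provenance=ts.provenance,
        )
        res = fit_dynamics(zero, seed=0)
        pred = res.predict(ts.features)
        np.testing.assert_allclose(pred, 0.0, atol=1e-8)

    def test_deterministic_under_fixed_seed(self, small_pool):
        ts = build_training_set(small_pool.series[:2], target_points=60)
        r1 = fit_dynamics(ts, seed=7)
        r2 = fit_dynamics(ts, seed=7)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        assert r1.winners.to_dict() == r2.winners.to_dict()

    def test_enlarging_space_never_worsens_winner(self):
        ts = _linear_training_set(noise=0.05)
        small = SearchSpace((Candidate("knn", _knn, 2, 1),))
        big = SearchSpace((Candidate("knn", _knn, 2, 1),
                           Candidate("lin", _exact_linear, 1, 1)))
        _, t_small = select_model(ts, "mA", small, seed=0)
        _, t_big = select_model(ts, "mA", big, seed=0)
        assert t_big["cv_rmse"].min() <= t_small["cv_rmse"].min() + 1e-12

    def test_summary_mentions_every_metabolite(self, small_pool):
        ts = build_training_set(small_pool.series[:2], target_points=60)
        res = fit_dynamics(ts, seed=0)
        text = res.summary()
        for met in ts.metabolite_names:
            assert met in text


class TestAssessDerivativeFit:
    def test_ten_repeats_give_ten_rows_per_metabolite(self):
        ts = _linear_training_set()
        res = fit_dynamics(ts, SearchSpace.single(
            Candidate("lin", _exact_linear, 1, 1)), seed=0)
        table = assess_derivative_fit(res, ts, repeats=10, seed=0)
        counts = table.groupby("metabolite").size()
        assert (counts == 10).all()

    def test_interpolator_scores_perfect_on_train_split(self):
        ts = _linear_training_set(noise=0.05)
        res = fit_dynamics(ts, SearchSpace.single(
            Candidate("knn1", lambda seed: Pipeline([
                ("reg", KNeighborsRegressor(n_neighbors=1))]), 1, 1)), seed=0)
        table = assess_derivative_fit(res, ts, repeats=3, seed=0)
        np.testing.assert_allclose(table["train_r2"], 1.0, atol=1e-9)

    def test_linear_truth_generalizes_on_test_split(self):
        ts = _linear_training_set(noise=0.0)
        res = fit_dynamics(ts, SearchSpace.single(
            Candidate("lin", _exact_linear, 1, 1)), seed=0)
        table = assess_derivative_fit(res, ts, repeats=5, seed=0)
        assert (table["test_r2"] > 0.99).all()


class TestPersistence:
    def test_bundle_round_trip(self, small_pool, tmp_path):
        ts = build_training_set(small_pool.series[:2], target_points=60)
        res = fit_dynamics(ts, seed=0)
        res.save(tmp_path / "bundle")
        back = MetabolicDynamicsResults.load(tmp_path / "bundle")
        X = ts.features[:17]
        np.testing.assert_allclose(back.predict(X), res.predict(X))
        assert back.metabolite_names == res.metabolite_names
        assert back.seed == res.seed

    def test_fast_predictor_matches_sklearn_pipelines(self, small_pool):
        ts = build_training_set(small_pool.series[:3], target_points=60)
        res = fit_dynamics(ts, seed=1)
        rng = np.random.default_rng(0)
        rows = ts.features[rng.choice(ts.n_rows, 15, replace=False)]
        slow = res.predict(rows)
        fast = np.stack([res.predict_derivative(r) for r in rows])
        np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-10)
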