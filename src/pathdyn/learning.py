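"""Learning the pathway vector field: per-metabolite regressor selection.

The supervised-learning problem: given state–derivative training pairs
(m, p) -> dm_j/dt assembled by :mod:`pathdyn.preprocess`, find for each
metabolite j the function f_j minimising the summed squared derivative
error over all training examples. Candidate scikit-learn pipelines are
scored by tenfold cross-validated RMSE and the winner is refit on all
training rows — independently for each metabolite, so the aggregate model
is a stack of n scalar regressors.

The public surface follows the model/results idiom: build a
:class:`MetabolicDynamics` model from a training set (or directly from
time series), call :meth:`~MetabolicDynamics.fit`, and work with the
returned :class:`MetabolicDynamicsResults` — prediction, trajectory
integration, persistence and the summary table all live there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, ShuffleSplit
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import (FunctionTransformer, PolynomialFeatures,
                                   StandardScaler)

from .exceptions import ConfigurationError, ValidationError
from .preprocess import DerivativeTrainingSet, build_training_set
from .timeseries import OmicsTimeSeries

__all__ = [
    "Candidate",
    "SearchSpace",
    "MetabolicDynamics",
    "MetabolicDynamicsResults",
    "select_model",
    "fit_dynamics",
    "assess_derivative_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """One entry of the model search space.

    ``build(seed)`` returns a fresh (unfitted) scikit-learn pipeline;
    ``n_steps`` and ``n_hyperparams`` feed the simplicity tie-break.
    """

    name: str
    build: "callable"
    n_steps: int
    n_hyperparams: int


def _seeded(est, seed):
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def _make_linear(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("reg", Ridge(alpha=1e-2)),
    ])


def _make_poly_ridge(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("poly", PolynomialFeatures(degree=2, include_bias=False)),
        ("reg", Ridge(alpha=1.0)),
    ])


def _make_log_poly_ridge(seed):
    # log1p puts concentrations spanning decades on a natural scale
    return Pipeline([
        ("log", FunctionTransformer(np.log1p)),
        ("scale", StandardScaler()),
        ("poly", PolynomialFeatures(degree=2, include_bias=False)),
        ("reg", Ridge(alpha=3.0)),
    ])


def _make_knn(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("reg", KNeighborsRegressor(n_neighbors=5, weights="distance")),
    ])


def _make_log_knn(seed):
    return Pipeline([
        ("log", FunctionTransformer(np.log1p)),
        ("scale", StandardScaler()),
        ("reg", KNeighborsRegressor(n_neighbors=5, weights="distance")),
    ])


def _make_forest(seed):
    return Pipeline([
        ("reg", _seeded(RandomForestRegressor(
            n_estimators=30, min_samples_leaf=2, n_jobs=1), seed)),
    ])


def _make_gbr(seed):
    return Pipeline([
        ("reg", _seeded(GradientBoostingRegressor(
            n_estimators=100, max_depth=3, learning_rate=0.1), seed)),
    ])


def _make_kernel_ridge(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("reg", KernelRidge(kernel="rbf", alpha=1e-3, gamma=0.1)),
    ])


_DEFAULT_CANDIDATES: tuple[Candidate, ...] = (
    Candidate("ridge", _make_linear, 2, 1),
    Candidate("poly2-ridge", _make_poly_ridge, 3, 2),
    Candidate("log-poly2-ridge", _make_log_poly_ridge, 4, 2),
    Candidate("knn", _make_knn, 2, 2),
    Candidate("log-knn", _make_log_knn, 3, 2),
)

_EXTENDED_CANDIDATES: tuple[Candidate, ...] = _DEFAULT_CANDIDATES + (
    Candidate("random-forest", _make_forest, 1, 2),
    Candidate("gradient-boosting", _make_gbr, 1, 3),
    Candidate("kernel-ridge", _make_kernel_ridge, 2, 3),
)


@dataclass(frozen=True)
class SearchSpace:
    """Candidate regressor families and the strategy for searching them.

    The default space is a small curated set of classical families —
    ridge, quadratic polynomial ridge (raw and log1p-scaled features), and
    distance-weighted nearest-neighbours (raw and log1p-scaled) — searched
    exhaustively; :meth:`extended` adds a compact random forest, gradient
    boosting and an RBF kernel ridge. ``strategy`` may be
    ``"exhaustive"`` (score every candidate) or ``"random"`` (score
    ``budget`` candidates drawn without replacement). An evolutionary
    backend can be plugged in by supplying custom candidates produced by an
    external optimiser; the selection contract is unchanged — argmin of
    tenfold CV RMSE.
    """

    candidates: tuple[Candidate, ...] = _DEFAULT_CANDIDATES
    strategy: str = "exhaustive"
    budget: int = 10**9
    folds: int = 10

    def __post_init__(self):
        if not self.candidates:
            raise ConfigurationError("search space must contain at least one candidate")
        if self.strategy not in ("exhaustive", "random"):
            raise ConfigurationError(f"unknown search strategy {self.strategy!r}")
        if self.budget < 1:
            raise ConfigurationError("budget must be >= 1 evaluation")
        if self.folds < 2:
            raise ConfigurationError("need at least 2 CV folds")

    @classmethod
    def default(cls, folds: int = 10) -> "SearchSpace":
        return cls(folds=folds)

    @classmethod
    def extended(cls, folds: int = 10) -> "SearchSpace":
        return cls(candidates=_EXTENDED_CANDIDATES, folds=folds)

    @classmethod
    def single(cls, candidate: Candidate, folds: int = 10) -> "SearchSpace":
        return cls(candidates=(candidate,), folds=folds)

    def draw(self, rng: np.random.Generator) -> tuple[Candidate, ...]:
        if self.strategy == "exhaustive":
            return self.candidates
        k = min(self.budget, len(self.candidates))
        idx = rng.choice(len(self.candidates), size=k, replace=False)
        return tuple(self.candidates[i] for i in sorted(idx))


def _cv_splits(train: DerivativeTrainingSet, folds: int, seed: int):
    """Fold assignment groups rows by strain (leave-strains-out CV).

    All of one strain's rows land in the same fold: scoring a candidate on a
    held-out fold then measures transfer to unseen strains, which is what
    trajectory prediction requires. Augmented time points from one strain are
    near-duplicates, so row-shuffled folds would reward pure interpolators
    regardless of their cross-strain behaviour. With fewer strains than the
    requested folds the count drops to one fold per strain (leave-one-strain-
    out); single-strain training sets fall back to shuffled row folds.
    """
    n = train.n_rows
    if min(folds, n) < 2:
        raise ValidationError("need at least 2 training rows for cross-validation")
    strains = train.strain_labels
    codes, uniques = pd.factorize(strains)
    n_strains = len(uniques)
    if n_strains < 2:
        splitter = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
        return list(splitter.split(train.features))
    n_folds = min(folds, n_strains)
    rng = np.random.default_rng(seed)
    fold_of_strain = rng.permutation(n_strains) % n_folds
    fold_of_row = fold_of_strain[codes]
    idx = np.arange(n)
    return [
        (idx[fold_of_row != f], idx[fold_of_row == f]) for f in range(n_folds)
    ]


def select_model(
    train: DerivativeTrainingSet,
    metabolite: str,
    space: SearchSpace | None = None,
    seed: int = 0,
) -> tuple[Pipeline, pd.DataFrame]:
    """Pick the best regressor for one metabolite's derivative target.

    Every candidate in the space is scored by its mean cross-validated RMSE
    (tenfold by default, folds grouping rows by strain; fewer folds when
    fewer strains, with a log message) on that metabolite's derivative
    column. The winner — ties broken by fewer
    pipeline steps, then fewer hyperparameters, then declaration order — is
    refit on all training rows. Returns the fitted pipeline and the
    candidate score table.
    """
    space = space or SearchSpace.default()
    y = train.target_for(metabolite)
    X = train.features
    splits = _cv_splits(train, space.folds, seed)
    if len(splits) < space.folds:
        logger.info("reduced CV folds from %d to %d", space.folds, len(splits))
    rng = np.random.default_rng(seed)
    rows = []
    for order, cand in enumerate(space.draw(rng)):
        sq_errs = []
        for tr_idx, te_idx in splits:
            est = cand.build(seed)
            est.fit(X[tr_idx], y[tr_idx])
            resid = est.predict(X[te_idx]) - y[te_idx]
            sq_errs.append(float(np.sqrt(np.mean(resid**2))))
        rows.append({
            "candidate": cand.name,
            "cv_rmse": float(np.mean(sq_errs)),
            "cv_rmse_std": float(np.std(sq_errs)),
            "n_steps": cand.n_steps,
            "n_hyperparams": cand.n_hyperparams,
            "order": order,
            "_cand": cand,
        })
    table = pd.DataFrame(rows).sort_values(
        ["cv_rmse", "n_steps", "n_hyperparams", "order"]
    ).reset_index(drop=True)
    winner: Candidate = table.loc[0, "_cand"]
    fitted = winner.build(seed)
    fitted.fit(X, y)
    return fitted, table.drop(columns="_cand")


class MetabolicDynamics:
    """Model object: the vector-field learning problem for one pathway.

    Parameters
    ----------
    training_set : DerivativeTrainingSet
        State–derivative pairs covering all pathway metabolites.
    space : SearchSpace, optional
        Candidate regressors; defaults to the curated classical set.
    """

    def __init__(self, training_set: DerivativeTrainingSet,
                 space: SearchSpace | None = None):
        self.training_set = training_set
        self.space = space or SearchSpace.default()

    @classmethod
    def from_timeseries(
        cls,
        strains: list[OmicsTimeSeries],
        space: SearchSpace | None = None,
        window: int = 7,
        polyorder: int = 2,
        target_points: int = 200,
        augment: bool = True,
    ) -> "MetabolicDynamics":
        """Build the model straight from raw multiomics time series."""
        ts = build_training_set(strains, window=window, polyorder=polyorder,
                                target_points=target_points, augment=augment)
        return cls(ts, space)

    def fit(self, seed: int = 0) -> "MetabolicDynamicsResults":
        """Run model selection for every metabolite and refit the winners.

        Deterministic under a fixed seed: fold assignment, candidate draws
        and any stochastic regressor all derive from it.
        """
        sub_models: dict[str, Pipeline] = {}
        tables = []
        failures = []
        for metabolite in self.training_set.metabolite_names:
            try:
                fitted, table = select_model(self.training_set, metabolite,
                                             self.space, seed)
            except Exception as exc:  # aggregate per-metabolite failures
                failures.append((metabolite, exc))
                continue
            sub_models[metabolite] = fitted
            table = table.assign(metabolite=metabolite)
            tables.append(table)
        if failures:
            details = "; ".join(f"{m}: {e}" for m, e in failures)
            raise ValidationError(f"model search failed for metabolites [{details}]")
        scores = pd.concat(tables, ignore_index=True)
        return MetabolicDynamicsResults(
            model=self,
            sub_models=sub_models,
            scores=scores,
            seed=seed,
        )


@dataclass
class MetabolicDynamicsResults:
    """Fitted vector field: one regressor per metabolite, plus diagnostics.

    Treat as immutable once returned by :meth:`MetabolicDynamics.fit`. The
    per-metabolite winners and their cross-validation score tables are in
    ``scores``; ``predict`` evaluates the learned f on feature rows and
    ``predict_trajectory`` integrates it forward for an unseen strain.
    """

    model: MetabolicDynamics
    sub_models: dict[str, Pipeline]
    scores: pd.DataFrame
    seed: int
    _fast: list | None = field(default=None, repr=False)

    # -- introspection -------------------------------------------------

    @property
    def metabolite_names(self) -> tuple[str, ...]:
        return self.model.training_set.metabolite_names

    @property
    def protein_names(self) -> tuple[str, ...]:
        return self.model.training_set.protein_names

    @property
    def winners(self) -> pd.Series:
        """Selected candidate name per metabolite."""
        best = self.scores.sort_values(
            ["metabolite", "cv_rmse", "n_steps", "n_hyperparams", "order"]
        ).groupby("metabolite", sort=False).first()
        return best["candidate"]

    @property
    def cv_rmse(self) -> pd.Series:
        best = self.scores.sort_values(
            ["metabolite", "cv_rmse", "n_steps", "n_hyperparams", "order"]
        ).groupby("metabolite", sort=False).first()
        return best["cv_rmse"]

    @property
    def training_feature_max(self) -> np.ndarray:
        """Per-feature maximum over the training rows (divergence ceiling base)."""
        return np.max(np.abs(self.model.training_set.features), axis=0)

    @property
    def training_target_max(self) -> np.ndarray:
        """Per-metabolite maximum |derivative| over the training targets."""
        return np.max(np.abs(self.model.training_set.targets), axis=0)

    @property
    def training_target_range(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-metabolite (min, max) of the training derivative targets."""
        t = self.model.training_set.targets
        return np.min(t, axis=0), np.max(t, axis=0)

    def summary(self) -> str:
        """Human-readable fit report."""
        best = pd.DataFrame({"winner": self.winners, "cv_rmse": self.cv_rmse})
        lines = [
            "Metabolic dynamics fit",
            "=" * 54,
            f"training rows:      {self.model.training_set.n_rows}",
            f"feature dimension:  {self.model.training_set.features.shape[1]}"
            f" ({len(self.metabolite_names)} metabolites + "
            f"{len(self.protein_names)} proteins)",
            f"strains:            {len(np.unique(self.model.training_set.strain_labels))}",
            f"seed:               {self.seed}",
            "-" * 54,
            f"{'metabolite':<20}{'winner':<20}{'CV RMSE':>12}",
            "-" * 54,
        ]
        for met in self.metabolite_names:
            lines.append(f"{met:<20}{best.loc[met, 'winner']:<20}"
                         f"{best.loc[met, 'cv_rmse']:>12.4g}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- prediction ----------------------------------------------------

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predicted derivatives for feature rows; shape (rows, n_metabolites)."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        out = np.column_stack([
            self.sub_models[m].predict(X) for m in self.metabolite_names
        ])
        if not np.all(np.isfinite(out)):
            raise ValidationError("non-finite derivative prediction")
        return out

    def _fast_predictors(self) -> list:
        """Low-overhead single-row predictors (used inside ODE integration).

        Bypasses sklearn Pipeline dispatch: StandardScaler and degree-2
        PolynomialFeatures steps are applied with plain numpy, then the
        terminal estimator is called directly.
        """
        if self._fast is None:
            object.__setattr__(self, "_fast", [
                _compile_pipeline(self.sub_models[m]) for m in self.metabolite_names
            ])
        return self._fast

    def predict_derivative(self, x: np.ndarray) -> np.ndarray:
        """Learned f evaluated at a single concatenated (m, p) state."""
        x = np.asarray(x, dtype=float)
        return np.array([fp(x) for fp in self._fast_predictors()])

    def predict_trajectory(self, proteins: OmicsTimeSeries, m0: np.ndarray,
                           times: np.ndarray, **kwargs):
        from .predict import predict_trajectory
        return predict_trajectory(self, proteins, m0, times, **kwargs)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Persist as a versioned bundle directory (joblib models + manifest)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for met, est in self.sub_models.items():
            joblib.dump(est, path / f"model_{self.metabolite_names.index(met)}.joblib")
        manifest = {
            "format_version": "1",
            "metabolite_names": list(self.metabolite_names),
            "protein_names": list(self.protein_names),
            "seed": self.seed,
            "winners": self.winners.to_dict(),
            "cv_rmse": {k: float(v) for k, v in self.cv_rmse.items()},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        self.scores.to_csv(path / "scores.csv", index=False)
        joblib.dump(self.model.training_set, path / "training_set.joblib")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MetabolicDynamicsResults":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        training_set = joblib.load(path / "training_set.joblib")
        model = MetabolicDynamics(training_set)
        sub_models = {
            met: joblib.load(path / f"model_{i}.joblib")
            for i, met in enumerate(manifest["metabolite_names"])
        }
        scores = pd.read_csv(path / "scores.csv")
        return cls(model=model, sub_models=sub_models, scores=scores,
                   seed=manifest["seed"])


def _compile_pipeline(pipe: Pipeline):
    """Build a fast single-row predictor for a fitted pipeline."""
    steps = []
    for name, step in pipe.steps[:-1]:
        if isinstance(step, StandardScaler):
            mean, scale = step.mean_.copy(), step.scale_.copy()
            steps.append(lambda x, m=mean, s=scale: (x - m) / s)
        elif isinstance(step, PolynomialFeatures):
            powers = step.powers_
            steps.append(lambda x, P=powers: np.prod(x**P, axis=1))
        elif isinstance(step, FunctionTransformer):
            fn = step.func or (lambda a: a)
            steps.append(lambda x, f=fn: f(x))
        elif hasattr(step, "get_support"):  # feature selectors
            mask = step.get_support()
            steps.append(lambda x, m=mask: x[m])
        else:  # fall back to the transformer itself
            steps.append(lambda x, t=step: t.transform(x[None, :])[0])
    final = pipe.steps[-1][1]
    if isinstance(final, Ridge):
        coef, intercept = final.coef_.copy(), float(final.intercept_)

        def predictor(x, _steps=tuple(steps), c=coef, b=intercept):
            for s in _steps:
                x = s(x)
            return float(x @ c + b)
    elif isinstance(final, KNeighborsRegressor):
        from scipy.spatial import cKDTree

        tree = cKDTree(np.asarray(final._fit_X))
        y_fit = np.asarray(final._y, dtype=float)
        k = final.n_neighbors
        weighted = final.weights == "distance"

        def predictor(x, _steps=tuple(steps), tree=tree, y=y_fit, k=k,
                      weighted=weighted):
            for s in _steps:
                x = s(x)
            dist, idx = tree.query(x, k=k)
            if not weighted:
                return float(np.mean(y[idx]))
            if dist[0] == 0.0:
                return float(y[idx[0]])
            w = 1.0 / dist
            return float(np.dot(w, y[idx]) / np.sum(w))
    else:
        def predictor(x, _steps=tuple(steps), est=final):
            for s in _steps:
                x = s(x)
            return float(est.predict(x[None, :])[0])
    return predictor


def fit_dynamics(train: DerivativeTrainingSet, space: SearchSpace | None = None,
                 seed: int = 0) -> MetabolicDynamicsResults:
    """Functional entry point: fit the full vector field from a training set."""
    return MetabolicDynamics(train, space).fit(seed=seed)


def assess_derivative_fit(
    results: MetabolicDynamicsResults,
    data: DerivativeTrainingSet,
    repeats: int = 10,
    seed: int = 0,
    test_size: float = 0.25,
) -> pd.DataFrame:
    """Repeated shuffle-split assessment of derivative-level accuracy.

    The winning pipeline family per metabolite is refit on each train split
    and scored by Pearson R^2 of predicted vs. estimated derivatives on both
    splits. Returns one row per (metabolite, repeat) with train/test R^2.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    splitter = ShuffleSplit(n_splits=repeats, test_size=test_size, random_state=seed)
    rows = []
    X = data.features
    for rep, (tr, te) in enumerate(splitter.split(X)):
        for met in data.metabolite_names:
            y = data.target_for(met)
            est = clone(results.sub_models[met])
            est.fit(X[tr], y[tr])
            row = {"metabolite": met, "repeat": rep}
            for label, idx in (("train", tr), ("test", te)):
                pred = est.predict(X[idx])
                if np.std(pred) == 0 or np.std(y[idx]) == 0:
                    r2 = np.nan
                else:
                    r2 = pearsonr(pred, y[idx]).statistic ** 2
                row[f"{label}_r2"] = float(r2)
            rows.append(row)
    return pd.DataFrame(rows)
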