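"""Prediction-quality metrics and the ranking / scaling experiments.

The headline metric is the integral trajectory RMSE

    RMSE = sqrt( (1/n) * sum_j \\int_{t0}^{tf} ( mbar_j(t) - m_j(t) )^2 dt )

where ``mbar_j`` interpolates the reference (measured or simulated) series
and ``m_j`` is the prediction; the integral is evaluated by the trapezoid
rule on a common dense grid. Percent error is reported per metabolite as
the time-averaged absolute error normalised by the time-averaged reference
magnitude, times 100 — note that absolute percent-error numbers depend on
this normalisation choice.

Two experiments quantify how performance scales with training-set size on a
pool of virtual strains sharing kinetic constants:

* :func:`ranking_experiment` — can a model trained on a few strains order
  random (high, medium, low) triples of unseen strains by final product?
  A random ranker succeeds with probability 1/6.
* :func:`scaling_experiment` — trajectory RMSE on a fixed held-out strain
  as training size grows, repeated over independent training draws.
"""

from __future__ import annotations

import logging
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import DivergenceError, IncompatibilityError, ValidationError
from .learning import SearchSpace, fit_dynamics
from .predict import TrajectoryPrediction, predict_trajectory
from .preprocess import build_training_set
from .simulator import StrainPool
from .timeseries import OmicsTimeSeries

__all__ = [
    "trajectory_rmse",
    "percent_error",
    "ranking_experiment",
    "scaling_experiment",
    "random_ranking_baseline",
]

logger = logging.getLogger(__name__)


def _as_series_like(obj):
    if isinstance(obj, TrajectoryPrediction):
        return obj.times, obj.metabolites, tuple(obj.metabolite_names)
    if isinstance(obj, OmicsTimeSeries):
        return obj.times, obj.metabolites, tuple(obj.metabolite_names)
    raise ValidationError(f"cannot evaluate object of type {type(obj).__name__}")


def _interp(times, values, grid):
    """Columnwise interpolation: cubic spline when enough points, else linear."""
    if len(times) >= 4:
        return CubicSpline(times, values, axis=0)(grid)
    out = np.empty((len(grid), values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(grid, times, values[:, j])
    return out


def _common_grid(t_pred, t_ref, grid_points):
    t0 = max(t_pred[0], t_ref[0])
    tf = min(t_pred[-1], t_ref[-1])
    if tf <= t0:
        raise IncompatibilityError(
            f"prediction span [{t_pred[0]}, {t_pred[-1]}] and reference span "
            f"[{t_ref[0]}, {t_ref[-1]}] do not overlap"
        )
    return np.linspace(t0, tf, grid_points)


def trajectory_rmse(
    predicted, reference, grid_points: int = 1001
) -> tuple[float, pd.Series]:
    """Integral trajectory RMSE between a prediction and a reference series.

    Returns ``(total, per_metabolite)`` where each per-metabolite component
    is sqrt(integral of the squared pointwise difference over the common
    span) and the total is the root of their mean square.
    """
    tp, mp, names_p = _as_series_like(predicted)
    tr, mr, names_r = _as_series_like(reference)
    if set(names_p) != set(names_r):
        raise IncompatibilityError("prediction and reference metabolite names differ")
    grid = _common_grid(tp, tr, grid_points)
    pred = _interp(tp, mp, grid)
    ref = _interp(tr, mr, grid)
    # align reference columns to prediction order
    order = [names_r.index(n) for n in names_p]
    diff2 = (ref[:, order] - pred) ** 2
    per_met_sq = np.trapezoid(diff2, grid, axis=0)
    per_met = pd.Series(np.sqrt(per_met_sq), index=list(names_p), name="rmse")
    total = float(np.sqrt(np.mean(per_met_sq)))
    return total, per_met


def percent_error(predicted, reference, grid_points: int = 1001) -> pd.Series:
    """Per-metabolite percent error.

    Time-averaged absolute deviation divided by the time-averaged reference
    magnitude, times 100. Metabolites whose reference is identically zero
    are undefined (NaN) and should be excluded from averages.
    """
    tp, mp, names_p = _as_series_like(predicted)
    tr, mr, names_r = _as_series_like(reference)
    if set(names_p) != set(names_r):
        raise IncompatibilityError("prediction and reference metabolite names differ")
    grid = _common_grid(tp, tr, grid_points)
    pred = _interp(tp, mp, grid)
    ref = _interp(tr, mr, grid)[:, [names_r.index(n) for n in names_p]]
    mean_abs_err = np.mean(np.abs(ref - pred), axis=0)
    mean_ref = np.mean(np.abs(ref), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mean_ref > 0, 100.0 * mean_abs_err / mean_ref, np.nan)
    return pd.Series(pct, index=list(names_p), name="percent_error")


def random_ranking_baseline(n_triples: int, seed: int | None = None) -> float:
    """Monte-Carlo success rate of ranking triples by a uniformly random order.

    The analytic value is 1/6: a random permutation of three distinct
    producers matches the true full order with probability 1/3!.
    """
    rng = np.random.default_rng(seed)
    perms = np.array(list(permutations(range(3))))
    truth = rng.random((n_triples, 3)).argsort(axis=1)
    guess = perms[rng.integers(0, 6, n_triples)]
    return float(np.mean(np.all(truth == guess, axis=1)))


def _derived_seed(seed: int, *parts: int) -> int:
    """Stable sub-seed below 2**31 from a base seed and context integers."""
    ss = np.random.SeedSequence([int(seed), *map(int, parts)])
    return int(ss.generate_state(1)[0] % (2**31))


def _predict_final_product(results, pool: StrainPool, idx: int,
                           product: str = "limonene",
                           rtol: float = 1e-4, atol: float = 1e-7) -> float:
    series = pool.series[idx]
    try:
        pred = predict_trajectory(results, series, series.metabolites[0], series.times,
                                  rtol=rtol, atol=atol)
    except DivergenceError as exc:
        logger.warning("prediction diverged for strain %s: %s", series.strain_id, exc)
        return np.nan
    return float(pred.metabolite(product)[-1])


def _rank_order(values: np.ndarray) -> tuple:
    # stable argsort: ties (measure zero) break by position, i.e. strain order
    return tuple(np.argsort(values, kind="stable"))


def ranking_experiment(
    pool: StrainPool,
    train_sizes: list[int],
    repeats: int = 10,
    triples: int = 10,
    space: SearchSpace | None = None,
    seed: int = 0,
    target_points: int = 200,
    product: str = "limonene",
    rtol: float = 1e-4,
    atol: float = 1e-7,
) -> pd.DataFrame:
    """Production-ranking success rate vs. training-set size.

    For each training size and repeat: sample that many training strains
    from the pool, fit the dynamics, then for ``triples`` random triples of
    unseen strains predict each strain's final product by forward
    integration and score a triple as a success only if the complete
    predicted order (low < medium < high) matches the truth. A diverged
    prediction counts the triple as a failure. Also reports the
    top-producer failure rate (wrong argmax only).

    Returns one row per (size, repeat) with columns ``success_rate`` and
    ``top_failure_rate``; aggregate with a groupby over ``train_size``.
    """
    space = space or SearchSpace.default()
    if len(pool) < max(train_sizes) + 3:
        raise ValidationError("pool too small for requested training sizes + triples")
    truth = pool.final_products
    records = []
    for size in train_sizes:
        for rep in range(repeats):
            rng = np.random.default_rng(_derived_seed(seed, size, rep))
            train_idx = rng.choice(len(pool), size=size, replace=False)
            train_set = build_training_set(
                [pool.series[i] for i in train_idx], target_points=target_points
            )
            results = fit_dynamics(train_set, space, seed=_derived_seed(seed, size, rep, 1))
            test_idx = np.setdiff1d(np.arange(len(pool)), train_idx)
            predicted_final: dict[int, float] = {}
            n_success = n_top_fail = 0
            for _ in range(triples):
                triple = rng.choice(test_idx, size=3, replace=False)
                for i in triple:
                    if i not in predicted_final:
                        predicted_final[i] = _predict_final_product(
                            results, pool, i, product, rtol=rtol, atol=atol
                        )
                preds = np.array([predicted_final[i] for i in triple])
                if np.any(~np.isfinite(preds)):
                    n_top_fail += 1
                    continue
                true_vals = truth[triple]
                if _rank_order(preds) == _rank_order(true_vals):
                    n_success += 1
                if int(np.argmax(preds)) != int(np.argmax(true_vals)):
                    n_top_fail += 1
            records.append({
                "train_size": size,
                "repeat": rep,
                "n_triples": triples,
                "success_rate": n_success / triples,
                "top_failure_rate": n_top_fail / triples,
            })
    return pd.DataFrame(records)


def scaling_experiment(
    pool: StrainPool,
    train_sizes: list[int],
    repeats: int = 10,
    space: SearchSpace | None = None,
    seed: int = 0,
    target_points: int = 200,
    heldout_index: int | None = None,
    prediction_grid_points: int = 73,
    rtol: float = 1e-4,
    atol: float = 1e-7,
) -> pd.DataFrame:
    """Trajectory RMSE on a fixed held-out strain vs. training-set size.

    One pool strain is held out for the whole experiment (never sampled for
    training); for each size and repeat, a fresh training set is drawn, the
    dynamics refit, and the held-out strain's trajectory predicted from its
    protein series and initial metabolite observation. Returns one row per
    (size, repeat) with the integral RMSE (NaN if the prediction diverged).
    """
    space = space or SearchSpace.default()
    if len(pool) < max(train_sizes) + 1:
        raise ValidationError("pool too small for requested training sizes")
    rng0 = np.random.default_rng(_derived_seed(seed, 0xE))
    heldout = int(rng0.integers(len(pool))) if heldout_index is None else heldout_index
    reference = pool.series[heldout]
    candidates = np.setdiff1d(np.arange(len(pool)), [heldout])
    t_dense = np.linspace(reference.times[0], reference.times[-1],
                          prediction_grid_points)
    records = []
    for size in train_sizes:
        for rep in range(repeats):
            rng = np.random.default_rng(_derived_seed(seed, size, rep))
            train_idx = rng.choice(candidates, size=size, replace=False)
            train_set = build_training_set(
                [pool.series[i] for i in train_idx], target_points=target_points
            )
            results = fit_dynamics(train_set, space,
                                   seed=_derived_seed(seed, size, rep, 1))
            try:
                pred = predict_trajectory(
                    results, reference, reference.metabolites[0], t_dense,
                    rtol=rtol, atol=atol,
                )
                rmse, _ = trajectory_rmse(pred, reference)
            except DivergenceError as exc:
                logger.warning("size=%d repeat=%d diverged: %s", size, rep, exc)
                rmse = np.nan
            records.append({
                "train_size": size,
                "repeat": rep,
                "heldout": reference.strain_id,
                "rmse": rmse,
            })
    return pd.DataFrame(records)
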