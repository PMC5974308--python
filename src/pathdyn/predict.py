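"""Trajectory prediction: integrate the learned vector field forward.

Given a fitted :class:`~pathdyn.learning.MetabolicDynamicsResults`, an
unseen strain's protein time series, and that strain's initial metabolite
observation, solve the initial value problem

    dm/dt = f(m, p(t)),    m(t0) = observed m(t0)

with adaptive RK45. Protein concentrations at interior solver times come
from a continuous interpolant of the provided series (cubic spline, clipped
at zero). Because the learned regressors are unconstrained, the state passed
to f is clipped at zero (events counted), predicted derivatives are clipped
to the per-metabolite training-target interval expanded by one span on each
side (regressors that extrapolate polynomially can otherwise return rates
orders of magnitude beyond anything physical), and integration aborts with a
:class:`~pathdyn.exceptions.DivergenceError` if any state exceeds a ceiling
of 10^6 times that feature's training-data maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DivergenceError, ExtrapolationError, ValidationError
from scipy.interpolate import CubicSpline, PchipInterpolator
from .timeseries import OmicsTimeSeries

__all__ = ["TrajectoryPrediction", "interpolate_proteins", "predict_trajectory"]

DIVERGENCE_FACTOR = 1e6


@dataclass(frozen=True)
class TrajectoryPrediction:
    """A predicted metabolite trajectory with integrator diagnostics."""

    strain_id: str
    times: np.ndarray
    metabolites: np.ndarray  # (s, n)
    metabolite_names: tuple[str, ...]
    n_rhs_evals: int
    n_clip_events: int

    def metabolite(self, name: str) -> np.ndarray:
        return self.metabolites[:, self.metabolite_names.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.metabolites[-1]

    def to_series(self) -> OmicsTimeSeries:
        """View as a (metabolomics-only) time series for evaluation / export."""
        return OmicsTimeSeries(
            strain_id=self.strain_id,
            times=self.times,
            metabolites=np.clip(self.metabolites, 0.0, None),
            proteins=np.empty((len(self.times), 0)),
            metabolite_names=self.metabolite_names,
            protein_names=(),
        )


def interpolate_proteins(series: OmicsTimeSeries):
    """Continuous protein evaluator p(t) on the observed span.

    Cubic-spline interpolation of each protein column, clipped at zero (a
    monotone scheme replaces the spline for columns that overshoot below
    zero, consistent with the augmentation interpolant). Exact at observed
    times; raises :class:`ExtrapolationError` outside [t1, ts].
    """
    if series.n_times < 2:
        raise ValidationError("need at least 2 time points to interpolate proteins")
    t_lo, t_hi = series.span
    times = series.times
    values = series.proteins
    # build per-column interpolants once; spline unless it dips below zero,
    # then the monotone-preserving scheme (same policy as augmentation)
    interpolants = []
    probe = np.linspace(t_lo, t_hi, max(4 * series.n_times, 64))
    for j in range(values.shape[1]):
        if series.n_times >= 4:
            f = CubicSpline(times, values[:, j])
            if np.any(f(probe) < 0):
                f = PchipInterpolator(times, values[:, j])
        else:
            f = lambda t, _t=times, _v=values[:, j]: np.interp(t, _t, _v)
        interpolants.append(f)

    def evaluator(t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < t_lo - 1e-9) or np.any(t_arr > t_hi + 1e-9):
            raise ExtrapolationError(
                f"protein series spans [{t_lo}, {t_hi}] h; queried at {t}"
            )
        t_arr = np.clip(t_arr, t_lo, t_hi)
        out = np.clip(np.stack([f(t_arr) for f in interpolants], axis=1),
                      0.0, None)
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    evaluator.span = (t_lo, t_hi)
    return evaluator


def predict_trajectory(
    results,
    proteins: OmicsTimeSeries,
    m0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    divergence_factor: float = DIVERGENCE_FACTOR,
    derivative_cap_factor: float | None = 1.0,
) -> TrajectoryPrediction:
    """Predict a full metabolite trajectory for an unseen strain.

    Parameters
    ----------
    results : MetabolicDynamicsResults
        The fitted vector field.
    proteins : OmicsTimeSeries
        The strain's protein observations (its metabolite block is ignored);
        must span the requested output grid.
    m0 : array of length n
        Initial metabolite observation m(t0); the prediction starts exactly
        there.
    times : array
        Output grid, within the protein series' span.
    """
    times = np.asarray(times, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    n = len(results.metabolite_names)
    if len(m0) != n:
        raise ValidationError(f"m0 must have length {n}, got {len(m0)}")
    if tuple(proteins.protein_names) != tuple(results.protein_names):
        raise ValidationError("protein series names do not match the fitted model")
    t_lo, t_hi = proteins.span
    if times[0] < t_lo - 1e-9 or times[-1] > t_hi + 1e-9:
        raise ExtrapolationError(
            f"output grid [{times[0]}, {times[-1]}] outside protein span [{t_lo}, {t_hi}]"
        )

    # dense protein interpolant, sampled once on a fine grid for cheap lookup
    p_of_t = interpolate_proteins(proteins)
    dense_t = np.linspace(t_lo, t_hi, 2001)
    dense_p = p_of_t(dense_t)

    ceiling = divergence_factor * np.maximum(results.training_feature_max[:n], 1e-12)
    if derivative_cap_factor is not None:
        # clip rates to the observed training-target interval, expanded by
        # derivative_cap_factor spans on each side
        tgt_lo, tgt_hi = results.training_target_range
        span = np.maximum(tgt_hi - tgt_lo, 1e-12)
        rate_lo = tgt_lo - derivative_cap_factor * span
        rate_hi = tgt_hi + derivative_cap_factor * span
    else:
        rate_lo = rate_hi = None
    counters = {"rhs": 0, "clip": 0, "last_t": float(times[0])}

    def f(t, m):
        counters["rhs"] += 1
        if np.any(np.abs(m) > ceiling):
            raise DivergenceError(
                f"state exceeded divergence ceiling at t={t:.3f} h",
                last_valid_time=counters["last_t"],
            )
        clipped = np.clip(m, 0.0, None)
        if np.any(clipped != m):
            counters["clip"] += 1
        counters["last_t"] = float(t)
        p = np.array([np.interp(t, dense_t, dense_p[:, j])
                      for j in range(dense_p.shape[1])])
        dm = results.predict_derivative(np.concatenate([clipped, p]))
        if rate_lo is not None:
            dm = np.clip(dm, rate_lo, rate_hi)
        return dm

    sol = solve_ivp(f, (times[0], times[-1]), m0, method="RK45",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise DivergenceError(
            f"integration failed: {sol.message}", last_valid_time=counters["last_t"]
        )
    return TrajectoryPrediction(
        strain_id=proteins.strain_id,
        times=times,
        metabolites=np.clip(sol.y.T, 0.0, None),
        metabolite_names=tuple(results.metabolite_names),
        n_rhs_evals=counters["rhs"],
        n_clip_events=counters["clip"],
    )
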