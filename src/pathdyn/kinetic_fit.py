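"""Baseline comparator: fit the Michaelis–Menten model's constants to data.

The handcrafted kinetic model of the limonene pathway has 22 free constants
(catalytic capacities, substrate affinities, and the acetyl-CoA supply).
:class:`KineticFit` estimates them from one or more strains' multiomics time
series by global optimisation: candidate parameter vectors are simulated
against each strain's observed protein profiles and scored by the summed
squared deviation between simulated and observed metabolite trajectories at
the observed times. Optimisation uses differential evolution over the
parameter box — by default the deliberately wide [1e-12, 1e9] — searched in
log10 space, since a 21-decade box is not navigable on a linear scale.
Candidate simulations that fail receive a large finite penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import differential_evolution

from .exceptions import DivergenceError, FitFailureError, ValidationError
from .predict import TrajectoryPrediction, interpolate_proteins
from .simulator import DEFAULT_BOUNDS, PARAMETER_NAMES, KineticModel, KineticParameters
from .timeseries import OmicsTimeSeries

__all__ = ["KineticFit", "KineticFitResults", "compare_ml_vs_kinetic",
           "simulate_with_observed_proteins"]

PENALTY = 1e12


def simulate_with_observed_proteins(
    model: KineticModel,
    strain: OmicsTimeSeries,
    times: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TrajectoryPrediction:
    """Integrate a kinetic model driven by a strain's observed protein series.

    Protein concentrations at interior solver times come from the same
    cubic-spline interpolant used for learned-model prediction; the initial
    metabolite state is the strain's first observation.
    """
    times = strain.times if times is None else np.asarray(times, dtype=float)
    p_of_t = interpolate_proteins(strain)
    m0 = strain.metabolites[0]
    # presample the interpolant once; linear lookup inside the RHS
    dense_t = np.linspace(times[0], times[-1], 2001)
    dense_p = p_of_t(dense_t)
    dt = dense_t[1] - dense_t[0] if len(dense_t) > 1 else 1.0

    def protein_at(t):
        x = (t - dense_t[0]) / dt
        i = min(max(int(x), 0), len(dense_t) - 2)
        w = x - i
        return (1.0 - w) * dense_p[i] + w * dense_p[i + 1]

    def f(t, m):
        return model.rhs(t, np.clip(m, 0.0, None), protein_at(float(t)))

    sol = solve_ivp(f, (times[0], times[-1]), m0, method="RK45",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise DivergenceError(f"kinetic simulation failed: {sol.message}")
    return TrajectoryPrediction(
        strain_id=strain.strain_id,
        times=times,
        metabolites=np.clip(sol.y.T, 0.0, None),
        metabolite_names=tuple(model.metabolite_names),
        n_rhs_evals=int(sol.nfev),
        n_clip_events=0,
    )


class KineticFit:
    """Model object: kinetic constants to be fitted to strain data.

    Parameters
    ----------
    strains : list of OmicsTimeSeries
        Training strains; each must carry the full metabolite and protein
        species sets of the pathway model.
    bounds : (lo, hi) or dict, optional
        Box constraints per constant; a single pair applies to every
        constant. Defaults to [1e-12, 1e9].
    """

    def __init__(
        self,
        strains: list[OmicsTimeSeries],
        bounds: tuple[float, float] | dict[str, tuple[float, float]] | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ):
        self.rtol = rtol
        self.atol = atol
        if not strains:
            raise ValidationError("at least one training strain required")
        self.strains = list(strains)
        if bounds is None:
            bounds = DEFAULT_BOUNDS
        if isinstance(bounds, tuple):
            bounds = {name: bounds for name in PARAMETER_NAMES}
        for name, (lo, hi) in bounds.items():
            if not (0 < lo < hi):
                raise ValidationError(f"bounds for {name} must satisfy 0 < lo < hi")
        self.bounds = {name: bounds[name] for name in PARAMETER_NAMES}

    def objective(self, params: KineticParameters) -> float:
        """Summed squared trajectory misfit across training strains."""
        model = KineticModel(params)
        total = 0.0
        for strain in self.strains:
            try:
                sim = simulate_with_observed_proteins(model, strain,
                                                      rtol=self.rtol,
                                                      atol=self.atol)
            except (DivergenceError, ValueError):
                return PENALTY
            resid = sim.metabolites - strain.metabolites
            if not np.all(np.isfinite(resid)):
                return PENALTY
            total += float(np.sum(resid**2))
        return total

    def _clipped_params(self, x: np.ndarray) -> KineticParameters:
        # 10**log10(bound) can land one ulp outside the box; clip back in
        theta = 10.0**np.asarray(x, dtype=float)
        lo = np.array([self.bounds[n][0] for n in PARAMETER_NAMES])
        hi = np.array([self.bounds[n][1] for n in PARAMETER_NAMES])
        return KineticParameters.from_vector(np.clip(theta, lo, hi), self.bounds)

    def _objective_log10(self, x: np.ndarray) -> float:
        return self.objective(self._clipped_params(x))

    def fit(
        self,
        seed: int = 0,
        maxiter: int = 30,
        popsize: int = 10,
        polish: bool = False,
        tol: float = 1e-10,
    ) -> "KineticFitResults":
        """Run differential evolution over the log10-parameter box.

        ``maxiter=0`` evaluates only the initial population and returns its
        best member. Deterministic under a fixed seed.
        """
        log_bounds = [tuple(np.log10(self.bounds[n])) for n in PARAMETER_NAMES]
        trace: list[float] = []

        best_holder = {"f": np.inf}

        def wrapped(x):
            f = self._objective_log10(x)
            if f < best_holder["f"]:
                best_holder["f"] = f
            return f

        def callback(xk, convergence=None):
            trace.append(best_holder["f"])

        result = differential_evolution(
            wrapped, log_bounds, seed=seed, maxiter=max(maxiter, 0),
            popsize=popsize, polish=polish, tol=tol, init="sobol",
            callback=callback, updating="immediate",
        )
        if not np.isfinite(result.fun) or result.fun >= PENALTY:
            raise FitFailureError("all candidate simulations diverged")
        params = self._clipped_params(result.x)
        return KineticFitResults(
            model=self,
            params=params,
            objective_value=float(result.fun),
            trace=trace,
            n_evaluations=int(result.nfev),
            converged=bool(result.success),
            seed=seed,
        )


@dataclass
class KineticFitResults:
    """Best-fit kinetic constants and optimiser diagnostics."""

    model: KineticFit
    params: KineticParameters
    objective_value: float
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    converged: bool = False
    seed: int = 0

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return self.model.bounds

    def predict_trajectory(self, strain: OmicsTimeSeries,
                           times: np.ndarray | None = None) -> TrajectoryPrediction:
        """Simulate the fitted model for a strain's observed protein profiles."""
        return simulate_with_observed_proteins(
            KineticModel(self.params), strain, times
        )

    def summary(self) -> str:
        lines = [
            "Kinetic model fit (differential evolution, log10 box)",
            "=" * 56,
            f"training strains:   {len(self.model.strains)}",
            f"objective (SSE):    {self.objective_value:.6g}",
            f"evaluations:        {self.n_evaluations}",
            f"generations traced: {len(self.trace)}",
            f"converged:          {self.converged}",
            "-" * 56,
            f"{'constant':<22}{'value':>14}{'bounds':>18}",
            "-" * 56,
        ]
        for name in PARAMETER_NAMES:
            lo, hi = self.bounds[name]
            lines.append(f"{name:<22}{self.params[name]:>14.5g}"
                         f"{f'[{lo:g}, {hi:g}]':>18}")
        lines.append("=" * 56)
        return "\n".join(lines)


def compare_ml_vs_kinetic(
    ml_results, kinetic_results: KineticFitResults, test_strain: OmicsTimeSeries,
    prediction_grid_points: int = 73,
) -> pd.DataFrame:
    """Paired evaluation of the learned and kinetic models on one held-out strain.

    Both predictors start from the strain's first metabolite observation and
    are driven by the same observed protein profiles; the table reports the
    integral trajectory RMSE and the mean percent error for each.
    """
    from .evaluate import percent_error, trajectory_rmse
    from .predict import predict_trajectory

    t_dense = np.linspace(test_strain.times[0], test_strain.times[-1],
                          prediction_grid_points)
    rows = {}
    ml_pred = predict_trajectory(ml_results, test_strain,
                                 test_strain.metabolites[0], t_dense)
    kin_pred = kinetic_results.predict_trajectory(test_strain, t_dense)
    for label, pred in (("machine-learning", ml_pred), ("kinetic", kin_pred)):
        total, _ = trajectory_rmse(pred, test_strain)
        pct = percent_error(pred, test_strain)
        rows[label] = {
            "rmse": total,
            "mean_percent_error": float(np.nanmean(pct.to_numpy())),
        }
    return pd.DataFrame(rows).T
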