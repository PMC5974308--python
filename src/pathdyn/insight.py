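"""Biological-insight analysis: production-aligned proteomics directions.

Given final-time-point proteomics for a collection of (real or model-
generated) strains and their final product titres, a two-block partial
least squares (PLS) regression finds the directions in proteomics phase
space that best covary with production. Component 1 is the over/under-
expression recipe: its loading signs say which enzymes to push up or down,
and stepping a base strain's expression profiles along it proposes new
strains whose full metabolite trajectories the learned dynamics model can
then predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .exceptions import DegenerateResponseError, ValidationError
from .predict import TrajectoryPrediction, predict_trajectory
from .timeseries import OmicsTimeSeries

__all__ = ["InsightResult", "pls_production_directions", "propose_and_simulate"]


@dataclass(frozen=True)
class InsightResult:
    """PLS projection of final-time proteomics against production.

    ``loadings`` (l x k) are unit-norm weight vectors in *standardised*
    protein coordinates; ``scores`` (q x k) are the centred, standardised
    proteomics projected on them. ``column_mean``/``column_std`` record the
    standardisation so directions can be mapped back to raw units.
    """

    scores: np.ndarray
    loadings: np.ndarray
    protein_names: tuple[str, ...]
    production: np.ndarray
    column_mean: np.ndarray
    column_std: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def component_table(self, component: int = 0) -> pd.DataFrame:
        """Proteins ranked by |loading| on a component, with expression signs."""
        w = self.loadings[:, component]
        df = pd.DataFrame({
            "protein": list(self.protein_names),
            "loading": w,
            "direction": np.where(w >= 0, "overexpress", "underexpress"),
        })
        return df.reindex(df["loading"].abs().sort_values(ascending=False).index
                          ).reset_index(drop=True)

    def raw_direction(self, component: int = 0) -> np.ndarray:
        """Component direction mapped back to raw concentration units."""
        return self.loadings[:, component] * self.column_std


def pls_production_directions(
    final_proteomics: np.ndarray,
    production: np.ndarray,
    protein_names: tuple[str, ...],
    n_components: int = 2,
    standardize: bool = True,
) -> InsightResult:
    """PLS regression of final production on final-time proteomics.

    Proteomics columns are standardised (zero mean, unit variance) before
    the fit, since enzyme abundances span scales; pass ``standardize=False``
    to work in raw (centred-only) coordinates. Returns unit-normalised
    weight vectors (loadings), the per-strain scores, and the production
    vector for plotting.
    """
    X = np.asarray(final_proteomics, dtype=float)
    y = np.asarray(production, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("proteomics matrix and production vector mismatch")
    if X.shape[0] < n_components + 1:
        raise ValidationError(
            f"need at least {n_components + 1} strains for {n_components} components"
        )
    if X.shape[1] != len(protein_names):
        raise ValidationError("protein_names length does not match matrix width")
    if np.std(y) == 0:
        raise DegenerateResponseError("production vector is constant")
    mean = X.mean(axis=0)
    if standardize:
        std = X.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)
    else:
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, y)
    W = pls.x_weights_ / np.linalg.norm(pls.x_weights_, axis=0, keepdims=True)
    scores = Xs @ W
    return InsightResult(
        scores=scores,
        loadings=W,
        protein_names=tuple(protein_names),
        production=y.copy(),
        column_mean=mean,
        column_std=std,
    )


def propose_and_simulate(
    results,
    base_strain: OmicsTimeSeries,
    direction: np.ndarray,
    step_sizes: list[float],
    m0: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> list[TrajectoryPrediction]:
    """Propose strains along a proteomics direction and predict their dynamics.

    For each step size, the base strain's final-time protein targets are
    displaced by ``step * direction`` (raw units, clipped at zero) and each
    protein's entire expression profile is scaled multiplicatively to hit
    the displaced final value — so a proposed strain keeps the base strain's
    expression shapes but shifted amplitudes. The learned dynamics model
    then predicts all metabolite trajectories for each proposed strain.
    """
    direction = np.asarray(direction, dtype=float)
    if len(direction) != base_strain.n_proteins:
        raise ValidationError("direction length must equal the number of proteins")
    m0 = base_strain.metabolites[0] if m0 is None else np.asarray(m0, dtype=float)
    times = base_strain.times if times is None else np.asarray(times, dtype=float)
    base_final = base_strain.proteins[-1]
    predictions = []
    for step in step_sizes:
        target_final = np.clip(base_final + step * direction, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(base_final > 0, target_final / base_final, 1.0)
        proposed = base_strain.with_values(proteins=base_strain.proteins * scale)
        proposed = OmicsTimeSeries(
            strain_id=f"{base_strain.strain_id}+step{step:g}",
            times=proposed.times,
            metabolites=proposed.metabolites,
            proteins=proposed.proteins,
            metabolite_names=proposed.metabolite_names,
            protein_names=proposed.protein_names,
        )
        predictions.append(predict_trajectory(results, proposed, m0, times))
    return predictions
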