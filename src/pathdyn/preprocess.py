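"""Smoothing, augmentation and state–derivative training-set construction.

Sparse noisy observations (typically seven samples over a 72 h fermentation)
are turned into supervised-learning examples in three steps:

1. **Smooth** every metabolite and protein column with a Savitzky–Golay
   filter (default window 7, polynomial order 2; with seven samples this is
   a single global quadratic fit, the filter's degenerate case).
2. **Augment** by interpolating the filtered curves onto a dense uniform
   grid (default 200 points) spanning the observed window — multiplying
   training examples without extrapolating beyond the data.
3. **Differentiate** the metabolite columns by central differences on the
   (possibly nonuniform) grid, one-sided at the two endpoints, giving the
   derivative targets dm/dt.

Stacking the concatenated (m, p) feature rows against the derivative targets
across all training strains yields one training example per retained time
point per strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.signal import savgol_filter

from .exceptions import (
    DegenerateGridError,
    InsufficientPointsError,
    SchemaError,
    ValidationError,
)
from .timeseries import OmicsTimeSeries

__all__ = [
    "smooth_series",
    "estimate_derivatives",
    "augment_series",
    "build_training_set",
    "interpolate_columns",
    "DerivativeTrainingSet",
    "DEFAULT_WINDOW",
    "DEFAULT_POLYORDER",
    "DEFAULT_TARGET_POINTS",
]

DEFAULT_WINDOW = 7
DEFAULT_POLYORDER = 2
DEFAULT_TARGET_POINTS = 200


@dataclass(frozen=True)
class DerivativeTrainingSet:
    """Paired state–derivative training examples across strains.

    ``features`` holds concatenated (metabolite, protein) concentration rows
    of width n + l; ``targets`` the estimated metabolite derivatives (one
    column per metabolite); ``provenance`` records the (strain, time) origin
    of every row so cross-validation can be audited.
    """

    features: np.ndarray
    targets: np.ndarray
    metabolite_names: tuple[str, ...]
    protein_names: tuple[str, ...]
    provenance: pd.DataFrame  # columns: strain, time

    def __post_init__(self):
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValidationError("feature and target row counts differ")
        if self.features.shape[0] != len(self.provenance):
            raise ValidationError("provenance rows do not match feature rows")
        n, l = len(self.metabolite_names), len(self.protein_names)
        if self.features.shape[1] != n + l:
            raise ValidationError(
                f"feature width {self.features.shape[1]} != n + l = {n + l}"
            )
        if self.targets.shape[1] != n:
            raise ValidationError("one target column per metabolite required")
        if not (np.all(np.isfinite(self.features)) and np.all(np.isfinite(self.targets))):
            raise ValidationError("training set contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"met:{n}" for n in self.metabolite_names) + tuple(
            f"prot:{n}" for n in self.protein_names
        )

    @property
    def strain_labels(self) -> np.ndarray:
        return self.provenance["strain"].to_numpy()

    def target_for(self, metabolite: str) -> np.ndarray:
        return self.targets[:, self.metabolite_names.index(metabolite)]


def smooth_series(
    series: OmicsTimeSeries,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> OmicsTimeSeries:
    """Savitzky–Golay smooth every species column; times unchanged.

    The filter fits a local polynomial of the given order in a sliding
    window of ``window`` samples. Window must be odd, larger than the
    polynomial order, and no larger than the number of samples. Smoothed
    values are clipped at zero (filter overshoot can dip below a physical
    concentration floor).
    """
    s = series.n_times
    if window > s:
        raise InsufficientPointsError(
            f"window {window} exceeds the {s} available time points"
        )
    if window % 2 == 0 or window <= polyorder:
        raise ValidationError("window must be odd and greater than polyorder")
    mets = np.clip(savgol_filter(series.metabolites, window, polyorder, axis=0), 0.0, None)
    prots = series.proteins
    if prots.shape[1]:
        prots = np.clip(savgol_filter(prots, window, polyorder, axis=0), 0.0, None)
    return series.with_values(metabolites=mets, proteins=prots)


def estimate_derivatives(smoothed: OmicsTimeSeries) -> np.ndarray:
    """Estimate metabolite derivatives dm/dt at every time point.

    Interior points use the nonuniform-grid central-difference formula
    (second-order accurate); the two endpoints use one-sided differences so
    every time point keeps a training example. Returns an (s, n) matrix.
    """
    if smoothed.n_times < 3:
        raise InsufficientPointsError("need at least 3 time points to differentiate")
    if np.any(np.diff(smoothed.times) == 0):
        raise DegenerateGridError("duplicate time values in grid")
    return np.gradient(smoothed.metabolites, smoothed.times, axis=0)


def interpolate_columns(
    times: np.ndarray, values: np.ndarray, new_times: np.ndarray
) -> np.ndarray:
    """Columnwise cubic-spline interpolation, nonnegativity-safe.

    Columns whose cubic spline overshoots below zero are re-interpolated
    with a monotone-preserving (PCHIP) scheme; any residual negatives are
    clipped at zero.
    """
    out = np.empty((len(new_times), values.shape[1]))
    for j in range(values.shape[1]):
        col = CubicSpline(times, values[:, j])(new_times)
        if np.any(col < 0):
            col = PchipInterpolator(times, values[:, j])(new_times)
        out[:, j] = col
    return np.clip(out, 0.0, None)


def augment_series(
    series: OmicsTimeSeries,
    target_points: int = DEFAULT_TARGET_POINTS,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    smooth: bool = True,
) -> OmicsTimeSeries:
    """Expand a sparse series onto a dense uniform grid.

    The series is Savitzky–Golay filtered, then every column is
    interpolated over the filtered curve onto a uniform grid of exactly
    ``target_points`` points spanning the observed window — the original
    endpoints are preserved and no value is extrapolated.
    """
    if target_points < series.n_times:
        raise ValidationError(
            f"target_points={target_points} below the {series.n_times} observed points"
        )
    base = smooth_series(series, window, polyorder) if smooth else series
    new_times = np.linspace(series.times[0], series.times[-1], target_points)
    mets = interpolate_columns(base.times, base.metabolites, new_times)
    if base.proteins.shape[1]:
        prots = interpolate_columns(base.times, base.proteins, new_times)
    else:
        prots = np.empty((target_points, 0))
    return series.with_values(times=new_times, metabolites=mets, proteins=prots)


def build_training_set(
    training_strains: list[OmicsTimeSeries],
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    target_points: int = DEFAULT_TARGET_POINTS,
    augment: bool = True,
) -> DerivativeTrainingSet:
    """Assemble state–derivative pairs from a list of training strains.

    Each strain is smoothed and (optionally) augmented to ``target_points``
    points, then differentiated on the augmented grid; feature rows and
    derivative targets are stacked across strains with provenance recorded.
    All strains must share identical species name sets.
    """
    if not training_strains:
        raise ValidationError("at least one training strain required")
    ref = training_strains[0]
    feats, targs, prov_strain, prov_time = [], [], [], []
    for s in training_strains:
        if (s.metabolite_names != ref.metabolite_names
                or s.protein_names != ref.protein_names):
            raise SchemaError(
                f"strain {s.strain_id!r} species names differ from {ref.strain_id!r}"
            )
        if augment:
            dense = augment_series(s, target_points, window, polyorder)
        else:
            dense = smooth_series(s, min(window, s.n_times if s.n_times % 2 else s.n_times - 1), polyorder)
        deriv = estimate_derivatives(dense)
        feats.append(dense.features())
        targs.append(deriv)
        prov_strain.extend([s.strain_id] * dense.n_times)
        prov_time.extend(dense.times.tolist())
    return DerivativeTrainingSet(
        features=np.vstack(feats),
        targets=np.vstack(targs),
        metabolite_names=ref.metabolite_names,
        protein_names=ref.protein_names,
        provenance=pd.DataFrame({"strain": prov_strain, "time": prov_time}),
    )
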