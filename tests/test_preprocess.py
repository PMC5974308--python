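"""Smoothing, derivative estimation, augmentation, training-set assembly."""

import numpy as np
import pytest

from pathdyn.exceptions import (
    InsufficientPointsError,
    SchemaError,
    ValidationError,
)
from pathdyn.preprocess import (
    DerivativeTrainingSet,
    augment_series,
    build_training_set,
    estimate_derivatives,
    smooth_series,
)
from pathdyn.timeseries import OmicsTimeSeries


def _series(times, cols, strain="s", prot_cols=None):
    cols = np.atleast_2d(np.asarray(cols, dtype=float))
    if cols.shape[0] != len(times):
        cols = cols.T
    prots = (np.empty((len(times), 0)) if prot_cols is None
             else np.atleast_2d(np.asarray(prot_cols, dtype=float)))
    return OmicsTimeSeries(
        strain_id=strain, times=np.asarray(times, dtype=float),
        metabolites=cols, proteins=prots,
        metabolite_names=tuple(f"m{i}" for i in range(cols.shape[1])),
        protein_names=tuple(f"p{i}" for i in range(prots.shape[1])),
    )


class TestSmoothing:
    def test_constant_column_unchanged(self):
        t = np.linspace(0, 72, 7)
        s = _series(t, np.full((7, 1), 3.5))
        out = smooth_series(s, window=7, polyorder=2)
        np.testing.assert_allclose(out.metabolites, 3.5)

    def test_exact_quadratic_reproduced(self):
        t = np.linspace(0, 72, 7)
        quad = 0.001 * t**2 + 0.05 * t + 1.0
        out = smooth_series(_series(t, quad[:, None]), window=7, polyorder=2)
        np.testing.assert_allclose(out.metabolites[:, 0], quad, rtol=1e-10)

    def test_noise_reduction_on_quadratic(self):
        """Monte-Carlo: smoothing reduces MSE vs. the true quadratic."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 72, 7)
        truth = 0.001 * t**2 + 0.05 * t + 1.0
        improved = 0
        for _ in range(100):
            noisy = np.clip(truth + rng.normal(0, 0.1, 7), 0, None)
            sm = smooth_series(_series(t, noisy[:, None]), 7, 2).metabolites[:, 0]
            if np.mean((sm - truth) ** 2) < np.mean((noisy - truth) ** 2):
                improved += 1
        assert improved > 80  # strictly smaller on average, allow a few flips

    def test_window_exceeding_points_rejected(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(InsufficientPointsError):
            smooth_series(_series(t, np.ones((5, 1))), window=7, polyorder=2)

    def test_even_window_rejected(self):
        t = np.linspace(0, 10, 6)
        with pytest.raises(ValidationError):
            smooth_series(_series(t, np.ones((6, 1))), window=4, polyorder=2)


class TestDerivatives:
    def test_linear_series_exact_everywhere(self):
        t = np.linspace(0, 10, 6)
        d = estimate_derivatives(_series(t, (3.0 * t)[:, None]))
        np.testing.assert_allclose(d[:, 0], 3.0)

    def test_quadratic_exact_at_interior_points(self):
        t = np.linspace(0, 10, 11)
        d = estimate_derivatives(_series(t, (t**2)[:, None]))
        np.testing.assert_allclose(d[1:-1, 0], 2.0 * t[1:-1], rtol=1e-12)

    def test_matches_kinetic_rhs_on_dense_noise_free_simulation(
            self, kinetic_model, dense_reference_strain):
        """Finite differences on a dense simulated grid track the true RHS."""
        s = dense_reference_strain
        d = estimate_derivatives(s)
        true = np.stack([
            kinetic_model.rhs(t, m, p)
            for t, m, p in zip(s.times, s.metabolites, s.proteins)
        ])
        # compare where fluxes are well above the discretisation floor
        floor = 0.05 * np.max(np.abs(true))
        mask = np.abs(true[1:-1]) > floor
        rel = np.abs(d[1:-1][mask] - true[1:-1][mask]) / np.abs(true[1:-1][mask])
        assert np.median(rel) < 0.05

    def test_shift_invariance(self):
        t = np.linspace(0, 10, 8)
        vals = np.sin(t)[:, None] + 1.0
        d0 = estimate_derivatives(_series(t, vals))
        d1 = estimate_derivatives(_series(t + 100.0, vals))
        np.testing.assert_allclose(d0, d1)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientPointsError):
            estimate_derivatives(_series([0.0, 1.0], np.ones((2, 1))))


class TestAugmentation:
    def test_seven_points_expand_to_exactly_200(self, reference_strain):
        dense = augment_series(reference_strain, target_points=200)
        assert dense.n_times == 200
        assert dense.times[0] == reference_strain.times[0]
        assert dense.times[-1] == reference_strain.times[-1]

    def test_identity_grid_preserved(self):
        t = np.linspace(0, 72, 7)
        s = _series(t, (0.1 * t)[:, None])
        out = augment_series(s, target_points=7)
        np.testing.assert_allclose(out.times, t)

    def test_never_extrapolates(self, reference_strain):
        dense = augment_series(reference_strain, target_points=150)
        assert dense.times.min() >= reference_strain.times[0]
        assert dense.times.max() <= reference_strain.times[-1]
        assert np.all(dense.metabolites >= 0)

    def test_interpolation_consistent_with_noise_free_input(
            self, dense_reference_strain):
        """Doubling the grid of a dense noise-free series preserves values."""
        s = dense_reference_strain
        out = augment_series(s, target_points=2 * s.n_times, smooth=False)
        for j in range(s.n_metabolites):
            back = np.interp(s.times, out.times, out.metabolites[:, j])
            scale = np.max(np.abs(s.metabolites[:, j])) + 1e-12
            assert np.max(np.abs(back - s.metabolites[:, j])) < 0.01 * scale

    def test_fewer_target_points_than_observations_rejected(self, reference_strain):
        with pytest.raises(ValidationError):
            augment_series(reference_strain, target_points=3)


class TestBuildTrainingSet:
    def test_two_strains_give_400_rows(self, small_pool):
        ts = build_training_set(small_pool.series[:2], target_points=200)
        assert ts.n_rows == 400
        assert ts.features.shape[1] == 19  # 10 metabolites + 9 proteins
        assert ts.targets.shape == (400, 10)

    def test_augmentation_disabled_keeps_original_rows(self, reference_strain):
        ts = build_training_set([reference_strain], augment=False)
        assert ts.n_rows == reference_strain.n_times == 7

    def test_provenance_tracks_strains(self, small_pool):
        ts = build_training_set(small_pool.series[:3], target_points=50)
        assert set(ts.strain_labels) == {s.strain_id for s in small_pool.series[:3]}
        assert ts.n_rows == 150

    def test_inconsistent_species_rejected(self, reference_strain):
        other = _series(np.linspace(0, 72, 7), np.ones((7, 1)))
        with pytest.raises(SchemaError):
            build_training_set([reference_strain, other])

    def test_pipeline_deterministic(self, small_pool):
        a = build_training_set(small_pool.series[:2])
        b = build_training_set(small_pool.series[:2])
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.targets, b.targets)

    def test_mismatched_row_counts_rejected(self):
        import pandas as pd
        with pytest.raises(ValidationError):
            DerivativeTrainingSet(
                features=np.ones((3, 2)), targets=np.ones((2, 1)),
                metabolite_names=("m",), protein_names=("p",),
                provenance=pd.DataFrame({"strain": ["a"] * 3,
                                         "time": [0.0, 1.0, 2.0]}),
            )
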