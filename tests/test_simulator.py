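"""Kinetic ground-truth model: Hill profiles, integration, pool generation."""

import numpy as np
import pytest

from pathdyn.exceptions import InvalidParameterError, ValidationError
from pathdyn.simulator import (
    DEFAULT_INITIAL_METABOLITES,
    METABOLITES,
    PROTEINS,
    HillProteinParams,
    KineticModel,
    KineticParameters,
    generate_pool,
    hill_profile,
    reference_parameters,
    simulate_strain,
)


class TestHillProfile:
    @pytest.mark.parametrize("t, expected", [(0.0, 0.5), (1.0, 1.5)])
    def test_closed_form_values(self, t, expected):
        # p(t) = k_f t/(k_m + t) + k_l: leak at t=0, half-saturation at t=k_m
        p = HillProteinParams(k_f=2.0, k_m=1.0, k_l=0.5)
        assert hill_profile(p, np.array([t]))[0] == pytest.approx(expected)

    def test_saturates_monotonically_toward_kf_plus_kl(self):
        p = HillProteinParams(k_f=2.0, k_m=1.0, k_l=0.5)
        t = np.linspace(0.0, 5000.0, 400)
        vals = hill_profile(p, t)
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] < 2.5
        assert vals[-1] == pytest.approx(2.5, rel=1e-3)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(InvalidParameterError):
            HillProteinParams(k_f=1.0, k_m=0.0, k_l=0.0)


class TestKineticParameters:
    def test_default_bounds_are_wide_box(self):
        params = reference_parameters()
        assert all(b == (1e-12, 1e9) for b in params.bounds.values())

    def test_out_of_bounds_rejected(self):
        vals = dict(reference_parameters().values)
        vals["LS_kcat"] = 1e10
        with pytest.raises(InvalidParameterError):
            KineticParameters(vals)

    def test_nonpositive_rejected(self):
        vals = dict(reference_parameters().values)
        vals["LS_kcat"] = 0.0
        with pytest.raises(InvalidParameterError):
            KineticParameters(vals)


class TestSimulateStrain:
    def test_no_enzymes_no_supply_keeps_state_constant(self):
        vals = dict(reference_parameters().values)
        vals["acetyl_coa_supply"] = 1e-12
        vals["acetyl_coa_decay"] = 1e-12
        model = KineticModel(KineticParameters(vals))
        silent = {name: HillProteinParams(k_f=0.0, k_m=1.0, k_l=0.0)
                  for name in PROTEINS}
        s = simulate_strain(model, silent)
        expected = np.tile(DEFAULT_INITIAL_METABOLITES, (7, 1))
        np.testing.assert_allclose(s.metabolites, expected, atol=1e-7)

    def test_limonene_is_nondecreasing_terminal_sink(self, kinetic_model, ref_hill):
        s = simulate_strain(kinetic_model, ref_hill,
                            times=np.linspace(0.0, 72.0, 33))
        assert np.all(np.diff(s.metabolite("limonene")) >= -1e-10)

    def test_no_negative_concentrations(self, small_pool):
        for s in small_pool.series:
            assert np.all(s.metabolites >= 0)
            assert np.all(s.proteins >= 0)

    def test_negative_initial_state_rejected(self, kinetic_model, ref_hill):
        m0 = np.array(DEFAULT_INITIAL_METABOLITES)
        m0[0] = -0.1
        with pytest.raises(ValidationError):
            simulate_strain(kinetic_model, ref_hill, initial_metabolites=m0)

    def test_reference_dynamics_have_nonmonotonic_intermediate(
            self, dense_reference_strain):
        # IPP rises, peaks, then declines over the 72 h fermentation
        ipp = dense_reference_strain.metabolite("IPP")
        peak = int(np.argmax(ipp))
        assert 0 < peak < len(ipp) - 1
        assert ipp[peak] > 1.05 * ipp[-1]

    def test_adaptive_matches_fixed_step_rk4_oracle(self, kinetic_model, ref_hill):
        """Final state agrees with an independent fixed-step RK4 integration."""
        hp = [ref_hill[name] for name in PROTEINS]

        def p_of_t(t):
            return np.array([h.k_f * t / (h.k_m + t) + h.k_l for h in hp])

        def f(t, m):
            return kinetic_model.rhs(t, np.clip(m, 0.0, None), p_of_t(t))

        dt = 1e-3
        t_end = 12.0  # a short window keeps the oracle cheap but non-trivial
        m = np.array(DEFAULT_INITIAL_METABOLITES)
        n_steps = int(round(t_end / dt))
        t = 0.0
        for _ in range(n_steps):
            k1 = f(t, m)
            k2 = f(t + dt / 2, m + dt / 2 * k1)
            k3 = f(t + dt / 2, m + dt / 2 * k2)
            k4 = f(t + dt, m + dt * k3)
            m = m + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        s = simulate_strain(kinetic_model, ref_hill,
                            times=np.array([0.0, t_end]))
        adaptive = s.metabolites[-1]
        scale = np.max(np.abs(m))
        np.testing.assert_allclose(adaptive, m, atol=1e-3 * scale, rtol=1e-3)


class TestEnzymeScaling:
    def test_doubling_an_enzyme_scales_its_flux_linearly(self, kinetic_model):
        m = np.full(10, 0.2)
        p = np.full(9, 1.0)
        base = kinetic_model.fluxes(m, p)
        for i, name in enumerate(PROTEINS):
            p2 = p.copy()
            p2[i] = 2.0
            doubled = kinetic_model.fluxes(m, p2)
            if name == "Idi":  # net reversible flux still doubles
                assert doubled[name] == pytest.approx(2 * base[name])
            else:
                assert doubled[name] == pytest.approx(2 * base[name])
                assert doubled[name] >= base[name]


class TestGeneratePool:
    def test_pool_size_and_shared_constants(self, small_pool, kinetic_model):
        assert len(small_pool) == 12
        assert small_pool.model.params.values == kinetic_model.params.values

    def test_same_seed_reproduces_pool_exactly(self, kinetic_model):
        p1 = generate_pool(kinetic_model, 2, seed=42)
        p2 = generate_pool(kinetic_model, 2, seed=42)
        for a, b in zip(p1.series, p2.series):
            np.testing.assert_array_equal(a.metabolites, b.metabolites)
            np.testing.assert_array_equal(a.proteins, b.proteins)

    def test_different_seeds_differ(self, kinetic_model):
        p1 = generate_pool(kinetic_model, 1, seed=1)
        p2 = generate_pool(kinetic_model, 1, seed=2)
        assert not np.array_equal(p1.series[0].proteins, p2.series[0].proteins)

    def test_final_products_recorded(self, small_pool):
        finals = np.array([s.metabolite("limonene")[-1] for s in small_pool.series])
        np.testing.assert_array_equal(small_pool.final_products, finals)

    def test_metabolite_registry_matches_pathway(self, small_pool):
        assert small_pool.series[0].metabolite_names == METABOLITES
        assert small_pool.series[0].protein_names == PROTEINS
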