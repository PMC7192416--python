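"""GMA model construction, anchoring, rate evaluation and Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmaens import (
    ReferenceState,
    build_pathway,
    evaluate_rates,
    jacobian,
    mass_balance_rhs,
    rate_constants,
)
from gmaens.pipeline import make_fixture

from conftest import random_k


def _single_reaction_model(order=0.5):
    return build_pathway(
        {
            "species": [
                {"name": "s", "role": "independent", "value": 4.0},
                {"name": "p", "role": "dependent"},
            ],
            "reactions": [
                {"name": "v1", "stoichiometry": {"p": 1}, "orders": {"s": order}},
                {"name": "v2", "stoichiometry": {"p": -1}, "orders": {"p": 1.0}},
            ],
        }
    )


class TestBuildPathway:
    def test_case_study_design_space_partition(self, case_study):
        model, _ = case_study
        assert (model.n, model.m, model.r) == (3, 2, 4)
        # 12 design dimensions: 1 flux + 3 concentrations + 8 kinetic orders
        assert len(model.free_entries) == 8
        assert 1 + model.n + len(model.free_entries) == 12
        assert ("v1", "x3") in model.orders_free  # the feedback entry f_{1,3}
        assert model.entry_label("v1", "x3") == "f_1,3"

    def test_minimal_chain(self):
        model = _single_reaction_model()
        assert (model.n, model.r) == (1, 2)

    def test_undeclared_species_rejected(self):
        cfg = {
            "species": [{"name": "x1", "role": "dependent"}],
            "reactions": [{"name": "v1", "stoichiometry": {"x1": 1}, "orders": {"x9": 0.5}}],
        }
        with pytest.raises(ValueError, match="x9"):
            build_pathway(cfg)

    def test_empty_reaction_rejected(self):
        cfg = {
            "species": [{"name": "x1", "role": "dependent"}],
            "reactions": [{"name": "v1", "stoichiometry": {"x1": 1}, "orders": {}}],
        }
        with pytest.raises(ValueError, match="no kinetic orders"):
            build_pathway(cfg)

    def test_non_numeric_range_rejected(self):
        cfg = {
            "species": [{"name": "x1", "role": "dependent"}],
            "reactions": [
                {"name": "v1", "stoichiometry": {"x1": 1}, "orders": {"x1": ["a", 1]}}
            ],
        }
        with pytest.raises(ValueError, match="non-numeric"):
            build_pathway(cfg)


class TestAnchoring:
    def test_unit_reference_gives_flux_as_gamma(self, case_study, rng):
        model, _ = case_study
        ref = ReferenceState(
            v0=np.full(4, 31.5), x_d0=np.ones(3), x_i0=np.ones(2)
        )
        gamma = rate_constants(model, ref, random_k(model, rng))
        assert np.allclose(gamma.gamma, 31.5)

    def test_direct_substitution(self):
        model = _single_reaction_model(order=0.5)
        ref = ReferenceState(v0=np.array([8.0, 8.0]), x_d0=np.array([2.0]), x_i0=np.array([4.0]))
        gamma = rate_constants(model, ref, [])
        assert gamma.gamma[0] == pytest.approx(8.0 / 2.0)  # 8 / 4**0.5

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_reproduces_reference_flux(self, case_study, seed):
        """Anchored rates evaluated at the reference state return v0 exactly."""
        model, _ = case_study
        r = np.random.default_rng(seed)
        ref = ReferenceState(
            v0=np.full(4, 31.5),
            x_d0=np.exp(r.uniform(np.log(1e-4), np.log(10), 3)),
            x_i0=np.array([10.0, 1.0]),
        )
        k = random_k(model, r)
        gamma = rate_constants(model, ref, k)
        v = evaluate_rates(model, gamma, ref.x_d0, ref.x_i0, k=k)
        assert np.max(np.abs(v / ref.v0 - 1)) <= 1e-12

    def test_nonpositive_reference_rejected(self, case_study):
        model, _ = case_study
        with pytest.raises(ValueError):
            ReferenceState(v0=np.full(4, 31.5), x_d0=np.array([1.0, 0.0, 1.0]), x_i0=np.ones(2))


class TestRates:
    def test_power_law_value(self):
        model = _single_reaction_model(order=0.5)
        v = evaluate_rates(model, np.array([2.0, 1.0]), np.array([1.0]), np.array([4.0]), k=[])
        assert v[0] == pytest.approx(4.0)  # 2 * 4**0.5

    def test_zero_orders_give_constant_rate(self, case_study, rng):
        model, ref = case_study
        k = np.zeros(8)
        gamma = rate_constants(model, ref, k)
        v = evaluate_rates(model, gamma, rng.uniform(0.5, 5, 3), ref.x_i0, k=k)
        # f_{4,4}=1 is fixed, so only the demand step still sees a variable
        assert np.allclose(v[:3], gamma.gamma[:3])

    def test_end_product_inhibition_sign(self, case_study, rng):
        model, ref = case_study
        k = random_k(model, rng)
        gamma = rate_constants(model, ref, k)
        x = np.array([1.0, 1.0, 1.0])
        x2 = np.array([1.0, 1.0, 2.0])
        v1 = evaluate_rates(model, gamma, x, ref.x_i0, k=k)[0]
        v1_hi = evaluate_rates(model, gamma, x2, ref.x_i0, k=k)[0]
        assert v1_hi < v1  # doubling x3 throttles the inhibited first step

    def test_nonpositive_concentration_rejected(self, case_study, rng):
        model, ref = case_study
        k = random_k(model, rng)
        gamma = rate_constants(model, ref, k)
        with pytest.raises(ValueError):
            evaluate_rates(model, gamma, np.array([1.0, -1.0, 1.0]), ref.x_i0, k=k)


class TestMassBalance:
    def test_zero_at_anchored_reference(self, case_study, rng):
        model, ref = case_study
        k = random_k(model, rng)
        gamma = rate_constants(model, ref, k)
        rhs = mass_balance_rhs(model, gamma, ref.x_d0, ref.x_i0, k=k)
        assert np.max(np.abs(rhs)) < 1e-10

    def test_accumulation_when_inflow_exceeds_outflow(self):
        model = _single_reaction_model(order=0.0)
        # v1 = 2 (constant), v2 = 1 * x1: at x1 = 1 inflow exceeds outflow
        rhs = mass_balance_rhs(model, np.array([2.0, 1.0]), np.array([1.0]), np.array([4.0]), k=[])
        assert rhs[0] > 0


class TestJacobian:
    def test_linear_degradation_closed_form(self):
        # v1 = gamma1 (zero order), v2 = gamma2 * x1: J = [-v0/x1] at steady state
        model = _single_reaction_model(order=0.0)
        ref = ReferenceState(v0=np.array([6.0, 6.0]), x_d0=np.array([3.0]), x_i0=np.array([4.0]))
        gamma = rate_constants(model, ref, [])
        J = jacobian(model, gamma, ref.x_d0, ref.x_i0, k=[])
        assert J[0, 0] == pytest.approx(-6.0 / 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, case_study, seed):
        model, _ = case_study
        r = np.random.default_rng(seed)
        ref = ReferenceState(
            v0=np.full(4, 31.5), x_d0=r.uniform(0.5, 5.0, 3), x_i0=np.array([10.0, 1.0])
        )
        k = random_k(model, r)
        gamma = rate_constants(model, ref, k)
        J = jacobian(model, gamma, ref.x_d0, ref.x_i0, k=k)
        h = 1e-7
        for j in range(3):
            xp, xm = ref.x_d0.copy(), ref.x_d0.copy()
            xp[j] *= 1 + h
            xm[j] *= 1 - h
            fd = (
                mass_balance_rhs(model, gamma, xp, ref.x_i0, k=k)
                - mass_balance_rhs(model, gamma, xm, ref.x_i0, k=k)
            ) / (2 * h * ref.x_d0[j])
            assert np.max(np.abs(fd - J[:, j])) / max(np.max(np.abs(J[:, j])), 1.0) < 1e-6

    def test_finite_differences_on_random_small_chain(self):
        fix = make_fixture("chain-n", {"n": 4})
        model = fix["model"]
        r = np.random.default_rng(5)
        ref = ReferenceState(
            v0=np.full(model.r, 10.0), x_d0=r.uniform(0.5, 3.0, model.n),
            x_i0=np.ones(model.m),
        )
        k = random_k(model, r)
        gamma = rate_constants(model, ref, k)
        J = jacobian(model, gamma, ref.x_d0, ref.x_i0, k=k)
        h = 1e-7
        for j in range(model.n):
            xp, xm = ref.x_d0.copy(), ref.x_d0.copy()
            xp[j] *= 1 + h
            xm[j] *= 1 - h
            fd = (
                mass_balance_rhs(model, gamma, xp, ref.x_i0, k=k)
                - mass_balance_rhs(model, gamma, xm, ref.x_i0, k=k)
            ) / (2 * h * ref.x_d0[j])
            assert np.max(np.abs(fd - J[:, j])) < 1e-5 * max(np.max(np.abs(J)), 1.0)

    def test_homogeneity_in_gamma(self, case_study, rng):
        """Scaling all rate constants by c scales rates and Jacobian by c."""
        model, ref = case_study
        k = random_k(model, rng)
        gamma = rate_constants(model, ref, k)
        x = rng.uniform(0.5, 5.0, 3)
        c = 3.7
        v1 = evaluate_rates(model, gamma, x, ref.x_i0, k=k)
        v2 = evaluate_rates(model, c * gamma.gamma, x, ref.x_i0, k=k)
        J1 = jacobian(model, gamma, x, ref.x_i0, k=k)
        J2 = jacobian(model, c * gamma.gamma, x, ref.x_i0, k=k)
        assert np.allclose(v2, c * v1, rtol=1e-12)
        assert np.allclose(J2, c * J1, rtol=1e-12)
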