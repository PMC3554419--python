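"""Rate laws, steady states and time courses on the three-step toy pathway
(closed-form oracle) and the packaged glycolysis model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycotherm import (ConfigurationError, DomainError, RateLaw, Reaction,
                        evaluate_rate, mass_action_ratio, simulate,
                        solve_steady_state, toy_pathway)

TOY_A = 18.0 / 11.0          # steady state at S = 9 mM, closed form


def toy_concentrations(s=9.0):
    return {"S": s, "A": TOY_A, "B": TOY_A, "P": 0.0}


class TestEvaluateRate:
    def test_irreversible_mm_hand_value(self):
        law = RateLaw("irreversible_mm", 20.0, {"A": 2.0})
        rate = evaluate_rate(law, {"A": TOY_A}, scale=1.0)
        assert rate == pytest.approx(9.0, abs=1e-12)       # 20·(18/11)/(2+18/11)

    @pytest.mark.parametrize("kind,kwargs,conc", [
        ("irreversible_mm", dict(km_substrates={"A": 2.0}), {"A": 1.0, "B": 0.0}),
        ("reversible_mm", dict(km_substrates={"A": 1.0}, km_products={"B": 1.0},
                               keq_ref=2.0), {"A": 1.0, "B": 1.0}),
        ("facilitated_diffusion", dict(km_substrates={"A": 1.0}),
         {"A": 5.0, "B": 1.0}),
        ("mass_action", dict(keq_ref=2.0), {"A": 1.0, "B": 1.0}),
    ])
    def test_zero_scale_zeroes_any_law(self, kind, kwargs, conc):
        law = RateLaw(kind, 10.0, **kwargs)
        stoich = {"A": -1, "B": 1}
        assert evaluate_rate(law, conc, scale=0.0, stoichiometry=stoich) == 0.0

    def test_scale_multiplies_linearly(self):
        law = RateLaw("irreversible_mm", 20.0, {"A": 2.0})
        base = evaluate_rate(law, {"A": 1.0}, scale=1.0)
        assert evaluate_rate(law, {"A": 1.0}, scale=0.37) == pytest.approx(0.37 * base)

    def test_reversible_zero_at_equilibrium(self):
        law = RateLaw("reversible_mm", 10.0, {"A": 1.0}, {"B": 1.0}, keq_ref=2.0)
        stoich = {"A": -1, "B": 1}
        rate = evaluate_rate(law, {"A": 1.5, "B": 3.0}, stoichiometry=stoich)
        assert rate == pytest.approx(0.0, abs=1e-14)

    def test_rate_sign_follows_thermodynamic_bracket(self):
        law = RateLaw("reversible_mm", 10.0, {"A": 1.0}, {"B": 1.0}, keq_ref=2.0)
        stoich = {"A": -1, "B": 1}
        assert evaluate_rate(law, {"A": 1.0, "B": 1.0}, stoichiometry=stoich) > 0
        assert evaluate_rate(law, {"A": 1.0, "B": 4.0}, stoichiometry=stoich) < 0

    def test_missing_species_is_configuration_error(self):
        law = RateLaw("irreversible_mm", 20.0, {"A": 2.0})
        with pytest.raises(ConfigurationError):
            evaluate_rate(law, {"X": 1.0})

    def test_negative_concentration_is_domain_error(self):
        law = RateLaw("irreversible_mm", 20.0, {"A": 2.0})
        with pytest.raises(DomainError):
            evaluate_rate(law, {"A": -0.5})


class TestMassActionRatio:
    def test_uni_uni(self):
        rxn = Reaction("r", {"A": -1, "B": 1}, RateLaw("mass_action", 1.0))
        assert mass_action_ratio(rxn, {"A": 2.0, "B": 1.0}) == pytest.approx(0.5)

    def test_stoichiometric_exponents(self):
        rxn = Reaction("ald", {"FBP": -1, "TRIO": 2}, RateLaw("mass_action", 1.0))
        assert mass_action_ratio(rxn, {"FBP": 1.0, "TRIO": 2.0}) == pytest.approx(4.0)

    def test_gamma_equal_keq_gives_zero_rate(self):
        law = RateLaw("reversible_mm", 10.0, {"FBP": 0.3}, {"TRIO": 1.0}, keq_ref=4.0)
        rxn = Reaction("ald", {"FBP": -1, "TRIO": 2}, law)
        conc = {"FBP": 1.0, "TRIO": 2.0}
        assert mass_action_ratio(rxn, conc) == pytest.approx(law.keq_ref)
        assert evaluate_rate(law, conc, stoichiometry=rxn.stoichiometry) == \
            pytest.approx(0.0, abs=1e-14)

    def test_zero_substrate_signalled_distinctly(self):
        rxn = Reaction("r", {"A": -1, "B": 1}, RateLaw("mass_action", 1.0))
        with pytest.raises(DomainError, match="undefined"):
            mass_action_ratio(rxn, {"A": 0.0, "B": 1.0})


class TestSteadyState:
    def test_toy_closed_form(self):
        ss = solve_steady_state(toy_pathway(), {"S": 9.0, "P": 0.0})
        assert ss.concentrations["A"] == pytest.approx(TOY_A, abs=1e-8)
        assert ss.concentrations["B"] == pytest.approx(TOY_A, abs=1e-8)
        assert ss.fluxes["v1"] == pytest.approx(9.0, abs=1e-8)
        assert ss.residual_norm <= 1e-9

    def test_uniform_scaling_leaves_concentrations(self):
        """Shared capacity scaling cancels from the steady-state balance:
        concentrations are invariant while fluxes scale linearly."""
        toy = toy_pathway()
        scaled = solve_steady_state(toy, {"S": 9.0, "P": 0.0},
                                    scales={r.id: 0.5 for r in toy.reactions})
        assert scaled.concentrations["A"] == pytest.approx(TOY_A, rel=1e-8)
        assert scaled.fluxes["v1"] == pytest.approx(4.5, rel=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(r=st.floats(min_value=0.05, max_value=20.0),
           s=st.floats(min_value=0.5, max_value=50.0))
    def test_uniform_scaling_property(self, r, s):
        toy = toy_pathway()
        base = solve_steady_state(toy, {"S": s, "P": 0.0})
        scaled = solve_steady_state(toy, {"S": s, "P": 0.0},
                                    scales={x.id: r for x in toy.reactions},
                                    initial_guess=base.concentrations)
        for sp in ("A", "B"):
            assert scaled.concentrations[sp] == \
                pytest.approx(base.concentrations[sp], rel=1e-6)
        assert scaled.fluxes["v2"] == pytest.approx(r * base.fluxes["v2"], rel=1e-6)

    def test_manifold_equivalence_imposed_flux(self):
        """State at (scale r, flux v) ≡ state at (scale 1, flux v/r); closed
        form for the toy chain gives S = 1.5, A = 6/7 mM."""
        toy = toy_pathway()
        half = solve_steady_state(toy, {"S": 5.0, "P": 0.0},
                                  scales={x.id: 0.5 for x in toy.reactions},
                                  imposed_flux=("v1", 3.0), free_clamped="S")
        full = solve_steady_state(toy, {"S": 5.0, "P": 0.0},
                                  imposed_flux=("v1", 6.0), free_clamped="S")
        assert half.concentrations["S"] == pytest.approx(1.5, abs=1e-8)
        assert half.concentrations["A"] == pytest.approx(6.0 / 7.0, abs=1e-8)
        for sp in ("S", "A", "B"):
            assert half.concentrations[sp] == \
                pytest.approx(full.concentrations[sp], abs=1e-8)

    def test_bisection_oracle_agreement(self):
        """Independent route: bisect the flux, invert each Michaelis-Menten
        step for its substrate, and compare with the nonlinear solver."""
        from scipy.optimize import bisect
        s_clamp = 4.0
        vmax, km = (10.0, 20.0, 20.0), (1.0, 2.0, 2.0)

        def residual(j):
            return vmax[0] * s_clamp / (km[0] + s_clamp) - j
        j_star = bisect(residual, 1e-9, vmax[0] - 1e-9, xtol=1e-12)
        a_star = km[1] * j_star / (vmax[1] - j_star)
        b_star = km[2] * j_star / (vmax[2] - j_star)
        ss = solve_steady_state(toy_pathway(), {"S": s_clamp, "P": 0.0})
        assert ss.fluxes["v1"] == pytest.approx(j_star, abs=1e-8)
        assert ss.concentrations["A"] == pytest.approx(a_star, abs=1e-8)
        assert ss.concentrations["B"] == pytest.approx(b_star, abs=1e-8)

    def test_all_zero_vmax_returns_trivial_state_with_warning(self):
        toy = toy_pathway(vmax=(0.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="zero"):
            ss = solve_steady_state(toy, {"S": 9.0, "P": 0.0})
        assert all(v == 0.0 for v in ss.fluxes.values())

    def test_packaged_model_residual_and_positivity(self, model):
        clamps = {"GLCo": 110.0, "ETOH": 0.0, "GLYC": 0.0, "CO2": 0.0}
        ss = solve_steady_state(model, clamps,
                                initial_guess={s: 1.0 for s in model.dynamic_species})
        assert ss.residual_norm <= 1e-9
        assert all(ss.concentrations[s] > 0 for s in model.dynamic_species)

    def test_unclamped_extracellular_is_configuration_error(self, model):
        with pytest.raises(ConfigurationError):
            solve_steady_state(model, {"GLCo": 110.0})


class TestSimulate:
    def test_terminal_state_matches_steady_state(self):
        toy = toy_pathway()
        ss = solve_steady_state(toy, {"S": 9.0, "P": 0.0})
        traj = simulate(toy, {"S": 9.0, "P": 0.0}, None, (0.0, 5.0),
                        np.linspace(0, 5, 11), initial={"A": 0.1, "B": 0.1})
        for sp in ("A", "B"):
            assert traj.concentrations[sp][-1] == \
                pytest.approx(ss.concentrations[sp], rel=1e-6)

    def test_t_eval_zero_returns_initial_exactly(self):
        toy = toy_pathway()
        traj = simulate(toy, {"S": 9.0, "P": 0.0}, None, (0.0, 1.0), [0.0],
                        initial={"A": 0.123, "B": 0.456})
        assert traj.concentrations["A"][0] == 0.123
        assert traj.concentrations["B"][0] == 0.456

    def test_scales_halved_midrun_concentrations_return(self):
        """Halving every capacity mid-run perturbs nothing at steady state:
        pools return to the closed-form values, fluxes halve."""
        toy = toy_pathway()
        step = {r.id: (lambda t: 1.0 if t < 2.0 else 0.5) for r in toy.reactions}
        traj = simulate(toy, {"S": 9.0, "P": 0.0}, step, (0.0, 10.0),
                        [0.0, 1.9, 2.1, 10.0],
                        initial={"A": TOY_A, "B": TOY_A})
        assert traj.concentrations["A"][-1] == pytest.approx(TOY_A, rel=1e-6)
        assert traj.concentrations["B"][-1] == pytest.approx(TOY_A, rel=1e-6)
        assert traj.fluxes["v1"][-1] == pytest.approx(4.5, rel=1e-6)

    def test_unsorted_t_eval_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate(toy_pathway(), {"S": 9.0, "P": 0.0}, None, (0.0, 1.0),
                     [0.5, 0.1], initial={"A": 1.0, "B": 1.0})
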