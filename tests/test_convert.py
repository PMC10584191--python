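"""Model generation: ODE/SDE translation, jump classification, dependency graphs."""

import numpy as np
import pytest
import sympy as sp

import crnkit as ck
from crnkit.convert import classify_jumps, dependency_graph, to_ode_model, to_sde_model
from crnkit.core import jump_propensity, param_vector
from crnkit.simulate import prepare_jumps

from conftest import random_integer_states, random_positive_states

k = sp.Symbol("k")


class TestOdeModel:
    def test_linear_decay(self):
        system = ck.ReactionSystem.from_reactions([ck.make_reaction(k, [("X", 1)], [])])
        m = to_ode_model(system, jacobian="dense")
        assert np.allclose(m.f([2.0], [3.0]), [-6.0])
        assert np.allclose(m.jac([2.0], [3.0]), [[-3.0]])
        assert sp.simplify(m.sym_jac[0, 0] + k) == 0

    def test_brusselator_trace_at_fixed_point(self, brusselator):
        """Classic-form Jacobian trace at (A, B/A) is B - 1 - A**2: the Hopf criterion."""
        m = to_ode_model(brusselator.system, combinatoric=False, jacobian="dense")
        A, B = sp.symbols("A B")
        J = m.sym_jac.subs({sp.Symbol("X"): A, sp.Symbol("Y"): B / A})
        assert sp.simplify(J.trace() - (B - 1 - A**2)) == 0

    def test_dimerization_sparse_pattern_dense(self, dimerization):
        m = to_ode_model(dimerization.system, jacobian="sparse")
        assert set(m.jac_sparsity) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    @pytest.mark.parametrize("name", ["brusselator", "birth_death", "dimerization", "mm_enzyme"])
    def test_symbolic_jacobian_matches_finite_differences(self, fixtures, name):
        fx = fixtures[name]
        m = to_ode_model(fx.system, combinatoric=fx.combinatoric, jacobian="dense")
        fd = to_ode_model(
            fx.system, combinatoric=fx.combinatoric, jacobian="dense", jac_method="finite_diff"
        )
        pv = param_vector(m.parameters, fx.params)
        states = random_positive_states(m.n_species, 50, seed=1234)
        for x in states:
            Js, Jf = m.jac(x, pv), fd.jac(x, pv)
            scale = np.maximum(np.abs(Js), 1.0)
            assert np.max(np.abs(Js - Jf) / scale) < 1e-6

    @pytest.mark.parametrize("name", ["brusselator", "dimerization", "mm_enzyme"])
    def test_sparse_matches_dense(self, fixtures, name):
        fx = fixtures[name]
        dense = to_ode_model(fx.system, jacobian="dense")
        sparse = to_ode_model(fx.system, jacobian="sparse")
        pv = param_vector(dense.parameters, fx.params)
        for x in random_positive_states(dense.n_species, 10, seed=7):
            Jd = dense.jac(x, pv)
            Js = sparse.jac(x, pv).toarray()
            assert np.allclose(Jd, Js)
            # pattern is a superset of the numerically nonzero entries
            nz = set(zip(*np.nonzero(Jd)))
            assert nz <= set(sparse.jac_sparsity)

    def test_symbolic_stoichiometry_rejected(self):
        m_sym = sp.Symbol("m")
        system = ck.ReactionSystem.from_reactions(
            [ck.make_reaction(k, [("X", m_sym)], [("Y", 1)])]
        )
        with pytest.raises(ck.SymbolicStoichiometryError):
            to_ode_model(system)


class TestSdeModel:
    def test_zero_rates_degenerate_to_ode(self, birth_death):
        m = to_sde_model(birth_death.system)
        g = m.noise([5.0], [0.0, 0.0])
        assert np.all(g == 0.0)

    def test_absolute_value_guard(self):
        """Noise stays finite at (unphysical) negative states."""
        system = ck.ReactionSystem.from_reactions([ck.make_reaction(k, [("X", 1)], [])])
        m = to_sde_model(system)
        g = m.noise([-0.5], [1.0])
        assert np.isfinite(g).all()
        assert g[0, 0] == pytest.approx(-np.sqrt(0.5))  # S[0,0] * sqrt(|-0.5*k|)

    def test_birth_death_noise_columns(self, birth_death):
        m = to_sde_model(birth_death.system)
        b, d, X = 10.0, 1.0, 4.0
        g = m.noise([X], [b, d])
        assert g[0] == pytest.approx([np.sqrt(b), -np.sqrt(d * X)])

    def test_drift_equals_ode_rhs(self, fixtures):
        for fx in fixtures.values():
            ode = to_ode_model(fx.system, combinatoric=fx.combinatoric)
            sde = to_sde_model(fx.system, combinatoric=fx.combinatoric)
            assert sp.simplify(sde.sym_drift - ode.sym_rhs) == sp.zeros(*ode.sym_rhs.shape)


class TestClassification:
    def test_three_classes(self):
        text = (
            "k, X --> 0\n"
            "hill(X, v, K, 2), 0 --> P\n"
            "A*(1+sin(t)), 0 --> X\n"
        )
        system = ck.parse_reaction_network(text)
        js = classify_jumps(system)
        assert js.kinds == ("mass_action", "constant_rate", "variable_rate")

    def test_species_free_expression_is_conservative(self):
        # X - X is algebraically constant, but classification is syntactic
        r = ck.make_reaction(sp.Symbol("X") - sp.Symbol("X") + k, [("X", 1)], [])
        system = ck.ReactionSystem.from_reactions([r])
        js = classify_jumps(system)
        assert js.kinds == ("mass_action",)  # sympy simplifies X - X away

    @pytest.mark.parametrize("name", ["brusselator", "birth_death", "dimerization", "mm_enzyme"])
    def test_classified_rate_equals_generic_propensity(self, fixtures, name):
        """Each classified representation reproduces the generic propensity
        at 200 random integer states to 1e-12 relative accuracy."""
        fx = fixtures[name]
        js = classify_jumps(fx.system)
        prep = prepare_jumps(js, fx.params)
        pv = param_vector(fx.system.parameters, fx.params)
        generic = [
            jump_propensity(r, fx.system.species, fx.system.parameters)
            for r in fx.system.reactions
        ]
        states = random_integer_states(fx.system.n_species, 200, seed=99)
        for x in states:
            xl = [int(v) for v in x]
            for j in range(js.n_jumps):
                a_class = prep.propensity(j, xl)
                a_gen = generic[j](xl, pv)
                assert a_class == pytest.approx(a_gen, rel=1e-12, abs=1e-12)


class TestDependencyGraph:
    def test_birth_death(self, birth_death):
        js = classify_jumps(birth_death.system)
        # birth (state-free rate) is nobody's dependent; death depends on both
        assert js.dependency == ((1,), (1,))

    def test_uncoupled_decays(self):
        system = ck.parse_reaction_network("k1, X --> 0\nk2, Y --> 0")
        js = classify_jumps(system)
        assert js.dependency == ((0,), (1,))

    def test_brusselator_birth_channel(self, brusselator):
        js = classify_jumps(brusselator.system)
        # r1 = 0 --> X at constant rate A: changes X, so every X-dependent
        # channel must refresh, but not r1 itself
        assert js.dependency[0] == (1, 2, 3)

    @pytest.mark.parametrize("name", ["brusselator", "birth_death", "dimerization", "mm_enzyme"])
    def test_superset_of_brute_force(self, fixtures, name):
        """Fire each channel and observe which propensities actually change;
        the declared graph must contain every observed dependency."""
        fx = fixtures[name]
        js = classify_jumps(fx.system)
        prep = prepare_jumps(js, fx.params)
        states = random_integer_states(fx.system.n_species, 20, seed=5, high=30) + 3
        for x in states:
            xl = [int(v) for v in x]
            base = [prep.propensity(j, xl) for j in range(js.n_jumps)]
            for j in range(js.n_jumps):
                fired = list(xl)
                for i, d in prep.net[j]:
                    fired[i] += d
                if min(fired) < 0:
                    continue
                changed = {
                    i
                    for i in range(js.n_jumps)
                    if prep.propensity(i, fired) != base[i]
                }
                assert changed <= set(js.dependency[j])
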