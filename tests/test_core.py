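"""Core IR: reaction construction, inference, matrices, rate-law conventions."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

import crnkit as ck
from crnkit.core import (
    DomainError,
    InvalidReactionError,
    InvalidStoichiometryError,
    SymbolicStoichiometryError,
    jump_propensity,
    ode_ratelaw,
)

k, X, Y = sp.symbols("k X Y")


class TestMakeReaction:
    def test_degradation(self):
        r = ck.make_reaction(k, [("X", 1)], [])
        assert r.substrates == (("X", 1),)
        assert r.products == ()
        assert r.rate == k

    def test_duplicates_merged(self):
        r = ck.make_reaction(k, [("X", 1), ("X", 1)], [("Y", 2)])
        assert r.substrates == (("X", 2),)

    def test_negative_stoichiometry_rejected(self):
        with pytest.raises(InvalidStoichiometryError):
            ck.make_reaction(k, [("X", -1)], [])

    def test_empty_to_empty_rejected(self):
        with pytest.raises(InvalidReactionError):
            ck.make_reaction(k, [], [])

    def test_parametric_stoichiometry_carried(self):
        m = sp.Symbol("m")
        r = ck.make_reaction(k, [("X", m)], [("Y", 1)])
        assert r.has_symbolic_stoich()
        # ...but rejected once a numeric representation is required
        system = ck.ReactionSystem.from_reactions([r])
        with pytest.raises(SymbolicStoichiometryError):
            ck.stoich_matrices(system)
        with pytest.raises(SymbolicStoichiometryError):
            jump_propensity(r, ["X", "Y"], ["k", "m"])


class TestInference:
    def test_brusselator(self, brusselator):
        species, params = ck.infer_species_and_parameters(brusselator.system.reactions)
        assert species == ["X", "Y"]
        assert params == ["A", "B"]

    def test_rate_symbols_become_parameters(self):
        r = ck.make_reaction("v*X/(K+X)", [("X", 1)], [("P", 1)])
        species, params = ck.infer_species_and_parameters([r])
        assert species == ["X", "P"]
        assert set(params) == {"v", "K"}

    def test_numeric_rate_no_parameters(self):
        r = ck.make_reaction(1.0, [("X", 1)], [("Y", 1)])
        species, params = ck.infer_species_and_parameters([r])
        assert (species, params) == (["X", "Y"], [])

    def test_stable_under_reordering(self, brusselator):
        rxs = brusselator.system.reactions
        s1, p1 = ck.infer_species_and_parameters(rxs)
        s2, p2 = ck.infer_species_and_parameters(rxs[::-1])
        assert set(s1) == set(s2) and set(p1) == set(p2)
        # idempotence: a system built from the result validates unchanged
        again = ck.ReactionSystem.from_reactions(rxs)
        assert again.species == tuple(s1) and again.parameters == tuple(p1)


class TestStoichMatrices:
    def test_brusselator_net_matrix(self, brusselator):
        sm = ck.stoich_matrices(brusselator.system)
        assert sm.S.tolist() == [[1, 1, -1, -1], [0, -1, 1, 0]]
        assert sm.S == sm.B - sm.A

    def test_single_conversion(self):
        system = ck.ReactionSystem.from_reactions([ck.make_reaction(k, [("A", 1)], [("B", 1)])])
        assert ck.stoich_matrices(system).S.tolist() == [[-1], [1]]

    def test_catalytic_cancellation(self):
        system = ck.ReactionSystem.from_reactions(
            [ck.make_reaction(k, [("X", 1)], [("X", 1), ("P", 1)])]
        )
        sm = ck.stoich_matrices(system)
        assert sm.S.tolist() == [[0], [1]]
        assert sm.A.tolist() == [[1], [0]]


class TestOdeRatelaw:
    def test_linear(self):
        r = ck.make_reaction(k, [("X", 1)], [])
        assert ode_ratelaw(r, combinatoric=True) == k * X
        assert ode_ratelaw(r, combinatoric=False) == k * X

    def test_bimolecular_conventions(self):
        r = ck.make_reaction(k, [("X", 2)], [])
        assert sp.simplify(ode_ratelaw(r, combinatoric=True) - k * X**2 / 2) == 0
        assert sp.simplify(ode_ratelaw(r, combinatoric=False) - k * X**2) == 0

    def test_only_use_rate_bypass(self):
        from crnkit.dsl import registered_function

        hill = registered_function("hill")
        v, K = sp.symbols("v K")
        rate = hill(X, v, K, 2)
        r = ck.make_reaction(rate, [], [("P", 1)], only_use_rate=True)
        assert ode_ratelaw(r) == rate

    def test_combinatoric_needs_integer_stoich(self):
        r = ck.make_reaction(k, [("X", 1.5)], [("Y", 1)])
        with pytest.raises(InvalidStoichiometryError):
            ode_ratelaw(r, combinatoric=True)
        # the classic convention accepts non-integer orders
        assert ode_ratelaw(r, combinatoric=False) is not None


class TestJumpPropensity:
    @pytest.mark.parametrize(
        "substrates, state, expected",
        [
            ([("X", 1)], [5, 0], 5.0),        # k*X
            ([("X", 2)], [5, 0], 10.0),       # k*C(5,2)
            ([("X", 1), ("Y", 1)], [2, 3], 6.0),
            ([("X", 2)], [1, 0], 0.0),        # below stoichiometry
            ([("X", 3)], [2, 0], 0.0),
        ],
    )
    def test_binomial_counting(self, substrates, state, expected):
        r = ck.make_reaction(k, substrates, [])
        a = jump_propensity(r, ["X", "Y"], ["k"])
        assert a(state, [2.0]) == pytest.approx(2.0 * expected)

    def test_negative_state_rejected(self):
        r = ck.make_reaction(k, [("X", 1)], [])
        a = jump_propensity(r, ["X"], ["k"])
        with pytest.raises(DomainError):
            a([-1], [1.0])

    def test_only_use_rate_evaluates_rate(self):
        r = ck.make_reaction("v*X/(K+X)", [], [("P", 1)], only_use_rate=True)
        a = jump_propensity(r, ["X", "P"], ["v", "K"])
        assert a([4, 0], [2.0, 4.0]) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.integers(min_value=0, max_value=200),
        y=st.integers(min_value=0, max_value=200),
        nux=st.integers(min_value=0, max_value=3),
        nuy=st.integers(min_value=0, max_value=3),
    )
    def test_nonnegative_and_zero_below_stoich(self, x, y, nux, nuy):
        """a(x) >= 0 always; a(x) = 0 exactly when some count < stoichiometry."""
        subs = [(n, nu) for n, nu in (("X", nux), ("Y", nuy)) if nu > 0]
        if not subs:
            subs = [("X", 1)]
            nux = 1
        r = ck.make_reaction(k, subs, [])
        a = jump_propensity(r, ["X", "Y"], ["k"])([x, y], [1.0])
        assert a >= 0.0
        counts = {"X": x, "Y": y}
        if any(counts[n] < nu for n, nu in subs):
            assert a == 0.0

    def test_agrees_with_combinatoric_law_at_large_counts(self):
        """rate law and propensity converge (ratio -> 1) as counts -> infinity."""
        r = ck.make_reaction(k, [("X", 2), ("Y", 1)], [])
        law = sp.lambdify((X, Y, k), ode_ratelaw(r, combinatoric=True))
        a = jump_propensity(r, ["X", "Y"], ["k"])
        x = 10**6
        ratio = a([x, x], [1.0]) / law(x, x, 1.0)
        assert ratio == pytest.approx(1.0, rel=1e-5)


def test_symbolic_derivatives_match_finite_differences():
    """Symbolic differentiation of rate expressions is exact."""
    v, K = sp.symbols("v K")
    expr = v * X**2 / (K**2 + X**2)
    d = sp.diff(expr, X)
    f = sp.lambdify((X, v, K), expr)
    df = sp.lambdify((X, v, K), d)
    h = 1e-6
    for x0 in (0.5, 1.7, 9.3):
        fd = (f(x0 + h, 2.0, 3.0) - f(x0 - h, 2.0, 3.0)) / (2 * h)
        assert df(x0, 2.0, 3.0) == pytest.approx(fd, rel=1e-6)


def test_substitution_yields_finite_float():
    expr = ck.make_reaction("v*X/(K+X)", [("X", 1)], [("P", 1)]).rate
    val = float(expr.subs({"v": 1.0, "K": 2.0, "X": 3.0}))
    assert np.isfinite(val)
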