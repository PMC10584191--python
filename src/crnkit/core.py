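"""Symbolic core of crnkit: reactions, reaction systems, and rate-law conventions.

A chemical reaction network (CRN) couples a set of species with a set of
reaction events.  Each :class:`Reaction` carries a symbolic rate expression
and substrate/product multisets; an ordered collection of reactions forms a
:class:`ReactionSystem`, the intermediate representation every other module
(DSL parser, network analysis, model conversion, simulators) consumes.

Two rate-law conventions live here and are used consistently everywhere:

* **ODE rate law** (macroscopic): ``rate * prod_i x_i^nu_i / nu_i!`` with the
  factorial ("combinatoric") divisor on by default, so that the deterministic
  law matches the stochastic convention at large copy number.
* **Jump propensity** (stochastic): ``rate * prod_i C(x_i, nu_i)`` — the
  binomial count of distinct reactant combinations.  The literature rarely
  writes this out; it is the standard stochastic mass-action form and is the
  single source of truth for every SSA in :mod:`crnkit.simulate`.

Symbolic expressions are plain :class:`sympy.Expr`; compilation to numeric
callables happens once, via :func:`compile_expr`, never inside hot loops.
"""

from __future__ import annotations

import keyword
from dataclasses import dataclass, field
from numbers import Real
from typing import Callable, Iterable, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "CRNError",
    "InvalidStoichiometryError",
    "InvalidReactionError",
    "SymbolicStoichiometryError",
    "UndefinedSymbolError",
    "DomainError",
    "SymExpr",
    "TIME",
    "as_symexpr",
    "compile_expr",
    "Reaction",
    "make_reaction",
    "infer_species_and_parameters",
    "ReactionSystem",
    "StoichMatrices",
    "stoich_matrices",
    "ode_ratelaw",
    "jump_propensity",
    "state_vector",
    "param_vector",
]


class CRNError(Exception):
    """Base class for all crnkit errors."""


class InvalidStoichiometryError(CRNError):
    """A numeric stoichiometric coefficient is negative or otherwise invalid."""


class InvalidReactionError(CRNError):
    """A reaction is structurally invalid (e.g. the empty reaction 0 --> 0)."""


class SymbolicStoichiometryError(CRNError):
    """A symbolic (parametric) stoichiometry reached a numeric-only code path."""


class UndefinedSymbolError(CRNError):
    """A rate expression references a symbol that is neither species, parameter nor time."""


class DomainError(CRNError):
    """A propensity was evaluated at an invalid (negative) integer state."""


#: Symbolic scalar expressions are sympy expressions.
SymExpr = sp.Expr

#: The default time symbol.  Species and parameters may not shadow it.
TIME = sp.Symbol("t")


def as_symexpr(value) -> sp.Expr:
    """Coerce a number, string or sympy object to a :class:`sympy.Expr`.

    Strings go through :func:`sympy.sympify`; floats are converted to exact
    rationals of their decimal representation so that downstream rational
    arithmetic (stoichiometric matrices, conservation laws) stays exact.
    """
    if isinstance(value, sp.Expr):
        return value
    if isinstance(value, bool):
        raise TypeError("booleans are not valid symbolic expressions")
    if isinstance(value, int):
        return sp.Integer(value)
    if isinstance(value, float):
        return sp.Rational(repr(value))
    if isinstance(value, str):
        return sp.sympify(value, rational=True)
    return sp.sympify(value)


def compile_expr(
    exprs,
    species: Sequence[str],
    parameters: Sequence[str],
    time_symbol: sp.Symbol = TIME,
) -> Callable:
    """Compile symbolic expression(s) into ``f(x, p, t) -> float | ndarray``.

    ``x`` and ``p`` are sequences ordered like *species* and *parameters*.
    A single expression yields a scalar-returning function; a list/Matrix
    yields an array-returning one.  Compilation happens once here; simulators
    only ever call the resulting natives.
    """
    xs = [sp.Symbol(s) for s in species]
    ps = [sp.Symbol(p) for p in parameters]
    scalar = isinstance(exprs, sp.Expr)
    body = exprs if scalar else list(exprs)
    # dummy symbols avoid clashes when species/parameters are empty
    fn = sp.lambdify((xs, ps, time_symbol), body, modules="numpy")
    if scalar:
        def call(x, p=(), t=0.0):
            return float(fn(x, p, t))
    else:
        def call(x, p=(), t=0.0):
            return np.asarray(fn(x, p, t), dtype=float)
    return call


def _free_symbols(expr: sp.Expr) -> set[str]:
    return {s.name for s in expr.free_symbols}


def _is_number(stoich) -> bool:
    return isinstance(stoich, Real) or (isinstance(stoich, sp.Expr) and stoich.is_number)


def _check_name(name: str) -> str:
    if not isinstance(name, str) or not name.isidentifier() or keyword.iskeyword(name):
        raise CRNError(f"invalid species/parameter name: {name!r}")
    return name


def _normalize_side(side, label: str) -> tuple[tuple[str, object], ...]:
    """Merge duplicate species on one side of a reaction and validate coefficients."""
    merged: dict[str, object] = {}
    for entry in side:
        name, stoich = entry
        _check_name(name)
        if _is_number(stoich):
            stoich = sp.nsimplify(stoich, rational=True)
            if stoich < 0:
                raise InvalidStoichiometryError(
                    f"negative stoichiometry {stoich} for species {name!r} in {label}"
                )
            if stoich == sp.Integer(stoich):
                stoich = sp.Integer(stoich)
        else:
            stoich = as_symexpr(stoich)
        if name in merged:
            merged[name] = sp.nsimplify(merged[name] + stoich, rational=True)
        else:
            merged[name] = stoich
    # drop explicit zero coefficients
    return tuple((n, s) for n, s in merged.items() if not (_is_number(s) and s == 0))


@dataclass(frozen=True)
class Reaction:
    """One reaction event.

    ``rate`` is a symbolic expression.  Unless ``only_use_rate`` is set, the
    full rate law / propensity is ``rate`` times the mass-action factor over
    the substrates; with the flag set, ``rate`` *is* the full law.
    """

    rate: sp.Expr
    substrates: tuple[tuple[str, object], ...]
    products: tuple[tuple[str, object], ...]
    only_use_rate: bool = False

    @property
    def species_names(self) -> list[str]:
        seen: list[str] = []
        for name, _ in (*self.substrates, *self.products):
            if name not in seen:
                seen.append(name)
        return seen

    @property
    def net_change(self) -> dict[str, object]:
        """Net stoichiometric change per species (products minus substrates)."""
        delta: dict[str, object] = {}
        for name, nu in self.products:
            delta[name] = delta.get(name, sp.Integer(0)) + nu
        for name, nu in self.substrates:
            delta[name] = delta.get(name, sp.Integer(0)) - nu
        return {n: sp.nsimplify(d) for n, d in delta.items() if d != 0}

    def has_symbolic_stoich(self) -> bool:
        return any(
            not _is_number(nu) for _, nu in (*self.substrates, *self.products)
        )

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        def side(terms):
            if not terms:
                return "0"
            return " + ".join(
                f"{nu}*{n}" if nu != 1 else n for n, nu in terms
            )

        arrow = "=>" if self.only_use_rate else "-->"
        return f"{self.rate}, {side(self.substrates)} {arrow} {side(self.products)}"


def make_reaction(rate, substrates=(), products=(), only_use_rate: bool = False) -> Reaction:
    """Construct a normalized :class:`Reaction`.

    Duplicate species within one side are merged by summing stoichiometries.
    Stoichiometries must be nonnegative numbers (integers, decimals) or
    symbolic expressions (parametric stoichiometry is carried in the IR and
    rejected later at matrix/jump construction).
    """
    rate = as_symexpr(rate)
    subs = _normalize_side(substrates, "substrates")
    prods = _normalize_side(products, "products")
    if not subs and not prods:
        raise InvalidReactionError("the empty reaction 0 --> 0 is not allowed")
    return Reaction(rate=rate, substrates=subs, products=prods, only_use_rate=only_use_rate)


def infer_species_and_parameters(
    reactions: Iterable[Reaction], time_symbol: sp.Symbol = TIME
) -> tuple[list[str], list[str]]:
    """Extract species and parameters from a reaction collection.

    Species are every name appearing in a substrate/product position, in
    first-appearance order.  Parameters are all remaining free symbols of the
    rates and of symbolic stoichiometries, excluding the time symbol, also in
    first-appearance order.  A name used both as species and inside a rate is
    a species.
    """
    reactions = list(reactions)
    if not reactions:
        raise CRNError("cannot infer species/parameters from an empty reaction list")
    species: list[str] = []
    for r in reactions:
        for name in r.species_names:
            if name not in species:
                species.append(name)
    params: list[str] = []
    species_set = set(species)
    for r in reactions:
        candidates: list[sp.Symbol] = []
        # deterministic first-appearance order within an expression: sorted by
        # position in the srepr is overkill; use sorted-by-name within one
        # expression, expression order across reactions.
        candidates.extend(sorted(r.rate.free_symbols, key=lambda s: s.name))
        for _, nu in (*r.substrates, *r.products):
            if isinstance(nu, sp.Expr) and not nu.is_number:
                candidates.extend(sorted(nu.free_symbols, key=lambda s: s.name))
        for sym in candidates:
            name = sym.name
            if name == time_symbol.name or name in species_set:
                continue
            if name not in params:
                params.append(name)
    return species, params


@dataclass(frozen=True)
class ReactionSystem:
    """The intermediate representation: ordered species, parameters and reactions."""

    name: str
    species: tuple[str, ...]
    parameters: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    time_symbol: sp.Symbol = TIME

    def __post_init__(self):
        species = tuple(_check_name(s) for s in self.species)
        parameters = tuple(_check_name(p) for p in self.parameters)
        if len(set(species)) != len(species):
            raise CRNError("duplicate species names")
        if len(set(parameters)) != len(parameters):
            raise CRNError("duplicate parameter names")
        overlap = set(species) & set(parameters)
        if overlap:
            raise CRNError(f"names used as both species and parameter: {sorted(overlap)}")
        tname = self.time_symbol.name
        if tname in species or tname in parameters:
            raise CRNError(f"the time symbol {tname!r} cannot be a species or parameter")
        allowed = set(species) | set(parameters) | {tname}
        for i, r in enumerate(self.reactions):
            for name, _ in (*r.substrates, *r.products):
                if name not in species:
                    raise CRNError(
                        f"reaction {i} references unknown species {name!r}"
                    )
            unknown = _free_symbols(r.rate) - allowed
            for _, nu in (*r.substrates, *r.products):
                if isinstance(nu, sp.Expr):
                    unknown |= {s.name for s in nu.free_symbols} - allowed
            if unknown:
                raise UndefinedSymbolError(
                    f"reaction {i} rate uses undefined symbols {sorted(unknown)}"
                )
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "parameters", parameters)
        object.__setattr__(self, "reactions", tuple(self.reactions))

    @classmethod
    def from_reactions(
        cls, reactions: Iterable[Reaction], name: str = "crn", time_symbol: sp.Symbol = TIME
    ) -> "ReactionSystem":
        reactions = tuple(reactions)
        species, params = infer_species_and_parameters(reactions, time_symbol)
        return cls(
            name=name,
            species=tuple(species),
            parameters=tuple(params),
            reactions=reactions,
            time_symbol=time_symbol,
        )

    # -- convenience ------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def species_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s) for s in self.species]

    def parameter_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(p) for p in self.parameters]

    def pretty(self) -> str:
        """Render the system back to DSL text (one reaction per line).

        Reactions constructed with ``only_use_rate`` have no DSL notation and
        cannot be rendered.
        """
        lines = []
        for r in self.reactions:
            if r.only_use_rate:
                raise CRNError(
                    "only_use_rate reactions have no DSL representation"
                )
            lines.append(_reaction_to_dsl(r))
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        body = "\n".join(f"  {r}" for r in self.reactions)
        return (
            f"ReactionSystem {self.name!r}: {self.n_species} species "
            f"{list(self.species)}, {self.n_parameters} parameters "
            f"{list(self.parameters)}, {self.n_reactions} reactions\n{body}"
        )


def _complex_to_dsl(terms) -> str:
    if not terms:
        return "0"
    parts = []
    for name, nu in terms:
        if nu == 1:
            parts.append(name)
        else:
            parts.append(f"{nu}*{name}")
    return " + ".join(parts)


def _reaction_to_dsl(r: Reaction) -> str:
    rate = sp.sstr(r.rate)
    return f"{rate}, {_complex_to_dsl(r.substrates)} --> {_complex_to_dsl(r.products)}"


@dataclass(frozen=True)
class StoichMatrices:
    """Substrate (A), product (B) and net (S = B - A) stoichiometric matrices.

    Rows follow the system's species order, columns its reaction order.
    Entries are exact rationals; column j of S is the state change caused by
    one firing of reaction j.
    """

    A: sp.MutableDenseMatrix
    B: sp.MutableDenseMatrix
    S: sp.MutableDenseMatrix
    species: tuple[str, ...] = field(default=())

    def as_numpy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        to = lambda M: np.array(M.tolist(), dtype=float)
        return to(self.A), to(self.B), to(self.S)


def stoich_matrices(system: ReactionSystem) -> StoichMatrices:
    """Build exact stoichiometric matrices for a numeric-stoichiometry system."""
    n, m = system.n_species, system.n_reactions
    A = sp.zeros(n, m)
    B = sp.zeros(n, m)
    index = {s: i for i, s in enumerate(system.species)}
    for j, r in enumerate(system.reactions):
        if r.has_symbolic_stoich():
            raise SymbolicStoichiometryError(
                f"reaction {j} has symbolic stoichiometry; matrix form requires numbers"
            )
        for name, nu in r.substrates:
            A[index[name], j] += sp.nsimplify(nu)
        for name, nu in r.products:
            B[index[name], j] += sp.nsimplify(nu)
    return StoichMatrices(A=A, B=B, S=B - A, species=system.species)


def ode_ratelaw(r: Reaction, combinatoric: bool = True) -> sp.Expr:
    """Macroscopic (reaction-rate-equation) rate law of one reaction.

    Mass-action: ``rate * prod_i x_i^nu_i / nu_i!`` when *combinatoric* (the
    default; matches the stochastic convention in the large-copy-number
    limit), or ``rate * prod_i x_i^nu_i`` in the classic textbook convention.
    With ``only_use_rate`` the rate expression is returned unchanged.
    """
    if r.only_use_rate:
        return r.rate
    law = r.rate
    for name, nu in r.substrates:
        x = sp.Symbol(name)
        law = law * x ** nu
        if combinatoric:
            if not (_is_number(nu) and nu == sp.Integer(nu)):
                raise InvalidStoichiometryError(
                    f"combinatoric rate law requires integer stoichiometry, got {nu}"
                )
            law = law / sp.factorial(sp.Integer(nu))
    return law


def _falling_binomial(x: float, nu: int) -> float:
    """C(x, nu) = x (x-1) ... (x-nu+1) / nu! — number of reactant combinations."""
    acc = 1.0
    for i in range(nu):
        acc *= x - i
    for i in range(2, nu + 1):
        acc /= i
    return acc


def jump_propensity(
    r: Reaction,
    species: Sequence[str],
    parameters: Sequence[str] = (),
    time_symbol: sp.Symbol = TIME,
) -> Callable:
    """Compile the stochastic propensity ``a(x, p, t)`` of one reaction.

    For mass-action reactions the propensity is
    ``rate(p, t) * prod_i C(x_i, nu_i)`` (binomial counting of reactant
    combinations; rates that also depend on species multiply that factor).
    With ``only_use_rate`` the compiled rate expression itself is evaluated at
    the state.  Negative state entries raise :class:`DomainError`.
    """
    if r.has_symbolic_stoich():
        raise SymbolicStoichiometryError(
            "jump propensities require numeric integer stoichiometry"
        )
    rate_fn = compile_expr(r.rate, species, parameters, time_symbol)
    if r.only_use_rate:
        def prop(x, p=(), t=0.0):
            for xi in x:
                if xi < 0:
                    raise DomainError(f"negative state entries in {list(x)}")
            return rate_fn(x, p, t)
        return prop

    index = {s: i for i, s in enumerate(species)}
    reac: list[tuple[int, int]] = []
    for name, nu in r.substrates:
        nu_i = sp.nsimplify(nu)
        if nu_i != sp.Integer(nu_i):
            raise InvalidStoichiometryError(
                f"jump propensity requires integer stoichiometry, got {nu} for {name!r}"
            )
        reac.append((index[name], int(nu_i)))

    def prop(x, p=(), t=0.0):
        a = rate_fn(x, p, t)
        for i, nu_i in reac:
            xi = x[i]
            if xi < 0:
                raise DomainError(f"negative count {xi} for species {species[i]!r}")
            a *= _falling_binomial(xi, nu_i)
        return a

    return prop


def state_vector(species: Sequence[str], u0) -> np.ndarray:
    """Coerce a dict or sequence of initial values into species order."""
    if isinstance(u0, dict):
        unknown = set(u0) - set(species)
        if unknown:
            raise CRNError(f"unknown species in initial condition: {sorted(unknown)}")
        return np.array([u0.get(s, 0) for s in species], dtype=float)
    arr = np.asarray(u0, dtype=float)
    if arr.shape != (len(species),):
        raise CRNError(
            f"initial condition has length {arr.size}, expected {len(species)}"
        )
    return arr


def param_vector(parameters: Sequence[str], p) -> np.ndarray:
    """Coerce a dict or sequence of parameter values into parameter order."""
    if p is None:
        p = {}
    if isinstance(p, dict):
        missing = set(parameters) - set(p)
        if missing:
            raise CRNError(f"missing parameter values: {sorted(missing)}")
        return np.array([p[name] for name in parameters], dtype=float)
    arr = np.asarray(p, dtype=float)
    if arr.shape != (len(parameters),):
        raise CRNError(f"parameter vector has length {arr.size}, expected {len(parameters)}")
    return arr
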