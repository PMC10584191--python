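"""Translation of a ReactionSystem into simulatable mathematical models.

Three physical scales are generated from the same symbolic IR:

* :func:`to_ode_model` — the macroscopic reaction rate equation (RRE),
  ``dx/dt = S v(x, p, t)``, with all mass-action terms inlined into a single
  compiled derivative function and an optional symbolic Jacobian (dense or
  sparse with a stored sparsity pattern);
* :func:`to_sde_model` — the chemical Langevin equation (CLE), sharing the
  RRE drift and adding one noise column per reaction,
  ``g[:, j] = S[:, j] * sqrt(|v_j|)``; the absolute value guards against
  square roots of transiently negative rate laws;
* :func:`classify_jumps` — the stochastic-chemical-kinetics jump process,
  with each reaction classified into the most performant physically valid
  representation: *mass-action* (rate free of species and time),
  *constant-rate* (species-dependent rate, constant between firings) or
  *variable-rate* (explicit time dependence).  Classification is syntactic
  (free-symbol analysis), preferring soundness over minimality.

:func:`dependency_graph` derives, for each jump, the set of jumps whose
propensities must be recomputed after it fires — the structure all SSA
variants in :mod:`crnkit.simulate` rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse
import sympy as sp

from .core import (
    CRNError,
    Reaction,
    ReactionSystem,
    SymbolicStoichiometryError,
    compile_expr,
    jump_propensity,
    ode_ratelaw,
    stoich_matrices,
)

__all__ = [
    "ODEModel",
    "SDEModel",
    "MassActionJump",
    "ConstantRateJump",
    "VariableRateJump",
    "JumpSet",
    "to_ode_model",
    "to_sde_model",
    "classify_jumps",
    "dependency_graph",
]


def _symbolic_rhs(system: ReactionSystem, combinatoric: bool) -> sp.MutableDenseMatrix:
    S = stoich_matrices(system).S
    v = sp.Matrix([ode_ratelaw(r, combinatoric) for r in system.reactions])
    return S * v


@dataclass(frozen=True)
class ODEModel:
    """Compiled RRE right-hand side with optional Jacobian."""

    name: str
    species: tuple[str, ...]
    parameters: tuple[str, ...]
    f: Callable  # f(x, p, t) -> ndarray (n_species,)
    jac: Callable | None  # jac(x, p, t) -> (n, n) ndarray or sparse matrix
    jac_sparsity: tuple[tuple[int, int], ...] | None
    sym_rhs: sp.MutableDenseMatrix
    sym_jac: sp.MutableDenseMatrix | None
    combinatoric: bool

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class SDEModel:
    """Chemical Langevin model: RRE drift plus per-reaction noise columns."""

    name: str
    species: tuple[str, ...]
    parameters: tuple[str, ...]
    drift: Callable  # identical to the ODE f
    noise: Callable  # g(x, p, t) -> (n_species, n_reactions)
    sym_drift: sp.MutableDenseMatrix
    sym_noise: sp.MutableDenseMatrix
    combinatoric: bool

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return self.sym_noise.cols


def _check_numeric_integer_stoich(system: ReactionSystem, integer: bool = False):
    for j, r in enumerate(system.reactions):
        if r.has_symbolic_stoich():
            raise SymbolicStoichiometryError(
                f"reaction {j} has symbolic stoichiometry; "
                "model conversion requires numeric coefficients"
            )
        if integer:
            for name, nu in (*r.substrates, *r.products):
                if sp.nsimplify(nu) != sp.Integer(sp.nsimplify(nu)):
                    raise SymbolicStoichiometryError(
                        f"reaction {j} has non-integer stoichiometry {nu} for {name!r}; "
                        "jump models require integers"
                    )


def to_ode_model(
    system: ReactionSystem,
    combinatoric: bool = True,
    jacobian: str = "none",
    jac_method: str = "symbolic",
) -> ODEModel:
    """Generate the RRE ODE model ``dx/dt = S v(x, p, t)``.

    ``jacobian`` selects none/"dense"/"sparse"; ``jac_method`` "symbolic"
    (exact differentiation) or "finite_diff" (central differences of the
    compiled f).  The sparse variant stores the structural sparsity pattern
    (nonzeros of the symbolic Jacobian) and returns CSC matrices.
    """
    if jacobian not in ("none", "dense", "sparse"):
        raise ValueError(f"jacobian must be none|dense|sparse, got {jacobian!r}")
    if jac_method not in ("symbolic", "finite_diff"):
        raise ValueError(f"jac_method must be symbolic|finite_diff, got {jac_method!r}")
    _check_numeric_integer_stoich(system)
    rhs = _symbolic_rhs(system, combinatoric)
    f = compile_expr(list(rhs), system.species, system.parameters, system.time_symbol)
    xs = system.species_symbols()
    sym_jac = sp.Matrix(list(rhs)).jacobian(xs) if jacobian != "none" else None

    jac = None
    sparsity = None
    n = system.n_species
    if jacobian == "dense":
        if jac_method == "symbolic":
            rows = [list(sym_jac.row(i)) for i in range(n)]
            jfn = compile_expr(
                [e for row in rows for e in row],
                system.species,
                system.parameters,
                system.time_symbol,
            )

            def jac(x, p=(), t=0.0, _jfn=jfn, _n=n):
                return np.asarray(_jfn(x, p, t), dtype=float).reshape(_n, _n)

        else:
            jac = _finite_diff_jac(f, n)
    elif jacobian == "sparse":
        pattern = tuple(
            (i, j) for i in range(n) for j in range(n) if sym_jac[i, j] != 0
        )
        sparsity = pattern
        if jac_method == "symbolic":
            entries = [sym_jac[i, j] for i, j in pattern]
            efn = compile_expr(
                entries, system.species, system.parameters, system.time_symbol
            )
            rows = np.array([i for i, _ in pattern], dtype=int)
            cols = np.array([j for _, j in pattern], dtype=int)

            def jac(x, p=(), t=0.0, _efn=efn, _r=rows, _c=cols, _n=n):
                data = np.atleast_1d(np.asarray(_efn(x, p, t), dtype=float))
                return scipy.sparse.csc_matrix((data, (_r, _c)), shape=(_n, _n))

        else:
            dense = _finite_diff_jac(f, n)
            rows = np.array([i for i, _ in pattern], dtype=int)
            cols = np.array([j for _, j in pattern], dtype=int)

            def jac(x, p=(), t=0.0, _d=dense, _r=rows, _c=cols, _n=n):
                J = _d(x, p, t)
                return scipy.sparse.csc_matrix((J[_r, _c], (_r, _c)), shape=(_n, _n))

    return ODEModel(
        name=system.name,
        species=system.species,
        parameters=system.parameters,
        f=f,
        jac=jac,
        jac_sparsity=sparsity,
        sym_rhs=rhs,
        sym_jac=sym_jac,
        combinatoric=combinatoric,
    )


def _finite_diff_jac(f: Callable, n: int, rel_h: float = 1e-6) -> Callable:
    def jac(x, p=(), t=0.0):
        x = np.asarray(x, dtype=float)
        J = np.empty((n, n))
        for j in range(n):
            h = rel_h * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (np.asarray(f(xp, p, t)) - np.asarray(f(xm, p, t))) / (2 * h)
        return J

    return jac


def to_sde_model(system: ReactionSystem, combinatoric: bool = True) -> SDEModel:
    """Generate the CLE SDE model.

    Drift is the RRE right-hand side; the noise matrix has one column per
    reaction, ``g[i, j] = S[i, j] * sqrt(|v_j|)``.  Wrapping the rate law in
    an absolute value keeps the noise evaluable (no NaN) when a trajectory
    makes a transient negative excursion.
    """
    _check_numeric_integer_stoich(system)
    S = stoich_matrices(system).S
    v = [ode_ratelaw(r, combinatoric) for r in system.reactions]
    drift_sym = S * sp.Matrix(v)
    n, m = system.n_species, system.n_reactions
    noise_sym = sp.zeros(n, m)
    for j in range(m):
        col_noise = sp.sqrt(sp.Abs(v[j]))
        for i in range(n):
            if S[i, j] != 0:
                noise_sym[i, j] = S[i, j] * col_noise
    drift = compile_expr(
        list(drift_sym), system.species, system.parameters, system.time_symbol
    )
    flat = [noise_sym[i, j] for i in range(n) for j in range(m)]
    gfn = compile_expr(flat, system.species, system.parameters, system.time_symbol)

    def noise(x, p=(), t=0.0):
        return np.asarray(gfn(x, p, t), dtype=float).reshape(n, m)

    return SDEModel(
        name=system.name,
        species=system.species,
        parameters=system.parameters,
        drift=drift,
        noise=noise,
        sym_drift=drift_sym,
        sym_noise=noise_sym,
        combinatoric=combinatoric,
    )


# ---------------------------------------------------------------------------
# jumps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MassActionJump:
    """Jump whose rate expression is free of species and time.

    The propensity is ``k(p) * prod_i C(x_i, nu_i)`` over the reactant
    stoichiometry; ``net`` is the integer state change on firing.
    """

    reaction_index: int
    rate: sp.Expr  # parameters only
    reactant_stoich: tuple[tuple[int, int], ...]  # (species index, nu)
    net: tuple[tuple[int, int], ...]  # (species index, delta)


@dataclass(frozen=True)
class ConstantRateJump:
    """Jump with a general state-dependent rate, constant between firings."""

    reaction_index: int
    rate_species: tuple[int, ...]  # species indices the rate depends on
    net: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class VariableRateJump:
    """Jump whose rate depends explicitly on time (not supported by exact SSAs)."""

    reaction_index: int
    rate_species: tuple[int, ...]
    net: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class JumpSet:
    """Reactions classified into mass-action / constant-rate / variable-rate.

    ``propensities[j]`` is the compiled generic propensity of reaction j (it
    equals :func:`crnkit.core.jump_propensity` by construction);
    ``dependency`` maps each jump to the jumps whose rates must be recomputed
    after it fires (computed lazily by :func:`dependency_graph`).
    """

    system: ReactionSystem
    mass_action: tuple[MassActionJump, ...]
    constant_rate: tuple[ConstantRateJump, ...]
    variable_rate: tuple[VariableRateJump, ...]
    propensities: tuple[Callable, ...]
    kinds: tuple[str, ...]  # per reaction: "mass_action"|"constant_rate"|"variable_rate"
    dependency: tuple[tuple[int, ...], ...] = field(default=())

    @property
    def n_jumps(self) -> int:
        return len(self.kinds)

    @property
    def has_variable_rate(self) -> bool:
        return bool(self.variable_rate)

    def jump(self, j: int):
        for group in (self.mass_action, self.constant_rate, self.variable_rate):
            for jmp in group:
                if jmp.reaction_index == j:
                    return jmp
        raise IndexError(j)


def _net_change_indices(r: Reaction, species: Sequence[str]) -> tuple[tuple[int, int], ...]:
    idx = {s: i for i, s in enumerate(species)}
    return tuple(
        sorted((idx[name], int(delta)) for name, delta in r.net_change.items())
    )


def classify_jumps(system: ReactionSystem, build_dependency: bool = True) -> JumpSet:
    """Classify each reaction into its most performant valid jump type.

    The decision is purely syntactic on the rate expression: no species
    symbols and no ``t`` and not ``only_use_rate`` -> mass-action; no ``t``
    -> constant-rate; otherwise variable-rate.  An expression like ``X - X``
    is therefore (conservatively) constant-rate.
    """
    _check_numeric_integer_stoich(system, integer=True)
    species_syms = set(system.species)
    tname = system.time_symbol.name
    sp_index = {s: i for i, s in enumerate(system.species)}

    ma, cr, vr, kinds, props = [], [], [], [], []
    for j, r in enumerate(system.reactions):
        free = {s.name for s in r.rate.free_symbols}
        rate_species = tuple(sorted(sp_index[n] for n in free & species_syms))
        net = _net_change_indices(r, system.species)
        props.append(jump_propensity(r, system.species, system.parameters))
        if not r.only_use_rate and not rate_species and tname not in free:
            reac = tuple(
                (sp_index[name], int(sp.nsimplify(nu))) for name, nu in r.substrates
            )
            ma.append(MassActionJump(j, r.rate, reac, net))
            kinds.append("mass_action")
        elif tname not in free:
            cr.append(ConstantRateJump(j, rate_species, net))
            kinds.append("constant_rate")
        else:
            vr.append(VariableRateJump(j, rate_species, net))
            kinds.append("variable_rate")

    js = JumpSet(
        system=system,
        mass_action=tuple(ma),
        constant_rate=tuple(cr),
        variable_rate=tuple(vr),
        propensities=tuple(props),
        kinds=tuple(kinds),
    )
    if build_dependency:
        dep = dependency_graph(js, system)
        js = JumpSet(
            system=system,
            mass_action=js.mass_action,
            constant_rate=js.constant_rate,
            variable_rate=js.variable_rate,
            propensities=js.propensities,
            kinds=js.kinds,
            dependency=dep,
        )
    return js


def _rate_determining_species(jumpset: JumpSet, j: int) -> set[int]:
    """Species whose counts enter jump j's propensity: substrates for
    mass-action, all species in the rate expression otherwise (plus
    substrates when the mass-action factor applies)."""
    jmp = jumpset.jump(j)
    if isinstance(jmp, MassActionJump):
        return {i for i, _ in jmp.reactant_stoich}
    r = jumpset.system.reactions[j]
    det = set(jmp.rate_species)
    if not r.only_use_rate:
        idx = {s: i for i, s in enumerate(jumpset.system.species)}
        det |= {idx[name] for name, _ in r.substrates}
    return det


def dependency_graph(jumpset: JumpSet, system: ReactionSystem | None = None) -> tuple[tuple[int, ...], ...]:
    """Adjacency list: jump j -> jumps whose rates change when j fires.

    Jump i depends on jump j iff i's rate-determining species intersect j's
    net-change species; with i = j this makes self-dependence explicit, so
    SSA update loops never hold a stale propensity.  The graph is a sound
    superset of the true firing-induced rate changes.
    """
    system = system or jumpset.system
    n = jumpset.n_jumps
    determining = [_rate_determining_species(jumpset, i) for i in range(n)]
    changed = [
        {i for i, _ in jumpset.jump(j).net} for j in range(n)
    ]
    return tuple(
        tuple(i for i in range(n) if determining[i] & changed[j]) for j in range(n)
    )
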