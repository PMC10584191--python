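"""Chemical-reaction-network-theory analysis.

Implements the standard structural computations on a reaction network: the
set of *complexes* (the multisets of species on either side of a reaction,
with the empty complex as a bona fide node), *linkage classes* (connected
components of the undirected complex graph), *weak reversibility* (every
directed component strongly connected), the *deficiency index*

    delta = n_complexes - n_linkage_classes - rank(S),

and *conservation laws* — an integer basis of the left null space of the net
stoichiometric matrix S, computed in exact rational arithmetic so no rank
tolerance is ever needed.  Conserved species can be eliminated symbolically,
producing a reduced ODE system of dimension ``n_species - n_laws`` with a
non-singular Jacobian (the full system's Jacobian is singular along each
conservation relation).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Sequence

import networkx as nx
import numpy as np
import sympy as sp

from .core import (
    CRNError,
    ReactionSystem,
    SymbolicStoichiometryError,
    compile_expr,
    ode_ratelaw,
    stoich_matrices,
)

__all__ = [
    "ComplexSet",
    "reaction_complexes",
    "linkage_classes",
    "is_weakly_reversible",
    "deficiency",
    "ConservationLaws",
    "conservation_laws",
    "ReducedODESystem",
    "eliminate_conserved",
    "analyze",
]

Complex = tuple[tuple[str, sp.Integer], ...]


def _canonical_complex(side, species_order: Sequence[str]) -> Complex:
    order = {s: i for i, s in enumerate(species_order)}
    terms = []
    for name, nu in side:
        nu = sp.nsimplify(nu)
        if nu != sp.Integer(nu):
            raise SymbolicStoichiometryError(
                "complex computations require integer stoichiometry"
            )
        terms.append((name, sp.Integer(nu)))
    return tuple(sorted(terms, key=lambda t: order[t[0]]))


def complex_label(cplx: Complex) -> str:
    if not cplx:
        return "0"
    return " + ".join(f"{int(nu)}*{n}" if nu != 1 else n for n, nu in cplx)


@dataclass(frozen=True)
class ComplexSet:
    """Deduplicated complexes plus the incidence and composition matrices.

    ``Z`` is complexes x reactions with -1 at each reaction's source complex
    and +1 at its sink; ``Y`` is species x complexes giving each complex's
    composition.  The factorization S = Y Z holds exactly.
    """

    complexes: tuple[Complex, ...]
    Z: sp.MutableDenseMatrix
    Y: sp.MutableDenseMatrix
    sources: tuple[int, ...]  # per reaction: source complex index
    sinks: tuple[int, ...]

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    def index(self, cplx: Complex) -> int:
        return self.complexes.index(cplx)

    def labels(self) -> list[str]:
        return [complex_label(c) for c in self.complexes]


def reaction_complexes(system: ReactionSystem) -> ComplexSet:
    """Enumerate the distinct complexes of a network (first-appearance order)."""
    complexes: list[Complex] = []
    index: dict[Complex, int] = {}
    sources, sinks = [], []
    for r in system.reactions:
        for side, bucket in ((r.substrates, sources), (r.products, sinks)):
            c = _canonical_complex(side, system.species)
            if c not in index:
                index[c] = len(complexes)
                complexes.append(c)
            bucket.append(index[c])
    n_c, n_r = len(complexes), system.n_reactions
    Z = sp.zeros(n_c, n_r)
    for j, (src, snk) in enumerate(zip(sources, sinks)):
        Z[src, j] -= 1
        Z[snk, j] += 1
    sp_index = {s: i for i, s in enumerate(system.species)}
    Y = sp.zeros(system.n_species, n_c)
    for ci, cplx in enumerate(complexes):
        for name, nu in cplx:
            Y[sp_index[name], ci] = nu
    S = stoich_matrices(system).S
    assert Y * Z == S, "complex decomposition inconsistent with S = Y*Z"
    return ComplexSet(
        complexes=tuple(complexes),
        Z=Z,
        Y=Y,
        sources=tuple(sources),
        sinks=tuple(sinks),
    )


def _complex_graph(cs: ComplexSet, directed: bool) -> nx.Graph:
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(cs.n_complexes))
    g.add_edges_from(zip(cs.sources, cs.sinks))
    return g


def linkage_classes(system: ReactionSystem) -> list[list[int]]:
    """Partition complex indices into connected components of the complex graph.

    Components are sorted by their smallest complex index; indices within a
    component are sorted, so the result is deterministic.
    """
    cs = reaction_complexes(system)
    comps = [sorted(c) for c in nx.connected_components(_complex_graph(cs, False))]
    return sorted(comps, key=lambda c: c[0])


def is_weakly_reversible(system: ReactionSystem) -> bool:
    """True iff every connected component of the directed complex graph is strongly connected."""
    cs = reaction_complexes(system)
    g = _complex_graph(cs, directed=True)
    for comp in nx.weakly_connected_components(g):
        if not nx.is_strongly_connected(g.subgraph(comp)):
            return False
    return True


def deficiency(system: ReactionSystem) -> int:
    """Deficiency delta = n_complexes - n_linkage_classes - rank(S) (always >= 0)."""
    cs = reaction_complexes(system)
    n = cs.n_complexes
    ell = len(linkage_classes(system))
    s = stoich_matrices(system).S.rank()
    delta = n - ell - s
    assert delta >= 0
    return delta


# ---------------------------------------------------------------------------
# conservation laws
# ---------------------------------------------------------------------------


def _primitive_integer(vec: sp.MutableDenseMatrix) -> list[sp.Integer]:
    """Scale a rational vector to coprime integers with positive leading entry."""
    denoms = [sp.nsimplify(v).q for v in vec]
    lcm = sp.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
    ints = [int(sp.nsimplify(v) * lcm) for v in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    lead = next((v for v in ints if v != 0), 1)
    if lead < 0:
        ints = [-v for v in ints]
    return [sp.Integer(v) for v in ints]


@dataclass(frozen=True)
class ConservationLaws:
    """Integer basis of the left null space of S.

    Each row gamma of ``matrix`` satisfies gamma . S = 0 exactly, so
    ``gamma . x(t)`` is invariant along every trajectory (deterministic or
    stochastic).  ``names`` label the derived conserved constants C_k.
    """

    matrix: sp.MutableDenseMatrix  # laws x species, integer entries
    species: tuple[str, ...]
    names: tuple[str, ...]

    @property
    def n_laws(self) -> int:
        return self.matrix.rows

    def as_numpy(self) -> np.ndarray:
        return np.array(self.matrix.tolist(), dtype=int)

    def constants(self, x0) -> dict[str, float]:
        """Evaluate each conserved quantity at a state (dict or vector)."""
        from .core import state_vector

        x = state_vector(self.species, x0)
        vals = self.as_numpy() @ x
        return dict(zip(self.names, vals.tolist()))


def conservation_laws(system: ReactionSystem) -> ConservationLaws:
    """Compute the conservation-law matrix Gamma in exact rational arithmetic.

    The basis comes from sympy's rational null space of S^T, scaled row-wise
    to coprime integers with the first nonzero entry positive.  An empty
    Gamma (full-rank S) is a valid result, not an error.
    """
    S = stoich_matrices(system).S
    null = S.T.nullspace()
    rows = [_primitive_integer(v) for v in null]
    matrix = sp.Matrix(rows) if rows else sp.zeros(0, system.n_species)
    existing = set(system.parameters) | set(system.species)
    names = []
    for k in range(matrix.rows):
        name = f"C{k + 1}"
        while name in existing:
            name = "_" + name
        existing.add(name)
        names.append(name)
    return ConservationLaws(matrix=matrix, species=system.species, names=tuple(names))


@dataclass(frozen=True)
class ReducedODESystem:
    """ODE system after symbolic elimination of conserved species.

    One dependent species per conservation law is solved for,
    ``x_dep = (C_k - sum_others gamma_j x_j) / gamma_dep``, and substituted
    into every rate law.  The remaining ``independent_species`` evolve under
    ``rhs``; parameters are the original ones followed by the conserved
    constants.  With no laws this is the identity transformation.
    """

    name: str
    independent_species: tuple[str, ...]
    parameters: tuple[str, ...]  # original parameters + conserved constants
    rhs: tuple[sp.Expr, ...]
    substitution: dict[str, sp.Expr]  # dependent species -> expression
    conserved_params: tuple[str, ...]
    laws: ConservationLaws
    combinatoric: bool

    @property
    def n_species(self) -> int:
        return len(self.independent_species)

    def f(self):
        """Compile the reduced right-hand side to ``f(x, p, t)``."""
        return compile_expr(list(self.rhs), self.independent_species, self.parameters)

    def jacobian(self) -> sp.MutableDenseMatrix:
        xs = [sp.Symbol(s) for s in self.independent_species]
        return sp.Matrix(list(self.rhs)).jacobian(xs)

    def parameter_values(self, p: dict, u0) -> dict[str, float]:
        """Extend a parameter dict with conserved constants evaluated at u0."""
        out = {k: float(v) for k, v in p.items()}
        out.update(self.laws.constants(u0))
        return out

    def initial_condition(self, u0) -> np.ndarray:
        from .core import state_vector

        full = state_vector(self.laws.species, u0)
        idx = [self.laws.species.index(s) for s in self.independent_species]
        return full[idx]

    def reconstruct(self, x, p: dict) -> dict[str, float]:
        """Recover dependent-species values from a reduced state."""
        subs = {sp.Symbol(s): v for s, v in zip(self.independent_species, x)}
        subs.update({sp.Symbol(k): v for k, v in p.items()})
        return {
            name: float(expr.subs(subs)) for name, expr in self.substitution.items()
        }


def _choose_dependents(gamma: sp.MutableDenseMatrix, n_species: int) -> list[int]:
    """Pick one dependent species per law: largest |gamma| entry, ties to the
    latest species; fall back to RREF pivots if the greedy choice is singular."""
    chosen: list[int] = []
    for k in range(gamma.rows):
        best, best_abs = None, None
        for j in range(n_species):
            if j in chosen:
                continue
            a = abs(gamma[k, j])
            if a == 0:
                continue
            if best is None or a > best_abs or (a == best_abs and j > best):
                best, best_abs = j, a
        if best is None:
            raise CRNError("conservation law with no available dependent species")
        chosen.append(best)
    if gamma.extract(range(gamma.rows), chosen).det() != 0:
        return chosen
    _, pivots = gamma.rref()
    return list(pivots[: gamma.rows])


def eliminate_conserved(
    system: ReactionSystem, combinatoric: bool = True
) -> tuple[ReducedODESystem, dict[str, sp.Expr], tuple[str, ...]]:
    """Eliminate conserved species from the ODE form of a system.

    Returns ``(reduced, substitution_map, conserved_constant_names)``.  With
    an empty Gamma the "reduced" system is just the full ODE system (identity
    transformation, no error).
    """
    laws = conservation_laws(system)
    S = stoich_matrices(system).S
    v = sp.Matrix([ode_ratelaw(r, combinatoric) for r in system.reactions])
    rhs_full = S * v
    xs = [sp.Symbol(s) for s in system.species]

    if laws.n_laws == 0:
        reduced = ReducedODESystem(
            name=system.name,
            independent_species=system.species,
            parameters=system.parameters,
            rhs=tuple(rhs_full),
            substitution={},
            conserved_params=(),
            laws=laws,
            combinatoric=combinatoric,
        )
        return reduced, {}, ()

    gamma = laws.matrix
    dep_idx = _choose_dependents(gamma, system.n_species)
    indep_idx = [j for j in range(system.n_species) if j not in dep_idx]
    c_syms = [sp.Symbol(n) for n in laws.names]
    # solve Gamma_dep * x_dep = C - Gamma_indep * x_indep exactly
    G_dep = gamma.extract(range(gamma.rows), dep_idx)
    G_ind = gamma.extract(range(gamma.rows), indep_idx)
    x_ind = sp.Matrix([xs[j] for j in indep_idx])
    rhs_vec = sp.Matrix(c_syms) - G_ind * x_ind
    x_dep_exprs = G_dep.solve(rhs_vec)
    substitution = {
        system.species[dep_idx[i]]: sp.expand(x_dep_exprs[i])
        for i in range(len(dep_idx))
    }
    sub_map = {sp.Symbol(k): e for k, e in substitution.items()}
    reduced_rhs = tuple(
        sp.expand(rhs_full[j].subs(sub_map, simultaneous=True)) for j in indep_idx
    )
    reduced = ReducedODESystem(
        name=system.name,
        independent_species=tuple(system.species[j] for j in indep_idx),
        parameters=system.parameters + laws.names,
        rhs=reduced_rhs,
        substitution=substitution,
        conserved_params=laws.names,
        laws=laws,
        combinatoric=combinatoric,
    )
    return reduced, substitution, laws.names


def analyze(system: ReactionSystem) -> dict:
    """Full structural report used by ``crnkit analyze``."""
    cs = reaction_complexes(system)
    lc = linkage_classes(system)
    laws = conservation_laws(system)
    return {
        "name": system.name,
        "n_species": system.n_species,
        "n_parameters": system.n_parameters,
        "n_reactions": system.n_reactions,
        "n_complexes": cs.n_complexes,
        "complexes": cs.labels(),
        "linkage_classes": lc,
        "n_linkage_classes": len(lc),
        "weakly_reversible": is_weakly_reversible(system),
        "deficiency": deficiency(system),
        "rank_S": stoich_matrices(system).S.rank(),
        "conservation_laws": laws.as_numpy().tolist(),
        "conserved_names": list(laws.names),
    }
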