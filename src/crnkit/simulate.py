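"""Numerical engines: ODE integration, Euler–Maruyama for the CLE, and four
exact stochastic simulation algorithms (SSAs).

The four SSAs all sample the same continuous-time Markov jump process exactly
and differ only in bookkeeping:

* ``direct`` — Gillespie's direct method: exponential waiting time on the
  total propensity, channel chosen by linear search of the cumulative sum
  (strict inequality, so a zero-propensity channel is unselectable);
* ``sorting_direct`` — the direct method with the search order adapted
  online: a fired channel bubbles one position toward the front, so frequent
  channels are found early;
* ``rssa`` — rejection SSA: each species is given a fluctuation interval
  around its current count, propensities are bracketed by evaluating
  mass-action terms at the interval endpoints (exact degenerate brackets for
  non-mass-action rates), and candidate firings are accepted by rejection;
  brackets are only refreshed when a species exits its interval;
* ``rssacr`` — composition-rejection RSSA: channels are binned by
  upper-bound magnitude into power-of-two groups; a group is chosen by
  composition and the member by rejection, giving scalable selection for
  large networks.

All methods consume the dependency graph from :mod:`crnkit.convert`, so only
affected propensities are recomputed after each firing.  Simulations are
bit-reproducible: (method, model, seed) determines the trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .core import CRNError, param_vector, state_vector
from .convert import JumpSet, MassActionJump, ODEModel, SDEModel

__all__ = [
    "SimulationError",
    "UnsupportedMethodError",
    "SSAConfig",
    "RNGStream",
    "Trajectory",
    "solve_ode",
    "solve_sde_em",
    "simulate_jumps",
    "prepare_jumps",
    "sample_final_states",
    "SSA_METHODS",
    "periodogram_peak",
]

#: Default tolerances for ODE integration.
DEFAULT_ABSTOL = 1e-9
DEFAULT_RELTOL = 1e-6

SSA_METHODS = ("direct", "sorting_direct", "rssa", "rssacr")


class SimulationError(CRNError):
    """A numerical simulation failed (integrator error, non-finite state, ...)."""


class UnsupportedMethodError(CRNError):
    """The requested method cannot simulate the given model."""


@dataclass(frozen=True)
class SSAConfig:
    """Tunable knobs of the rejection-based SSAs.

    ``rssa_fluctuation`` is the relative half-width of each species'
    bracketing interval (default +-10% of the current count);
    ``rssa_min_halfwidth`` an absolute floor on the half-width, applied for
    counts below ``rssa_small_count`` so that small populations do not force
    a bracket refresh on every firing.
    """

    rssa_fluctuation: float = 0.1
    rssa_min_halfwidth: int = 2
    rssa_small_count: int = 20


@dataclass(frozen=True)
class RNGStream:
    """A named pseudo-random generator plus an explicit integer seed.

    The default algorithm is PCG64, a modern 64-bit generator; the same seed
    always reproduces the identical trajectory for a given method and model.
    """

    seed: int
    algorithm: str = "PCG64"

    def generator(self) -> np.random.Generator:
        try:
            bitgen = getattr(np.random, self.algorithm)
        except AttributeError:
            raise CRNError(f"unknown RNG algorithm {self.algorithm!r}") from None
        return np.random.Generator(bitgen(self.seed))


def _as_generator(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, RNGStream):
        return rng.generator()
    if isinstance(rng, (int, np.integer)):
        return RNGStream(int(rng)).generator()
    raise CRNError(f"cannot interpret {rng!r} as a random number generator")


@dataclass(frozen=True)
class Trajectory:
    """Times, states and provenance of one simulation run."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if states.ndim != 2 or states.shape[0] != times.size:
            raise CRNError(
                f"states shape {states.shape} inconsistent with {times.size} times"
            )
        if states.shape[1] != len(self.species):
            raise CRNError("state width does not match the number of species")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise CRNError("trajectory times must be nondecreasing")

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, species_name: str) -> np.ndarray:
        return self.states[:, self.species.index(species_name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


# ---------------------------------------------------------------------------
# ODE
# ---------------------------------------------------------------------------


def solve_ode(
    model: ODEModel,
    u0,
    p=None,
    tspan=(0.0, 1.0),
    abstol: float = DEFAULT_ABSTOL,
    reltol: float = DEFAULT_RELTOL,
    saveat=None,
    method: str | None = None,
) -> Trajectory:
    """Integrate the RRE with an adaptive scipy integrator.

    The adapter contract: the integrator receives the compiled derivative,
    the model's Jacobian when available, the tolerance pair (defaults
    1e-9 absolute / 1e-6 relative) and an optional dense-output grid
    ``saveat``.  ``method`` defaults to LSODA (automatic stiff/non-stiff
    switching), or BDF when a sparse Jacobian is attached.
    """
    if abstol <= 0 or reltol <= 0:
        raise CRNError("tolerances must be positive")
    x0 = state_vector(model.species, u0)
    pv = param_vector(model.parameters, p)
    if method is None:
        method = "BDF" if model.jac_sparsity is not None else "LSODA"
    jac = None
    if model.jac is not None:
        jac = lambda t, y: model.jac(y, pv, t)
    t_eval = None if saveat is None else np.asarray(saveat, dtype=float)
    sol = solve_ivp(
        lambda t, y: model.f(y, pv, t),
        tuple(tspan),
        x0,
        method=method,
        jac=jac,
        rtol=reltol,
        atol=abstol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration of {model.name!r} failed: {sol.message}")
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        species=model.species,
        metadata={
            "method": f"ode:{method}",
            "abstol": abstol,
            "reltol": reltol,
            "model": model.name,
        },
    )


# ---------------------------------------------------------------------------
# SDE (Euler–Maruyama)
# ---------------------------------------------------------------------------


def solve_sde_em(
    model: SDEModel,
    u0,
    p=None,
    tspan=(0.0, 1.0),
    dt: float = 0.01,
    rng=None,
    saveat=None,
) -> Trajectory:
    """Fixed-step Euler–Maruyama integration of the CLE.

    Each reaction channel drives one independent Wiener process:
    ``x_{n+1} = x_n + f(x_n) dt + g(x_n) dW`` with ``dW ~ N(0, dt I_m)``.
    The run is deterministic under a fixed seed; a non-finite state aborts
    with the offending step index.
    """
    if dt <= 0:
        raise CRNError("dt must be positive")
    gen = _as_generator(rng)
    x = state_vector(model.species, u0)
    pv = param_vector(model.parameters, p)
    t0, tend = float(tspan[0]), float(tspan[1])
    n_steps = max(1, int(math.ceil((tend - t0) / dt - 1e-12)))
    m = model.n_reactions
    sqrt_dt = math.sqrt(dt)

    grid = None if saveat is None else np.asarray(saveat, dtype=float)
    times, states = [], []
    gp = 0

    def record(t, x):
        times.append(t)
        states.append(x.copy())

    if grid is None:
        record(t0, x)
    t = t0
    for step in range(n_steps):
        # record grid points covered by the current state
        t_next = min(t0 + (step + 1) * dt, tend)
        if grid is not None:
            while gp < grid.size and grid[gp] < t + 1e-15:
                record(grid[gp], x)
                gp += 1
        h = t_next - t
        dW = gen.standard_normal(m) * math.sqrt(h) if h != dt else gen.standard_normal(m) * sqrt_dt
        x = x + model.drift(x, pv, t) * h + model.noise(x, pv, t) @ dW
        if not np.all(np.isfinite(x)):
            raise SimulationError(
                f"non-finite state at step {step} (t={t_next:g}) in SDE model {model.name!r}"
            )
        t = t_next
        if grid is None:
            record(t, x)
    if grid is not None:
        while gp < grid.size:
            record(grid[gp], x)
            gp += 1
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        species=model.species,
        metadata={
            "method": "sde:euler_maruyama",
            "dt": dt,
            "model": model.name,
            "rng": repr(rng),
        },
    )


# ---------------------------------------------------------------------------
# SSA: shared numeric channel representation
# ---------------------------------------------------------------------------


class PreparedJumps:
    """Jump set bound to numeric parameter values, ready for repeated runs.

    Mass-action channels are reduced to ``(rate constant, reactant stoich,
    net change)`` triples evaluated with inlined falling-binomial arithmetic;
    other channels keep their compiled rate callables.  Building this once
    and reusing it across ensemble runs avoids recompilation.
    """

    def __init__(self, jumpset: JumpSet, p=None):
        if jumpset.has_variable_rate:
            raise UnsupportedMethodError(
                "exact SSA methods require time-homogeneous rates; "
                f"{len(jumpset.variable_rate)} variable-rate jump(s) present"
            )
        system = jumpset.system
        self.name = system.name
        self.species = system.species
        self.n_species = system.n_species
        pv = param_vector(system.parameters, p)
        pdict = dict(zip(system.parameter_symbols(), pv))
        n = jumpset.n_jumps
        self.n_jumps = n
        self.kinds = jumpset.kinds
        self.net: list[tuple[tuple[int, int], ...]] = [()] * n
        self.ma_rate: list[float | None] = [None] * n
        self.ma_reac: list[tuple[tuple[int, int], ...] | None] = [None] * n
        self.rate_fn: list[Callable | None] = [None] * n
        for jmp in jumpset.mass_action:
            j = jmp.reaction_index
            self.net[j] = jmp.net
            self.ma_rate[j] = float(sp.nsimplify(jmp.rate.subs(pdict)))
            self.ma_reac[j] = jmp.reactant_stoich
        pv_tuple = tuple(pv)
        for jmp in (*jumpset.constant_rate, *jumpset.variable_rate):
            j = jmp.reaction_index
            self.net[j] = jmp.net
            prop = jumpset.propensities[j]
            self.rate_fn[j] = lambda x, t=0.0, _prop=prop, _pv=pv_tuple: _prop(x, _pv, t)
        self.deps = jumpset.dependency or tuple(
            tuple(range(n)) for _ in range(n)
        )
        # species -> mass-action channels whose brackets depend on it (RSSA)
        self.ma_by_species: list[list[int]] = [[] for _ in range(self.n_species)]
        # species -> non-mass-action channels whose exact rate depends on it
        self.cr_by_species: list[list[int]] = [[] for _ in range(self.n_species)]
        for jmp in jumpset.mass_action:
            for i, _ in jmp.reactant_stoich:
                self.ma_by_species[i].append(jmp.reaction_index)
        for jmp in jumpset.constant_rate:
            det = set(jmp.rate_species)
            r = system.reactions[jmp.reaction_index]
            if not r.only_use_rate:
                idx = {s: k for k, s in enumerate(system.species)}
                det |= {idx[name] for name, _ in r.substrates}
            for i in det:
                self.cr_by_species[i].append(jmp.reaction_index)

    def propensity(self, j: int, x) -> float:
        k = self.ma_rate[j]
        if k is not None:
            a = k
            for i, nu in self.ma_reac[j]:
                xi = x[i]
                if nu == 1:
                    a *= xi
                elif nu == 2:
                    a *= xi * (xi - 1) * 0.5
                else:
                    for d in range(nu):
                        a *= xi - d
                    a /= math.factorial(nu)
            return a
        return self.rate_fn[j](x)

    def ma_bound(self, j: int, counts) -> float:
        """Mass-action propensity at a vector of (bound) counts."""
        a = self.ma_rate[j]
        for i, nu in self.ma_reac[j]:
            xi = counts[i]
            if nu == 1:
                a *= xi
            elif nu == 2:
                a *= xi * (xi - 1) * 0.5
            else:
                for d in range(nu):
                    a *= xi - d
                a /= math.factorial(nu)
        return max(a, 0.0)


def prepare_jumps(jumpset: JumpSet, p=None) -> PreparedJumps:
    """Bind a classified jump set to parameter values for repeated simulation."""
    return PreparedJumps(jumpset, p)


class _Recorder:
    """Accumulates (time, state) pairs, honouring an optional save grid.

    With a grid, the state recorded at grid time s is the state immediately
    before the first jump occurring after s.  Without one, every event is
    recorded (including the initial state).
    """

    def __init__(self, grid, t0: float, x0: list):
        self.grid = grid
        self.gp = 0
        self.times: list[float] = []
        self.states: list[list] = []
        if grid is None:
            self.times.append(t0)
            self.states.append(list(x0))

    def before_jump(self, t_new: float, x: list):
        if self.grid is not None:
            g, n = self.grid, self.grid.size
            while self.gp < n and g[self.gp] < t_new:
                self.times.append(float(g[self.gp]))
                self.states.append(list(x))
                self.gp += 1

    def after_jump(self, t: float, x: list):
        if self.grid is None:
            self.times.append(t)
            self.states.append(list(x))

    def finish(self, tend: float, x: list):
        if self.grid is None:
            if not self.times or self.times[-1] < tend:
                self.times.append(tend)
                self.states.append(list(x))
        else:
            g, n = self.grid, self.grid.size
            while self.gp < n:
                self.times.append(float(g[self.gp]))
                self.states.append(list(x))
                self.gp += 1


def simulate_jumps(
    jumpset: JumpSet | PreparedJumps,
    u0,
    p=None,
    tspan=(0.0, 1.0),
    method: str = "direct",
    rng=None,
    saveat=None,
    config: SSAConfig = SSAConfig(),
) -> Trajectory:
    """Simulate the jump process exactly with one of the four SSA variants.

    ``method`` is one of ``direct``, ``sorting_direct``, ``rssa``,
    ``rssacr``.  ``u0`` must be nonnegative integers.  When the total
    propensity reaches zero the trajectory advances to the end of ``tspan``.
    Variable-rate jumps are rejected (time-inhomogeneous intensities are out
    of scope for these exact methods).
    """
    if method not in SSA_METHODS:
        raise UnsupportedMethodError(
            f"unknown SSA method {method!r}; available: {SSA_METHODS}"
        )
    prep = jumpset if isinstance(jumpset, PreparedJumps) else PreparedJumps(jumpset, p)
    x0f = state_vector(prep.species, u0)
    if np.any(x0f < 0) or np.any(x0f != np.round(x0f)):
        raise CRNError("SSA initial conditions must be nonnegative integers")
    x = [int(v) for v in x0f]
    gen = _as_generator(rng)
    t0, tend = float(tspan[0]), float(tspan[1])
    grid = None if saveat is None else np.asarray(saveat, dtype=float)
    rec = _Recorder(grid, t0, x)

    runner = _SSA_RUNNERS[method]
    runner(prep, x, t0, tend, gen, rec, config)

    seed_repr = rng.seed if isinstance(rng, RNGStream) else rng
    return Trajectory(
        times=np.array(rec.times),
        states=np.array(rec.states, dtype=np.int64),
        species=prep.species,
        metadata={"method": f"ssa:{method}", "model": getattr(prep, "name", ""),
                  "seed": seed_repr if isinstance(seed_repr, (int, np.integer)) else None},
    )


def _apply(net, x):
    for i, d in net:
        x[i] += d


def _ssa_direct(prep: PreparedJumps, x, t0, tend, gen, rec, config, *, sorting=False):
    n = prep.n_jumps
    a = [prep.propensity(j, x) for j in range(n)]
    a0 = sum(a)
    order = list(range(n))
    deps = prep.deps
    rand = gen.random
    t = t0
    resync = 0
    while True:
        if a0 <= 0.0:
            rec.finish(tend, x)
            return
        t += -math.log(rand()) / a0
        rec.before_jump(min(t, tend), x)
        if t > tend:
            rec.finish(tend, x)
            return
        # strict cumulative-sum selection: zero-propensity channels unselectable
        r = rand() * a0
        c = 0.0
        pos = -1
        for k in range(n):
            c += a[order[k]]
            if r < c:
                pos = k
                break
        if pos < 0:  # float round-off: take the last positive channel
            for k in range(n - 1, -1, -1):
                if a[order[k]] > 0.0:
                    pos = k
                    break
        j = order[pos]
        _apply(prep.net[j], x)
        for i in deps[j]:
            new = prep.propensity(i, x)
            a0 += new - a[i]
            a[i] = new
        resync += 1
        if resync >= 4096:  # guard against float drift in the running total
            a0 = sum(a)
            resync = 0
        if sorting and pos > 0:
            order[pos - 1], order[pos] = order[pos], order[pos - 1]
        rec.after_jump(t, x)


def _ssa_sorting_direct(prep, x, t0, tend, gen, rec, config):
    _ssa_direct(prep, x, t0, tend, gen, rec, config, sorting=True)


class _Brackets:
    """Species fluctuation intervals and per-channel propensity brackets."""

    def __init__(self, prep: PreparedJumps, x, config: SSAConfig):
        self.prep = prep
        self.cfg = config
        self.lo = [0] * prep.n_species
        self.hi = [0] * prep.n_species
        for i, xi in enumerate(x):
            self._set_interval(i, xi)
        n = prep.n_jumps
        self.ub = [0.0] * n
        self.lb = [0.0] * n
        for j in range(n):
            self._refresh_channel(j, x)

    def _set_interval(self, i: int, xi: int):
        frac = self.cfg.rssa_fluctuation
        hw = int(math.ceil(frac * xi))
        if xi < self.cfg.rssa_small_count:
            hw = max(hw, self.cfg.rssa_min_halfwidth)
        self.lo[i] = max(xi - hw, 0)
        self.hi[i] = xi + hw

    def _refresh_channel(self, j: int, x):
        prep = self.prep
        if prep.ma_rate[j] is not None:
            self.ub[j] = prep.ma_bound(j, self.hi)
            self.lb[j] = prep.ma_bound(j, self.lo)
        else:
            # general rates get exact (degenerate) brackets, refreshed on any
            # change of a determining species
            a = prep.rate_fn[j](x)
            self.ub[j] = a
            self.lb[j] = a

    def update_after_fire(self, j: int, x) -> list[tuple[int, float]]:
        """Refresh intervals/brackets after channel j fired.

        Mass-action brackets are only recomputed when a species leaves its
        fluctuation interval; degenerate brackets of general-rate channels
        are refreshed on any change of a determining species.  Returns
        ``(channel, old upper bound)`` pairs for incremental total updates
        and group migration.
        """
        prep = self.prep
        touched: set[int] = set()
        for i, _ in prep.net[j]:
            if not (self.lo[i] <= x[i] <= self.hi[i]):
                self._set_interval(i, x[i])
                touched.update(prep.ma_by_species[i])
            touched.update(prep.cr_by_species[i])
        out = []
        for c in sorted(touched):
            old = self.ub[c]
            self._refresh_channel(c, x)
            out.append((c, old))
        return out


def _ssa_rssa(prep: PreparedJumps, x, t0, tend, gen, rec, config):
    n = prep.n_jumps
    br = _Brackets(prep, x, config)
    ub, lb = br.ub, br.lb
    a0ub = sum(ub)
    rand = gen.random
    t = t0
    resync = 0
    while True:
        if a0ub <= 0.0:
            rec.finish(tend, x)
            return
        t += -math.log(rand()) / a0ub
        rec.before_jump(min(t, tend), x)
        if t > tend:
            rec.finish(tend, x)
            return
        r = rand() * a0ub
        c = 0.0
        j = -1
        for k in range(n):
            c += ub[k]
            if r < c:
                j = k
                break
        if j < 0:
            for k in range(n - 1, -1, -1):
                if ub[k] > 0.0:
                    j = k
                    break
        u2 = rand() * ub[j]
        accept = u2 <= lb[j] or u2 <= prep.propensity(j, x)
        if accept:
            _apply(prep.net[j], x)
            for cch, old in br.update_after_fire(j, x):
                a0ub += ub[cch] - old
            rec.after_jump(t, x)
            resync += 1
            if resync >= 4096:  # guard against float drift
                a0ub = sum(ub)
                resync = 0
        # rejected trials consume time but fire nothing


def _ssa_rssacr(prep: PreparedJumps, x, t0, tend, gen, rec, config):
    n = prep.n_jumps
    br = _Brackets(prep, x, config)
    ub, lb = br.ub, br.lb

    # power-of-two groups over upper bounds: channel with ub in (2^(e-1), 2^e]
    groups: dict[int, list[int]] = {}
    gsum: dict[int, float] = {}
    chan_group = [None] * n
    chan_pos = [0] * n

    def group_exp(u: float) -> int:
        m, e = math.frexp(u)
        if m == 0.5:  # exact power of two: u = 2^(e-1)
            return e - 1
        return e

    def insert(j: int):
        u = ub[j]
        if u <= 0.0:
            chan_group[j] = None
            return
        e = group_exp(u)
        lst = groups.setdefault(e, [])
        gsum.setdefault(e, 0.0)
        chan_group[j] = e
        chan_pos[j] = len(lst)
        lst.append(j)
        gsum[e] += u

    def remove(j: int, old_ub: float):
        e = chan_group[j]
        if e is None:
            return
        lst = groups[e]
        pos = chan_pos[j]
        last = lst[-1]
        lst[pos] = last
        chan_pos[last] = pos
        lst.pop()
        gsum[e] -= old_ub
        if not lst:
            del groups[e]
            del gsum[e]
        chan_group[j] = None

    for j in range(n):
        insert(j)
    total = sum(gsum.values())
    rand = gen.random
    t = t0
    resync = 0
    while True:
        if total <= 0.0:
            rec.finish(tend, x)
            return
        t += -math.log(rand()) / total
        rec.before_jump(min(t, tend), x)
        if t > tend:
            rec.finish(tend, x)
            return
        # composition step: choose a group proportionally to its bound mass
        r = rand() * total
        c = 0.0
        chosen_e = None
        for e, s in gsum.items():
            c += s
            if r < c:
                chosen_e = e
                break
        if chosen_e is None:
            chosen_e = next(reversed(gsum))
        lst = groups[chosen_e]
        bound = math.ldexp(1.0, chosen_e)  # 2^e >= every ub in the group
        # rejection step: uniform member, accept with prob ub/2^e
        while True:
            k = int(rand() * len(lst))
            if k == len(lst):
                k -= 1
            j = lst[k]
            if rand() * bound <= ub[j]:
                break
        u2 = rand() * ub[j]
        accept = u2 <= lb[j] or u2 <= prep.propensity(j, x)
        if accept:
            _apply(prep.net[j], x)
            for cch, old in br.update_after_fire(j, x):
                new = ub[cch]
                if new != old:
                    remove(cch, old)
                    insert(cch)
                    total += new - old
            rec.after_jump(t, x)
            resync += 1
            if resync >= 4096:
                total = sum(gsum.values())
                resync = 0
        # rejected trials consume time but fire nothing


_SSA_RUNNERS = {}


def _register_runners():
    _SSA_RUNNERS["direct"] = _ssa_direct
    _SSA_RUNNERS["sorting_direct"] = _ssa_sorting_direct
    _SSA_RUNNERS["rssa"] = _ssa_rssa
    _SSA_RUNNERS["rssacr"] = _ssa_rssacr


_register_runners()


def sample_final_states(
    jumpset: JumpSet | PreparedJumps,
    u0,
    p=None,
    t_end: float = 1.0,
    n_paths: int = 1000,
    method: str = "direct",
    seed: int = 0,
    t0: float = 0.0,
    config: SSAConfig = SSAConfig(),
) -> np.ndarray:
    """Simulate ``n_paths`` independent trajectories, returning states at ``t_end``.

    One generator (seeded once) drives all paths, so the ensemble is fully
    reproducible.  The jump set is prepared once and reused.
    """
    prep = jumpset if isinstance(jumpset, PreparedJumps) else PreparedJumps(jumpset, p)
    gen = RNGStream(seed).generator()
    out = np.empty((n_paths, prep.n_species), dtype=np.int64)
    for k in range(n_paths):
        traj = simulate_jumps(
            prep, u0, tspan=(t0, t_end), method=method, rng=gen,
            saveat=[t_end], config=config,
        )
        out[k] = traj.states[-1]
    return out


def periodogram_peak(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Dominant nonzero frequency of a uniformly sampled signal.

    Returns ``(frequency, prominence)`` where prominence is the ratio of the
    peak periodogram power to the median power over nonzero frequencies.
    Used to detect noise-induced oscillations in stochastic trajectories.
    """
    from scipy.signal import periodogram

    times = np.asarray(times, float)
    values = np.asarray(values, float)
    dt = np.diff(times)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise CRNError("periodogram_peak requires a uniform time grid")
    fs = 1.0 / dt[0]
    f, pxx = periodogram(values - values.mean(), fs=fs)
    f, pxx = f[1:], pxx[1:]  # drop DC
    if not pxx.size or pxx.max() == 0:
        return 0.0, 0.0
    k = int(np.argmax(pxx))
    med = float(np.median(pxx))
    prominence = float(pxx[k] / med) if med > 0 else float("inf")
    return float(f[k]), prominence
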