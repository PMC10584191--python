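# Methods

This note documents the models crnkit implements, the conventions it pins
down, the numerical choices behind the simulators, and what the bundled
models can and cannot demonstrate.

## The intermediate representation

A network is an ordered list of species, parameters, and reactions. Each
reaction holds a symbolic rate expression (a sympy `Expr`), substrate and
product multisets, and an `only_use_rate` flag. Unless that flag is set, the
full rate law is the rate expression *times* the mass-action factor over the
substrates; with the flag, the expression is the complete law (used, e.g.,
for imported BioNetGen reactions and phenomenological rate laws supplied
programmatically).

Species order is first textual appearance; it fixes the row order of every
matrix and the column order of every trajectory. Stoichiometric matrices and
all network-theory computations use exact rational arithmetic, so no rank or
null-space tolerance exists anywhere in the structural code. Parametric and
non-integer stoichiometries are carried in the IR but rejected with a clear
error at matrix/jump construction; random-variable stoichiometry is out of
scope.

### Rate-law conventions

Two conventions coexist and are used deliberately:

* **Combinatoric (default for ODE/SDE conversion):**
  `rate · Π x_i^{ν_i}/ν_i!`. This matches the stochastic convention in the
  large-copy-number limit, so deterministic and jump models of the same
  network agree to leading order.
* **Classic:** `rate · Π x_i^{ν_i}`, selectable per conversion call
  (`combinatoric=False`). The Brusselator fixture pins this convention so
  the textbook Hopf criterion `B > 1 + A²` holds exactly with its printed
  rate constants.

The stochastic propensity is always the binomial form
`a(x) = rate · Π C(x_i, ν_i)` (falling factorial over `ν!`). The literature
often leaves this implicit; it is stated here because it is the single
source of truth every SSA consumes, and because it differs from the classic
rate law at low copy numbers (`x²` vs `x(x−1)/2`).

## The DSL

One statement per line: `rate, reactants ARROW products`, with arrows
`-->`, `<--`, `<-->`, `#` comments, `0`/`∅` for the empty complex,
coefficient–species juxtaposition (`2X`) or explicit `2*X`, and decimal
coefficients (converted to exact rationals). Rates are arbitrary arithmetic
expressions; `mm(S, v, K)` and `hill(S, v, K, n)` are provided and expand to
plain expressions at parse time, so `hill(·, ·, ·, 1)` is *identically* the
Michaelis–Menten form. Any non-species symbol in a rate becomes a parameter;
`t` is the reserved time symbol.

Bundled tuples broadcast elementwise (`(k1,k2), (X,Y) --> 0` is two
degradations); a reversible line needs a rate pair `(kf, kr)` and plain
(non-tuple) complexes — forward first, then backward. `<--` swaps sides and
parses as `-->`. Nested-tuple corner syntax is rejected rather than guessed.
No DSL arrow maps to `only_use_rate`; that flag is reachable only
programmatically, since the notation above always implies mass-action
scaling. Parsing is pure: identical text gives an identical system.

## Network analysis

Standard chemical-reaction-network-theory definitions are used, with the
empty complex as an ordinary node:

* complexes are deduplicated reaction sides; the incidence factorization
  `S = Y·Z` is asserted on construction;
* linkage classes are connected components of the undirected complex graph,
  weak reversibility requires every weakly connected component of the
  directed graph to be strongly connected (networkx);
* deficiency is `δ = n − ℓ − rank(S)` with the rank computed rationally;
* conservation laws are sympy's rational basis of the left null space of
  `S`, scaled row-wise to coprime integers with a positive leading entry.

Conserved-species elimination solves, per law, for one dependent species —
the one with the largest `|γ|` entry, ties broken toward the latest species
in order; if that greedy choice happens to give a singular submatrix, the
RREF pivot columns are used instead. The dependent species are substituted
symbolically into all rate laws, each law contributes a new conserved
parameter `C_k = γ_k·x(0)`, and the reduced system of dimension
`n − n_laws` has a non-singular Jacobian where the full system is singular
along every conservation relation. With no laws the transformation is the
identity.

## Model generation

All symbolic → numeric compilation happens once at conversion time
(`sympy.lambdify`); the simulators only call natives.

* **ODE:** a single compiled derivative `f(x, p, t) = S·v`. Jacobians are
  symbolic by default (finite differences available as an option); the
  sparse variant stores the structural pattern (symbolic nonzeros, a
  superset of the numeric nonzeros) and returns CSC matrices.
* **SDE:** the CLE with one Wiener channel per reaction. Noise
  coefficients wrap the rate law in an absolute value,
  `g[i,j] = S[i,j]·sqrt(|v_j|)`, so transient negative excursions of the
  continuous state cannot produce NaNs. This guard changes nothing in the
  physical regime `v_j ≥ 0`.
* **Jumps:** each reaction is classified *syntactically* by the free
  symbols of its rate: no species and no `t` → mass-action; no `t` →
  constant-rate; otherwise variable-rate. Syntactic analysis is conservative
  (an expression that only cancels algebraically to a constant is kept in
  the more general class) — soundness is preferred over minimality, and the
  classified representation is verified against the generic propensity in
  the test suite.

The dependency graph sets jump `i` as a dependent of jump `j` iff `i`'s
rate-determining species (substrates for mass-action, all species in the
rate expression otherwise) intersect `j`'s net-change species. Applying the
rule with `i = j` makes self-dependence explicit, so update loops never keep
a stale propensity. The graph is by construction a superset of the true
firing-induced dependencies; the tests confirm this by brute force.

## Simulators

* **ODE:** an adapter over `scipy.integrate.solve_ivp` — LSODA by default
  (automatic stiff/non-stiff switching), BDF when a sparse Jacobian is
  attached. Default tolerances are `abstol 1e-9`, `reltol 1e-6`.
* **Euler–Maruyama:** fixed step `dt`, one independent `N(0, dt)` increment
  per reaction channel per step. Weak order 1 is verified on the linear
  birth–death model with coupled-seed ensembles.
* **SSAs.** All four methods are exact samplers of the same jump process;
  they are validated against the analytic birth–death solution
  (Poisson(b/d) at stationarity) and against each other (pairwise
  Kolmogorov–Smirnov at n = 10⁴).
  * *direct:* exponential waiting time on the total propensity; channel by
    linear search with strict cumulative-sum inequality (`u·a0 < cumsum`),
    which makes zero-propensity channels unselectable.
  * *sorting direct:* the fired channel swaps one position toward the front
    of the search order (bubble-up); ties cannot arise as the order is
    positional.
  * *RSSA:* each species gets a fluctuation interval of ±10% of its current
    count, with an absolute half-width floor of 2 for counts below 20
    (exposed in `SSAConfig`). Mass-action propensities are bracketed by
    evaluation at the interval endpoints (they are monotone in each
    substrate count); general state-dependent rates get exact degenerate
    brackets refreshed on any change of a determining species, which keeps
    the rejection step exact without assuming monotonicity. Brackets are
    refreshed only when a species exits its interval.
  * *RSSACR:* channels are binned by upper bound into powers of two
    (`ub ∈ (2^{e−1}, 2^e]`); a group is chosen by composition over group
    sums, the member by uniform draw + rejection against `2^e` (acceptance
    ≥ 1/2), followed by the RSSA accept/reject. Channels migrate groups
    when their bound changes; empty groups are dropped.

  Running totals of propensities/bounds are resynchronized every 4096
  firings to cancel floating-point drift. The default generator is PCG64
  with an explicit integer seed; a (method, model, seed) triple reproduces
  the trajectory bit for bit, and the CLI refuses stochastic runs without a
  seed.

Variable-rate (time-inhomogeneous) jumps are rejected by all four methods;
τ-leaping, hybrid ODE–jump coupling, and adaptive SDE schemes are out of
scope.

## BioNetGen .net import

The importer targets the elementary-rate-constant dialect: `parameters`,
`species`, `reactions` blocks, 1-based indices (converted to 0-based at the
boundary only), rates like `k1` or `2*kon` with the statistical-factor
multiplier taken as printed. Each reaction line becomes an explicit-rate
reaction with law `(multiplier·k)·Π x^ν` over the substrate multiplicities —
the BioNetGen convention, which reproduces the benchmark models' dynamics
without double-counting symmetry factors. Functional rate laws referencing
species are rejected with a line-numbered error, as are missing blocks and
dangling indices. Species patterns are sanitized to identifiers
(non-alphanumerics → `_`, numeric-suffix collision scheme).

## Bundled models and what the tests show

The fixtures are small, analytically tractable networks chosen so that every
pipeline stage has an exact or statistical oracle:

* **brusselator** — Hopf bifurcation at `B = 1 + A²` (classic convention
  pinned); exercises the DSL, symbolic Jacobians, all three scales, and
  noise-induced oscillation below the Hopf point (A=1, B=1.8, volume 100,
  i.e. copy numbers of order 100–200, where quasi-cycles are strongly
  amplified);
* **birth_death** — linear, with Poisson stationary law: the SSA exactness
  and CLE mean/convergence oracles;
* **dimerization** — one integer conservation law `X + 2·X2`: exact
  invariance along jump paths and conservation elimination;
* **mm_enzyme** — two conservation laws, a 4-species stress case for
  elimination and dependency graphs.

These models validate correctness of the algorithms, not their scalability:
they have 1–4 species, so the performance-oriented structure of the sorting
/rejection/composition-rejection methods is exercised for correctness only,
and no claim is made about relative runtimes on large rule-based networks.
Statistical checks use n = 10⁴ paths (3·SE acceptance bands, KS p > 0.001)
with fixed seeds, and ensembles of 1000–4000 paths for the CLE; these sizes
make the checks deterministic and fast while keeping the standard errors an
order of magnitude below the tested effects.

## Known limitations

* No SBML or `.bngl` rule files (only generated `.net`), no groups or
  observables evaluation.
* No physical units; rate constants are assumed consistent with the chosen
  scale.
* Classification never simplifies rates before inspecting symbols, so
  algebraically constant expressions may be simulated through the slower
  general-rate path.
* The DSL has no notation for `only_use_rate` reactions; they cannot be
  round-tripped through text.
* The conservation-elimination API produces an ODE-only reduced system;
  reduced SDE/jump models are not generated.
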