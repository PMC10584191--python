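"""Model and trajectory IO plus bundled fixture models.

Covers three file formats:

* ``.crn`` — the plain-text reaction-notation DSL (see :mod:`crnkit.dsl`);
* BioNetGen-generated ``.net`` network files (reader and a minimal writer
  used for round-trip checks).  Rate constants are taken *as printed*,
  including BioNetGen's statistical-factor multipliers, and the imported
  reactions therefore carry explicit rate laws of the form
  ``(multiplier*k) * prod_i x_i^nu_i`` over the substrate multiplicities —
  the BioNetGen convention, which avoids double-counting symmetry factors;
* CSV/JSON trajectory serialization with lossless float round-trip.

The fixture models (Brusselator, birth–death, dimerization, Michaelis–Menten
enzyme kinetics) exercise every pipeline stage and pin canonical parameter
sets.  The Brusselator fixture uses the classic (non-combinatoric) rate-law
convention so that its Hopf criterion is exactly ``B > 1 + A**2``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import sympy as sp

from .core import (
    CRNError,
    Reaction,
    ReactionSystem,
    make_reaction,
)
from .simulate import Trajectory

__all__ = [
    "NetImportError",
    "NetFile",
    "read_bngl_net",
    "write_bngl_net",
    "write_timeseries",
    "read_timeseries",
    "Fixture",
    "fixture_model",
    "scaled_brusselator",
    "FIXTURE_NAMES",
]


class NetImportError(CRNError):
    """A .net file could not be parsed; message names the block/line."""


# ---------------------------------------------------------------------------
# .net import
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetFile:
    """Parsed blocks of a BioNetGen .net file (1-based indices as printed)."""

    parameters: dict[str, float]
    species: tuple[tuple[int, str, float], ...]  # (index, pattern, initial)
    reactions: tuple[tuple[int, tuple[int, ...], tuple[int, ...], str], ...]
    path: str = ""


_BLOCK_RE = re.compile(r"^begin\s+(\w[\w ]*)$")


def _read_blocks(lines: list[str], path: str) -> dict[str, list[tuple[int, str]]]:
    blocks: dict[str, list[tuple[int, str]]] = {}
    current = None
    opened_at = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _BLOCK_RE.match(line)
        if m:
            if current is not None:
                raise NetImportError(
                    f"{path}:{lineno}: 'begin {m.group(1)}' inside open block "
                    f"{current!r} (opened at line {opened_at})"
                )
            current = m.group(1).strip()
            opened_at = lineno
            blocks.setdefault(current, [])
            continue
        if line.startswith("end"):
            name = line[3:].strip()
            if current is None or name != current:
                raise NetImportError(
                    f"{path}:{lineno}: 'end {name}' does not close any open block"
                )
            current = None
            continue
        if current is not None:
            blocks[current].append((lineno, line))
    if current is not None:
        raise NetImportError(
            f"{path}: missing 'end {current}' (block opened at line {opened_at})"
        )
    return blocks


def _sanitize(pattern: str, used: set[str]) -> str:
    name = re.sub(r"\W", "_", pattern)
    if not name or name[0].isdigit():
        name = "S_" + name
    base = name
    k = 2
    while name in used:
        name = f"{base}_{k}"
        k += 1
    used.add(name)
    return name


def parse_net_file(path) -> NetFile:
    """Parse the parameters/species/reactions blocks of a .net file."""
    path = Path(path)
    if not path.exists():
        raise NetImportError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    blocks = _read_blocks(lines, str(path))
    for required in ("parameters", "species", "reactions"):
        if required not in blocks:
            raise NetImportError(f"{path}: missing 'begin {required}' block")

    params: dict[str, float] = {}
    for lineno, line in blocks["parameters"]:
        parts = line.split()
        if len(parts) < 3:
            raise NetImportError(f"{path}:{lineno}: malformed parameter line {line!r}")
        _, name, value_txt = parts[0], parts[1], parts[2]
        try:
            value = float(
                sp.sympify(value_txt, locals={k: sp.Float(v) for k, v in params.items()})
            )
        except Exception as exc:
            raise NetImportError(
                f"{path}:{lineno}: cannot evaluate parameter {name!r} = {value_txt!r}: {exc}"
            ) from exc
        params[name] = value

    species: list[tuple[int, str, float]] = []
    for lineno, line in blocks["species"]:
        parts = line.split()
        if len(parts) < 3:
            raise NetImportError(f"{path}:{lineno}: malformed species line {line!r}")
        try:
            idx = int(parts[0])
            init = float(
                sp.sympify(parts[2], locals={k: sp.Float(v) for k, v in params.items()})
            )
        except NetImportError:
            raise
        except Exception as exc:
            raise NetImportError(
                f"{path}:{lineno}: cannot parse species line {line!r}: {exc}"
            ) from exc
        species.append((idx, parts[1], init))

    n_species = len(species)
    indices = {idx for idx, _, _ in species}
    reactions: list[tuple[int, tuple[int, ...], tuple[int, ...], str]] = []
    for lineno, line in blocks["reactions"]:
        parts = line.split()
        if len(parts) < 4:
            raise NetImportError(f"{path}:{lineno}: malformed reaction line {line!r}")
        try:
            ridx = int(parts[0])
            subs = tuple(int(v) for v in parts[1].split(",") if int(v) != 0)
            prods = tuple(int(v) for v in parts[2].split(",") if int(v) != 0)
        except ValueError as exc:
            raise NetImportError(
                f"{path}:{lineno}: bad species index in {line!r}: {exc}"
            ) from exc
        for i in (*subs, *prods):
            if i not in indices:
                raise NetImportError(
                    f"{path}:{lineno}: dangling species index {i} "
                    f"(valid: 1..{n_species})"
                )
        rate_txt = parts[3]
        reactions.append((ridx, subs, prods, rate_txt))
    return NetFile(
        parameters=params,
        species=tuple(species),
        reactions=tuple(reactions),
        path=str(path),
    )


def read_bngl_net(path) -> tuple[ReactionSystem, dict[str, float], dict[str, float]]:
    """Import a BioNetGen .net file.

    Returns ``(system, initial_conditions, parameter_values)``.  Species
    pattern strings are sanitized to identifiers (non-alphanumerics become
    underscores, collisions get numeric suffixes); each reaction becomes an
    explicit-rate reaction with rate law ``rate_expr * prod x^nu`` (rate
    constants as printed, statistical factors folded in).  Functional rate
    laws that reference species are rejected.
    """
    nf = parse_net_file(path)
    used: set[str] = set()
    name_of: dict[int, str] = {}
    u0: dict[str, float] = {}
    for idx, pattern, init in nf.species:
        name = _sanitize(pattern, used)
        name_of[idx] = name
        u0[name] = init

    param_syms = {k: sp.Symbol(k) for k in nf.parameters}
    reactions: list[Reaction] = []
    for ridx, subs_idx, prods_idx, rate_txt in nf.reactions:
        try:
            rate_const = sp.sympify(rate_txt, locals=dict(param_syms))
        except Exception as exc:
            raise NetImportError(
                f"{nf.path}: reaction {ridx}: unparseable rate {rate_txt!r}: {exc}"
            ) from exc
        bad = {s.name for s in rate_const.free_symbols} - set(nf.parameters)
        if bad:
            raise NetImportError(
                f"{nf.path}: reaction {ridx}: functional rate laws are not "
                f"supported (rate references {sorted(bad)}); only "
                "elementary rate constants over the parameters block are accepted"
            )
        sub_counts: dict[str, int] = {}
        for i in subs_idx:
            sub_counts[name_of[i]] = sub_counts.get(name_of[i], 0) + 1
        prod_counts: dict[str, int] = {}
        for i in prods_idx:
            prod_counts[name_of[i]] = prod_counts.get(name_of[i], 0) + 1
        # BioNetGen convention: propensity/rate law is rate * prod x^nu
        law = rate_const
        for sname, nu in sub_counts.items():
            law = law * sp.Symbol(sname) ** nu
        reactions.append(
            make_reaction(
                law,
                list(sub_counts.items()),
                list(prod_counts.items()),
                only_use_rate=True,
            )
        )
    # keep the file's species order, including species untouched by reactions
    species_order = tuple(name_of[idx] for idx, _, _ in nf.species)
    parameters = tuple(nf.parameters)
    system = ReactionSystem(
        name=Path(nf.path).stem,
        species=species_order,
        parameters=parameters,
        reactions=tuple(reactions),
    )
    return system, u0, dict(nf.parameters)


def write_bngl_net(system: ReactionSystem, u0: dict, params: dict, path) -> None:
    """Write an equivalent .net reaction table for an imported system.

    Only systems in the importer's normal form (explicit rate laws
    ``const * prod x^nu``) can be exported; used for round-trip validation.
    """
    lines = ["begin parameters"]
    for k, (name, value) in enumerate(params.items(), start=1):
        lines.append(f"  {k} {name} {value!r}")
    lines.append("end parameters")
    lines.append("begin species")
    index = {}
    for k, name in enumerate(system.species, start=1):
        index[name] = k
        lines.append(f"  {k} {name} {u0.get(name, 0.0)!r}")
    lines.append("end species")
    lines.append("begin reactions")
    for k, r in enumerate(system.reactions, start=1):
        denom = sp.Integer(1)
        subs_list, prods_list = [], []
        for name, nu in r.substrates:
            denom *= sp.Symbol(name) ** nu
            subs_list.extend([index[name]] * int(nu))
        for name, nu in r.products:
            prods_list.extend([index[name]] * int(nu))
        rate_const = sp.cancel(r.rate / denom)
        if {s.name for s in rate_const.free_symbols} & set(system.species):
            raise CRNError(
                f"reaction {k} is not in importer normal form; cannot export"
            )
        sub_txt = ",".join(map(str, subs_list)) or "0"
        prod_txt = ",".join(map(str, prods_list)) or "0"
        lines.append(f"  {k} {sub_txt} {prod_txt} {sp.sstr(rate_const)}")
    lines.append("end reactions")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory serialization
# ---------------------------------------------------------------------------


def write_timeseries(traj: Trajectory, path, format: str = "csv") -> None:
    """Serialize a trajectory to CSV (``time,<species...>`` header) or JSON.

    Floats are written with 17 significant digits, so a read-back reproduces
    times and states bit-exactly.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", *traj.species])
            for t, row in zip(traj.times, traj.states):
                w.writerow([f"{t:.17g}", *(f"{v:.17g}" for v in row)])
    elif format == "json":
        payload = {
            "metadata": {k: v for k, v in traj.metadata.items()
                         if isinstance(v, (str, int, float, bool, type(None)))},
            "species": list(traj.species),
            "times": [float(t) for t in traj.times],
            "states": [[float(v) for v in row] for row in traj.states],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise CRNError(f"unknown trajectory format {format!r} (use csv or json)")


def read_timeseries(path, format: str | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_timeseries`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        payload = json.loads(path.read_text())
        return Trajectory(
            times=np.array(payload["times"], dtype=float),
            states=np.array(payload["states"], dtype=float).reshape(
                len(payload["times"]), len(payload["species"])
            ),
            species=tuple(payload["species"]),
            metadata=payload.get("metadata", {}),
        )
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    if not header or header[0] != "time":
        raise CRNError(f"{path}: not a crnkit timeseries CSV")
    species = tuple(header[1:])
    data = np.array([[float(v) for v in row] for row in rows[1:]], dtype=float)
    if data.size == 0:
        data = data.reshape(0, len(species) + 1)
    return Trajectory(
        times=data[:, 0], states=data[:, 1:], species=species, metadata={}
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """A bundled model with canonical parameter values and initial state."""

    system: ReactionSystem
    params: dict[str, float]
    u0: dict[str, float]
    tspan: tuple[float, float]
    combinatoric: bool = True
    notes: str = ""


def _brusselator_system(name: str = "brusselator") -> ReactionSystem:
    A, B = sp.Symbol("A"), sp.Symbol("B")
    one = sp.Integer(1)
    reactions = (
        make_reaction(A, [], [("X", 1)]),
        make_reaction(one, [("X", 2), ("Y", 1)], [("X", 3)]),
        make_reaction(B, [("X", 1)], [("Y", 1)]),
        make_reaction(one, [("X", 1)], []),
    )
    return ReactionSystem.from_reactions(reactions, name=name)


_FIXTURES = {}


def _fixture(fn):
    _FIXTURES[fn.__name__.lstrip("_")] = fn
    return fn


@_fixture
def _brusselator() -> Fixture:
    return Fixture(
        system=_brusselator_system(),
        params={"A": 1.0, "B": 3.0},
        u0={"X": 1.0, "Y": 1.0},
        tspan=(0.0, 50.0),
        combinatoric=False,
        notes=(
            "Classic-form Brusselator: dX/dt = A + X^2 Y - (B+1) X, "
            "dY/dt = B X - X^2 Y.  The non-combinatoric convention is pinned "
            "so the Hopf criterion is exactly B > 1 + A^2."
        ),
    )


@_fixture
def _birth_death() -> Fixture:
    b, d = sp.Symbol("b"), sp.Symbol("d")
    system = ReactionSystem.from_reactions(
        (
            make_reaction(b, [], [("X", 1)]),
            make_reaction(d, [("X", 1)], []),
        ),
        name="birth_death",
    )
    return Fixture(
        system=system,
        params={"b": 10.0, "d": 1.0},
        u0={"X": 0.0},
        tspan=(0.0, 10.0),
        notes="Birth-death process; stationary copy-number law is Poisson(b/d).",
    )


@_fixture
def _dimerization() -> Fixture:
    kon, koff = sp.Symbol("kon"), sp.Symbol("koff")
    system = ReactionSystem.from_reactions(
        (
            make_reaction(kon, [("X", 2)], [("X2", 1)]),
            make_reaction(koff, [("X2", 1)], [("X", 2)]),
        ),
        name="dimerization",
    )
    return Fixture(
        system=system,
        params={"kon": 0.01, "koff": 0.2},
        u0={"X": 100.0, "X2": 0.0},
        tspan=(0.0, 20.0),
        notes="Reversible dimerization 2X <-> X2; X + 2*X2 is conserved.",
    )


@_fixture
def _mm_enzyme() -> Fixture:
    kB, kD, kP = sp.Symbol("kB"), sp.Symbol("kD"), sp.Symbol("kP")
    system = ReactionSystem.from_reactions(
        (
            make_reaction(kB, [("S", 1), ("E", 1)], [("SE", 1)]),
            make_reaction(kD, [("SE", 1)], [("S", 1), ("E", 1)]),
            make_reaction(kP, [("SE", 1)], [("P", 1), ("E", 1)]),
        ),
        name="mm_enzyme",
    )
    return Fixture(
        system=system,
        params={"kB": 0.01, "kD": 0.1, "kP": 0.1},
        u0={"S": 100.0, "E": 10.0, "SE": 0.0, "P": 0.0},
        tspan=(0.0, 100.0),
        notes=(
            "Michaelis-Menten enzyme kinetics S + E <-> SE -> P + E; "
            "conserved: total enzyme E + SE and total substrate S + SE + P."
        ),
    )


FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture_model(name: str) -> Fixture:
    """Return a bundled fixture model by name.

    Available: ``brusselator`` (Hopf-capable classic form), ``birth_death``,
    ``dimerization`` (one conservation law), ``mm_enzyme`` (two laws).
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise CRNError(
            f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}"
        ) from None
    return builder()


def scaled_brusselator(A: float = 1.0, B: float = 1.8, V: float = 100.0):
    """Volume-scaled Brusselator for discrete stochastic simulation.

    Copy numbers X ~ V*x track the classic concentrations x; the rate
    constants (A*V, 2/V^2, B, 1) are chosen so that the binomial mass-action
    propensities reproduce the classic deterministic limit
    dx/dt = A + x^2 y - (B+1) x as V grows.  Returns ``(system, u0)`` with
    the initial state at the deterministic fixed point (A*V, B*V/A).
    """
    reactions = (
        make_reaction(sp.Float(A * V), [], [("X", 1)]),
        make_reaction(sp.Float(2.0 / V**2), [("X", 2), ("Y", 1)], [("X", 3)]),
        make_reaction(sp.Float(B), [("X", 1)], [("Y", 1)]),
        make_reaction(sp.Integer(1), [("X", 1)], []),
    )
    system = ReactionSystem.from_reactions(reactions, name="brusselator_jump")
    u0 = {"X": round(A * V), "Y": round(B * V / A)}
    return system, u0
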