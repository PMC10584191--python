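"""Parser for classic chemical-reaction notation.

One reaction statement per line, each preceded by its rate::

    A, 0 --> X            # zero-order production at rate A
    1.0, 2*X + Y --> 3*X  # trimolecular autocatalysis
    B, X --> Y
    1.0, X --> 0

Supported syntax:

* arrows ``-->`` (forward), ``<--`` (backward, sides swapped), ``<-->``
  (reversible, rate must be a 2-tuple ``(kf, kr)``);
* bundling: rate and/or complex specs may be parenthesized tuples of equal
  length (or scalars broadcast against a tuple), e.g.
  ``(k1, k2), (X, Y) --> 0`` expands to two degradation reactions;
* complexes: ``+``-separated terms ``[coeff][*]Name`` (``2X`` and ``2*X``
  both work; coefficients may be decimal); ``0`` and ``∅`` denote the empty
  complex;
* rates: arbitrary arithmetic expressions over parameters, species and the
  time symbol ``t``, ``^`` or ``**`` for powers, plus the registered
  Michaelis–Menten and Hill functions ``mm(S, v, K)`` and
  ``hill(S, v, K, n)``;
* ``#`` starts a comment; blank lines are ignored.

Parsing is pure: the same text always produces the same
:class:`~crnkit.core.ReactionSystem`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import sympy as sp
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

from .core import (
    CRNError,
    Reaction,
    ReactionSystem,
    make_reaction,
)

__all__ = [
    "ParseError",
    "UndefinedFunctionError",
    "registered_function",
    "register_function",
    "parse_rate_expr",
    "parse_complex",
    "parse_reaction_network",
    "ReactionLine",
]


class ParseError(CRNError):
    """A reaction statement could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


class UndefinedFunctionError(ParseError):
    """A rate expression called a function that is not in the registry."""


# ---------------------------------------------------------------------------
# registered rate functions
# ---------------------------------------------------------------------------

def _mm(S, v, K):
    return v * S / (K + S)


def _hill(S, v, K, n):
    return v * S ** n / (K ** n + S ** n)


_FUNCTION_REGISTRY: dict[str, object] = {"mm": _mm, "hill": _hill}


def registered_function(name: str):
    """Return the symbolic template of a registered rate function.

    The registry ships Michaelis–Menten ``mm(S, v, K) = v*S/(K+S)`` and Hill
    ``hill(S, v, K, n) = v*S^n/(K^n + S^n)``; both expand to plain
    expressions at parse time, so ``hill(S, v, K, 1)`` is *identically*
    ``mm(S, v, K)``.
    """
    try:
        return _FUNCTION_REGISTRY[name]
    except KeyError:
        raise UndefinedFunctionError(
            f"unknown rate function {name!r}; registered: {sorted(_FUNCTION_REGISTRY)}"
        ) from None


def register_function(name: str, template) -> None:
    """Extend the rate-function registry (template maps sympy args to an Expr)."""
    _FUNCTION_REGISTRY[name] = template


# names resolvable inside rate expressions besides species/parameters
_SAFE_GLOBALS = {
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "abs": sp.Abs,
    "Abs": sp.Abs,
    "pi": sp.pi,
    "E": sp.E,
    "min": sp.Min,
    "max": sp.Max,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Symbol": sp.Symbol,
}

_TRANSFORMS = standard_transformations + (convert_xor,)


def parse_rate_expr(text: str, line: int | None = None) -> sp.Expr:
    """Parse one rate expression to a sympy expression.

    Unknown function calls are rejected with the registry listing; bare
    unknown names become symbols (species or parameters, decided later).
    """
    local = dict(_SAFE_GLOBALS)
    local.update(_FUNCTION_REGISTRY)
    try:
        expr = parse_expr(text, local_dict=local, transformations=_TRANSFORMS)
    except UndefinedFunctionError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse rate expression {text!r}: {exc}", line) from exc
    if not isinstance(expr, sp.Expr):
        raise ParseError(f"rate {text!r} is not a scalar expression", line)
    undef = expr.atoms(sp.core.function.AppliedUndef)
    if undef:
        names = sorted({f.func.__name__ for f in undef})
        raise UndefinedFunctionError(
            f"unknown rate function(s) {names}; registered: {sorted(_FUNCTION_REGISTRY)}",
            line,
        )
    # decimal literals become exact rationals, consistent with the rest of the IR
    if expr.atoms(sp.Float):
        expr = sp.nsimplify(expr, rational=True)
    return expr


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"^\s*(?:(?P<coeff>\d+(?:\.\d+)?|\.\d+)\s*\*?\s*)?(?P<name>[A-Za-z_]\w*)\s*$"
)

_EMPTY_TOKENS = {"0", "∅"}


def parse_complex(token: str, line: int | None = None) -> list[tuple[str, object]]:
    """Parse one complex such as ``2X + Y`` into ``[(X, 2), (Y, 1)]``.

    ``0`` and ``∅`` denote the empty complex.  Repeated species are merged
    (``X + X`` -> ``[(X, 2)]``); decimal coefficients become exact rationals.
    """
    token = token.strip()
    if token in _EMPTY_TOKENS:
        return []
    if not token:
        raise ParseError("empty complex specification", line)
    merged: dict[str, object] = {}
    order: list[str] = []
    for term in token.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"malformed complex term {term.strip()!r}", line)
        name = m.group("name")
        coeff_txt = m.group("coeff")
        if coeff_txt is None:
            coeff = sp.Integer(1)
        elif re.fullmatch(r"\d+", coeff_txt):
            coeff = sp.Integer(coeff_txt)
        else:
            coeff = sp.Rational(coeff_txt)
        if name in merged:
            merged[name] += coeff
        else:
            merged[name] = coeff
            order.append(name)
    return [(n, merged[n]) for n in order]


# ---------------------------------------------------------------------------
# statements
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"(<-->|-->|<--)")


@dataclass(frozen=True)
class ReactionLine:
    """One parsed reaction statement, before bundling/reversibility expansion."""

    rates: tuple[str, ...]
    reactants: tuple[str, ...]
    arrow: str
    products: tuple[str, ...]
    line: int


def _split_top_level(text: str, line: int) -> list[str]:
    """Split on commas at parenthesis depth 0."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced parentheses", line)
        if ch == "," and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if depth != 0:
        raise ParseError("unbalanced parentheses", line)
    parts.append("".join(buf))
    return parts


def _tuple_items(text: str, line: int) -> tuple[str, ...] | None:
    """If *text* is a parenthesized tuple ``(a, b, ...)``, return its items."""
    text = text.strip()
    if not (text.startswith("(") and text.endswith(")")):
        return None
    inner = text[1:-1]
    # the trailing ')' must match the leading '(' for this to be a tuple/paren group
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth == 0 and i != len(text) - 1:
                return None  # e.g. "(a+b)*(c)" — not a tuple
    items = _split_top_level(inner, line)
    if len(items) == 1:
        return None  # just a parenthesized expression
    return tuple(item.strip() for item in items)


def _parse_statement(stmt: str, lineno: int) -> ReactionLine:
    arrows = _ARROW_RE.findall(stmt)
    if not arrows:
        raise ParseError(f"no reaction arrow in {stmt.strip()!r}", lineno)
    if len(arrows) > 1:
        raise ParseError(f"multiple arrows in {stmt.strip()!r}", lineno)
    arrow = arrows[0]
    left, right = _ARROW_RE.split(stmt)[0], _ARROW_RE.split(stmt)[2]
    pieces = _split_top_level(left, lineno)
    if len(pieces) != 2:
        raise ParseError(
            "expected 'rate, reactants ARROW products' "
            f"(found {len(pieces)} top-level comma-separated fields before the arrow)",
            lineno,
        )
    rate_spec, reactant_spec = pieces[0].strip(), pieces[1].strip()
    product_spec = right.strip()
    if not rate_spec:
        raise ParseError("missing rate specification", lineno)

    rates = _tuple_items(rate_spec, lineno) or (rate_spec,)
    reactants = _tuple_items(reactant_spec, lineno) or (reactant_spec,)
    products = _tuple_items(product_spec, lineno) or (product_spec,)
    return ReactionLine(
        rates=rates, reactants=reactants, arrow=arrow, products=products, line=lineno
    )


def _broadcast(line: ReactionLine) -> list[tuple[str, str, str]]:
    """Expand bundled tuples into (rate, reactant, product) triples."""
    arities = {len(line.rates), len(line.reactants), len(line.products)}
    arities.discard(1)
    if len(arities) > 1:
        raise ParseError(
            f"tuple arity mismatch: rates={len(line.rates)}, "
            f"reactants={len(line.reactants)}, products={len(line.products)}",
            line.line,
        )
    n = arities.pop() if arities else 1
    pick = lambda seq, i: seq[i] if len(seq) > 1 else seq[0]
    return [
        (pick(line.rates, i), pick(line.reactants, i), pick(line.products, i))
        for i in range(n)
    ]


def _expand_line(line: ReactionLine) -> list[Reaction]:
    if line.arrow == "<-->":
        if len(line.rates) != 2:
            raise ParseError(
                "a reversible reaction needs a rate pair (kf, kr), "
                f"got {len(line.rates)} rate(s)",
                line.line,
            )
        if len(line.reactants) != 1 or len(line.products) != 1:
            raise ParseError(
                "bundled complexes are not supported with <--> ; "
                "write the forward and backward lines separately",
                line.line,
            )
        kf, kr = line.rates
        subs = parse_complex(line.reactants[0], line.line)
        prods = parse_complex(line.products[0], line.line)
        return [
            make_reaction(parse_rate_expr(kf, line.line), subs, prods),
            make_reaction(parse_rate_expr(kr, line.line), prods, subs),
        ]
    if line.arrow == "<--":
        line = ReactionLine(
            rates=line.rates,
            reactants=line.products,
            arrow="-->",
            products=line.reactants,
            line=line.line,
        )
    out = []
    for rate_txt, sub_txt, prod_txt in _broadcast(line):
        try:
            out.append(
                make_reaction(
                    parse_rate_expr(rate_txt, line.line),
                    parse_complex(sub_txt, line.line),
                    parse_complex(prod_txt, line.line),
                )
            )
        except ParseError:
            raise
        except CRNError as exc:
            raise ParseError(str(exc), line.line) from exc
    return out


def parse_reaction_network(text: str, name: str = "crn") -> ReactionSystem:
    """Parse reaction-notation text into a :class:`~crnkit.core.ReactionSystem`.

    Species and parameters are inferred automatically (species: every name in
    a substrate/product position, first-appearance order; parameters: all
    other free symbols of the rates, excluding ``t``).
    """
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stmt = raw.split("#", 1)[0].strip()
        if not stmt:
            continue
        reactions.extend(_expand_line(_parse_statement(stmt, lineno)))
    if not reactions:
        raise ParseError("no reactions found in input")
    return ReactionSystem.from_reactions(reactions, name=name)
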