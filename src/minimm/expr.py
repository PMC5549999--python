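"""Algebraic energy/integrator expressions: parsing, differentiation, compilation.

This is the engine behind every "custom" interaction and integrator step: the
user writes an algebraic expression such as ``"k*(theta-theta0)^2"``, the
parser turns it into an AST, :func:`differentiate` produces the analytic
derivative (the force is minus the derivative with respect to the geometric
variable), and :func:`compile_function` turns either expression into a pure,
batch-capable callable built on numpy.

Grammar
-------
Real literals, identifiers, ``+ - * / ^`` (with unary minus), parentheses and
function calls.  ``^`` is right-associative and binds tighter than unary
minus.  A trailing, semicolon-separated list of intermediate definitions is
allowed: ``"4*eps*((sig/r)^12-(sig/r)^6); sig=0.5*(sig1+sig2);
eps=sqrt(eps1*eps2)"``.  Definitions may reference each other acyclically.

Conventions
-----------
``step(x)`` is 1 for x >= 0 else 0; ``delta(x)`` is 1 iff x == 0; both have
derivative 0 everywhere.  ``0^0`` evaluates to 1.  Division by zero, log of a
non-positive value and even roots of negatives raise at evaluation time, not
at parse time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExprNode",
    "ParsedExpression",
    "CompiledFunction",
    "ExpressionError",
    "parse",
    "differentiate",
    "simplify",
    "compile_function",
    "unparse",
    "FUNCTIONS",
]


class ExpressionError(ValueError):
    """Raised for syntax errors, unknown functions, or bad variable requests."""


#: function name -> arity
FUNCTIONS: dict[str, int] = {
    "sin": 1, "cos": 1, "tan": 1,
    "asin": 1, "acos": 1, "atan": 1,
    "sinh": 1, "cosh": 1, "tanh": 1,
    "exp": 1, "log": 1, "sqrt": 1,
    "abs": 1, "floor": 1, "ceil": 1,
    "min": 2, "max": 2,
    "step": 1, "delta": 1,
    "select": 3,
}


@dataclass(frozen=True)
class ExprNode:
    """One node of an expression AST.

    ``kind`` is one of ``constant``, ``variable``, ``unary``, ``binary``,
    ``call``.  ``value`` holds the constant; ``name`` the variable name,
    operator symbol, or function name; ``children`` the ordered operands.
    """

    kind: str
    value: float = 0.0
    name: str = ""
    children: tuple["ExprNode", ...] = ()

    def __post_init__(self):
        if self.kind == "constant" and not math.isfinite(self.value):
            raise ExpressionError("constants must be finite")
        if self.kind == "binary" and len(self.children) != 2:
            raise ExpressionError("binary node needs exactly 2 children")
        if self.kind == "unary" and len(self.children) != 1:
            raise ExpressionError("unary node needs exactly 1 child")
        if self.kind == "call":
            arity = FUNCTIONS.get(self.name)
            if arity is None:
                raise ExpressionError(f"unknown function {self.name!r}")
            if len(self.children) != arity:
                raise ExpressionError(
                    f"{self.name} takes {arity} argument(s), got {len(self.children)}"
                )


def _const(v: float) -> ExprNode:
    return ExprNode("constant", value=float(v))


def _var(name: str) -> ExprNode:
    return ExprNode("variable", name=name)


def _bin(op: str, a: ExprNode, b: ExprNode) -> ExprNode:
    return ExprNode("binary", name=op, children=(a, b))


def _neg(a: ExprNode) -> ExprNode:
    return ExprNode("unary", name="-", children=(a,))


def _call(fn: str, *args: ExprNode) -> ExprNode:
    return ExprNode("call", name=fn, children=tuple(args))


def variables_of(node: ExprNode) -> set[str]:
    """All variable names appearing in the subtree."""
    if node.kind == "variable":
        return {node.name}
    out: set[str] = set()
    for c in node.children:
        out |= variables_of(c)
    return out


@dataclass
class ParsedExpression:
    """A parsed expression plus its ordered intermediate definitions.

    ``free_variables`` are the names that must be supplied at evaluation
    time; ``parameters`` is an optional caller-declared subset used by the
    force machinery to distinguish per-item parameters from geometry.
    """

    root: ExprNode
    definitions: list[tuple[str, ExprNode]] = field(default_factory=list)
    parameters: set[str] = field(default_factory=set)

    def __post_init__(self):
        names = [n for n, _ in self.definitions]
        if len(names) != len(set(names)):
            raise ExpressionError("duplicate definition name")
        self._topo = _toposort_definitions(self.definitions)

    @property
    def free_variables(self) -> set[str]:
        defined = {n for n, _ in self.definitions}
        used = variables_of(self.root)
        for _, node in self.definitions:
            used |= variables_of(node)
        return used - defined

    def substituted(self) -> ExprNode:
        """Root with every intermediate definition inlined."""
        env: dict[str, ExprNode] = {}
        for name in self._topo:
            node = dict(self.definitions)[name]
            env[name] = _substitute(node, env)
        return _substitute(self.root, env)


def _toposort_definitions(defs: list[tuple[str, ExprNode]]) -> list[str]:
    names = {n for n, _ in defs}
    table = dict(defs)
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(n: str, stack: tuple[str, ...]):
        if state.get(n) == 1:
            return
        if state.get(n) == 0:
            raise ExpressionError(f"cyclic definitions involving {n!r}")
        state[n] = 0
        for dep in variables_of(table[n]) & names:
            visit(dep, stack + (n,))
        state[n] = 1
        order.append(n)

    for n, _ in defs:
        visit(n, ())
    return order


def _substitute(node: ExprNode, env: dict[str, ExprNode]) -> ExprNode:
    if node.kind == "variable" and node.name in env:
        return env[node.name]
    if not node.children:
        return node
    return ExprNode(
        node.kind,
        value=node.value,
        name=node.name,
        children=tuple(_substitute(c, env) for c in node.children),
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>[-+*/^(),]))"
)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                stripped = text[pos:].lstrip()
                if not stripped:
                    break
                raise ExpressionError(
                    f"syntax error at position {pos}: unexpected {stripped[0]!r}"
                )
            if m.group("num") is not None:
                self.tokens.append(("num", m.group("num"), m.start("num")))
            elif m.group("ident") is not None:
                self.tokens.append(("ident", m.group("ident"), m.start("ident")))
            else:
                self.tokens.append(("op", m.group("op"), m.start("op")))
            pos = m.end()
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("syntax error: unexpected end of expression")
        self.i += 1
        return tok

    def expect(self, sym: str):
        tok = self.next()
        if tok[0] != "op" or tok[1] != sym:
            raise ExpressionError(
                f"syntax error at position {tok[2]}: expected {sym!r}, got {tok[1]!r}"
            )

    def parse(self) -> ExprNode:
        node = self.expression()
        tok = self.peek()
        if tok is not None:
            raise ExpressionError(
                f"syntax error at position {tok[2]}: unexpected {tok[1]!r}"
            )
        return node

    def expression(self) -> ExprNode:
        node = self.term()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "+-":
            self.next()
            rhs = self.term()
            node = _bin(tok[1], node, rhs)
        return node

    def term(self) -> ExprNode:
        node = self.unary()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "*/":
            self.next()
            rhs = self.unary()
            node = _bin(tok[1], node, rhs)
        return node

    def unary(self) -> ExprNode:
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "-":
            self.next()
            return _neg(self.unary())
        if tok and tok[0] == "op" and tok[1] == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self) -> ExprNode:
        base = self.atom()
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "^":
            self.next()
            # right associative; exponent may carry a sign
            exponent = self.unary_power()
            return _bin("^", base, exponent)
        return base

    def unary_power(self) -> ExprNode:
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "-":
            self.next()
            return _neg(self.unary_power())
        return self.power()

    def atom(self) -> ExprNode:
        tok = self.next()
        kind, text, pos = tok
        if kind == "num":
            return _const(float(text))
        if kind == "ident":
            nxt = self.peek()
            if nxt and nxt[0] == "op" and nxt[1] == "(":
                if text not in FUNCTIONS:
                    raise ExpressionError(f"unknown function {text!r} at position {pos}")
                self.next()
                args = [self.expression()]
                while (t := self.peek()) and t[0] == "op" and t[1] == ",":
                    self.next()
                    args.append(self.expression())
                self.expect(")")
                return _call(text, *args)
            return _var(text)
        if kind == "op" and text == "(":
            node = self.expression()
            self.expect(")")
            return node
        raise ExpressionError(f"syntax error at position {pos}: unexpected {text!r}")


def parse(text: str, parameters: set[str] | None = None) -> ParsedExpression:
    """Parse ``"energy; name=expr; ..."`` into a :class:`ParsedExpression`."""
    if not text or not text.strip():
        raise ExpressionError("empty expression")
    parts = [p for p in text.split(";")]
    if any(not p.strip() for p in parts):
        raise ExpressionError("empty clause between semicolons")
    root = _Parser(parts[0]).parse()
    definitions: list[tuple[str, ExprNode]] = []
    for clause in parts[1:]:
        if "=" not in clause:
            raise ExpressionError(f"definition {clause.strip()!r} lacks '='")
        name, rhs = clause.split("=", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z_0-9]*", name):
            raise ExpressionError(f"invalid definition name {name!r}")
        definitions.append((name, _Parser(rhs).parse()))
    pe = ParsedExpression(root, definitions, parameters or set())
    overlap = pe.free_variables & {n for n, _ in definitions}
    assert not overlap
    return pe


# ---------------------------------------------------------------------------
# simplification
# ---------------------------------------------------------------------------

_SAFE_FOLD = {
    "sin": math.sin, "cos": math.cos, "tan": math.tan,
    "sinh": math.sinh, "cosh": math.cosh, "tanh": math.tanh,
    "exp": math.exp, "abs": abs, "floor": math.floor, "ceil": math.ceil,
    "step": lambda x: 1.0 if x >= 0 else 0.0,
    "delta": lambda x: 1.0 if x == 0 else 0.0,
    "min": min, "max": max,
}


def simplify(node: ExprNode) -> ExprNode:
    """Local algebraic cleanup: constant folding, 0/1 identities.  Idempotent."""
    if not node.children:
        return node
    ch = tuple(simplify(c) for c in node.children)
    node = ExprNode(node.kind, value=node.value, name=node.name, children=ch)

    def isconst(n: ExprNode, v: float | None = None) -> bool:
        return n.kind == "constant" and (v is None or n.value == v)

    if node.kind == "unary":
        (a,) = ch
        if isconst(a):
            return _const(-a.value)
        if a.kind == "unary" and a.name == "-":
            return a.children[0]
        return node

    if node.kind == "binary":
        a, b = ch
        op = node.name
        if isconst(a) and isconst(b):
            try:
                v = _fold_binary(op, a.value, b.value)
            except (ZeroDivisionError, ValueError, OverflowError):
                return node
            if math.isfinite(v):
                return _const(v)
            return node
        if op == "+":
            if isconst(a, 0.0):
                return b
            if isconst(b, 0.0):
                return a
        elif op == "-":
            if isconst(b, 0.0):
                return a
            if isconst(a, 0.0):
                return simplify(_neg(b))
        elif op == "*":
            if isconst(a, 0.0) or isconst(b, 0.0):
                return _const(0.0)
            if isconst(a, 1.0):
                return b
            if isconst(b, 1.0):
                return a
        elif op == "/":
            if isconst(b, 1.0):
                return a
        elif op == "^":
            if isconst(b, 1.0):
                return a
            if isconst(b, 0.0):
                return _const(1.0)  # 0^0 == 1 by convention
        return node

    if node.kind == "call":
        fn = node.name
        if all(isconst(c) for c in ch):
            if fn == "select":
                return ch[1] if ch[0].value != 0 else ch[2]
            f = _SAFE_FOLD.get(fn)
            if f is not None:
                try:
                    v = float(f(*[c.value for c in ch]))
                except (ValueError, OverflowError):
                    return node
                if math.isfinite(v):
                    return _const(v)
        return node

    return node


def _fold_binary(op: str, a: float, b: float) -> float:
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    if op == "/":
        return a / b
    if op == "^":
        if a == 0.0 and b == 0.0:
            return 1.0
        return a ** b
    raise AssertionError(op)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _diff_node(node: ExprNode, var: str) -> ExprNode:
    if node.kind == "constant":
        return _const(0.0)
    if node.kind == "variable":
        return _const(1.0 if node.name == var else 0.0)
    if node.kind == "unary":
        return _neg(_diff_node(node.children[0], var))
    if node.kind == "binary":
        a, b = node.children
        da, db = _diff_node(a, var), _diff_node(b, var)
        op = node.name
        if op == "+":
            return _bin("+", da, db)
        if op == "-":
            return _bin("-", da, db)
        if op == "*":
            return _bin("+", _bin("*", da, b), _bin("*", a, db))
        if op == "/":
            num = _bin("-", _bin("*", da, b), _bin("*", a, db))
            return _bin("/", num, _bin("^", b, _const(2.0)))
        if op == "^":
            if b.kind == "constant":
                c = b.value
                return _bin(
                    "*",
                    _bin("*", _const(c), _bin("^", a, _const(c - 1.0))),
                    da,
                )
            # u^v : u^v * (v'*log(u) + v*u'/u)
            term1 = _bin("*", db, _call("log", a))
            term2 = _bin("/", _bin("*", b, da), a)
            return _bin("*", node, _bin("+", term1, term2))
        raise AssertionError(op)
    # calls
    fn = node.name
    args = node.children
    if fn in ("step", "delta", "floor", "ceil"):
        return _const(0.0)
    if fn == "select":
        return _call("select", args[0], _diff_node(args[1], var), _diff_node(args[2], var))
    if fn == "min":
        a, b = args
        da, db = _diff_node(a, var), _diff_node(b, var)
        gate = _call("step", _bin("-", b, a))  # 1 where a <= b
        return _bin("+", _bin("*", gate, da),
                    _bin("*", _bin("-", _const(1.0), gate), db))
    if fn == "max":
        a, b = args
        da, db = _diff_node(a, var), _diff_node(b, var)
        gate = _call("step", _bin("-", a, b))
        return _bin("+", _bin("*", gate, da),
                    _bin("*", _bin("-", _const(1.0), gate), db))
    (u,) = args
    du = _diff_node(u, var)
    outer: ExprNode
    if fn == "sin":
        outer = _call("cos", u)
    elif fn == "cos":
        outer = _neg(_call("sin", u))
    elif fn == "tan":
        outer = _bin("/", _const(1.0), _bin("^", _call("cos", u), _const(2.0)))
    elif fn == "asin":
        outer = _bin("/", _const(1.0),
                     _call("sqrt", _bin("-", _const(1.0), _bin("^", u, _const(2.0)))))
    elif fn == "acos":
        outer = _neg(_bin("/", _const(1.0),
                          _call("sqrt", _bin("-", _const(1.0), _bin("^", u, _const(2.0))))))
    elif fn == "atan":
        outer = _bin("/", _const(1.0), _bin("+", _const(1.0), _bin("^", u, _const(2.0))))
    elif fn == "sinh":
        outer = _call("cosh", u)
    elif fn == "cosh":
        outer = _call("sinh", u)
    elif fn == "tanh":
        outer = _bin("-", _const(1.0), _bin("^", _call("tanh", u), _const(2.0)))
    elif fn == "exp":
        outer = _call("exp", u)
    elif fn == "log":
        outer = _bin("/", _const(1.0), u)
    elif fn == "sqrt":
        outer = _bin("/", _const(1.0), _bin("*", _const(2.0), _call("sqrt", u)))
    elif fn == "abs":
        outer = _bin("-", _bin("*", _const(2.0), _call("step", u)), _const(1.0))
    else:  # pragma: no cover
        raise ExpressionError(f"cannot differentiate {fn}")
    return _bin("*", outer, du)


def differentiate(pe: ParsedExpression, var: str) -> ParsedExpression:
    """Analytic partial derivative of ``pe`` with respect to ``var``.

    Intermediate definitions are inlined first so the chain rule flows
    through them; the result carries no definitions.
    """
    if var not in pe.free_variables:
        raise ExpressionError(f"{var!r} is not a free variable of the expression")
    inlined = pe.substituted()
    return ParsedExpression(simplify(_diff_node(inlined, var)), [], set(pe.parameters))


# ---------------------------------------------------------------------------
# unparse (round-trip support)
# ---------------------------------------------------------------------------

_PREC = {"+": 1, "-": 1, "*": 2, "/": 2, "neg": 3, "^": 4}


def unparse(node: ExprNode) -> str:
    """Render an AST back to parseable text."""

    def go(n: ExprNode, parent_prec: int) -> str:
        if n.kind == "constant":
            s = repr(n.value)
            return f"({s})" if n.value < 0 and parent_prec > 1 else s
        if n.kind == "variable":
            return n.name
        if n.kind == "unary":
            inner = go(n.children[0], _PREC["neg"])
            s = f"-{inner}"
            return f"({s})" if parent_prec > _PREC["neg"] else s
        if n.kind == "call":
            return f"{n.name}({', '.join(go(c, 0) for c in n.children)})"
        op = n.name
        p = _PREC[op]
        # ^ is right-associative; -,/ are left-associative
        lp = p if op != "^" else p + 1
        rp = p + 1 if op in "-/" else p
        if op == "^":
            rp = p
        s = f"{go(n.children[0], lp)}{op}{go(n.children[1], rp)}"
        return f"({s})" if p < parent_prec else s

    return go(node, 0)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _rt_div(a, b):
    b_arr = np.asarray(b)
    if np.any(b_arr == 0):
        raise ZeroDivisionError("division by zero in expression")
    return np.divide(a, b)


def _rt_log(x):
    x_arr = np.asarray(x)
    if np.any(x_arr <= 0):
        raise ValueError("log of non-positive value in expression")
    return np.log(x)


def _rt_sqrt(x):
    x_arr = np.asarray(x)
    if np.any(x_arr < 0):
        raise ValueError("sqrt of negative value in expression")
    return np.sqrt(x)


def _rt_pow(a, b):
    a_arr, b_arr = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.power(a_arr, b_arr)
    # 0^0 -> 1 by convention (numpy already does this for floats)
    bad = ~np.isfinite(out)
    if np.any(bad):
        neg_zero_pow = (a_arr == 0) & (b_arr < 0)
        if np.any(neg_zero_pow & bad):
            raise ZeroDivisionError("zero raised to negative power")
        raise ValueError("invalid power (negative base with fractional exponent?)")
    return out


def _rt_asin(x):
    x_arr = np.asarray(x)
    if np.any(np.abs(x_arr) > 1):
        raise ValueError("asin/acos argument outside [-1, 1]")
    return x


_RUNTIME = {
    "np": np,
    "_div": _rt_div,
    "_log": _rt_log,
    "_sqrt": _rt_sqrt,
    "_pow": _rt_pow,
    "_chk_asin": _rt_asin,
}

_CALL_CODE = {
    "sin": "np.sin({0})", "cos": "np.cos({0})", "tan": "np.tan({0})",
    "asin": "np.arcsin(_chk_asin({0}))", "acos": "np.arccos(_chk_asin({0}))",
    "atan": "np.arctan({0})",
    "sinh": "np.sinh({0})", "cosh": "np.cosh({0})", "tanh": "np.tanh({0})",
    "exp": "np.exp({0})", "log": "_log({0})", "sqrt": "_sqrt({0})",
    "abs": "np.abs({0})", "floor": "np.floor({0})", "ceil": "np.ceil({0})",
    "min": "np.minimum({0}, {1})", "max": "np.maximum({0}, {1})",
    "step": "np.where(np.asarray({0}, dtype=float) >= 0, 1.0, 0.0)",
    "delta": "np.where(np.asarray({0}, dtype=float) == 0, 1.0, 0.0)",
    "select": "np.where(np.asarray({0}, dtype=float) != 0, {1}, {2})",
}


def _emit(node: ExprNode, names: dict[str, str]) -> str:
    if node.kind == "constant":
        return repr(node.value)
    if node.kind == "variable":
        try:
            return names[node.name]
        except KeyError:
            raise ExpressionError(f"unbound variable {node.name!r}") from None
    if node.kind == "unary":
        return f"(-{_emit(node.children[0], names)})"
    if node.kind == "binary":
        a = _emit(node.children[0], names)
        b = _emit(node.children[1], names)
        if node.name == "/":
            return f"_div({a}, {b})"
        if node.name == "^":
            return f"_pow({a}, {b})"
        return f"({a} {node.name} {b})"
    args = [_emit(c, names) for c in node.children]
    return "(" + _CALL_CODE[node.name].format(*args) + ")"


class CompiledFunction:
    """A pure callable evaluating a :class:`ParsedExpression`.

    Accepts scalars or aligned numpy arrays (elementwise) for each input in
    ``input_names`` and returns a float or array of the broadcast shape.
    """

    def __init__(self, pe: ParsedExpression, input_names: list[str]):
        missing = pe.free_variables - set(input_names)
        if missing:
            raise ExpressionError(f"input_order is missing variables {sorted(missing)}")
        self.input_names = list(input_names)
        self.arity = len(self.input_names)
        names = {n: f"_in[{i}]" for i, n in enumerate(self.input_names)}
        lines = ["def _f(_in):"]
        table = dict(pe.definitions)
        for dname in pe._topo:
            reg = f"_d_{dname}"
            lines.append(f"    {reg} = {_emit(table[dname], names)}")
            names[dname] = reg
        lines.append(f"    return {_emit(pe.root, names)}")
        src = "\n".join(lines)
        scope = dict(_RUNTIME)
        exec(compile(src, "<minimm-expr>", "exec"), scope)
        self._fn = scope["_f"]
        self._source = src

    def __call__(self, *args):
        if len(args) != self.arity:
            raise TypeError(f"expected {self.arity} arguments, got {len(args)}")
        vals = [np.asarray(a, dtype=float) for a in args]
        out = self._fn(vals)
        out = np.asarray(out, dtype=float)
        shape = np.broadcast_shapes(*[v.shape for v in vals]) if vals else ()
        out = np.broadcast_to(out, shape).copy() if out.shape != shape else out
        if out.shape == ():
            return float(out)
        return out


def compile_function(pe: ParsedExpression, input_order: list[str]) -> CompiledFunction:
    """Compile ``pe`` into a pure batch-capable callable over ``input_order``."""
    return CompiledFunction(pe, input_order)


def evaluate(pe: ParsedExpression, **values: float):
    """Convenience one-shot evaluation (interprets via a fresh compile)."""
    names = sorted(pe.free_variables)
    fn = compile_function(pe, names)
    return fn(*[values[n] for n in names])
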