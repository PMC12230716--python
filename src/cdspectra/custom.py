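"""User-defined model fitting from expression strings.

The fitting function is supplied as text in one variable ``x`` plus named
parameters, e.g. ``"A + B*exp(-x/t)"``.  Expressions are parsed by a small
recursive-descent parser against a whitelist (identifiers, numbers,
``+ - * / ^``, parentheses, and the functions exp, log, sqrt, sin, cos, abs,
power); nothing is ever passed to the Python interpreter, so arbitrary code
cannot run.  ``^`` denotes power; implicit multiplication is rejected.
Parsed models are fitted with the same global Levenberg–Marquardt engine and
covariance-based errors as the unfolding models, so they work on
single-wavelength series and decomposition-coefficient series alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .unfolding import Curve, FitResult


class ModelParseError(ValueError):
    pass


_FUNCTIONS = {
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "sin": np.sin,
    "cos": np.cos,
    "abs": np.abs,
    "power": np.power,
}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>[-+*/^(),]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ModelParseError(
                f"unexpected character {text[pos]!r} at position {pos}"
            )
        if m.group("num") is not None:
            tokens.append(("num", m.group("num"), m.start()))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name"), m.start()))
        else:
            tokens.append(("op", m.group("op"), m.start()))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Grammar: expr := term (('+'|'-') term)*
    term := unary (('*'|'/') unary)* ; unary := ('+'|'-') unary | power
    power := atom ('^' unary)?      ; atom := num | name | name '(' args ')'
                                             | '(' expr ')'
    """

    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.i = 0
        self.params: list[str] = []

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str):
        kind, val, pos = self.next()
        if kind != "op" or val != op:
            raise ModelParseError(f"expected {op!r} at position {pos}, got {val!r}")

    def parse(self):
        node = self.expr()
        kind, val, pos = self.peek()
        if kind != "end":
            raise ModelParseError(f"unexpected {val!r} at position {pos}")
        return node

    def expr(self):
        node = self.term()
        while self.peek()[:2] in (("op", "+"), ("op", "-")):
            _, op, _ = self.next()
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.unary()
        while self.peek()[:2] in (("op", "*"), ("op", "/")):
            _, op, _ = self.next()
            node = (op, node, self.unary())
        return node

    def unary(self):
        kind, val, _ = self.peek()
        if kind == "op" and val in ("+", "-"):
            self.next()
            child = self.unary()
            return child if val == "+" else ("neg", child)
        return self.power()

    def power(self):
        node = self.atom()
        if self.peek()[:2] == ("op", "^"):
            self.next()
            node = ("^", node, self.unary())  # right-associative
        return node

    def atom(self):
        kind, val, pos = self.next()
        if kind == "num":
            return ("const", float(val))
        if kind == "name":
            if self.peek()[:2] == ("op", "("):
                if val not in _FUNCTIONS:
                    raise ModelParseError(
                        f"unknown function {val!r} at position {pos}"
                    )
                self.next()
                args = [self.expr()]
                while self.peek()[:2] == ("op", ","):
                    self.next()
                    args.append(self.expr())
                self.expect_op(")")
                want = 2 if val == "power" else 1
                if len(args) != want:
                    raise ModelParseError(
                        f"{val} takes {want} argument(s), got {len(args)}"
                    )
                return ("call", val, args)
            if val == "x":
                return ("var",)
            if val not in self.params:
                self.params.append(val)
            return ("param", val)
        if kind == "op" and val == "(":
            node = self.expr()
            self.expect_op(")")
            return node
        raise ModelParseError(f"unexpected {val!r} at position {pos}")


def _eval(node, x, params: dict[str, float]):
    op = node[0]
    if op == "const":
        return node[1]
    if op == "var":
        return x
    if op == "param":
        return params[node[1]]
    if op == "neg":
        return -_eval(node[1], x, params)
    if op == "call":
        return _FUNCTIONS[node[1]](*[_eval(a, x, params) for a in node[2]])
    a, b = _eval(node[1], x, params), _eval(node[2], x, params)
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    if op == "/":
        return a / b
    if op == "^":
        return np.power(a, b)
    raise ModelParseError(f"unknown node {op!r}")


@dataclass
class CustomModel:
    expression: str
    parameter_names: list[str]
    _ast: tuple = field(repr=False, default=())

    def evaluate(self, x, **params) -> np.ndarray:
        missing = set(self.parameter_names) - set(params)
        if missing:
            raise ModelParseError(f"missing parameter values: {sorted(missing)}")
        return np.asarray(_eval(self._ast, np.asarray(x, dtype=float), params))


def parse_model(expression: str) -> CustomModel:
    """Parse a fitting-function string into a CustomModel.

    ``x`` is the experimental variable; every other identifier becomes a fit
    parameter, in order of appearance.  At least one parameter is required.
    """
    parser = _Parser(expression)
    ast = parser.parse()
    if not parser.params:
        raise ModelParseError("expression contains no fit parameters")
    return CustomModel(expression, parser.params, ast)


def fit_custom(
    curves: list[Curve],
    model: CustomModel,
    shared: dict[str, str] | None = None,
    init: dict[str, float] | None = None,
) -> FitResult:
    """Global least-squares fit of a user-defined model over several curves.

    ``shared`` maps each parameter to 'global' (one value for all curves,
    the default) or 'local' (one value per curve).  Standard errors come
    from the covariance of the fitted parameters.
    """
    if not curves:
        raise ModelParseError("fit_custom needs at least one curve")
    shared = dict(shared or {})
    init = dict(init or {})
    unknown = set(shared) - set(model.parameter_names)
    if unknown:
        raise ModelParseError(f"shared map names unknown parameter(s): {sorted(unknown)}")
    shared_map = {p: shared.get(p, "global") for p in model.parameter_names}

    pars = lmfit.Parameters()
    name_map: dict[tuple[str, int], str] = {}
    for p in model.parameter_names:
        if shared_map[p] == "global":
            pars.add(p, value=init.get(p, 1.0))
            for i in range(len(curves)):
                name_map[(p, i)] = p
        else:
            for i in range(len(curves)):
                name = f"{p}_c{i}"
                pars.add(name, value=init.get(name, init.get(p, 1.0)))
                name_map[(p, i)] = name

    def residual(params):
        vals = {k: float(v) for k, v in params.valuesdict().items()}
        res = []
        for i, c in enumerate(curves):
            pv = {p: vals[name_map[(p, i)]] for p in model.parameter_names}
            res.append(model.evaluate(c.x, **pv) - c.y)
        return np.concatenate(res)

    minres = lmfit.minimize(residual, pars, method="leastsq", nan_policy="raise")
    vals = {k: float(v) for k, v in minres.params.valuesdict().items()}
    fitted, residuals = {}, {}
    for i, c in enumerate(curves):
        cid = c.curve_id or f"curve_{i}"
        pv = {p: vals[name_map[(p, i)]] for p in model.parameter_names}
        fitted[cid] = model.evaluate(c.x, **pv)
        residuals[cid] = fitted[cid] - c.y
    std = {
        k: (float(p.stderr) if p.stderr is not None else None)
        for k, p in minres.params.items()
        if p.vary
    }
    return FitResult(
        estimates=vals,
        std_errors=std,
        shared_map=shared_map,
        fitted=fitted,
        residuals=residuals,
        residual_norm=float(
            np.sqrt(sum(np.sum(r**2) for r in residuals.values()))
        ),
        success=bool(minres.success),
        message=str(minres.message),
        redchi=float(minres.redchi) if minres.redchi is not None else float("nan"),
        covar=getattr(minres, "covar", None),
    )
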