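"""Safe arithmetic expressions over named model parameters.

Branch probabilities and node payoffs in a decision tree are written as
small arithmetic expressions over parameter names, e.g. ``1 - p_readm_eul``
or ``c_eul_procedure + los_mean_eul * daily_bed_cost``.  Only the four
basic operations, unary signs, numeric literals and bare names are
admitted; the expression is validated against a whitelist of AST nodes at
parse time and compiled once, so repeated evaluation is cheap.

Evaluation environments map parameter names to scalars *or* NumPy arrays,
which lets a whole grid of sensitivity scenarios be pushed through a tree
in a single rollback.
"""
from __future__ import annotations

import ast
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["Expr", "ExpressionError", "as_expr"]


class ExpressionError(ValueError):
    """Expression cannot be parsed, contains forbidden syntax, or references
    a name missing from the evaluation environment."""


_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Constant,
    ast.Name,
    ast.Load,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.USub,
    ast.UAdd,
)


@dataclass(frozen=True)
class Expr:
    """A compiled arithmetic expression.

    Attributes
    ----------
    text : str
        The source text, kept for error messages and serialization.
    names : frozenset[str]
        Parameter names the expression references.
    """

    text: str
    names: frozenset
    code: Any = field(repr=False, compare=False, hash=False, default=None)

    def __call__(self, env: Mapping[str, Any]):
        missing = self.names - env.keys()
        if missing:
            raise ExpressionError(
                f"unknown parameter(s) {sorted(missing)} in expression {self.text!r}"
            )
        local = env if isinstance(env, dict) else dict(env)
        return eval(self.code, {"__builtins__": {}}, local)  # noqa: S307 - AST-whitelisted

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


def _parse(text: str) -> Expr:
    try:
        node = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {text!r}: {exc.msg}") from exc
    names = set()
    for sub in ast.walk(node):
        if not isinstance(sub, _ALLOWED_NODES):
            raise ExpressionError(
                f"forbidden syntax {type(sub).__name__!r} in expression {text!r}"
            )
        if isinstance(sub, ast.Constant):
            if not isinstance(sub.value, (int, float)):
                raise ExpressionError(
                    f"non-numeric literal {sub.value!r} in expression {text!r}"
                )
        if isinstance(sub, ast.Name):
            names.add(sub.id)
    code = compile(node, "<stonecea-expr>", "eval")
    return Expr(text=text, names=frozenset(names), code=code)


def as_expr(value) -> Expr:
    """Coerce a number, string or :class:`Expr` into a compiled ``Expr``."""
    if isinstance(value, Expr):
        return value
    if isinstance(value, bool):
        raise ExpressionError("boolean is not a valid expression")
    if isinstance(value, (int, float)):
        return _parse(repr(float(value)))
    if isinstance(value, str):
        return _parse(value)
    raise ExpressionError(f"cannot build an expression from {value!r}")


ZERO = as_expr(0.0)
ONE = as_expr(1.0)
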