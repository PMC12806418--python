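"""Restricted arithmetic expressions for penetrance functions.

Penetrance cells of an epistasis model with marginal effects are written as
formulas in two variables: ``x`` (the baseline penetrance, usually called
alpha) and ``y`` (the relative penetrance f).  Only literal numbers, the two
variables, parentheses, unary minus and the operators ``+ - * / ^`` are
accepted; ``^`` means exponentiation.  Anything else (names, calls,
attributes, comparisons) is rejected at parse time, so model files cannot
execute code.
"""

from __future__ import annotations

import ast
import math

from .exceptions import ExpressionError

__all__ = ["PenetranceExpression"]

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)
_VARIABLES = frozenset({"x", "y"})


class PenetranceExpression:
    """A validated, compiled arithmetic expression in ``x`` and ``y``.

    Parameters
    ----------
    text : str
        Formula such as ``"x*y^2"`` or ``"x*(1+2*y)"``.

    Raises
    ------
    ExpressionError
        If the formula does not parse, or uses anything beyond numbers,
        ``x``/``y`` and the arithmetic operators.
    """

    __slots__ = ("text", "_code")

    def __init__(self, text: str):
        if not isinstance(text, str) or not text.strip():
            raise ExpressionError("empty penetrance expression")
        self.text = text.strip()
        try:
            tree = ast.parse(self.text.replace("^", "**"), mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(
                f"cannot parse penetrance expression {self.text!r}: {exc.msg}"
            ) from None
        self._validate(tree.body)
        self._code = compile(tree, "<penetrance>", "eval")

    def _validate(self, node: ast.AST) -> None:
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            self._validate(node.left)
            self._validate(node.right)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
            self._validate(node.operand)
        elif isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)) or isinstance(node.value, bool):
                raise ExpressionError(
                    f"non-numeric constant {node.value!r} in {self.text!r}"
                )
        elif isinstance(node, ast.Name):
            if node.id not in _VARIABLES:
                raise ExpressionError(
                    f"unknown variable {node.id!r} in {self.text!r}; only x and y are allowed"
                )
        else:
            raise ExpressionError(
                f"disallowed syntax ({type(node).__name__}) in {self.text!r}"
            )

    def __call__(self, x: float, y: float) -> float:
        """Evaluate at baseline penetrance ``x`` and relative penetrance ``y``."""
        try:
            value = eval(self._code, {"__builtins__": {}}, {"x": float(x), "y": float(y)})
        except ZeroDivisionError:
            return math.inf
        return float(value)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PenetranceExpression({self.text!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PenetranceExpression) and other.text == self.text

    def __hash__(self) -> int:
        return hash(self.text)
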