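"""The eight candidate parameter-response function families.

Each family has the form ``f(x) = alpha * g(x) + beta`` with a fixed
transform g.  The same registry drives the correction stage (fitting and
the rearranged-function correction ``(f(x) - beta) / g(x)``) and the
synthetic feature generator (which draws data from a known family).

The order of :data:`FAMILY_ORDER` is the complexity order used to break
exact AIC ties.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FAMILY_ORDER", "g_transform", "evaluate"]

FAMILY_ORDER = (
    "a*x+b",
    "a*x^2+b",
    "a*x^3+b",
    "a/x+b",
    "a/x^2+b",
    "a/x^3+b",
    "a*log(x)+b",
    "a/log(x)+b",
)

_TRANSFORMS = {
    "a*x+b": lambda x: x,
    "a*x^2+b": lambda x: x**2,
    "a*x^3+b": lambda x: x**3,
    "a/x+b": lambda x: 1.0 / x,
    "a/x^2+b": lambda x: 1.0 / x**2,
    "a/x^3+b": lambda x: 1.0 / x**3,
    "a*log(x)+b": lambda x: np.log(x),
    "a/log(x)+b": lambda x: 1.0 / np.log(x),
}


def g_transform(family: str, x) -> np.ndarray:
    """Evaluate the transform g(x) of a family; x must be positive and != 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive (rescale upstream)")
    if family not in _TRANSFORMS:
        raise ValueError(f"unknown function family {family!r}; "
                         f"known: {list(FAMILY_ORDER)}")
    if "log" in family and np.any(x == 1.0):
        raise ValueError("x == 1 makes log-based transforms degenerate")
    return _TRANSFORMS[family](x)


def evaluate(family: str, x, alpha: float, beta: float) -> np.ndarray:
    """f(x) = alpha * g(x) + beta."""
    return alpha * g_transform(family, x) + beta
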