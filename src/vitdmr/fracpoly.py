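"""Fractional polynomial (FP) utilities.

The FP family uses the power grid {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, where
power 0 denotes log(x) and a repeated power p contributes x^p and
x^p * log(x).  Degree-1 models have one transformed term, degree-2 models
two; power 1 reproduces the straight line, so the linear model is nested in
both families.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

DEGREE1_MODELS = tuple((p,) for p in FP_POWERS)
DEGREE2_MODELS = tuple(combinations_with_replacement(FP_POWERS, 2))


def _xp(x: np.ndarray, p: float) -> np.ndarray:
    return np.log(x) if p == 0.0 else x ** p


def fp_terms(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Column matrix of FP transforms of strictly positive x.

    Repeated powers follow the Royston-Altman convention: (p, p) maps to
    [x^p, x^p log x].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomials need strictly positive x")
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        reps = seen.get(p, 0)
        base = _xp(x, p)
        cols.append(base * np.log(x) ** reps)
        seen[p] = reps + 1
    return np.column_stack(cols)


def fp_derivative_terms(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Basis spanning the derivative of the FP effect function.

    d/dx x^p = p x^(p-1) and d/dx log x = x^(-1), so each power p
    contributes a plain-power column x^(p-1) (x^0 meaning the constant 1 —
    the straight line's constant derivative, NOT log x); a repeated power
    adds x^(p-1) log x.  Constant factors are absorbed into the free
    coefficients, so a localized average causal effect (the local
    derivative of the causal dose-response curve) can be regressed
    directly on these columns.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomials need strictly positive x")
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        q = p - 1.0
        reps = seen.get(p, 0)
        cols.append(x ** q * np.log(x) ** reps)
        seen[p] = reps + 1
    return np.column_stack(cols)
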