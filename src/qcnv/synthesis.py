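"""Product-state encoding synthesis.

Real amplitude vectors that factor as a product of single-qubit states

    |psi> = (a_n|0> + b_n|1>) ... (a_1|0> + b_1|1>)

can be prepared with one RY rotation per qubit.  This module expands
such products, fits arbitrary targets to the nearest product state by
seeded multi-start least squares (entangled targets keep a nonzero
residual, which is reported rather than hidden), extracts RY angles,
and builds patterned encodings directly: suppressing or scaling half of
the regions at a given bit level sets the corresponding a_i or b_i,
which is how the built-in 64-region problems encode their block
structure with a handful of gates.

Only real amplitudes are handled; a global sign is the only phase the
classifier's data ever carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize


@dataclass(frozen=True)
class ProductState:
    """Per-qubit (a_i, b_i) pairs, each individually normalized."""

    pairs: tuple[tuple[float, float], ...]

    def __init__(self, pairs: Sequence[Sequence[float]]) -> None:
        ps = tuple((float(a), float(b)) for a, b in pairs)
        if not ps:
            raise ValueError("at least one qubit pair is required")
        for i, (a, b) in enumerate(ps, start=1):
            if abs(a * a + b * b - 1.0) > 1e-12:
                raise ValueError(f"pair {i}: a^2 + b^2 = {a*a + b*b} != 1")
        object.__setattr__(self, "pairs", ps)

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FitReport:
    """Outcome of a product-state fit."""

    pairs: ProductState
    residual: float
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs.pairs],
            "residual": self.residual,
            "converged": self.converged,
            "iterations": self.iterations,
        }


def expand_product_state(p: ProductState) -> np.ndarray:
    """Amplitudes of the product state over the 2^n basis states.

    The amplitude of |f_n ... f_1> (region ``1 + sum f_i 2^(i-1)``) is
    the product over i of ``b_i`` where f_i = 1 and ``a_i`` where
    f_i = 0.
    """
    amps = np.array([1.0])
    for a, b in p.pairs:  # pair i multiplies with stride 2^(i-1): kron from the left
        amps = np.kron([a, b], amps)
    return amps


def _pairs_from_angles(angles: np.ndarray) -> ProductState:
    return ProductState([(math.cos(t / 2), math.sin(t / 2)) for t in angles])


def angles_from_pairs(p: ProductState) -> list[float]:
    """RY angles with RY(angle_i)|0> = a_i|0> + b_i|1>: 2*atan2(b_i, a_i)."""
    return [2.0 * math.atan2(b, a) for a, b in p.pairs]


def fit_product_state(
    target: np.ndarray,
    tol: float = 1e-8,
    restarts: int = 16,
    seed: int | None = 0,
) -> FitReport:
    """Least-squares fit of a unit-norm real target to a product state.

    Parameterizing qubit i by a single angle enforces per-qubit
    normalization by construction.  ``restarts`` seeded uniform angle
    initializations guard against local minima; the best residual wins
    and ``converged`` records whether it reached ``tol``.  Entangled
    targets (for which no product state exists) simply report their
    floor residual.
    """
    target = np.asarray(target, dtype=float)
    n = int(math.log2(target.size))
    if 1 << n != target.size:
        raise ValueError("target length must be a power of two")
    if n > 8:
        raise ValueError("product-state fitting is capped at 8 qubits")
    if abs(np.linalg.norm(target) - 1.0) > 1e-9:
        raise ValueError("target must be unit norm")

    def objective(angles: np.ndarray) -> float:
        diff = expand_product_state(_pairs_from_angles(angles)) - target
        return float(diff @ diff)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int] | None = None
    for _ in range(max(1, restarts)):
        x0 = rng.uniform(-math.pi, math.pi, size=n)
        res = minimize(objective, x0, method="L-BFGS-B", options={"ftol": 1e-14, "gtol": 1e-12})
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x), int(res.nit))
        if best[0] <= (tol * tol) * 0.01:  # early exit on an essentially exact fit
            break
    sq, angles, nit = best
    residual = math.sqrt(max(sq, 0.0))
    return FitReport(
        pairs=_pairs_from_angles(angles),
        residual=residual,
        converged=residual <= tol,
        iterations=nit,
    )


def binomial_pattern_encode(n: int, pattern: Sequence[tuple] = ()) -> ProductState:
    """Build a patterned product encoding from block-level constraints.

    Each constraint addresses bit level ``i`` (1-based; level n splits
    the regions into halves, level n-1 into quarters, ...):

    * ``("suppress", i, "second")`` zeroes every region whose bit i is 1
      (the second half of each 2^i block), i.e. sets b_i = 0;
      ``"first"`` sets a_i = 0.
    * ``("scale", i, factor)`` makes first-half amplitudes at level i
      ``factor`` times the second half's (multiplies a_i).

    Unconstrained levels stay uniform.  Pairs are normalized at the end;
    suppressing both halves of a level is contradictory and refused.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a = np.ones(n)
    b = np.ones(n)
    for constraint in pattern:
        kind, level, arg = constraint
        if not (1 <= level <= n):
            raise ValueError(f"level {level} outside 1..{n}")
        i = level - 1
        if kind == "suppress":
            if arg == "first":
                a[i] = 0.0
            elif arg == "second":
                b[i] = 0.0
            else:
                raise ValueError(f"suppress expects 'first' or 'second', got {arg!r}")
        elif kind == "scale":
            a[i] *= float(arg)
        else:
            raise ValueError(f"unknown constraint kind {kind!r}")
    pairs = []
    for i in range(n):
        norm = math.hypot(a[i], b[i])
        if norm == 0.0:
            raise ValueError(f"level {i + 1}: both halves suppressed, nothing remains")
        pairs.append((a[i] / norm, b[i] / norm))
    return ProductState(pairs)
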