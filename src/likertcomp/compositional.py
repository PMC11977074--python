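"""Isometric log-ratio (ilr) transformation and its inverse.

A *composition* is a vector of D strictly positive parts carrying only
relative information: the parts sum to a fixed closure constant kappa
(for bipolar scale data D = 2 and kappa = 100, the parts being the order
of magnitude of agreement and of disagreement). Compositions live on the
simplex and obey the Aitchison geometry; the ilr transform maps them
isometrically onto R^{D-1}, where ordinary Euclidean statistics
(means, t-tests, regression) are valid.

The coordinates used here are the classical balances

    z_s = sqrt(s/(s+1)) * ln( gmean(x_1..x_s) / x_{s+1} ),  s = 1..D-1,

with the bivariate special case z_1 = sqrt(1/2) * ln(x* / (kappa - x*)).
The inverse map reconstructs the closed composition through a softmax of
the back-projected coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.special import expit, softmax

__all__ = [
    "Composition",
    "ilr",
    "inverse_ilr",
    "ilr_bivariate",
    "inverse_ilr_bivariate",
]

_SQRT_HALF = math.sqrt(0.5)

# Relative tolerance for the closure check sum(parts) == kappa.
_CLOSURE_RTOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """A D-part composition: strictly positive parts summing to ``kappa``.

    Parameters
    ----------
    parts
        The D positive components. Boundary compositions (a zero part)
        are rejected: the log-ratio transform is undefined there, and the
        scales in this package never produce them because the limit of
        quantification p is strictly positive.
    kappa
        Closure constant. If omitted, inferred from ``sum(parts)``.
    """

    parts: np.ndarray
    kappa: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        parts = np.asarray(self.parts, dtype=float)
        if parts.ndim != 1 or parts.size < 2:
            raise ValueError("a composition needs at least two parts")
        if not np.all(np.isfinite(parts)):
            raise ValueError("composition parts must be finite")
        if np.any(parts <= 0):
            raise ValueError(
                "composition parts must be strictly positive; boundary "
                "compositions are invalid inputs, not clamped"
            )
        kappa = float(parts.sum()) if self.kappa is None else float(self.kappa)
        if kappa <= 0:
            raise ValueError("closure constant kappa must be positive")
        if abs(parts.sum() - kappa) > _CLOSURE_RTOL * kappa:
            raise ValueError(
                f"parts sum to {parts.sum()!r}, expected kappa={kappa!r}"
            )
        object.__setattr__(self, "parts", parts)
        object.__setattr__(self, "kappa", kappa)

    @property
    def D(self) -> int:
        return self.parts.size


def ilr(x) -> np.ndarray:
    """ilr transform of a composition; returns the D-1 balance coordinates.

    ``x`` may be a :class:`Composition` or any positive 1-D array-like
    (closure then inferred from the sum).
    """
    comp = x if isinstance(x, Composition) else Composition(np.asarray(x, float))
    parts = comp.parts
    D = comp.D
    logx = np.log(parts)
    cum = np.cumsum(logx)
    s = np.arange(1, D)
    # z_s = sqrt(s/(s+1)) * ( mean(log x_1..x_s) - log x_{s+1} )
    return np.sqrt(s / (s + 1.0)) * (cum[:-1] / s - logx[1:])


def inverse_ilr(z, kappa: float = 100.0, D: int | None = None) -> Composition:
    """Inverse ilr: map coordinates z in R^{D-1} back onto the simplex.

    Uses the boundary convention z_0 := z_D := 0 and the softmax form
    x_s = kappa * exp(y_s) / sum_j exp(y_j), which is numerically stable
    for large |z|.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.ndim != 1:
        raise ValueError("z must be a 1-D coordinate vector")
    if D is None:
        D = z.size + 1
    if D != z.size + 1:
        raise ValueError(f"z has {z.size} coordinates; expected D-1={D - 1}")
    if not np.all(np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    j = np.arange(1, D + 1, dtype=float)
    zfull = np.append(z, 0.0)  # z_D := 0
    terms = zfull / np.sqrt(j * (j + 1.0))
    # tail sums: sum_{j=s}^{D} z_j / sqrt(j(j+1))
    tails = np.cumsum(terms[::-1])[::-1]
    s = np.arange(1, D + 1, dtype=float)
    zprev = np.concatenate(([0.0], z))  # z_{s-1} with z_0 := 0
    y = tails - np.sqrt((s - 1.0) / s) * zprev
    parts = kappa * softmax(y)
    return Composition(parts, kappa)


def ilr_bivariate(x_star, kappa: float = 100.0):
    """Vectorized bivariate ilr: z = sqrt(1/2) ln(x*/(kappa - x*)).

    ``x_star`` is the first part (the agreement magnitude); the second part
    is kappa - x_star. Works elementwise on arrays.
    """
    x = np.asarray(x_star, dtype=float)
    if np.any(x <= 0) or np.any(x >= kappa):
        raise ValueError("x* must lie strictly inside (0, kappa)")
    out = _SQRT_HALF * np.log(x / (kappa - x))
    return float(out) if out.ndim == 0 else out


def inverse_ilr_bivariate(z, kappa: float = 100.0):
    """Vectorized bivariate inverse ilr: x* = kappa * sigmoid(sqrt(2) z)."""
    z = np.asarray(z, dtype=float)
    out = kappa * expit(math.sqrt(2.0) * z)
    return float(out) if out.ndim == 0 else out
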