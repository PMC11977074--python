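"""Enumeration of the discrete sets of possible means (SPM).

Averaging I item responses drawn from a K-point scale can only produce
finitely many values. On the original RS these are the I*(K-1)+1 points
{1, 1+1/I, ..., K}; on the ilr response scale the category values are not
equidistant, so the achievable means form an irregular set of up to
C(K+I-1, I) points. Simulated continuous means are later snapped onto
these sets to emulate what real questionnaire data can actually realize.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb

import numpy as np
import pandas as pd

from .scales import StarScale

__all__ = [
    "PossibleMeansSet",
    "enumerate_possible_means",
    "map_star_mean_to_rs_mean",
]

#: refuse enumerations with more than this many multisets
DEFAULT_MAX_MULTISETS = 10**6


@dataclass(frozen=True, eq=False)
class PossibleMeansSet:
    """Sorted distinct achievable means of I responses on one scale.

    ``tol`` is the absolute tolerance used to merge floating-point
    duplicates (symmetric scales produce the same mean through different
    response multisets, e.g. {1,5} and {2,4} on the RS).
    """

    scale_tag: str
    I: int
    values: np.ndarray
    tol: float = 1e-9

    def __len__(self) -> int:
        return self.values.size

    @property
    def min(self) -> float:
        return float(self.values[0])

    @property
    def max(self) -> float:
        return float(self.values[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scale_tag": self.scale_tag, "I": self.I, "value": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_possible_means(
    scale_values,
    I: int,
    scale_tag: str = "custom",
    tol: float = 1e-9,
    max_multisets: int = DEFAULT_MAX_MULTISETS,
) -> PossibleMeansSet:
    """All means of size-I multisets drawn from ``scale_values``.

    Enumeration runs over combinations with replacement (responses are
    exchangeable within a mean), then sorts and merges values closer than
    ``tol``. The multiset count C(K+I-1, I) is capped to keep the
    enumeration tractable; the replication grids here stay far below it.
    """
    if int(I) != I or I < 1:
        raise ValueError(f"item count I must be an integer >= 1, got {I}")
    I = int(I)
    vals = np.sort(np.asarray(scale_values, dtype=float))
    if vals.size < 2:
        raise ValueError("scale must have at least 2 values")
    n_multisets = comb(vals.size + I - 1, I)
    if n_multisets > max_multisets:
        raise ValueError(
            f"enumeration of {n_multisets} multisets exceeds the cap "
            f"{max_multisets}; reduce K or I"
        )
    means = np.fromiter(
        (sum(c) for c in combinations_with_replacement(vals, I)),
        dtype=float,
        count=n_multisets,
    )
    means = np.sort(means / I)
    keep = np.empty(means.size, dtype=bool)
    keep[0] = True
    np.greater(np.diff(means), tol, out=keep[1:])
    return PossibleMeansSet(scale_tag=scale_tag, I=I, values=means[keep], tol=tol)


def map_star_mean_to_rs_mean(star_mean, star: StarScale):
    """Affine correspondence between RS* means and original-RS means.

    The RS -> RS* map is affine (x* = lLOQ + sw*(s-1)), so means of the
    same responses correspond one-to-one: rs_mean = 1 + (star_mean - lLOQ)/sw.
    Vectorized; total on all reals (not restricted to SPM members).
    """
    m = np.asarray(star_mean, dtype=float)
    out = 1.0 + (m - star.loq.lloq) / star.sw
    return float(out) if out.ndim == 0 else out
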