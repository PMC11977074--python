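"""Nearest-possible-mean replacement ("snapping") of simulated means.

A continuous simulated mean cannot be observed in practice: real
questionnaire means live on the discrete sets of possible means. Each raw
simulated ilr-scale value is therefore replaced along two parallel paths
starting from the same raw value:

* **ilr path** — snap directly to the nearest element of the ilr SPM
  (Euclidean metric on the ilr scale);
* **orig path** — inverse-ilr the raw value onto the star scale RS*, snap
  to the nearest RS* possible mean using the Euclidean metric there, then
  map affinely to the original RS mean.

Using the Euclidean metric on RS* is deliberate although the Aitchison
metric would be the compositionally correct one: the orig path emulates
common practice, where means are computed ignoring the compositional
structure, and the whole point of the comparison is to quantify the
consequences of that habit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositional import inverse_ilr_bivariate
from .possible_means import PossibleMeansSet, map_star_mean_to_rs_mean
from .scales import ScaleSystem

__all__ = ["snap", "SnappedPair", "snap_both_paths"]


def _grid_of(spm) -> np.ndarray:
    return spm.values if isinstance(spm, PossibleMeansSet) else np.asarray(spm, float)


def snap(value, spm):
    """Nearest element of the possible-means set, elementwise.

    Ties break toward the smaller element (a fixed deterministic rule;
    exact ties sit at SPM midpoints and have probability zero under the
    continuous DGP). Values outside the support clamp to the nearest
    extreme as an automatic consequence of nearest-neighbor search.
    """
    grid = _grid_of(spm)
    if grid.size == 0:
        raise ValueError("possible-means set is empty")
    v = np.asarray(value, dtype=float)
    if grid.size == 1:
        out = np.full_like(v, grid[0])
        return float(out) if out.ndim == 0 else out
    idx = np.clip(np.searchsorted(grid, v), 1, grid.size - 1)
    lo = grid[idx - 1]
    hi = grid[idx]
    out = np.where(v - lo <= hi - v, lo, hi)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SnappedPair:
    """The two dataset entries produced from one raw simulated mean."""

    mu_ilr: float
    mu_orig: float


def snap_both_paths(
    value,
    system: ScaleSystem,
    spm_ilr: PossibleMeansSet,
    spm_star: PossibleMeansSet,
):
    """Run both replacement paths from the same raw ilr-scale value.

    Returns a :class:`SnappedPair` for scalar input; for array input,
    a tuple of arrays ``(mu_ilr, mu_orig)``.
    """
    v = np.asarray(value, dtype=float)
    mu_ilr = snap(v, spm_ilr)
    star = snap(inverse_ilr_bivariate(v, system.star.kappa), spm_star)
    mu_orig = map_star_mean_to_rs_mean(star, system.star)
    if v.ndim == 0:
        return SnappedPair(mu_ilr=float(mu_ilr), mu_orig=float(mu_orig))
    return mu_ilr, mu_orig
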