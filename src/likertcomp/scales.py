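"""Response scales for bipolar Likert items and their trait-scale embedding.

Three linked scales describe one item format:

* the **trait scale** (TS) ``[L, U]`` — the continuum of all manifestations
  of the latent trait, by convention ``[0, 100]``;
* the **response scale** (RS) ``{1, ..., K}`` — the discrete categories a
  respondent can choose, unit-spaced without loss of generality;
* the **star scale** (RS*) — the RS embedded into the trait scale under a
  limit of quantification (LOQ): a fraction ``p`` of the trait continuum
  that no item wording can reach, split symmetrically into edge areas of
  width ``p/2`` below and above. The K categories map to equidistant
  values from ``lLOQ = kappa*p/2`` to ``uLOQ = kappa*(1 - p/2)``.

Each star value x* together with its complement ``kappa - x*`` forms a
two-part composition (agreement vs. disagreement magnitude), so the RS*
has an ilr image — the "ilr response scale" — whose spread grows without
bound as p -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositional import ilr_bivariate

__all__ = [
    "TraitScale",
    "LOQ",
    "ResponseScale",
    "StarScale",
    "ScaleSystem",
    "build_star_scale",
    "transform_response",
    "relative_edge_distance",
]


@dataclass(frozen=True)
class TraitScale:
    """The trait continuum [lower, upper]; kappa = upper - lower."""

    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("trait scale requires lower < upper")

    @property
    def kappa(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class LOQ:
    """Symmetric limit of quantification.

    ``p`` in (0, 1) is the fraction of the trait scale outside the reach of
    the response scale, split into equal edge areas delta_l = delta_u = p/2.
    Asymmetric limits are not representable by construction.
    """

    p: float
    kappa: float = 100.0

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"LOQ fraction p must lie in (0, 1), got {self.p}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def lloq(self) -> float:
        return self.kappa * self.p / 2.0

    @property
    def uloq(self) -> float:
        return self.kappa * (1.0 - self.p / 2.0)

    @property
    def delta_l(self) -> float:
        return self.p / 2.0

    @property
    def delta_u(self) -> float:
        return self.p / 2.0


@dataclass(frozen=True)
class ResponseScale:
    """The discrete categories {1, ..., K}, unit spacing."""

    K: int

    def __post_init__(self):
        if int(self.K) != self.K or self.K < 2:
            raise ValueError(f"K must be an integer >= 2, got {self.K}")
        object.__setattr__(self, "K", int(self.K))

    @property
    def k(self) -> int:
        return self.K - 1

    @property
    def values(self) -> np.ndarray:
        return np.arange(1, self.K + 1, dtype=float)


@dataclass(frozen=True, eq=False)
class StarScale:
    """RS* — K equidistant values from lLOQ to uLOQ on the trait scale."""

    K: int
    loq: LOQ
    values: np.ndarray
    sw: float

    @property
    def range(self) -> float:
        return self.loq.uloq - self.loq.lloq

    @property
    def kappa(self) -> float:
        return self.loq.kappa


def build_star_scale(K: int, p: float, kappa: float = 100.0) -> StarScale:
    """Construct the star scale RS* for K categories under LOQ fraction p.

    The step width is sw = (uLOQ - lLOQ) / (K - 1); category s maps to
    lLOQ + sw * (s - 1). Example: K=5, p=0.05 gives
    {2.5, 26.25, 50, 73.75, 97.5} with sw = 23.75.
    """
    rs = ResponseScale(K)  # validates K
    loq = LOQ(p, kappa)
    sw = (loq.uloq - loq.lloq) / rs.k
    values = loq.lloq + sw * np.arange(rs.K, dtype=float)
    return StarScale(K=rs.K, loq=loq, values=values, sw=sw)


def transform_response(x_prime: int, scale: StarScale) -> float:
    """Map a raw category x' in {1, ..., K} to its star-scale value."""
    if int(x_prime) != x_prime or not 1 <= x_prime <= scale.K:
        raise ValueError(
            f"response must be an integer category in 1..{scale.K}, got {x_prime}"
        )
    return float(scale.values[int(x_prime) - 1])


def relative_edge_distance(values) -> float:
    """Gap between the two largest distinct values relative to the range.

    On the original RS the edge categories are as close, relatively, as any
    others (e.g. (5-4)/(5-1) = 0.25 for K=5); on the ilr response scale the
    edges spread out and this diagnostic grows as p -> 0, which is the
    geometric driver of power loss for heavy-tailed data.
    """
    v = np.unique(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least 2 distinct values")
    return float((v[-1] - v[-2]) / (v[-1] - v[0]))


@dataclass(frozen=True, eq=False)
class ScaleSystem:
    """The linked triple: RS {1..K}, its star embedding RS*, and the ilr RS."""

    rs: ResponseScale
    star: StarScale
    ilr_values: np.ndarray

    @classmethod
    def create(cls, K: int, p: float, kappa: float = 100.0) -> "ScaleSystem":
        star = build_star_scale(K, p, kappa)
        ilr_values = ilr_bivariate(star.values, kappa)
        return cls(rs=ResponseScale(K), star=star, ilr_values=ilr_values)

    @property
    def K(self) -> int:
        return self.rs.K

    @property
    def p(self) -> float:
        return self.star.loq.p

    def to_config(self) -> dict:
        """Serializable scale definition (keys: K, p, kappa)."""
        return {"K": self.K, "p": self.p, "kappa": self.star.kappa}
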