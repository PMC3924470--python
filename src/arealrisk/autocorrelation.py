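"""Global and local spatial autocorrelation statistics.

Moran's I (normality / randomization analytic variance, or permutation
inference), the Getis-Ord General G concentration statistic, and the
local Gi* hot-spot statistic with its full-window (self-included)
formulation.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from arealrisk.areal_core import SpatialWeights
from arealrisk.errors import DegenerateInputError, DomainError

__all__ = [
    "GlobalStatResult",
    "LocalGResult",
    "classify_hot_cold",
    "general_g",
    "local_gi_star",
    "morans_i",
]


@dataclass
class GlobalStatResult:
    statistic: float
    expectation: float
    variance: float
    z: float
    p: float
    method: str
    n_permutations: int = 0

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "expectation": self.expectation,
            "variance": self.variance,
            "z": self.z,
            "p": self.p,
            "method": self.method,
            "n_permutations": self.n_permutations,
        }


@dataclass
class LocalGResult:
    area_ids: list[str]
    gi_star: np.ndarray
    z: np.ndarray
    p: np.ndarray
    cluster_label: list[str] | None = None


def _moment_sums(wmat: np.ndarray) -> tuple[float, float, float]:
    """S0, S1, S2 weight moments used by the analytic variances."""
    s0 = wmat.sum()
    s1 = 0.5 * ((wmat + wmat.T) ** 2).sum()
    s2 = ((wmat.sum(axis=1) + wmat.sum(axis=0)) ** 2).sum()
    return float(s0), float(s1), float(s2)


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def morans_i(
    values,
    w: SpatialWeights,
    method: str = "randomization",
    n_permutations: int = 0,
    seed: int | None = None,
) -> GlobalStatResult:
    """Global Moran's I with analytic or permutation inference.

    ``method`` is ``"normality"``, ``"randomization"`` (default, the
    usual closed-form variance under random relabelling) or
    ``"permutation"`` (empirical null; requires ``n_permutations`` and
    ``seed``).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateInputError("Moran's I needs at least 3 areas")
    if np.ptp(x) == 0:
        raise DegenerateInputError("values are constant; Moran's I undefined")
    wmat = w.matrix()
    s0, s1, s2 = _moment_sums(wmat)
    if s0 <= 0:
        raise DegenerateInputError("all weights zero")

    z = x - x.mean()
    denom = float(z @ z)
    stat = float(n / s0 * (z @ wmat @ z) / denom)
    e_i = -1.0 / (n - 1)

    if method == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
    elif method in ("randomization", "permutation"):
        b2 = n * float((z**4).sum()) / denom**2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i**2
    else:
        raise ValueError(f"unknown method {method!r}")

    zscore = (stat - e_i) / np.sqrt(var)
    if method == "permutation":
        if n_permutations < 1:
            raise ValueError("permutation method needs n_permutations >= 1")
        rng = np.random.default_rng(seed)
        sims = np.empty(n_permutations)
        for r in range(n_permutations):
            zp = z[rng.permutation(n)]
            sims[r] = n / s0 * (zp @ wmat @ zp) / denom
        if stat >= sims.mean():
            k = int((sims >= stat).sum())
        else:
            k = int((sims <= stat).sum())
        p = min(1.0, 2.0 * (k + 1) / (n_permutations + 1))
        return GlobalStatResult(stat, e_i, float(var), float(zscore), p,
                                "permutation", n_permutations)
    return GlobalStatResult(stat, e_i, float(var), float(zscore),
                            _two_sided_p(zscore), method)


def general_g(values, w: SpatialWeights) -> GlobalStatResult:
    """Getis-Ord General G: concentration of high values among neighbors.

    Defined for non-negative variates and binary symmetric weights; the
    variance follows the standard randomization moments, so the z-score
    matches brute-force permutation on small lattices.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateInputError("General G needs at least 2 areas")
    if np.any(x < 0):
        raise DomainError("General G is defined for non-negative values")
    if np.all(x == 0):
        raise DegenerateInputError("all values zero; General G undefined")
    wmat = w.matrix()
    s0, s1, s2 = _moment_sums(wmat)
    if s0 <= 0:
        raise DegenerateInputError("all weights zero")

    t1 = float(x.sum())
    t2 = float((x**2).sum())
    t3 = float((x**3).sum())
    t4 = float((x**4).sum())
    denom = t1 * t1 - t2  # sum over ordered pairs i != j of x_i x_j
    if denom <= 0:
        raise DegenerateInputError("degenerate value configuration for General G")
    num = float(x @ wmat @ x) - float((np.diag(wmat) * x * x).sum())
    stat = num / denom
    e_g = s0 / (n * (n - 1))
    if n < 4:
        # moment formulas need n >= 4; statistic and expectation still defined
        return GlobalStatResult(stat, float(e_g), float("nan"), float("nan"),
                                float("nan"), "normality")

    b0 =(n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0
    b1 = -((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
    b2 = -(2 * n * s1 - (n + 3) * s2 + 6 * s0 * s0)
    b3 = 4 * (n - 1) * s1 - 2 * (n + 1) * s2 + 8 * s0 * s0
    b4 = s1 - s2 + s0 * s0
    e_g2 = (b0 * t2 * t2 + b1 * t4 + b2 * t1 * t1 * t2 + b3 * t1 * t3 + b4 * t1**4) / (
        denom * denom * n * (n - 1) * (n - 2) * (n - 3)
    )
    var = e_g2 - e_g * e_g
    if var <= 0:
        zscore = 0.0
    else:
        zscore = (stat - e_g) / np.sqrt(var)
    return GlobalStatResult(stat, float(e_g), float(var), float(zscore),
                            _two_sided_p(zscore), "normality")


def local_gi_star(values, w: SpatialWeights, area_ids: list[str] | None = None) -> LocalGResult:
    """Local Gi* per area, full-window form (the focal area's own value
    is included with self-weight 1).

    A constant surface yields z = 0 everywhere (the local sum equals its
    expectation exactly).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateInputError("Gi* needs at least 3 areas")
    ids = list(area_ids) if area_ids is not None else list(w.ids)
    wmat = w.matrix(ids if area_ids is not None else None)
    np.fill_diagonal(wmat, 1.0)  # self-included window

    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    wi = wmat.sum(axis=1)
    s1i = (wmat**2).sum(axis=1)
    local_sum = wmat @ x

    total = x.sum()
    gi = np.divide(local_sum, total, out=np.zeros(n), where=total != 0)
    num = local_sum - xbar * wi
    scale = s * np.sqrt(np.maximum(n * s1i - wi**2, 0.0) / (n - 1))
    z = np.divide(num, scale, out=np.zeros(n), where=scale > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LocalGResult(area_ids=ids, gi_star=gi, z=z, p=p)


def classify_hot_cold(local: LocalGResult, alpha: float = 0.10) -> LocalGResult:
    """Label each area hot / cold / not_significant at level ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = []
    for z, p in zip(local.z, local.p):
        if p <= alpha and z > 0:
            labels.append("hot")
        elif p <= alpha and z < 0:
            labels.append("cold")
        else:
            labels.append("not_significant")
    return LocalGResult(
        area_ids=list(local.area_ids),
        gi_star=local.gi_star.copy(),
        z=local.z.copy(),
        p=local.p.copy(),
        cluster_label=labels,
    )
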