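"""Synthetic areal datasets with known generative structure.

Counts follow O_i ~ Poisson(E_i * risk_i) with log risk built from an
intercept, a covariate effect, iid normal heterogeneity, an intrinsic
CAR (Gaussian ICAR) spatially structured component sampled on the
sum-to-zero subspace, and optional embedded circular high-risk
clusters.  Every latent quantity is returned in a truth record so
estimator tests can close the generator-estimator loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from arealrisk.areal_core import AreaLattice, SpatialWeights, build_contiguity
from arealrisk.errors import DomainError
from arealrisk.standardization import CountTable

__all__ = ["SyntheticScenario", "generate", "grid_lattice", "sample_icar", "shenzhen_like"]


@dataclass
class SyntheticScenario:
    """Generative parameters for one synthetic areal dataset."""

    grid_rows: int = 10
    grid_cols: int = 10
    population_median: float = 50_000.0
    population_log_sd: float = 0.6
    total_cases_target: float = 10_000.0
    alpha0: float = 0.0
    beta: float = 0.0
    covariate_model: str = "gradient"  # "gradient" | "iid"
    covariate_sd: float = 1.0
    delta: float = 0.0  # SD of the iid heterogeneity U
    sigma: float = 0.0  # scale of the ICAR clustering S
    clusters: list[tuple[int, float, float]] = field(default_factory=list)
    # each cluster: (center area index, radius in cell units, risk multiplier)
    merge_pairs: int = 0  # horizontally merged cell pairs (irregular lattice)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise DomainError("grid dimensions must be positive")
        if self.delta < 0 or self.sigma < 0:
            raise DomainError("variance-component scales must be non-negative")
        if self.population_median <= 0 or self.total_cases_target <= 0:
            raise DomainError("population and case totals must be positive")
        for _, radius, rr in self.clusters:
            if radius < 0 or rr <= 0:
                raise DomainError("cluster radius must be >= 0 and multiplier > 0")

    @property
    def n_areas(self) -> int:
        return self.grid_rows * self.grid_cols - self.merge_pairs


def grid_lattice(rows: int, cols: int, merge_pairs: int = 0) -> AreaLattice:
    """Unit-square grid; optionally merge trailing horizontal cell pairs
    (scanning from the last cell backwards) to get an irregular count."""
    polys = []
    for r in range(rows):
        for c in range(cols):
            polys.append(box(c, r, c + 1, r + 1))
    merged = 0
    idx = rows * cols - 2
    while merged < merge_pairs and idx >= 0:
        r, c = divmod(idx, cols)
        if c + 1 < cols and polys[idx] is not None and polys[idx + 1] is not None:
            polys[idx] = unary_union([polys[idx], polys[idx + 1]])
            polys[idx + 1] = None
            merged += 1
            idx -= 2
        else:
            idx -= 1
    if merged < merge_pairs:
        raise DomainError("cannot merge that many cell pairs on this grid")
    keep = [p for p in polys if p is not None]
    ids = [f"A{k:03d}" for k in range(len(keep))]
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in keep])
    return AreaLattice(area_ids=ids, centroids=centroids, polygons=keep)


def sample_icar(w: SpatialWeights, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic Gaussian CAR on the sum-to-zero subspace.

    Covariance is sigma^2 times the pseudo-inverse of the graph
    Laplacian: coefficients along eigenvectors with eigenvalue lam get
    variance sigma^2 / lam; the null space (constants per component) is
    excluded.
    """
    if sigma < 0:
        raise DomainError("sigma must be non-negative")
    n = w.n
    if sigma == 0:
        return np.zeros(n)
    a = w.matrix()
    a = np.where(a > 0, 1.0, 0.0)
    lap = np.diag(a.sum(axis=1)) - a
    lam, vec = np.linalg.eigh(lap)
    pos = lam > 1e-9 * max(lam.max(), 1.0)
    coeffs = rng.normal(0.0, sigma / np.sqrt(lam[pos]))
    return vec[:, pos] @ coeffs


def generate(
    scenario: SyntheticScenario,
) -> tuple[AreaLattice, SpatialWeights, CountTable, dict]:
    """Generate (lattice, queen weights, count table, truth record)."""
    rng = np.random.default_rng(scenario.seed)
    lattice = grid_lattice(
        scenario.grid_rows, scenario.grid_cols, scenario.merge_pairs
    )
    n = lattice.n
    weights = build_contiguity(lattice, rule="queen")

    population = scenario.population_median * np.exp(
        rng.normal(0.0, scenario.population_log_sd, n)
    )

    if scenario.covariate_model == "gradient":
        gx = lattice.centroids[:, 0]
        x = (gx - gx.min()) / max(gx.max() - gx.min(), 1e-12)
        x = scenario.covariate_sd * x + rng.normal(0, 0.05 * scenario.covariate_sd, n)
    elif scenario.covariate_model == "iid":
        x = rng.normal(0.0, scenario.covariate_sd, n)
    else:
        raise DomainError(f"unknown covariate_model {scenario.covariate_model!r}")

    u = rng.normal(0.0, scenario.delta, n) if scenario.delta > 0 else np.zeros(n)
    s = sample_icar(weights, scenario.sigma, rng)

    cluster_mult = np.ones(n)
    cluster_members: list[list[str]] = []
    cent = lattice.centroids
    for center, radius, rr in scenario.clusters:
        d = np.hypot(cent[:, 0] - cent[center, 0], cent[:, 1] - cent[center, 1])
        members = np.flatnonzero(d <= radius + 1e-9)
        cluster_mult[members] *= rr
        cluster_members.append([lattice.area_ids[k] for k in members])

    risk = np.exp(scenario.alpha0 + scenario.beta * x + u + s) * cluster_mult

    # scale populations so the expected total case count hits the target
    base_rate = scenario.total_cases_target / float((population * risk).sum())
    expected_true = population * base_rate
    observed = rng.poisson(expected_true * risk).astype(float)

    lattice.population = population
    table = CountTable(
        area_ids=list(lattice.area_ids),
        observed=observed,
        population=population,
        covariates={"road_density": x},
    )
    truth = {
        "alpha0": scenario.alpha0,
        "beta": scenario.beta,
        "x": x,
        "u": u,
        "s": s,
        "risk": risk,
        "cluster_multiplier": cluster_mult,
        "cluster_members": cluster_members,
        "expected_true": expected_true,
        "population": population,
        "seed": scenario.seed,
    }
    return lattice, weights, table, truth


def shenzhen_like(seed: int = 0) -> SyntheticScenario:
    """A 57-area preset sized like a city-wide admission dataset: ~10,419
    total cases, one embedded 3-area corner cluster at risk ratio 2.7,
    covariate effect 0.45, modest unstructured and structured noise."""
    return SyntheticScenario(
        grid_rows=8,
        grid_cols=8,
        merge_pairs=7,
        population_median=100_000.0,
        population_log_sd=0.7,
        total_cases_target=10_419.0,
        alpha0=0.0,
        beta=0.45,
        covariate_model="gradient",
        covariate_sd=1.0,
        delta=0.15,
        sigma=0.3,
        clusters=[(0, 1.0, 2.7)],
        seed=seed,
    )
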