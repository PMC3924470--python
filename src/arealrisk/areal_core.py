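"""Areal data model, contiguity weights, and plain-text format I/O.

The spatial backbone of the pipeline: :class:`AreaLattice` holds per-area
geometry, centroids and populations; :class:`SpatialWeights` holds the
neighbor structure every autocorrelation and smoothing stage consumes.
Supported interchange formats are GeoJSON FeatureCollections (polygons,
property key ``area_id``), GAL neighbor-list files (ids, not indices) and
CSV area tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from arealrisk.errors import GeometryError, ValidationError

__all__ = [
    "AreaLattice",
    "SpatialWeights",
    "build_contiguity",
    "read_area_table",
    "read_gal",
    "read_geojson",
    "row_standardize",
    "write_gal",
    "write_geojson",
    "write_results",
]


@dataclass
class AreaLattice:
    """The areal units: ids, centroids, optional polygons, populations.

    Parameters
    ----------
    area_ids
        Unique, non-empty string identifier per area.
    centroids
        ``(n, 2)`` planar coordinates (projected units), or ``None``.
        Centroids are required before scan statistics can run.
    polygons
        Optional shapely geometry per area (``None`` entries allowed).
    population
        Non-negative resident count per area.
    area_size
        Positive area measure, used e.g. for road density = length/area.
        Derived from polygons when absent.
    """

    area_ids: list[str]
    centroids: np.ndarray | None = None
    polygons: list[BaseGeometry | None] | None = None
    population: np.ndarray | None = None
    area_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_ids = [str(a) for a in self.area_ids]
        if len(self.area_ids) != len(set(self.area_ids)):
            seen: set[str] = set()
            dups = sorted({a for a in self.area_ids if a in seen or seen.add(a)})
            raise ValidationError(f"duplicate area_ids: {dups}")
        if any(not a for a in self.area_ids):
            raise ValidationError("empty area_id encountered")
        n = len(self.area_ids)
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (n, 2):
                raise ValidationError(
                    f"centroids shape {self.centroids.shape} != ({n}, 2)"
                )
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=float)
            if self.population.shape != (n,):
                raise ValidationError("population length mismatch")
            if np.any(self.population < 0):
                bad = [self.area_ids[i] for i in np.flatnonzero(self.population < 0)]
                raise ValidationError(f"negative population for areas: {bad}")
        if self.polygons is not None and len(self.polygons) != n:
            raise ValidationError("polygons length mismatch")
        if self.area_size is not None:
            self.area_size = np.asarray(self.area_size, dtype=float)
            if np.any(self.area_size <= 0):
                raise ValidationError("area_size must be positive")
        elif self.polygons is not None:
            self.area_size = np.array(
                [p.area if p is not None else np.nan for p in self.polygons]
            )

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def index_of(self, area_id: str) -> int:
        return self.area_ids.index(area_id)

    def require_centroids(self) -> np.ndarray:
        if self.centroids is None:
            raise GeometryError("lattice has no centroids; scan statistics need them")
        return self.centroids


@dataclass
class SpatialWeights:
    """Neighbor lists with numeric weights per ordered pair.

    ``style`` is ``"binary"`` (symmetric 0/1 weights) or
    ``"row-standardized"`` (each non-isolated row sums to 1).
    Self-neighbors are forbidden.
    """

    ids: list[str]
    neighbors: dict[str, list[str]]
    weights: dict[str, list[float]] = field(default_factory=dict)
    style: str = "binary"

    def __post_init__(self) -> None:
        self.ids = [str(a) for a in self.ids]
        idset = set(self.ids)
        if len(self.ids) != len(idset):
            raise ValidationError("duplicate ids in weights")
        for i in self.ids:
            self.neighbors.setdefault(i, [])
        for i, nbrs in self.neighbors.items():
            if i not in idset:
                raise ValidationError(f"weights reference unknown id {i!r}")
            unknown = [j for j in nbrs if j not in idset]
            if unknown:
                raise ValidationError(f"area {i!r} references unknown ids {unknown}")
            if i in nbrs:
                raise ValidationError(f"self-neighbor w_ii != 0 for area {i!r}")
            if not self.weights.get(i):
                self.weights[i] = [1.0] * len(nbrs)
            elif len(self.weights[i]) != len(nbrs):
                raise ValidationError(f"weights length mismatch for area {i!r}")
        if self.style == "binary":
            nbr_sets = {i: set(v) for i, v in self.neighbors.items()}
            for i, nbrs in nbr_sets.items():
                for j in nbrs:
                    if i not in nbr_sets[j]:
                        raise ValidationError(
                            f"binary weights asymmetric: {i!r}->{j!r} but not back"
                        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def cardinalities(self) -> dict[str, int]:
        return {i: len(self.neighbors[i]) for i in self.ids}

    def islands(self) -> list[str]:
        return [i for i in self.ids if not self.neighbors[i]]

    def matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense weight matrix in the given (or native) id order."""
        order = list(order) if order is not None else self.ids
        pos = {a: k for k, a in enumerate(order)}
        w = np.zeros((len(order), len(order)))
        for i in self.ids:
            for j, wij in zip(self.neighbors[i], self.weights[i]):
                w[pos[i], pos[j]] = wij
        return w

    def neighbor_sets(self) -> dict[str, frozenset[str]]:
        return {i: frozenset(v) for i, v in self.neighbors.items()}


def build_contiguity(lattice: AreaLattice, rule: str = "queen") -> SpatialWeights:
    """Binary contiguity weights from polygon geometry.

    ``queen``: areas sharing any boundary point are neighbors.
    ``rook``: only areas sharing an edge of positive length.
    Isolated areas are retained (with a warning), not rejected.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    if lattice.polygons is None:
        raise GeometryError("lattice has no polygons; cannot build contiguity")
    for aid, poly in zip(lattice.area_ids, lattice.polygons):
        if poly is None or poly.is_empty:
            raise GeometryError(f"missing polygon for area {aid!r}")
        if not poly.is_valid:
            raise GeometryError(f"invalid polygon geometry for area {aid!r}")

    from shapely.strtree import STRtree

    polys = list(lattice.polygons)
    tree = STRtree(polys)
    neighbors: dict[str, list[str]] = {a: [] for a in lattice.area_ids}
    for i, poly in enumerate(polys):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            inter = poly.intersection(polys[j])
            if inter.is_empty:
                continue
            touch = inter.length > 0 if rule == "rook" else True
            if touch:
                neighbors[lattice.area_ids[i]].append(lattice.area_ids[j])
                neighbors[lattice.area_ids[j]].append(lattice.area_ids[i])
    for a in neighbors:
        neighbors[a].sort()
    w = SpatialWeights(ids=list(lattice.area_ids), neighbors=neighbors, style="binary")
    isl = w.islands()
    if isl:
        warnings.warn(f"isolated areas (no {rule} neighbors): {isl}", stacklevel=2)
    return w


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Rescale each row of weights to sum to one; isolated rows stay zero."""
    weights = {}
    for i in w.ids:
        row = np.asarray(w.weights[i], dtype=float)
        s = row.sum()
        weights[i] = list(row / s) if s > 0 else [0.0] * len(row)
    return SpatialWeights(
        ids=list(w.ids),
        neighbors={i: list(v) for i, v in w.neighbors.items()},
        weights=weights,
        style="row-standardized",
    )


# ---------------------------------------------------------------------------
# I/O


def read_area_table(path) -> tuple[AreaLattice, "pd.DataFrame"]:
    """Read a CSV area table (area_id, population, observed, covariates...).

    Returns a lattice (ids + population, plus centroids if ``x``/``y``
    columns are present) and the full table as a DataFrame.  Validation
    errors list all offending rows.
    """
    df = pd.read_csv(path, dtype={"area_id": str})
    required = {"area_id", "population", "observed"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"area table missing columns: {sorted(missing)}")
    dup = df["area_id"][df["area_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate area_ids: {sorted(set(dup))}")
    bad_obs = df.loc[df["observed"] < 0, "area_id"].tolist()
    if bad_obs:
        raise ValidationError(f"negative observed counts for areas: {bad_obs}")
    bad_pop = df.loc[df["population"] < 0, "area_id"].tolist()
    if bad_pop:
        raise ValidationError(f"negative population for areas: {bad_pop}")
    centroids = None
    if {"x", "y"} <= set(df.columns):
        centroids = df[["x", "y"]].to_numpy(float)
    lattice = AreaLattice(
        area_ids=df["area_id"].tolist(),
        centroids=centroids,
        population=df["population"].to_numpy(float),
    )
    return lattice, df


def write_results(path, table: pd.DataFrame) -> None:
    """Write a results table as CSV (or JSON records if path ends .json)."""
    path = str(path)
    if path.endswith(".json"):
        table.to_json(path, orient="records", indent=2)
    else:
        table.to_csv(path, index=False)


def read_gal(path, ids: Iterable[str] | None = None) -> SpatialWeights:
    """Read a GAL neighbor-list file (header count, then "id k" / neighbor lines)."""
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise ValidationError("empty GAL file")
    header = tokens_by_line[0]
    # header may be "n" or the four-field "0 n shapefile varname" variant
    n_declared = int(header[1] if len(header) >= 2 else header[0])
    neighbors: dict[str, list[str]] = {}
    order: list[str] = []
    k = 1
    while k < len(tokens_by_line):
        head = tokens_by_line[k]
        if len(head) != 2:
            raise ValidationError(f"malformed GAL record line: {' '.join(head)!r}")
        aid, deg = head[0], int(head[1])
        nbrs: list[str] = []
        if deg > 0:
            k += 1
            if k >= len(tokens_by_line):
                raise ValidationError(f"GAL truncated after area {aid!r}")
            nbrs = tokens_by_line[k]
            if len(nbrs) != deg:
                raise ValidationError(
                    f"area {aid!r} declares {deg} neighbors, lists {len(nbrs)}"
                )
        if aid in neighbors:
            raise ValidationError(f"duplicate GAL record for area {aid!r}")
        neighbors[aid] = nbrs
        order.append(aid)
        k += 1
    if len(order) != n_declared:
        raise ValidationError(
            f"GAL header declares {n_declared} areas, file has {len(order)}"
        )
    all_ids = list(ids) if ids is not None else order
    known = set(all_ids)
    offenders = sorted(
        {j for nbrs in neighbors.values() for j in nbrs if j not in known}
        | {i for i in order if i not in known}
    )
    if offenders:
        raise ValidationError(f"GAL references unknown ids: {offenders}")
    for a in all_ids:
        neighbors.setdefault(a, [])
    return SpatialWeights(ids=all_ids, neighbors=neighbors, style="binary")


def write_gal(path, w: SpatialWeights) -> None:
    """Write weights as a GAL neighbor-list file (ids, not indices)."""
    with open(path, "w") as fh:
        fh.write(f"{w.n}\n")
        for i in w.ids:
            nbrs = w.neighbors[i]
            fh.write(f"{i} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(nbrs) + "\n")


def read_geojson(path) -> AreaLattice:
    """Read a GeoJSON FeatureCollection with an ``area_id`` property."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    ids, polys, pops = [], [], []
    have_pop = True
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise ValidationError("feature missing 'area_id' property")
        ids.append(str(props["area_id"]))
        geom = feat.get("geometry")
        if geom is None:
            raise GeometryError(f"feature {props['area_id']!r} has no geometry")
        polys.append(shapely_shape(geom))
        if "population" in props:
            pops.append(float(props["population"]))
        else:
            have_pop = False
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    return AreaLattice(
        area_ids=ids,
        centroids=centroids,
        polygons=polys,
        population=np.asarray(pops) if have_pop and pops else None,
    )


def write_geojson(path, lattice: AreaLattice, properties: Mapping[str, Sequence] | None = None) -> None:
    """Write the lattice polygons as a GeoJSON FeatureCollection."""
    if lattice.polygons is None:
        raise GeometryError("lattice has no polygons to write")
    feats = []
    for k, (aid, poly) in enumerate(zip(lattice.area_ids, lattice.polygons)):
        props: dict = {"area_id": aid}
        if lattice.population is not None:
            props["population"] = float(lattice.population[k])
        if properties:
            for key, vals in properties.items():
                props[key] = vals[k]
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": shapely_mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
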