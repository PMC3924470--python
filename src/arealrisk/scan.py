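"""Purely spatial Poisson scan statistic with circular windows.

Windows are distance-ordered prefixes of areas around each centroid,
grown until the inside expected count reaches a fraction of the total
(default 50%).  The most likely cluster maximizes the Poisson likelihood
ratio; inference is by conditional Monte Carlo replication of the total
case count, and secondary clusters are reported under the no-overlap
rule.  Only high-rate (inside rate > outside rate) windows score by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from arealrisk.areal_core import AreaLattice
from arealrisk.errors import DegenerateInputError, DomainError, GeometryError
from arealrisk.standardization import CountTable, compute_expected

__all__ = [
    "ScanCluster",
    "ScanWindow",
    "cluster_relative_risk",
    "enumerate_windows",
    "poisson_llr",
    "scan",
]


@dataclass
class ScanWindow:
    center_area: str
    member_areas: list[str]
    inside_observed: float
    inside_expected: float


@dataclass
class ScanCluster:
    window: ScanWindow
    llr: float
    relative_risk: float
    p_value: float
    rank: int

    def as_dict(self) -> dict:
        return {
            "rank": self.rank,
            "center": self.window.center_area,
            "members": list(self.window.member_areas),
            "observed": self.window.inside_observed,
            "expected": self.window.inside_expected,
            "llr": self.llr,
            "relative_risk": self.relative_risk,
            "p_value": self.p_value,
        }


def poisson_llr(c: float, e: float, C: float, E: float) -> float:
    """Log likelihood ratio of a high-rate window (0 when not high-rate).

    Expected counts are rescaled so they total C before scoring, making
    the statistic invariant to uniform scaling of the expecteds.
    """
    if not 0 <= c <= C:
        raise DomainError(f"need 0 <= c <= C, got c={c}, C={C}")
    if e <= 0 or e >= E:
        raise DomainError(f"need 0 < e < E, got e={e}, E={E}")
    e = e * C / E  # normalize expected total to C
    inside = c / e
    outside = (C - c) / (C - e)
    if inside <= outside:
        return 0.0
    term_in = c * np.log(c / e) if c > 0 else 0.0
    term_out = (C - c) * np.log((C - c) / (C - e)) if C - c > 0 else 0.0
    return float(term_in + term_out)


def cluster_relative_risk(c: float, e: float, C: float, E: float) -> float:
    """Rate inside the window relative to the rate outside.

    RR = (c/e) / ((C-c)/(C-e)) after rescaling expecteds to total C.
    """
    if not 0 <= c <= C:
        raise DomainError(f"need 0 <= c <= C, got c={c}, C={C}")
    if e <= 0 or e >= E:
        raise DomainError(f"need 0 < e < E, got e={e}, E={E}")
    e = e * C / E
    if c == C:
        warnings.warn("window contains all cases; relative risk is infinite",
                      stacklevel=2)
        return float("inf")
    return float((c / e) / ((C - c) / (C - e)))


def _llr_vector(c: np.ndarray, e: np.ndarray, C: float) -> np.ndarray:
    """Vectorized high-rate LLR; expecteds already normalized to total C."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = c / e
        outside = (C - c) / (C - e)
        term_in = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0) / e), 0.0)
        co = C - c
        term_out = np.where(co > 0, co * np.log(np.where(co > 0, co, 1.0) / (C - e)), 0.0)
        llr = np.where(inside > outside, term_in + term_out, 0.0)
    return llr


def enumerate_windows(
    lattice: AreaLattice,
    table: CountTable,
    max_fraction: float = 0.5,
) -> list[ScanWindow]:
    """All distinct circular windows: distance-ordered prefixes per center,
    capped when inside expected exceeds ``max_fraction`` of the total."""
    idx = _window_index(lattice, _normalized_expected(table), max_fraction)
    expected = _normalized_expected(table)
    observed = table.observed
    out = []
    for center, members in idx:
        members = list(members)
        out.append(
            ScanWindow(
                center_area=lattice.area_ids[center],
                member_areas=[lattice.area_ids[k] for k in members],
                inside_observed=float(observed[members].sum()),
                inside_expected=float(expected[members].sum()),
            )
        )
    return out


def _normalized_expected(table: CountTable) -> np.ndarray:
    if table.expected is None:
        table = compute_expected(table)
    e = np.asarray(table.expected, dtype=float)
    total = e.sum()
    if total <= 0:
        raise DegenerateInputError("expected counts sum to zero")
    return e * table.observed.sum() / total


def _window_index(
    lattice: AreaLattice, expected: np.ndarray, max_fraction: float
) -> list[tuple[int, tuple[int, ...]]]:
    if not 0 < max_fraction <= 1:
        raise DegenerateInputError(
            f"max_fraction must be in (0, 1], got {max_fraction}"
        )
    cent = lattice.require_centroids()
    if np.any(~np.isfinite(cent)):
        bad = lattice.area_ids[int(np.flatnonzero(~np.isfinite(cent).all(axis=1))[0])]
        raise GeometryError(f"non-finite centroid for area {bad!r}")
    n = lattice.n
    cap = max_fraction * expected.sum()
    seen: set[tuple[int, ...]] = set()
    windows: list[tuple[int, tuple[int, ...]]] = []
    for i in range(n):
        d = np.hypot(cent[:, 0] - cent[i, 0], cent[:, 1] - cent[i, 1])
        # stable tie-break on area index keeps enumeration deterministic
        order = np.lexsort((np.arange(n), d))
        e_cum = 0.0
        members: list[int] = []
        for pos, k in enumerate(order):
            e_cum += expected[k]
            members.append(int(k))
            # single-area windows always allowed; larger ones obey the cap
            if pos > 0 and e_cum > cap:
                break
            key = tuple(sorted(members))
            if key not in seen:
                seen.add(key)
                windows.append((i, tuple(members)))
    if not windows:
        raise DegenerateInputError("no window satisfies the expected-count cap")
    return windows


def scan(
    lattice: AreaLattice,
    table: CountTable,
    n_mc: int = 999,
    max_fraction: float = 0.5,
    seed: int | None = None,
    max_reported: int | None = None,
) -> list[ScanCluster]:
    """Most likely cluster plus non-overlapping secondary clusters.

    Monte Carlo replicates redistribute the C observed cases
    multinomially with probabilities E_i / E; each reported cluster's
    p-value is the rank of its LLR among the replicate maxima, divided
    by ``n_mc + 1``.  Deterministic for a fixed seed.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    observed = np.asarray(table.observed, dtype=float)
    C = observed.sum()
    if C <= 0:
        raise DegenerateInputError("no cases observed; nothing to scan")
    expected = _normalized_expected(table)

    win_index = _window_index(lattice, expected, max_fraction)
    usable = [(c, m) for c, m in win_index if expected[list(m)].sum() > 0]
    if not usable:
        raise DegenerateInputError("no window has positive expected count")
    n_win = len(usable)
    member_mat = np.zeros((n_win, lattice.n))
    for r, (_, members) in enumerate(usable):
        member_mat[r, list(members)] = 1.0

    e_w = member_mat @ expected
    c_w = member_mat @ observed
    llr_obs = _llr_vector(c_w, e_w, C)

    rng = np.random.default_rng(seed)
    probs = expected / expected.sum()
    rep_max = np.empty(n_mc)
    # chunk replicates to bound memory on large lattices
    chunk = max(1, int(5e7 // max(n_win, 1) // lattice.n + 1))
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        counts = rng.multinomial(int(C), probs, size=b).astype(float)  # (b, n)
        c_rep = member_mat @ counts.T  # (n_win, b)
        llr_rep = _llr_vector(c_rep, e_w[:, None], C)
        rep_max[done : done + b] = llr_rep.max(axis=0)
        done += b

    order = np.argsort(-llr_obs, kind="stable")
    clusters: list[ScanCluster] = []
    covered: set[int] = set()
    for widx in order:
        if llr_obs[widx] <= 0:
            break
        _, members = usable[widx]
        if covered & set(members):
            continue
        covered.update(members)
        cw = usable[widx]
        window = ScanWindow(
            center_area=lattice.area_ids[cw[0]],
            member_areas=[lattice.area_ids[k] for k in members],
            inside_observed=float(c_w[widx]),
            inside_expected=float(e_w[widx]),
        )
        p = (1 + int((rep_max >= llr_obs[widx]).sum())) / (n_mc + 1)
        rr = cluster_relative_risk(c_w[widx], e_w[widx], C, float(expected.sum()))
        clusters.append(
            ScanCluster(
                window=window,
                llr=float(llr_obs[widx]),
                relative_risk=rr,
                p_value=p,
                rank=len(clusters) + 1,
            )
        )
        if max_reported is not None and len(clusters) >= max_reported:
            break
    return clusters
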