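"""Hierarchical Bayesian Poisson smoothing of areal standardized ratios.

Six model structures over log SR_i = intercept [+ covariate effect]
[+ iid normal heterogeneity U_i] [+ CAR-distributed clustering S_i],
fitted by an adaptive Metropolis-within-Gibbs sampler.  The CAR prior
comes in a Gaussian intrinsic variant (squared neighbor differences)
and a robust L1 variant (absolute differences, double-exponential
kernel).  Priors: flat intercept, wide normal coefficient, Uniform(0,
upper) on standard deviations.  Model comparison by DIC with the
plug-in deviance evaluated at posterior means of the stochastic
parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from arealrisk.areal_core import SpatialWeights
from arealrisk.errors import DegenerateInputError, DomainError
from arealrisk.standardization import CountTable, compute_expected

__all__ = [
    "FitResult",
    "McmcConfig",
    "ModelSpec",
    "PosteriorSummary",
    "car_log_prior",
    "dic",
    "fit",
    "gelman_rubin",
    "log_likelihood",
    "posterior_summary",
    "table3_models",
]


@dataclass
class ModelSpec:
    """Which structural components enter log SR."""

    has_covariate: bool = False
    covariate_free_coefficient: bool = False  # coefficient fixed at 1
    has_unstructured: bool = False
    has_structured: bool = False
    car_variant: str = "l1"  # "l1" | "gaussian_icar"
    prior_sd_upper: float = 100.0
    coefficient_prior_sd: float = 1000.0
    covariate_name: str | None = None
    standardize_covariate: bool = False

    def __post_init__(self) -> None:
        if self.covariate_free_coefficient and not self.has_covariate:
            raise ValueError("covariate_free_coefficient implies has_covariate")
        if self.car_variant not in ("l1", "gaussian_icar"):
            raise ValueError(f"unknown car_variant {self.car_variant!r}")
        if self.prior_sd_upper <= 0 or self.coefficient_prior_sd <= 0:
            raise ValueError("prior scales must be positive")

    @property
    def has_free_coefficient(self) -> bool:
        return self.has_covariate and not self.covariate_free_coefficient


def table3_models(car_variant: str = "l1") -> dict[int, ModelSpec]:
    """The default six-model sweep, keyed 1..6."""
    return {
        1: ModelSpec(has_covariate=True),
        2: ModelSpec(has_covariate=True, covariate_free_coefficient=True),
        3: ModelSpec(has_unstructured=True),
        4: ModelSpec(has_structured=True, car_variant=car_variant),
        5: ModelSpec(has_unstructured=True, has_structured=True,
                     car_variant=car_variant),
        6: ModelSpec(has_covariate=True, has_unstructured=True,
                     has_structured=True, car_variant=car_variant),
    }


@dataclass
class McmcConfig:
    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.35

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class PosteriorSummary:
    name: str
    mean: float
    sd: float
    mc_error: float
    q2_5: float
    q97_5: float


@dataclass
class FitResult:
    summaries: dict[str, PosteriorSummary]
    smoothed_sr: np.ndarray
    smoothed_sr_lower: np.ndarray
    smoothed_sr_upper: np.ndarray
    dbar: float
    dhat: float
    pd: float
    dic: float
    rhat: dict[str, float]
    acceptance_rates: dict[str, float]
    scalar_chains: dict[str, np.ndarray]  # (n_chains, n_retained) per scalar
    n_retained: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Likelihood / prior kernels


def log_likelihood(table: CountTable, params: dict) -> float:
    """Poisson log likelihood with mu_i = E_i * exp(linear predictor).

    ``params`` may hold ``alpha0``, ``beta`` (with ``x``), ``u`` and
    ``s``; absent components default to zero.  Includes the ln O_i!
    normalizing term, so deviance = -2 * log_likelihood is on the same
    scale WinBUGS-style DIC tables use.
    """
    if table.expected is None:
        table = compute_expected(table)
    e = np.asarray(table.expected, dtype=float)
    o = np.asarray(table.observed, dtype=float)
    mask = e > 0
    eta = np.zeros(table.n)
    eta += params.get("alpha0", 0.0)
    if "beta" in params or "x" in params:
        x = np.asarray(params.get("x", np.zeros(table.n)), dtype=float)
        eta += params.get("beta", 0.0) * x
    for key in ("u", "s"):
        if key in params:
            eta += np.asarray(params[key], dtype=float)
    if not np.all(np.isfinite(eta)):
        raise DomainError(f"non-finite linear predictor; params={params}")
    mu = e[mask] * np.exp(eta[mask])
    ll = -mu + o[mask] * np.log(mu) - gammaln(o[mask] + 1)
    # 0 * log 0 convention for empty areas
    ll = np.where((o[mask] == 0) & (mu == 0), -mu, ll)
    return float(ll.sum())


def deviance(table: CountTable, params: dict) -> float:
    return -2.0 * log_likelihood(table, params)


def car_log_prior(s, w: SpatialWeights, sigma: float, variant: str = "gaussian_icar") -> float:
    """Improper CAR kernel (up to a constant; use only as differences).

    gaussian_icar: -(1/(2 sigma^2)) * sum over unordered neighbor pairs
    of (s_i - s_j)^2.  l1: -(1/sigma) * sum of |s_i - s_j|.
    """
    if sigma <= 0:
        raise DomainError(f"sigma must be positive, got {sigma}")
    s = np.asarray(s, dtype=float)
    pos = {a: k for k, a in enumerate(w.ids)}
    total = 0.0
    for i in w.ids:
        si = s[pos[i]]
        for j in w.neighbors[i]:
            if pos[j] > pos[i]:  # each unordered pair once
                d = si - s[pos[j]]
                total += d * d if variant == "gaussian_icar" else abs(d)
    if variant == "gaussian_icar":
        return float(-total / (2.0 * sigma * sigma))
    if variant == "l1":
        return float(-total / sigma)
    raise ValueError(f"unknown CAR variant {variant!r}")


def dic(deviance_samples, dhat: float) -> tuple[float, float, float, float]:
    """(dbar, dhat, pd, dic) from retained deviance draws and the plug-in
    deviance at posterior means."""
    samples = np.asarray(deviance_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("deviance_samples must be non-empty")
    dbar = float(samples.mean())
    pd_ = dbar - dhat
    return dbar, float(dhat), pd_, dbar + pd_


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains (set n_chains >= 2)")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful PSRF")
    means = arr.mean(axis=1)
    within = float(arr.var(axis=1, ddof=1).mean())
    between_over_n = float(means.var(ddof=1))
    if within == 0:
        if between_over_n == 0:
            warnings.warn("constant identical chains; PSRF defined as 1.0",
                          stacklevel=2)
            return 1.0
        warnings.warn("zero within-chain variance with distinct chains",
                      stacklevel=2)
        return float("inf")
    var_hat = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_hat / within))


def posterior_summary(samples, name: str = "param") -> PosteriorSummary:
    """Mean, SD, batch-means MC error and central 95% interval."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample vector")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    mc = _batch_means_se(x)
    q_lo, q_hi = np.percentile(x, [2.5, 97.5])
    return PosteriorSummary(name, mean, sd, mc, float(q_lo), float(q_hi))


def _batch_means_se(x: np.ndarray, min_batches: int = 20) -> float:
    n = x.size
    if n < 2:
        return 0.0
    k = max(min_batches, int(np.floor(np.sqrt(n))))
    k = min(k, n)
    m = n // k
    if m < 1:
        return float(x.std(ddof=1) / np.sqrt(n))
    trimmed = x[: m * k].reshape(k, m)
    bm = trimmed.mean(axis=1)
    if k < 2:
        return float(x.std(ddof=1) / np.sqrt(n))
    return float(bm.std(ddof=1) / np.sqrt(k))


# ---------------------------------------------------------------------------
# Sampler


class _Adapter:
    """Scales random-walk step sizes toward a target acceptance rate
    during burn-in only (frozen afterwards to keep detailed balance)."""

    def __init__(self, step, target: float):
        self.step = np.asarray(step, dtype=float)
        self.scalar = self.step.ndim == 0
        self.accept = np.zeros_like(self.step, dtype=float)
        self.tries = 0
        self.target = target

    def record(self, accepted) -> None:
        self.accept = self.accept + accepted
        self.tries += 1

    def adapt(self) -> None:
        if self.tries == 0:
            return
        rate = self.accept / self.tries
        self.step = self.step * np.exp(np.clip(rate - self.target, -0.5, 0.5))
        self.accept = np.zeros_like(self.accept)
        self.tries = 0


def _car_rank(w: SpatialWeights) -> int:
    """Rank of the CAR precision = n minus number of connected components."""
    pos = {a: k for k, a in enumerate(w.ids)}
    rows, cols = [], []
    for i in w.ids:
        for j in w.neighbors[i]:
            rows.append(pos[i])
            cols.append(pos[j])
    n = w.n
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return n - ncomp


def fit(
    table: CountTable,
    w: SpatialWeights | None,
    spec: ModelSpec,
    cfg: McmcConfig,
) -> FitResult:
    """Fit one model by adaptive Metropolis-within-Gibbs.

    Runs ``cfg.n_chains`` chains from dispersed starts; retains
    post-burn-in, thinned draws; returns posterior summaries, smoothed
    SRs with 95% bounds, DIC components, per-parameter PSRFs and
    per-block acceptance rates.  Identical seed gives identical output.
    """
    if table.expected is None:
        table = compute_expected(table)
    e = np.asarray(table.expected, dtype=float)
    o = np.asarray(table.observed, dtype=float)
    n = table.n
    if np.any(e <= 0):
        raise DegenerateInputError(
            "areas with zero expected count present; filter them before fitting"
        )
    log_e = np.log(e)

    x = np.zeros(n)
    if spec.has_covariate:
        if not table.covariates:
            raise DegenerateInputError("model needs a covariate but table has none")
        name = spec.covariate_name or next(iter(table.covariates))
        x = np.asarray(table.covariates[name], dtype=float).copy()
        if spec.standardize_covariate:
            x = (x - x.mean()) / x.std(ddof=0)

    fit_warnings: list[str] = []
    nbrs: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    islands = np.zeros(n, dtype=bool)
    car_rank = 0
    if spec.has_structured:
        if w is None:
            raise DegenerateInputError("structured component requires weights")
        if w.style != "binary":
            raise DomainError("CAR prior requires binary symmetric weights")
        pos = {a: k for k, a in enumerate(w.ids)}
        nbrs = [np.array([pos[j] for j in w.neighbors[i]], dtype=int) for i in w.ids]
        islands = np.array([len(a) == 0 for a in nbrs])
        if islands.any():
            isl_ids = [w.ids[k] for k in np.flatnonzero(islands)]
            msg = f"islands held at S=0 under the CAR prior: {isl_ids}"
            warnings.warn(msg, stacklevel=2)
            fit_warnings.append(msg)
        car_rank = _car_rank(w)
    gaussian_car = spec.car_variant == "gaussian_icar"

    if np.ptp(o) == 0 and np.ptp(e) == 0:
        fit_warnings.append("no variation in the data; posterior driven by priors")

    n_retained = (cfg.n_iter - cfg.burn_in) // cfg.thin
    scalar_names = ["alpha0"]
    if spec.has_free_coefficient:
        scalar_names.append("beta")
    if spec.has_unstructured:
        scalar_names.append("delta")
    if spec.has_structured:
        scalar_names.append("sigma")

    scalar_chains = {p: np.empty((cfg.n_chains, n_retained)) for p in scalar_names}
    dev_chains = np.empty((cfg.n_chains, n_retained))
    sr_sum = np.zeros(n)
    sr_draws = np.empty((cfg.n_chains * n_retained, n))
    parent_sums = {"alpha0": 0.0, "beta": 0.0,
                   "u": np.zeros(n), "s": np.zeros(n)}
    accept_totals: dict[str, list[float]] = {}

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    gammaln_o = gammaln(o + 1)

    def area_loglik(eta: np.ndarray) -> np.ndarray:
        mu = e * np.exp(eta)
        return -mu + o * (log_e + eta) - gammaln_o

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[chain])
        # dispersed starts
        alpha0 = float(np.log(o.sum() / e.sum())) + rng.normal(0, 0.5)
        beta = rng.normal(0, 0.5) if spec.has_free_coefficient else (
            1.0 if spec.covariate_free_coefficient else 0.0
        )
        u = rng.normal(0, 0.1, n) if spec.has_unstructured else np.zeros(n)
        s = np.zeros(n)
        if spec.has_structured:
            s = rng.normal(0, 0.1, n)
            s[islands] = 0.0
            s -= s[~islands].mean() if (~islands).any() else 0.0
        delta = float(rng.uniform(0.2, 2.0))
        sigma = float(rng.uniform(0.2, 2.0))

        ad_alpha = _Adapter(0.1, cfg.target_accept)
        ad_beta = _Adapter(0.1, cfg.target_accept)
        ad_u = _Adapter(np.full(n, 0.3), cfg.target_accept)
        ad_s = _Adapter(np.full(n, 0.3), cfg.target_accept)
        ad_delta = _Adapter(0.3, cfg.target_accept)
        ad_sigma = _Adapter(0.3, cfg.target_accept)

        fixed_offset = x if spec.covariate_free_coefficient else None

        def linear_predictor() -> np.ndarray:
            eta = alpha0 + u + s
            if spec.has_free_coefficient:
                eta = eta + beta * x
            elif fixed_offset is not None:
                eta = eta + fixed_offset
            return eta

        eta = linear_predictor()
        ll_area = area_loglik(eta)
        kept = 0
        for it in range(cfg.n_iter):
            in_burn = it < cfg.burn_in

            # intercept (flat prior)
            prop = alpha0 + rng.normal(0, ad_alpha.step)
            new_eta = eta + (prop - alpha0)
            new_ll = area_loglik(new_eta)
            acc = np.log(rng.uniform()) < new_ll.sum() - ll_area.sum()
            if acc:
                alpha0, eta, ll_area = float(prop), new_eta, new_ll
            ad_alpha.record(float(acc))

            # coefficient (normal prior)
            if spec.has_free_coefficient:
                prop = beta + rng.normal(0, ad_beta.step)
                new_eta = eta + (prop - beta) * x
                new_ll = area_loglik(new_eta)
                dprior = (beta**2 - prop**2) / (2 * spec.coefficient_prior_sd**2)
                acc = np.log(rng.uniform()) < new_ll.sum() - ll_area.sum() + dprior
                if acc:
                    beta, eta, ll_area = float(prop), new_eta, new_ll
                ad_beta.record(float(acc))

            # unstructured effects: conditionally independent, vector update
            if spec.has_unstructured:
                prop_u = u + rng.normal(0, 1, n) * ad_u.step
                new_eta = eta + (prop_u - u)
                new_ll = area_loglik(new_eta)
                dprior = (u**2 - prop_u**2) / (2 * delta**2)
                accept = np.log(rng.uniform(size=n)) < new_ll - ll_area + dprior
                u = np.where(accept, prop_u, u)
                eta = np.where(accept, new_eta, eta)
                ll_area = np.where(accept, new_ll, ll_area)
                ad_u.record(accept.astype(float))

                # delta: uniform(0, upper) prior on the SD scale
                prop = delta + rng.normal(0, ad_delta.step)
                if 0 < prop < spec.prior_sd_upper:
                    dlp = (-n * np.log(prop) - (u**2).sum() / (2 * prop**2)) - (
                        -n * np.log(delta) - (u**2).sum() / (2 * delta**2)
                    )
                    acc = np.log(rng.uniform()) < dlp
                    if acc:
                        delta = float(prop)
                else:
                    acc = False
                ad_delta.record(float(acc))

            # structured effects: single-site sweep (conditionals overlap)
            if spec.has_structured:
                steps = ad_s.step
                noise = rng.normal(0, 1, n)
                logu = np.log(rng.uniform(size=n))
                acc_vec = np.zeros(n)
                inv_two_sig2 = 1.0 / (2 * sigma * sigma)
                inv_sig = 1.0 / sigma
                for i in range(n):
                    if islands[i]:
                        continue
                    si = s[i]
                    prop = si + noise[i] * steps[i]
                    sj = s[nbrs[i]]
                    if gaussian_car:
                        dprior = -inv_two_sig2 * (
                            ((prop - sj) ** 2).sum() - ((si - sj) ** 2).sum()
                        )
                    else:
                        dprior = -inv_sig * (
                            np.abs(prop - sj).sum() - np.abs(si - sj).sum()
                        )
                    deta = prop - si
                    mu_new = e[i] * np.exp(eta[i] + deta)
                    ll_new = -mu_new + o[i] * (log_e[i] + eta[i] + deta) - gammaln_o[i]
                    if logu[i] < ll_new - ll_area[i] + dprior:
                        s[i] = prop
                        eta[i] += deta
                        ll_area[i] = ll_new
                        acc_vec[i] = 1.0
                ad_s.record(acc_vec)

                # sum-to-zero recentring keeps the intercept identified; the
                # joint move (s - c, alpha0 + c) leaves the likelihood and
                # the improper CAR kernel unchanged, so eta is untouched.
                # skipped when islands exist (their fixed S=0 would shift).
                if not islands.any():
                    shift = s.mean()
                    s = s - shift
                    alpha0 += shift

                # sigma: uniform(0, upper) prior on the scale
                prop = sigma + rng.normal(0, ad_sigma.step)
                if 0 < prop < spec.prior_sd_upper:
                    if gaussian_car:
                        ss = 0.0
                        for i in range(n):
                            sj = s[nbrs[i]]
                            ss += ((s[i] - sj) ** 2).sum()
                        ss *= 0.5  # each unordered pair counted once
                        dlp = (-car_rank * np.log(prop) - ss / (2 * prop**2)) - (
                            -car_rank * np.log(sigma) - ss / (2 * sigma**2)
                        )
                    else:
                        sa = 0.0
                        for i in range(n):
                            sj = s[nbrs[i]]
                            sa += np.abs(s[i] - sj).sum()
                        sa *= 0.5
                        dlp = (-car_rank * np.log(prop) - sa / prop) - (
                            -car_rank * np.log(sigma) - sa / sigma
                        )
                    acc = np.log(rng.uniform()) < dlp
                    if acc:
                        sigma = float(prop)
                else:
                    acc = False
                ad_sigma.record(float(acc))

            if in_burn and (it + 1) % cfg.adapt_interval == 0:
                for ad in (ad_alpha, ad_beta, ad_u, ad_s, ad_delta, ad_sigma):
                    ad.adapt()

            if not in_burn and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_retained:
                scalar_chains["alpha0"][chain, kept] = alpha0
                if spec.has_free_coefficient:
                    scalar_chains["beta"][chain, kept] = beta
                if spec.has_unstructured:
                    scalar_chains["delta"][chain, kept] = delta
                if spec.has_structured:
                    scalar_chains["sigma"][chain, kept] = sigma
                dev_chains[chain, kept] = -2.0 * ll_area.sum()
                sr = np.exp(eta)
                sr_sum += sr
                sr_draws[chain * n_retained + kept] = sr
                parent_sums["alpha0"] += alpha0
                parent_sums["beta"] += beta
                parent_sums["u"] += u
                parent_sums["s"] += s
                kept += 1

        for label, ad in (
            ("alpha0", ad_alpha),
            ("beta", ad_beta),
            ("u", ad_u),
            ("s", ad_s),
            ("delta", ad_delta),
            ("sigma", ad_sigma),
        ):
            if ad.tries:
                accept_totals.setdefault(label, []).append(
                    float(np.mean(ad.accept) / ad.tries)
                )

    total_kept = cfg.n_chains * n_retained
    for key in parent_sums:
        parent_sums[key] = parent_sums[key] / total_kept

    # plug-in deviance at posterior means of the stochastic parents
    eta_hat = parent_sums["alpha0"] + parent_sums["u"] + parent_sums["s"]
    if spec.has_free_coefficient:
        eta_hat = eta_hat + parent_sums["beta"] * x
    elif spec.covariate_free_coefficient:
        eta_hat = eta_hat + x
    mu_hat = e * np.exp(eta_hat)
    dhat = float(-2.0 * (-mu_hat + o * np.log(mu_hat) - gammaln_o).sum())
    dbar, dhat, pd_, dic_ = dic(dev_chains.ravel(), dhat)

    summaries: dict[str, PosteriorSummary] = {}
    rhat: dict[str, float] = {}
    for pname, ch in scalar_chains.items():
        report = pname
        samples = ch.ravel()
        if pname in ("delta", "sigma"):
            # report the variance, Table-4 style, alongside the SD draws
            summaries[f"{pname}_sd"] = posterior_summary(samples, f"{pname}_sd")
            summaries[f"{pname}_var"] = posterior_summary(samples**2, f"{pname}_var")
        else:
            summaries[report] = posterior_summary(samples, report)
        if cfg.n_chains >= 2:
            rhat[pname] = gelman_rubin(ch)
    rhat["deviance"] = gelman_rubin(dev_chains) if cfg.n_chains >= 2 else float("nan")
    summaries["deviance"] = posterior_summary(dev_chains.ravel(), "deviance")

    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        msg = f"Gelman-Rubin above 1.1 for {sorted(bad)}; consider longer chains"
        warnings.warn(msg, stacklevel=2)
        fit_warnings.append(msg)

    sr_mean = sr_sum / total_kept
    sr_lo, sr_hi = np.percentile(sr_draws, [2.5, 97.5], axis=0)

    acceptance = {
        k: float(np.mean(v)) for k, v in accept_totals.items() if len(v)
    }

    return FitResult(
        summaries=summaries,
        smoothed_sr=sr_mean,
        smoothed_sr_lower=sr_lo,
        smoothed_sr_upper=sr_hi,
        dbar=dbar,
        dhat=dhat,
        pd=pd_,
        dic=dic_,
        rhat=rhat,
        acceptance_rates=acceptance,
        scalar_chains=scalar_chains,
        n_retained=n_retained,
        warnings=fit_warnings,
    )
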