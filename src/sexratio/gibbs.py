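"""Gibbs sampler for the day-specific sex-of-baby model.

Posterior simulation uses Poisson latent-count augmentation.  Introduce
independent W_ik ~ Poisson(lam_k xi_i X_ik); the cycle produces a male
exactly when sum_k W_ik >= 1, so conditioning on the observed sexes gives
the aggregated Bernoulli likelihood.  The sampler alternates exact
conditional draws:

1. latent counts   — W = 0 for female cycles; for male cycles the total is
   a >=1-truncated Poisson (inverse-CDF, exact) allocated over intercourse
   days by a multinomial with weights lam_k X_ik;
2. lambda update   — conditionally conjugate:
   lam_k | . ~ Gamma(a0k + sum_i W_ik, b0k + sum_i X_ik xi_i);
3. gamma update    — for each h, the one-inflated gamma prior yields an
   exact two-state mixture: a point mass at 1 with posterior weight
   computed in log space, else Gamma(a0h + A_h, b0h + B_h) with
   A_h = sum_{i: z_i > h} sum_k W_ik and
   B_h = sum_{i: z_i > h} sum_k X_ik lam_k prod_{h' < z_i, h' != h} gam_h'.

Scan order is fixed (latents, lam_1..lam_12, gam_1..gam_3); all moves are
exact conditional draws, so no acceptance bookkeeping is needed.  A
brute-force quadrature of the un-augmented posterior on low-dimensional
instances serves as the correctness oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as gamma_dist, poisson

from .data import CycleDataset, N_DAYS, RELATIVE_DAYS, ValidationError
from .model import ModelParameters, PriorSpec, N_GAMMA

logger = logging.getLogger("sexratio")

__all__ = [
    "LatentCounts",
    "MCMCConfig",
    "PosteriorSamples",
    "LAMBDA_NAMES",
    "GAMMA_NAMES",
    "PARAMETER_NAMES",
    "sample_truncated_poisson",
    "sample_latent_counts",
    "update_lambda",
    "update_gamma",
    "run_chain",
    "brute_force_posterior",
]

LAMBDA_NAMES = tuple(f"lambda_{d}" for d in RELATIVE_DAYS)
GAMMA_NAMES = tuple(f"gamma_{h}" for h in (1, 2, 3))
PARAMETER_NAMES = LAMBDA_NAMES + GAMMA_NAMES


@dataclass(frozen=True)
class LatentCounts:
    """Per-cycle, per-day Poisson latent counts W_ik (n x 12)."""

    W: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.int64)
        if W.ndim != 2 or W.shape[1] != N_DAYS or np.any(W < 0):
            raise ValidationError("W must be a non-negative n x 12 integer matrix")
        W.flags.writeable = False
        object.__setattr__(self, "W", W)

    def consistent_with(self, y) -> bool:
        """True iff counts are all-zero exactly for female cycles."""
        totals = self.W.sum(axis=1)
        y = np.asarray(y)
        return bool(np.all((totals == 0) == (y == 1)))


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 5000
    iterations: int = 40000
    chains: int = 2
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.burn_in < 0 or self.iterations <= 0:
            raise ValidationError("burn_in must be >= 0 and iterations > 0")
        if self.chains < 1 or self.thin < 1:
            raise ValidationError("chains and thin must be >= 1")
        if self.iterations // self.thin < 1:
            raise ValidationError("thin exceeds the number of retained iterations")


@dataclass(frozen=True)
class PosteriorSamples:
    """Retained draws: lam (chains, kept, 12) and gam (chains, kept, 3) or None."""

    lam: np.ndarray
    gam: np.ndarray | None
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return self.lam.shape[0]

    @property
    def n_kept(self) -> int:
        return self.lam.shape[1]

    @property
    def parameter_names(self) -> tuple:
        return LAMBDA_NAMES + (GAMMA_NAMES if self.gam is not None else ())

    def chain(self, name: str, c: int) -> np.ndarray:
        """Draws of one parameter from chain index c (0-based)."""
        if name in LAMBDA_NAMES:
            return self.lam[c, :, LAMBDA_NAMES.index(name)]
        if self.gam is not None and name in GAMMA_NAMES:
            return self.gam[c, :, GAMMA_NAMES.index(name)]
        raise KeyError(name)

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return np.concatenate([self.chain(name, c) for c in range(self.n_chains)])

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain (1-based), iteration (1-based, post-thin), parameter, value."""
        rows = []
        for c in range(self.n_chains):
            for j, name in enumerate(LAMBDA_NAMES):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c + 1,
                            "iteration": np.arange(1, self.n_kept + 1),
                            "parameter": name,
                            "value": self.lam[c, :, j],
                        }
                    )
                )
            if self.gam is not None:
                for j, name in enumerate(GAMMA_NAMES):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c + 1,
                                "iteration": np.arange(1, self.n_kept + 1),
                                "parameter": name,
                                "value": self.gam[c, :, j],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: MCMCConfig | None = None):
        chains = sorted(df["chain"].unique())
        kept = df["iteration"].max()
        has_gamma = any(name in set(df["parameter"]) for name in GAMMA_NAMES)
        lam = np.empty((len(chains), int(kept), N_DAYS))
        gam = np.empty((len(chains), int(kept), N_GAMMA)) if has_gamma else None
        for ci, c in enumerate(chains):
            sub = df[df["chain"] == c]
            for j, name in enumerate(LAMBDA_NAMES):
                vals = sub[sub["parameter"] == name].sort_values("iteration")["value"]
                lam[ci, :, j] = vals.to_numpy()
            if has_gamma:
                for j, name in enumerate(GAMMA_NAMES):
                    vals = sub[sub["parameter"] == name].sort_values("iteration")["value"]
                    gam[ci, :, j] = vals.to_numpy()
        if config is None:
            config = MCMCConfig(burn_in=0, iterations=int(kept), chains=len(chains))
        return cls(lam=lam, gam=gam, config=config)


# -- elementary draws --------------------------------------------------


def sample_truncated_poisson(rate, rng: np.random.Generator):
    """Poisson draw(s) conditioned on being >= 1, by exact inverse CDF.

    P(N = n) = e^-r r^n / (n! (1 - e^-r)) for n >= 1.  Accepts a scalar or
    an array of rates; returns the matching shape.
    """
    r = np.asarray(rate, dtype=float)
    if r.size == 0:
        return np.zeros(r.shape, dtype=np.int64)
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise ValidationError("truncated-Poisson rate must be positive and finite")
    scalar = np.isscalar(rate) or np.asarray(rate).shape == ()
    r = np.atleast_1d(r)
    u = rng.random(r.shape)
    draws = np.ones(r.shape, dtype=np.int64)
    # Inverse CDF of the >=1-truncated law by pmf recursion
    # pmf(1) = r / (e^r - 1), pmf(n+1) = pmf(n) * r / (n+1); exact and loop-free
    # in the rate (the recursion depth is bounded by the quantile, not the rate).
    small = r <= 30.0
    if small.any():
        rs, us = r[small], u[small]
        pmf = rs / np.expm1(rs)
        cum = pmf.copy()
        n_small = np.ones(rs.shape, dtype=np.int64)
        mask = us > cum
        k, cap = 1, 400
        while mask.any() and k < cap:
            k += 1
            pmf = pmf * (rs / k)
            cum = cum + pmf
            n_small[mask] = k
            mask = us > cum
        if mask.any():  # u astronomically deep in the tail: finish via ppf
            f0 = np.exp(-rs[mask])
            target = f0 + us[mask] * (1.0 - f0)
            n_small[mask] = np.maximum(
                poisson.ppf(np.minimum(target, 1.0 - 1e-16), rs[mask]), 1
            ).astype(np.int64)
        draws[small] = n_small
    big = ~small
    if big.any():
        f0 = np.exp(-r[big])
        target = f0 + u[big] * (1.0 - f0)
        draws[big] = np.maximum(
            poisson.ppf(np.minimum(target, 1.0 - 1e-16), r[big]), 1
        ).astype(np.int64)
    if scalar:
        return int(draws[0])
    return draws


def _allocate_counts(totals, weights, rng: np.random.Generator) -> np.ndarray:
    """Multinomial split of per-row totals across days, weights prop. to cols.

    Drawn as a chain of conditional binomials (exactly a multinomial draw),
    vectorised over rows.
    """
    totals = np.asarray(totals, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    m, K = weights.shape
    # suffix[:, k] = weights[:, k] + suffix[:, k+1], so the last non-zero
    # weight of a row gets probability exactly 1 and nothing is lost.
    suffix = np.cumsum(weights[:, ::-1], axis=1)[:, ::-1]
    W = np.zeros((m, K), dtype=np.int64)
    remaining = totals.copy()
    for k in range(K):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(suffix[:, k] > 0, weights[:, k] / suffix[:, k], 0.0)
        p = np.clip(p, 0.0, 1.0)
        draw = rng.binomial(remaining, p)
        W[:, k] = draw
        remaining -= draw
    return W


def _xi_from(gam, z):
    cum = np.concatenate([[1.0], np.cumprod(gam)])
    return cum[np.asarray(z, dtype=np.int64) - 1]


def _sample_latent(lam, gam, X, y, z, rng) -> np.ndarray:
    n = X.shape[0]
    W = np.zeros((n, N_DAYS), dtype=np.int64)
    male = np.where(np.asarray(y) == 0)[0]
    if male.size == 0:
        return W
    xi = _xi_from(gam, z)[male]
    Xm = np.asarray(X, dtype=float)[male]
    weights = Xm * lam  # allocation weights; xi cancels across days
    s = weights.sum(axis=1)
    eta = xi * s
    if np.any(eta <= 0):
        raise ValidationError("male cycle with zero conception hazard (no intercourse?)")
    totals = sample_truncated_poisson(eta, rng)
    W[male] = _allocate_counts(totals, weights, rng)
    return W


def sample_latent_counts(
    params: ModelParameters, data: CycleDataset, rng: np.random.Generator,
    covariate: bool = True,
) -> LatentCounts:
    """Draw the latent Poisson counts given parameters and observed sexes."""
    X, y, z, _ = data.to_arrays(covariate=covariate)
    return LatentCounts(W=_sample_latent(params.lam, params.gam, X, y, z, rng))


def _update_lambda(W, X, xi, priors: PriorSpec, rng) -> np.ndarray:
    shape = priors.a0k + W.sum(axis=0)
    rate = priors.b0k + (np.asarray(X, dtype=float) * xi[:, None]).sum(axis=0)
    return rng.gamma(shape, 1.0 / rate)


def update_lambda(
    latent: LatentCounts, params: ModelParameters, data: CycleDataset,
    priors: PriorSpec, rng: np.random.Generator, covariate: bool = True,
) -> np.ndarray:
    """Conjugate gamma full-conditional draw of the 12 lam parameters."""
    X, _, z, _ = data.to_arrays(covariate=covariate)
    return _update_lambda(latent.W, X, _xi_from(params.gam, z), priors, rng)


def _log_pointmass_prob(A, B, pi, a0, b0) -> float:
    """log posterior probability of the point-mass state gamma_h = 1.

    Mixture weight pi e^-B vs (1-pi) b0^a0/Gamma(a0) * Gamma(a0+A)/(b0+B)^(a0+A),
    evaluated entirely in log space so it is stable for A up to ~1e4+.
    """
    if pi >= 1.0:
        return 0.0
    if pi <= 0.0:
        return -np.inf
    log_w1 = np.log(pi) - B
    log_w0 = (
        np.log1p(-pi)
        + a0 * np.log(b0)
        - gammaln(a0)
        + gammaln(a0 + A)
        - (a0 + A) * np.log(b0 + B)
    )
    return float(log_w1 - np.logaddexp(log_w1, log_w0))


def pointmass_probability(A, B, pi, a0, b0) -> float:
    """Posterior probability that gamma_h sits at the point mass, given
    sufficient statistics A (latent-count sum) and B (exposure sum)."""
    return float(np.exp(_log_pointmass_prob(float(A), float(B), pi, a0, b0)))


def _update_gamma(W, X, z, lam, gam, priors: PriorSpec, rng) -> np.ndarray:
    gam = np.array(gam, dtype=float)
    s = np.asarray(X, dtype=float) @ lam
    row_counts = W.sum(axis=1)
    for h in range(N_GAMMA):  # systematic scan gamma_1, gamma_2, gamma_3
        mask = z > (h + 1)
        A = float(row_counts[mask].sum())
        if mask.any():
            xi_minus = _xi_from(gam, z[mask]) / gam[h]
            B = float((s[mask] * xi_minus).sum())
        else:
            B = 0.0
        p1 = np.exp(_log_pointmass_prob(A, B, priors.pi_h[h], priors.a0h[h], priors.b0h[h]))
        if rng.random() < p1:
            gam[h] = 1.0
        else:
            gam[h] = rng.gamma(priors.a0h[h] + A, 1.0 / (priors.b0h[h] + B))
    return gam


def update_gamma(
    latent: LatentCounts, params: ModelParameters, data: CycleDataset,
    priors: PriorSpec, rng: np.random.Generator,
) -> np.ndarray:
    """Exact one-inflated-gamma full-conditional scan over the 3 gam parameters."""
    X, _, z, _ = data.to_arrays(covariate=True)
    return _update_gamma(latent.W, X, z, params.lam, params.gam, priors, rng)


def _gibbs_sweep(lam, gam, X, y, z, priors, rng, covariate=True):
    """One full scan: latents -> lam -> gam.  Returns (lam, gam, W)."""
    W = _sample_latent(lam, gam, X, y, z, rng)
    lam = _update_lambda(W, X, _xi_from(gam, z), priors, rng)
    if covariate:
        gam = _update_gamma(W, X, z, lam, gam, priors, rng)
    return lam, gam, W


def run_chain(
    data: CycleDataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    covariate: bool = True,
    log_every: int = 1000,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return retained, thinned draws.

    Each chain uses an independent PCG64 generator seeded ``seed + chain``;
    lam starts at prior draws and gam at 1 (inside the point-mass state).
    With ``covariate`` off, gam is pinned at 1 and omitted from the output.
    """
    priors = priors or PriorSpec.default()
    config = config or MCMCConfig()
    X, y, z, _ = data.to_arrays(covariate=covariate)
    X = np.asarray(X, dtype=float)
    n_kept = config.iterations // config.thin
    lam_out = np.empty((config.chains, n_kept, N_DAYS))
    gam_out = np.empty((config.chains, n_kept, N_GAMMA)) if covariate else None
    total = config.burn_in + config.iterations
    for c in range(config.chains):
        rng = np.random.Generator(np.random.PCG64(config.seed + c))
        lam = rng.gamma(priors.a0k, 1.0 / priors.b0k)
        gam = np.ones(N_GAMMA)
        kept = 0
        for it in range(total):
            lam, gam, _ = _gibbs_sweep(lam, gam, X, y, z, priors, rng, covariate)
            post = it - config.burn_in
            if post >= 0 and (post + 1) % config.thin == 0:
                lam_out[c, kept] = lam
                if covariate:
                    gam_out[c, kept] = gam
                kept += 1
            if log_every and (it + 1) % log_every == 0:
                logger.info("chain %d: iteration %d/%d", c + 1, it + 1, total)
        assert kept == n_kept
    return PosteriorSamples(lam=lam_out, gam=gam_out, config=config)


# -- brute-force quadrature oracle ------------------------------------


def brute_force_posterior(
    data: CycleDataset, priors: PriorSpec | None = None, n_grid: int = 200
) -> dict:
    """Numerical posterior for low-dimensional instances, without augmentation.

    Integrates prior x likelihood (closed-form survival likelihood) over a
    midpoint grid in prior-quantile space — one dimension per "active" day
    (a day with any intercourse) and per "active" gam (a class step some
    cycle crosses) — with point-mass atoms handled by enumerating which
    active gam's sit at 1.  Refuses more than 3 continuous dimensions.
    The prior-quantile transform makes each 1-D integral an expectation of a
    smooth bounded integrand, so the midpoint rule converges as the grid is
    refined; the remaining error is O(m^-2) in the points-per-dimension m.

    Returns a dict with posterior ``lam_mean``, ``lam_sd``, ``gam_mean``,
    ``p_gamma_eq_1`` (prior values for inactive parameters) and the grid spec.
    """
    priors = priors or PriorSpec.default()
    if data.n:
        X, y, z, _ = data.to_arrays(covariate=True)
    else:
        X = np.zeros((0, N_DAYS), dtype=np.int8)
        y = np.zeros(0, dtype=np.int8)
        z = np.zeros(0, dtype=np.int64)
    active_days = [k for k in range(N_DAYS) if X[:, k].any()]
    active_gammas = [h for h in range(N_GAMMA) if np.any(z > h + 1)]
    dim = len(active_days) + len(active_gammas)
    if dim > 3:
        raise ValidationError(
            f"brute_force_posterior supports <= 3 continuous dimensions, got {dim}"
        )

    # prior means / sds as the starting point (exact for inactive parameters)
    lam_mean = priors.a0k / priors.b0k
    lam_sd = np.sqrt(priors.a0k) / priors.b0k
    prior_gam_mean = (
        priors.pi_h * 1.0 + (1 - priors.pi_h) * priors.a0h / priors.b0h
    )
    gam_mean = prior_gam_mean.copy()
    p_eq_1 = priors.pi_h.copy()
    if data.n == 0:
        return {
            "lam_mean": lam_mean, "lam_sd": lam_sd, "gam_mean": gam_mean,
            "p_gamma_eq_1": p_eq_1, "n_grid": n_grid, "active_days": active_days,
            "active_gammas": active_gammas,
        }

    # group cycles by (pattern over active days, z, y)
    groups: dict = {}
    for i in range(X.shape[0]):
        key = (tuple(int(X[i, k]) for k in active_days), int(z[i]), int(y[i]))
        groups[key] = groups.get(key, 0) + 1

    u = (np.arange(n_grid) + 0.5) / n_grid
    lam_grids = {
        k: gamma_dist.ppf(u, priors.a0k[k], scale=1.0 / priors.b0k[k]) for k in active_days
    }
    gam_grids = {
        h: gamma_dist.ppf(u, priors.a0h[h], scale=1.0 / priors.b0h[h]) for h in active_gammas
    }

    def branch_loglik(lam_vals, gam_vals):
        """Summed log likelihood over grouped cycles on broadcast grids."""
        total = 0.0
        for (patt, zi, yi), count in groups.items():
            s = 0.0
            for k, xk in zip(active_days, patt):
                if xk:
                    s = s + lam_vals[k]
            xi = 1.0
            for h in active_gammas:
                if zi > h + 1:
                    xi = xi * gam_vals.get(h, 1.0)  # atom branch: gamma_h = 1
            a = xi * s
            term = -a if yi == 1 else np.log(-np.expm1(-a))
            total = total + count * term
        return total

    # enumerate which active gammas are continuous (subset S) vs at the atom
    branch_logZ = []
    branch_stats = []  # (S, E[lam_k] numerators, E[gam_h] numerators)
    for r in range(len(active_gammas) + 1):
        for S in combinations(active_gammas, r):
            log_w = 0.0
            for h in active_gammas:
                log_w += np.log1p(-priors.pi_h[h]) if h in S else np.log(priors.pi_h[h])
            cont_dims = active_days + list(S)
            grids = [lam_grids[k] for k in active_days] + [gam_grids[h] for h in S]
            mesh = np.meshgrid(*grids, indexing="ij") if grids else []
            lam_vals = {k: mesh[j] for j, k in enumerate(active_days)}
            gam_vals = {h: mesh[len(active_days) + j] for j, h in enumerate(S)}
            ll = branch_loglik(lam_vals, gam_vals)
            ll = np.asarray(ll, dtype=float)
            logZ = log_w + logsumexp(ll) - dim_log(n_grid, len(cont_dims))
            lam_num = {}
            for k in active_days:
                lam_num[k] = (
                    log_w
                    + logsumexp(ll, b=lam_vals[k])
                    - dim_log(n_grid, len(cont_dims))
                )
            gam_num = {}
            for h in active_gammas:
                vals = gam_vals.get(h, None)
                if vals is None:
                    gam_num[h] = logZ  # gamma_h = 1 on this branch
                else:
                    gam_num[h] = (
                        log_w + logsumexp(ll, b=vals) - dim_log(n_grid, len(cont_dims))
                    )
            lam_sq = {
                k: log_w + logsumexp(ll, b=lam_vals[k] ** 2) - dim_log(n_grid, len(cont_dims))
                for k in active_days
            }
            branch_logZ.append(logZ)
            branch_stats.append((S, lam_num, gam_num, lam_sq))

    logZ_total = logsumexp(branch_logZ)
    for k in active_days:
        num = logsumexp([st[1][k] for st in branch_stats])
        sq = logsumexp([st[3][k] for st in branch_stats])
        lam_mean[k] = np.exp(num - logZ_total)
        lam_sd[k] = np.sqrt(max(np.exp(sq - logZ_total) - lam_mean[k] ** 2, 0.0))
    for h in active_gammas:
        num = logsumexp([st[2][h] for st in branch_stats])
        gam_mean[h] = np.exp(num - logZ_total)
        atom_branches = [
            lz for lz, st in zip(branch_logZ, branch_stats) if h not in st[0]
        ]
        p_eq_1[h] = np.exp(logsumexp(atom_branches) - logZ_total)
    return {
        "lam_mean": lam_mean, "lam_sd": lam_sd, "gam_mean": gam_mean,
        "p_gamma_eq_1": p_eq_1, "n_grid": n_grid, "active_days": active_days,
        "active_gammas": active_gammas,
    }


def dim_log(m: int, d: int) -> float:
    """log(m^d): normaliser of the midpoint rule in d quantile dimensions."""
    return d * np.log(m)
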