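"""Posterior summaries and MCMC convergence diagnostics.

Summaries pool post-burn-in draws across chains: mean, median, SD, 95%
equal-tailed credible interval (2.5% / 97.5% empirical quantiles, linear
interpolation), and — for the follicular-class multipliers — the posterior
probability of no effect, P(gamma_h = 1), estimated as the fraction of
draws exactly equal to 1 (the sampler sets the point-mass state exactly).

Diagnostics are the classical ones: Geweke's two-window z-score,
the Gelman–Rubin potential scale reduction factor, and effective sample
size n / (1 + 2 sum of autocorrelations) with Geyer's initial-positive-
sequence truncation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ValidationError
from .gibbs import GAMMA_NAMES, PosteriorSamples

logger = logging.getLogger("sexratio")

__all__ = [
    "DegenerateChainError",
    "summarize",
    "geweke_z",
    "gelman_rubin",
    "effective_sample_size",
    "diagnostics",
]


class DegenerateChainError(ValidationError):
    """A chain is constant (zero variance): the diagnostic is undefined."""


def summarize(samples: PosteriorSamples, include_day_probability: bool = False) -> pd.DataFrame:
    """Table of posterior summaries, one row per parameter.

    Columns: parameter, mean, median, sd, ci_lower, ci_upper, p_gamma_eq_1
    (NaN for the lam parameters).  With ``include_day_probability`` the
    implied single-day male probability 1 - exp(-lam) is appended as an
    extra column for lam rows (the model's lam is hazard-scale, not itself
    a probability).
    """
    if samples.n_kept == 0:
        raise ValidationError("cannot summarize empty samples")
    rows = []
    for name in samples.parameter_names:
        draws = samples.pooled(name)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        row = {
            "parameter": name,
            "mean": float(np.mean(draws)),
            "median": float(np.median(draws)),
            "sd": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "p_gamma_eq_1": float(np.mean(draws == 1.0)) if name in GAMMA_NAMES else np.nan,
        }
        if include_day_probability:
            row["day_probability"] = (
                float(np.mean(-np.expm1(-draws))) if name not in GAMMA_NAMES else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


# -- autocovariance machinery -----------------------------------------


def _autocovariances(x: np.ndarray) -> np.ndarray:
    """Biased sample autocovariances gamma_0..gamma_{n-1} via FFT."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    return acov


def _integrated_autocorr_time(x: np.ndarray) -> float:
    """tau = 1 + 2 sum rho_t with Geyer initial-positive-sequence truncation.

    Autocovariances are summed in adjacent pairs Gamma_m = gamma_2m +
    gamma_{2m+1}; the sum stops at the first non-positive pair.
    """
    acov = _autocovariances(x)
    if acov[0] <= 0:
        raise DegenerateChainError("constant chain: autocorrelation time undefined")
    n = acov.size
    total = -acov[0]
    for m in range(0, n // 2):
        pair = acov[2 * m] + (acov[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if pair <= 0:
            break
        total += 2.0 * pair
    tau = total / acov[0]
    return max(tau, 1e-12)


def effective_sample_size(chain) -> float:
    """ESS = n / (1 + 2 sum of autocorrelations), truncated by the
    initial-positive-sequence rule.  Requires length >= 100 and a
    non-constant chain."""
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValidationError(f"chain too short for ESS ({x.size} < 100)")
    return x.size / _integrated_autocorr_time(x)


def _spectral_var_of_mean(x: np.ndarray) -> float:
    """Variance of the sample mean, spectral-density-at-zero estimate."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.var(x) == 0:
        raise DegenerateChainError("constant segment: spectral variance undefined")
    tau = _integrated_autocorr_time(x)
    return np.var(x, ddof=1) * tau / x.size


def geweke_z(chain, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain windows.

    Means of the first ``frac_a`` and last ``frac_b`` of the chain,
    standardized by spectral-density-at-zero variance estimates.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValidationError(f"chain too short for Geweke diagnostic ({x.size} < 100)")
    if not (0 < frac_a < 1 and 0 < frac_b < 1 and frac_a + frac_b <= 1):
        raise ValidationError("window fractions must be in (0,1) with frac_a + frac_b <= 1")
    na = int(np.floor(frac_a * x.size))
    nb = int(np.floor(frac_b * x.size))
    a, b = x[:na], x[-nb:]
    va = _spectral_var_of_mean(a)
    vb = _spectral_var_of_mean(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def gelman_rubin(chains) -> float:
    """Classic Gelman–Rubin potential scale reduction factor.

    ``chains`` is a sequence of >= 2 equal-length chains of one parameter.
    R-hat = sqrt(((n-1)/n W + B/n) / W); equals sqrt((n-1)/n) when the
    chains are identical (zero between-chain variance) and approaches 1
    from either side as chains mix.
    """
    arr = [np.asarray(c, dtype=float) for c in chains]
    if len(arr) < 2:
        raise ValidationError("Gelman–Rubin requires at least 2 chains")
    n = arr[0].size
    if any(c.size != n for c in arr) or n < 100:
        raise ValidationError("chains must have equal length >= 100")
    means = np.array([c.mean() for c in arr])
    variances = np.array([c.var(ddof=1) for c in arr])
    W = variances.mean()
    if W == 0:
        raise DegenerateChainError("constant chains: R-hat undefined")
    B_over_n = means.var(ddof=1)  # = B / n
    V = (n - 1) / n * W + B_over_n
    return float(np.sqrt(V / W))


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter diagnostics table: Geweke z (chain 1), R-hat (if >= 2
    chains), total ESS.  Degenerate chains yield NaN with a warning rather
    than aborting the table."""
    rows = []
    for name in samples.parameter_names:
        row = {"parameter": name, "geweke_z": np.nan, "rhat": np.nan, "ess": np.nan}
        try:
            row["geweke_z"] = geweke_z(samples.chain(name, 0))
        except (DegenerateChainError, ValidationError) as exc:
            logger.warning("Geweke for %s unavailable: %s", name, exc)
        if samples.n_chains >= 2:
            try:
                row["rhat"] = gelman_rubin(
                    [samples.chain(name, c) for c in range(samples.n_chains)]
                )
            except (DegenerateChainError, ValidationError) as exc:
                logger.warning("R-hat for %s unavailable: %s", name, exc)
        else:
            logger.warning("single chain: Gelman–Rubin skipped for %s", name)
        try:
            row["ess"] = sum(
                effective_sample_size(samples.chain(name, c))
                for c in range(samples.n_chains)
            )
        except (DegenerateChainError, ValidationError) as exc:
            logger.warning("ESS for %s unavailable: %s", name, exc)
        rows.append(row)
    return pd.DataFrame(rows)
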