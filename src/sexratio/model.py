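"""Model parameters, priors and likelihood for day-specific sex-of-baby odds.

The outcome of a conception cycle is treated as an aggregated Bernoulli
event: each intercourse day in the fertile window independently "fails to
produce a female" with a day-specific probability, and the cycle yields a
female only if every intercourse day does.  With the complementary log-log
link, the probability that cycle i with intercourse pattern X_i and
follicular class z_i produces a female is

    P(Y_i = 1) = prod_k (1 - q_ik)^{X_ik} = exp(-xi_i * sum_k X_ik lam_k),

where q_ik = 1 - exp(-lam_k xi_i) is the single-day probability of a male,
lam_k > 0 is the hazard-scale baseline for window day k, and
xi_i = prod_{h < z_i} gam_h is the multiplicative follicular-class effect.
gam_h = 1 encodes "no effect of moving from class h to h+1" and carries
positive prior mass pi_h under a one-inflated gamma prior, so the posterior
probability of no association is available exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ConceptionCycle, CycleDataset, N_DAYS, ValidationError

__all__ = [
    "N_GAMMA",
    "ModelParameters",
    "PriorSpec",
    "CycleDesign",
    "covariate_multiplier",
    "day_hazard",
    "prob_female",
    "prob_female_vector",
    "log_likelihood",
    "sample_prior",
    "sample_prior_batch",
    "implied_female_prob_from_sex_ratio",
]

N_GAMMA = 3  # three multipliers parameterise the four follicular classes


def _as_positive_array(x, n, name):
    arr = np.asarray(x, dtype=float)
    if arr.shape == ():
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValidationError(f"{name} must have length {n}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError(f"{name} entries must be finite and strictly positive")
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class ModelParameters:
    """lam: 12 day-specific hazard parameters; gam: 3 class multipliers."""

    lam: np.ndarray
    gam: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lam", _as_positive_array(self.lam, N_DAYS, "lam"))
        object.__setattr__(self, "gam", _as_positive_array(self.gam, N_GAMMA, "gam"))


@dataclass(frozen=True)
class PriorSpec:
    """Gamma priors for lam; one-inflated gamma priors for gam.

    lam_k ~ Gamma(a0k, b0k) (shape/rate); gam_h = 1 with probability pi_h,
    else Gamma(a0h, b0h).
    """

    a0k: np.ndarray
    b0k: np.ndarray
    pi_h: np.ndarray
    a0h: np.ndarray
    b0h: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "a0k", _as_positive_array(self.a0k, N_DAYS, "a0k"))
        object.__setattr__(self, "b0k", _as_positive_array(self.b0k, N_DAYS, "b0k"))
        pi = np.asarray(self.pi_h, dtype=float)
        if pi.shape == ():
            pi = np.full(N_GAMMA, float(pi))
        if pi.shape != (N_GAMMA,) or np.any(pi < 0) or np.any(pi > 1):
            raise ValidationError("pi_h must be 3 probabilities in [0, 1]")
        pi.flags.writeable = False
        object.__setattr__(self, "pi_h", pi)
        object.__setattr__(self, "a0h", _as_positive_array(self.a0h, N_GAMMA, "a0h"))
        object.__setattr__(self, "b0h", _as_positive_array(self.b0h, N_GAMMA, "b0h"))

    @classmethod
    def default(cls) -> "PriorSpec":
        """Diffuse defaults: a0k = b0k = 1; pi_h = 0.5^(1/3) so that the joint
        null hypothesis gam = (1,1,1) has prior probability 0.5; a0h = b0h = 0.1."""
        return cls(
            a0k=np.ones(N_DAYS),
            b0k=np.ones(N_DAYS),
            pi_h=np.full(N_GAMMA, 0.5 ** (1.0 / 3.0)),
            a0h=np.full(N_GAMMA, 0.1),
            b0h=np.full(N_GAMMA, 0.1),
        )


@dataclass(frozen=True)
class CycleDesign:
    """Intercourse indicators and follicular class of one cycle."""

    x: tuple
    z: int

    def __post_init__(self):
        x = tuple(int(v) for v in self.x)
        if len(x) != N_DAYS or any(v not in (0, 1) for v in x):
            raise ValidationError("x must be 12 binary indicators")
        object.__setattr__(self, "x", x)
        if int(self.z) not in (1, 2, 3, 4):
            raise ValidationError(f"follicular class z must be in 1..4, got {self.z}")
        object.__setattr__(self, "z", int(self.z))

    @classmethod
    def from_cycle(cls, cycle: ConceptionCycle) -> "CycleDesign":
        z = 1 if cycle.follicular_class is None else cycle.follicular_class
        return cls(x=cycle.intercourse, z=z)


def covariate_multiplier(gam, z: int) -> float:
    """xi = prod of the first z-1 entries of gam (empty product = 1)."""
    gam = np.asarray(gam, dtype=float)
    if int(z) not in (1, 2, 3, 4):
        raise ValidationError(f"follicular class z must be in 1..4, got {z}")
    return float(np.prod(gam[: int(z) - 1]))


def day_hazard(lam_k: float, xi: float) -> float:
    """Single-day male probability q = 1 - exp(-lam_k * xi)."""
    if not (lam_k > 0 and np.isfinite(lam_k)) or not (xi > 0 and np.isfinite(xi)):
        raise ValidationError("day_hazard requires strictly positive finite inputs")
    return -float(np.expm1(-lam_k * xi))


def prob_female(params: ModelParameters, design) -> float:
    """P(Y = 1) = exp(-xi * sum_k X_k lam_k) for one cycle.

    ``design`` may be a CycleDesign or a ConceptionCycle.
    """
    if isinstance(design, ConceptionCycle):
        design = CycleDesign.from_cycle(design)
    x = np.asarray(design.x, dtype=float)
    if x.sum() == 0:
        raise ValidationError("cycle has no intercourse in the fertile window")
    xi = covariate_multiplier(params.gam, design.z)
    return float(np.exp(-xi * float(x @ params.lam)))


def prob_female_vector(lam, gam, X, z) -> np.ndarray:
    """Vectorised P(female) for an n x 12 indicator matrix and class vector."""
    lam = np.asarray(lam, dtype=float)
    gam = np.asarray(gam, dtype=float)
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=np.int64)
    cum = np.concatenate([[1.0], np.cumprod(gam)])  # xi for z = 1..4
    xi = cum[z - 1]
    return np.exp(-xi * (X @ lam))


def log_likelihood(params: ModelParameters, data: CycleDataset) -> float:
    """Bernoulli log likelihood over independent conception cycles."""
    if data.n == 0:
        raise ValidationError("log_likelihood requires a non-empty dataset")
    X, y, z, _ = data.to_arrays(covariate=True)
    p = prob_female_vector(params.lam, params.gam, X, z)
    a = -np.log(p)  # = xi * sum_k X_k lam_k > 0 for valid cycles
    # female term: log p = -a ; male term: log(1 - exp(-a))
    return float(np.sum(np.where(y == 1, -a, np.log(-np.expm1(-a)))))


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> ModelParameters:
    """One draw from the prior: gamma lam's, one-inflated-gamma gam's."""
    lam = rng.gamma(priors.a0k, 1.0 / priors.b0k)
    at_one = rng.random(N_GAMMA) < priors.pi_h
    gam = np.where(at_one, 1.0, rng.gamma(priors.a0h, 1.0 / priors.b0h))
    return ModelParameters(lam=lam, gam=gam)


def sample_prior_batch(priors: PriorSpec, size: int, rng: np.random.Generator):
    """(lam, gam) arrays of shapes (size, 12) and (size, 3) of prior draws.

    The point-mass state is set to exactly 1.0, so null membership can be
    tested with ``==``.
    """
    lam = rng.gamma(priors.a0k, 1.0 / priors.b0k, size=(size, N_DAYS))
    at_one = rng.random((size, N_GAMMA)) < priors.pi_h
    gam = np.where(at_one, 1.0, rng.gamma(priors.a0h, 1.0 / priors.b0h, size=(size, N_GAMMA)))
    return lam, gam


def implied_female_prob_from_sex_ratio(males_per_100_females: float) -> float:
    """Female-birth probability implied by a sex ratio of m males per 100 females.

    The near-constant human sex ratio at birth of about 106:100 gives ~0.485.
    """
    m = float(males_per_100_females)
    if not np.isfinite(m) or m <= 0:
        raise ValidationError("sex ratio must be a positive number of males per 100 females")
    return 100.0 / (100.0 + m)
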