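"""Truncated-Gaussian randomization: fitting, sampling, seed derivation.

Every randomized input of the Monte Carlo risk simulation — per-compound
inhalation concentrations Cin_i and the exposure parameters N_PR, F_S,
N_Y — is described by a truncated Gaussian: a normal law with location μ
and scale σ set to the sample mean and sample standard deviation of the
observed data, restricted to the observed [MIN, MAX] interval.  μ and σ
parameterize the *parent* (pre-truncation) normal; the realized mean of
the truncated law therefore differs from μ whenever the truncation is
asymmetric.  This literal convention is deliberate and the tests account
for it.

Sampling uses the inverse-CDF method on the truncated interval: u is
drawn uniformly on [Φ(α), Φ(β)] with α=(MIN−μ)/σ, β=(MAX−μ)/σ, and the
draw is μ + σ·Φ⁻¹(u).  This never rejects, so narrow truncation windows
cost nothing, and it is exactly equivariant under affine rescaling of
the spec (which makes linearity-in-k of the risk engine exact).

Reproducibility: one master seed; every parameter and compound consumes
an independent child stream derived from a stable hash of the master
seed and a name path, so adding a compound never perturbs the draws of
another.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "TruncatedGaussianSpec",
    "fit_spec",
    "sample",
    "sample_integer",
    "truncated_normal_ppf",
    "truncated_normal_moments",
    "child_rng",
    "derive_seed",
]


@dataclass
class TruncatedGaussianSpec:
    """(μ, σ, MIN, MAX) of a truncated Gaussian randomized input."""

    mu: float
    sigma: float
    lower: float
    upper: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) must be <= upper ({self.upper})")
        if not (self.lower <= self.mu <= self.upper):
            # legal but suspicious: the parent mean sits outside the window
            warnings.warn(
                f"parent mean {self.mu} lies outside the truncation interval "
                f"[{self.lower}, {self.upper}]",
                stacklevel=2,
            )

    def scaled(self, c: float) -> "TruncatedGaussianSpec":
        """Spec of the variable multiplied by a positive constant c."""
        if c <= 0:
            raise ValueError("scale factor must be > 0")
        return TruncatedGaussianSpec(
            self.mu * c, self.sigma * c, self.lower * c, self.upper * c, self.n_obs
        )


def fit_spec(observations) -> TruncatedGaussianSpec:
    """Descriptive-statistics fit: mean, sd (n−1), observed extremes.

    A single observation yields a point mass (σ = 0).
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.size == 0:
        raise ValueError("cannot fit a spec to zero observations")
    sigma = float(np.std(obs, ddof=1)) if obs.size > 1 else 0.0
    return TruncatedGaussianSpec(
        mu=float(np.mean(obs)),
        sigma=sigma,
        lower=float(np.min(obs)),
        upper=float(np.max(obs)),
        n_obs=int(obs.size),
    )


# ---------------------------------------------------------------------------
# seeding


def _hash_token(token) -> int:
    digest = hashlib.sha256(str(token).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def _seed_sequence(master_seed: int, *path) -> np.random.SeedSequence:
    entropy = [abs(int(master_seed))] + [_hash_token(p) for p in path]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *path) -> np.random.Generator:
    """Independent, reproducible generator for (master_seed, *path)."""
    return np.random.default_rng(_seed_sequence(master_seed, *path))


def derive_seed(master_seed: int, *path) -> int:
    """Deterministic 31-bit child seed for (master_seed, *path)."""
    return int(_seed_sequence(master_seed, *path).generate_state(1)[0]) & 0x7FFFFFFF


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# sampling and closed forms


def sample(spec: TruncatedGaussianSpec, n: int, seed) -> np.ndarray:
    """Draw n values from the truncated Gaussian; all lie in [MIN, MAX].

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Identical
    (spec, n, seed) triples give bitwise-identical output.  σ = 0 gives n
    copies of μ clamped into [MIN, MAX].
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    if n == 0:
        # consume nothing; an empty request leaves the stream untouched
        return np.empty(0, dtype=float)
    if spec.sigma == 0:
        value = min(max(spec.mu, spec.lower), spec.upper)
        return np.full(n, value, dtype=float)
    alpha = (spec.lower - spec.mu) / spec.sigma
    beta = (spec.upper - spec.mu) / spec.sigma
    lo, hi = ndtr(alpha), ndtr(beta)
    u = rng.uniform(lo, hi, size=n)
    draws = spec.mu + spec.sigma * ndtri(u)
    return np.clip(draws, spec.lower, spec.upper)


def sample_integer(spec: TruncatedGaussianSpec, n: int, seed) -> np.ndarray:
    """Integer draws for count-valued parameters (N_PR).

    Continuous draws are rounded to the nearest integer (ties to even),
    then clamped to [max(ceil(MIN), 1), floor(MAX)].
    """
    hi = math.floor(spec.upper)
    if hi < 1:
        raise ValueError(
            f"no valid presentation count: floor(upper) = {hi} < 1"
        )
    lo = max(math.ceil(spec.lower), 1)
    if lo > hi:
        raise ValueError(
            f"integer truncation window is empty: [{lo}, {hi}]"
        )
    draws = np.rint(sample(spec, n, seed))
    return np.clip(draws, lo, hi).astype(int)


def truncated_normal_ppf(spec: TruncatedGaussianSpec, q) -> float | np.ndarray:
    """Closed-form quantile of the truncated Gaussian.

    Inverts the CDF analytically: x_q = μ + σ·Φ⁻¹(Φ(α) + q·(Φ(β)−Φ(α))).
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    if spec.sigma == 0:
        value = min(max(spec.mu, spec.lower), spec.upper)
        out = np.full_like(q, value)
        return float(out) if out.ndim == 0 else out
    alpha = (spec.lower - spec.mu) / spec.sigma
    beta = (spec.upper - spec.mu) / spec.sigma
    lo, hi = ndtr(alpha), ndtr(beta)
    x = spec.mu + spec.sigma * ndtri(lo + q * (hi - lo))
    x = np.clip(x, spec.lower, spec.upper)
    return float(x) if x.ndim == 0 else x


def truncated_normal_moments(spec: TruncatedGaussianSpec) -> tuple[float, float]:
    """Mean and standard deviation of the truncated law (closed form)."""
    if spec.sigma == 0:
        return min(max(spec.mu, spec.lower), spec.upper), 0.0
    alpha = (spec.lower - spec.mu) / spec.sigma
    beta = (spec.upper - spec.mu) / spec.sigma
    z = ndtr(beta) - ndtr(alpha)
    phi = lambda x: math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
    mean = spec.mu + spec.sigma * (phi(alpha) - phi(beta)) / z
    var = spec.sigma**2 * (
        1
        + (alpha * phi(alpha) - beta * phi(beta)) / z
        - ((phi(alpha) - phi(beta)) / z) ** 2
    )
    return float(mean), float(math.sqrt(max(var, 0.0)))
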