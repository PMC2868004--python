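"""Beta posteriors for tag abundance and beta-mixture group models.

Under the urn model of tag sequencing, observing N tags for a gene out of T
sequenced tags is a binomial draw with success probability pi, the latent
mRNA abundance.  With a uniform prior the posterior of pi is
Beta(a, b) with a = N + 1, b = T - N + 1.

A *group* of m replicate libraries is encoded as an equal-weight mixture of
their m beta posteriors.  For m = 1 the mixture is exactly the single beta
distribution; sampling switches automatically between the plain-beta and
mixture modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(a, b) posterior of an abundance pi, a = N+1, b = T-N+1."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise DomainError(
                f"beta posterior parameters must be >= 1 (uniform-prior floor), "
                f"got a={self.a}, b={self.b}"
            )

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    def pdf(self, pi: float) -> float:
        return float(stats.beta.pdf(pi, self.a, self.b))

    def cdf(self, pi: float) -> float:
        return float(stats.beta.cdf(pi, self.a, self.b))


def beta_posterior(n: int, t: int) -> BetaPosterior:
    """Posterior of abundance after observing ``n`` tags out of ``t`` total.

    ``(n, t) = (0, 0)`` returns Beta(1, 1), the uniform prior.
    """
    if n < 0 or t < 0:
        raise DomainError(f"counts must be non-negative, got N={n}, T={t}")
    if n > t:
        raise DomainError(f"count N={n} exceeds total tags T={t}")
    return BetaPosterior(a=n + 1.0, b=t - n + 1.0)


@dataclass(frozen=True)
class GroupModel:
    """Named equal-weight mixture of beta posteriors, one per replicate library."""

    group_id: str
    components: tuple[BetaPosterior, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"group {self.group_id!r} has no components")

    @property
    def m(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.m, 1.0 / self.m)

    @property
    def mean(self) -> float:
        return float(np.mean([c.mean for c in self.components]))


def group_model(
    group_id: str, counts: list[int], totals: list[int]
) -> GroupModel:
    """Build a group model from per-library (N, T) pairs for one gene."""
    if len(counts) != len(totals):
        raise ValueError("counts and totals must have equal length")
    return GroupModel(
        group_id=group_id,
        components=tuple(beta_posterior(n, t) for n, t in zip(counts, totals)),
    )


def sample_abundance(
    model: GroupModel | BetaPosterior,
    n_draws: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n_draws`` abundance values from a posterior or group mixture.

    For a single-component model the draws come straight from Beta(a, b);
    for m > 1 each draw first picks a component uniformly at random, then
    draws from that component's beta (exact mixture sampling by indicator).
    Reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(model, BetaPosterior):
        return rng.beta(model.a, model.b, size=n_draws)
    if model.m == 1:
        c = model.components[0]
        return rng.beta(c.a, c.b, size=n_draws)
    a = np.array([c.a for c in model.components])
    b = np.array([c.b for c in model.components])
    idx = rng.integers(0, model.m, size=n_draws)
    return rng.beta(a[idx], b[idx])


def mixture_density(model: GroupModel | BetaPosterior, pi) -> np.ndarray | float:
    """Density of the (mixture) posterior at ``pi``: (1/m) sum_i BetaPDF(pi; a_i, b_i)."""
    pi_arr = np.asarray(pi, dtype=float)
    if np.any(pi_arr <= 0.0) or np.any(pi_arr >= 1.0):
        raise DomainError("pi must lie strictly inside (0, 1)")
    if isinstance(model, BetaPosterior):
        out = stats.beta.pdf(pi_arr, model.a, model.b)
    else:
        out = np.zeros_like(pi_arr)
        for c in model.components:
            out += stats.beta.pdf(pi_arr, c.a, c.b)
        out /= model.m
    return float(out) if np.isscalar(pi) else out


def mixture_cdf(model: GroupModel | BetaPosterior, pi) -> np.ndarray | float:
    """CDF of the (mixture) posterior at ``pi``."""
    pi_arr = np.asarray(pi, dtype=float)
    if isinstance(model, BetaPosterior):
        out = stats.beta.cdf(pi_arr, model.a, model.b)
    else:
        out = np.zeros_like(pi_arr, dtype=float)
        for c in model.components:
            out += stats.beta.cdf(pi_arr, c.a, c.b)
        out /= model.m
    return float(out) if np.isscalar(pi) else out
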