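"""Chemodiversity summaries from allele frequencies or raw populations.

Each locus stands for one metabolite; an individual produces it if it
carries at least one presence (1) allele.  Three summaries are used:

* gamma — number of loci segregating or fixed for the presence allele
  (total metabolites in the population),
* alpha — expected number of metabolites per individual under
  Hardy-Weinberg proportions, ``sum_l 1 - (1 - pi_l)^2``,
* beta — expected number of metabolites possessed by exactly one of two
  randomly drawn individuals, ``sum_l 2 q_l (1 - q_l)`` with carrier
  probability ``q_l = 1 - (1 - pi_l)^2``.

The estimator forms assume random mating; :func:`empirical_diversity`
provides a direct-count check on raw populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiversitySummary",
    "allele_frequencies",
    "gamma_diversity",
    "alpha_diversity",
    "beta_diversity",
    "polymorphic_loci",
    "diversity_summary",
    "empirical_diversity",
]


@dataclass(frozen=True)
class DiversitySummary:
    gamma: float
    alpha: float
    beta: float
    pi: np.ndarray  # per-locus frequency of the presence allele

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.gamma, self.alpha, self.beta)


def allele_frequencies(pop: np.ndarray) -> np.ndarray:
    """Per-locus presence-allele frequency of an (N, L, 2) population array."""
    N = pop.shape[0]
    return pop.sum(axis=(0, 2)) / (2.0 * N)


def gamma_diversity(pi: np.ndarray) -> int:
    """Number of loci carrying at least one presence allele (pi > 0 strictly)."""
    return int(np.count_nonzero(np.asarray(pi) > 0))


def alpha_diversity(pi: np.ndarray) -> float:
    """Expected metabolites per individual: sum_l [1 - (1 - pi_l)^2]."""
    pi = np.asarray(pi, dtype=float)
    return float((1.0 - (1.0 - pi) ** 2).sum())


def beta_diversity(pi: np.ndarray) -> float:
    """Expected unshared metabolites between two random individuals.

    Per locus ``2 q (1 - q)`` where ``q = 1 - (1 - pi)^2`` is the
    probability an individual carries the metabolite; equivalently
    ``2 (1 - pi)^2 [1 - (1 - pi)^2]``.  Zero at pi in {0, 1}, maximal
    (0.5 per locus) where q = 1/2.
    """
    pi = np.asarray(pi, dtype=float)
    q = 1.0 - (1.0 - pi) ** 2
    return float((2.0 * q * (1.0 - q)).sum())


def polymorphic_loci(pi: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> np.ndarray:
    """Indices of loci with allele frequency in [lower, upper] (inclusive)."""
    if not 0 <= lower < upper <= 1:
        raise ValueError("need 0 <= lower < upper <= 1")
    pi = np.asarray(pi, dtype=float)
    return np.flatnonzero((pi >= lower) & (pi <= upper))


def diversity_summary(pi: np.ndarray) -> DiversitySummary:
    """All three diversity measures from a frequency vector."""
    pi = np.asarray(pi, dtype=float)
    return DiversitySummary(
        gamma=gamma_diversity(pi),
        alpha=alpha_diversity(pi),
        beta=beta_diversity(pi),
        pi=pi,
    )


def empirical_diversity(pop: np.ndarray, n_pairs: int = 1000,
                        rng: np.random.Generator | None = None) -> DiversitySummary:
    """Direct-count diversity from a raw population (oracle for the estimators).

    alpha is the mean per-individual carrier count; beta the mean number
    of loci where exactly one member of a random pair (drawn with
    replacement, distinct indices) is a carrier.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    N = pop.shape[0]
    carriers = pop.sum(axis=2) > 0  # (N, L)
    pi = allele_frequencies(pop)
    alpha = float(carriers.sum(axis=1).mean())
    i = rng.integers(0, N, size=n_pairs)
    j = rng.integers(0, N - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct individuals
    beta = float((carriers[i] != carriers[j]).sum(axis=1).mean())
    return DiversitySummary(gamma=gamma_diversity(pi), alpha=alpha, beta=beta, pi=pi)
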