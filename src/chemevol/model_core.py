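"""Deterministic fitness machinery for the chemodiversity model.

A diploid plant genome has ``L`` biallelic loci, each controlling the
presence (allele 1) or absence (allele 0) of one defense metabolite.
Metabolite *l* has an effect ``m[l, i]`` on herbivore *i* (positive =
repellent, negative = attractant).  Per-herbivore antiherbivore activity
is additive across loci with dominance ``da`` for heterozygotes; the
benefit of activity is a logistic escape probability; metabolite
production carries a multiplicative fecundity cost ``exp(-c * zc)``
with its own dominance ``dc``.  All fitness components multiply.

Everything in this module is pure and deterministic; stochastic
population dynamics live in :mod:`chemevol.simulator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InvalidBenefitError",
    "Genotype",
    "DominanceParams",
    "BenefitParams",
    "ModelParams",
    "activity",
    "activities",
    "benefit",
    "cost_trait",
    "fecundity",
    "fitness",
    "geometric_mean_fitness",
    "dose_to_trait",
    "population_doses",
    "population_fitness",
]


class InvalidBenefitError(ValueError):
    """Raised when a calibrated benefit function yields a value <= 0.

    Only possible with a negative baseline intercept ``b0`` (produced by
    synergy calibration) combined with strongly negative activity.
    """


def _as_locus_array(value, L: int, name: str) -> np.ndarray:
    """Broadcast a scalar or length-L sequence to a float array of length L."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(L, float(arr))
    if arr.shape != (L,):
        raise ValueError(f"{name} must be a scalar or length-{L} sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Genotype:
    """Diploid multilocus genotype: L ordered pairs of 0/1 alleles.

    Heterozygotes are unordered (01 and 10 are the same state); only the
    per-locus allele dose (0, 1, or 2) enters the fitness machinery.
    """

    alleles: np.ndarray  # shape (L, 2), entries in {0, 1}

    def __post_init__(self):
        raw = np.asarray(self.alleles)
        if raw.ndim != 2 or raw.shape[1] != 2:
            raise ValueError("alleles must have shape (L, 2)")
        if not np.isin(raw, (0, 1)).all():
            raise ValueError("alleles must be 0 or 1")
        object.__setattr__(self, "alleles", raw.astype(np.int8))

    @property
    def L(self) -> int:
        return self.alleles.shape[0]

    @property
    def dose(self) -> np.ndarray:
        """Per-locus count of presence alleles (0, 1, or 2)."""
        return self.alleles.sum(axis=1)

    @property
    def is_homozygous(self) -> bool:
        return bool((self.alleles[:, 0] == self.alleles[:, 1]).all())

    @classmethod
    def homozygous(cls, presence: Sequence[int]) -> "Genotype":
        """Build a genotype homozygous at every locus from a 0/1 vector."""
        p = np.asarray(presence, dtype=np.int8)
        return cls(np.stack([p, p], axis=1))

    @classmethod
    def from_dose(cls, dose: Sequence[int]) -> "Genotype":
        """Build a genotype from per-locus allele doses (0, 1, or 2)."""
        d = np.asarray(dose, dtype=np.int8)
        if not np.isin(d, (0, 1, 2)).all():
            raise ValueError("dose entries must be 0, 1 or 2")
        first = (d >= 1).astype(np.int8)
        second = (d == 2).astype(np.int8)
        return cls(np.stack([first, second], axis=1))


@dataclass(frozen=True)
class DominanceParams:
    """Per-locus dominance coefficients in [0, 1].

    ``da`` scales the heterozygote's antiherbivore activity, ``dc`` its
    metabolic cost; both relative to the presence homozygote.  A
    dominance reversal means da > 0.5 together with dc < 0.5.
    Scalars broadcast to all loci.
    """

    da: np.ndarray
    dc: np.ndarray

    def __post_init__(self):
        da = np.atleast_1d(np.asarray(self.da, dtype=float))
        dc = np.atleast_1d(np.asarray(self.dc, dtype=float))
        if da.shape != dc.shape:
            raise ValueError("da and dc must have the same length")
        for name, arr in (("da", da), ("dc", dc)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "da", da)
        object.__setattr__(self, "dc", dc)

    @classmethod
    def broadcast(cls, da, dc, L: int) -> "DominanceParams":
        return cls(_as_locus_array(da, L, "da"), _as_locus_array(dc, L, "dc"))


@dataclass(frozen=True)
class BenefitParams:
    """Parameters of the logistic escape-probability (benefit) function.

    ``b0`` is the baseline probability to escape the herbivore for
    strongly negative activity; ``ahalf`` the half-saturation activity;
    ``s`` the sensitivity (logistic steepness).  ``b0`` may be negative
    only as an intercept produced by synergy calibration; realized
    benefits must stay in (0, 1].
    """

    b0: float = 0.0
    ahalf: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if not self.s > 0:
            raise ValueError("sensitivity s must be > 0")
        if self.b0 >= 1:
            raise ValueError("b0 must be < 1")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter bundle of the chemodiversity model.

    Defaults are the standard study conditions: a population of N=500
    diploids, nonoverlapping generations (theta=1), one herbivore
    present in 20% of 5-generation phases, L=10 loci of unit effect,
    cost c=0.02 and mutation rate u=1e-4 per allele copy.
    Dominance has no canonical default (it is the main experimental
    axis); 0.5/0.5 (purely intermediate heterozygotes) is used when not
    supplied.
    """

    N: int = 500
    theta: float = 1.0
    nh: int = 1
    g: int = 5
    p: float | Sequence[float] = 0.2
    L: int = 10
    M: float | np.ndarray = 1.0
    dom: DominanceParams | None = None
    benefit: BenefitParams | Sequence[BenefitParams] = field(default_factory=BenefitParams)
    c: float = 0.02
    u: float = 1e-4

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.nh < 1 or self.g < 1 or self.L < 1:
            raise ValueError("nh, g and L must be positive integers")
        if self.c < 0:
            raise ValueError("cost parameter c must be >= 0")
        if not 0 <= self.u < 1:
            raise ValueError("mutation probability u must be in [0, 1)")

        p = np.asarray(self.p, dtype=float)
        if p.ndim == 0:
            p = np.full(self.nh, float(p))
        if p.shape != (self.nh,):
            raise ValueError(f"p must be scalar or length-nh, got shape {p.shape}")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("herbivore presence probabilities must be in [0, 1]")
        object.__setattr__(self, "p", p)

        M = np.asarray(self.M, dtype=float)
        if M.ndim == 0:
            M = np.full((self.L, self.nh), float(M))
        if M.shape != (self.L, self.nh):
            raise ValueError(f"effect matrix must have shape ({self.L}, {self.nh})")
        if not np.isfinite(M).all():
            raise ValueError("effect matrix entries must be finite")
        object.__setattr__(self, "M", M)

        dom = self.dom
        if dom is None:
            dom = DominanceParams.broadcast(0.5, 0.5, self.L)
        elif dom.da.shape == (1,) and self.L != 1:
            dom = DominanceParams.broadcast(float(dom.da[0]), float(dom.dc[0]), self.L)
        if dom.da.shape != (self.L,):
            raise ValueError("dominance parameters must be scalar or length-L")
        object.__setattr__(self, "dom", dom)

        ben = self.benefit
        if isinstance(ben, BenefitParams):
            ben = tuple([ben] * self.nh)
        else:
            ben = tuple(ben)
        if len(ben) != self.nh:
            raise ValueError("need one BenefitParams per herbivore")
        object.__setattr__(self, "benefit", ben)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def dose_to_trait(dose: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Map allele dose {0,1,2} to trait contribution {0, d, 1} per locus."""
    dose = np.asarray(dose, dtype=float)
    return np.where(dose == 1, d, dose / 2.0)


def activity(geno: Genotype, params: ModelParams, herbivore: int) -> float:
    """Antiherbivore activity of a genotype against one herbivore.

    Additive across loci: ``a_i = sum_l m[l, i] * z_a[l]`` with
    ``z_a[l]`` = 0, da(l), or 1 for genotype 00, 01, 11.
    """
    if not 0 <= herbivore < params.nh:
        raise IndexError(f"herbivore index {herbivore} out of range [0, {params.nh})")
    za = dose_to_trait(geno.dose, params.dom.da)
    return float(za @ params.M[:, herbivore])


def activities(geno: Genotype, params: ModelParams) -> np.ndarray:
    """Activities against all nh herbivores as a length-nh array."""
    za = dose_to_trait(geno.dose, params.dom.da)
    return za @ params.M


def benefit(a, bp: BenefitParams):
    """Logistic escape probability b(a) = b0 + (1-b0)/(1+exp(-s(a-ahalf))).

    Strictly increasing in activity, with limits b0 (a -> -inf) and 1
    (a -> +inf).  Raises :class:`InvalidBenefitError` if the result is
    <= 0, which can only happen for calibrated negative b0.
    """
    a = np.asarray(a, dtype=float)
    with np.errstate(over="ignore"):
        val = bp.b0 + (1.0 - bp.b0) / (1.0 + np.exp(-bp.s * (a - bp.ahalf)))
    if np.any(val <= 0):
        raise InvalidBenefitError(
            f"benefit function yielded a non-positive value (b0={bp.b0}); "
            "escape probabilities must lie in (0, 1]"
        )
    return val if val.ndim else float(val)


def cost_trait(geno: Genotype, params: ModelParams) -> float:
    """Cost trait zc = sum_l z_c[l], with z_c[l] in {0, dc(l), 1}."""
    return float(dose_to_trait(geno.dose, params.dom.dc).sum())


def fecundity(zc: float, c: float) -> float:
    """Multiplicative fecundity f(zc) = exp(-c * zc), in (0, 1]."""
    return float(np.exp(-c * np.asarray(zc, dtype=float)))


def fitness(geno: Genotype, present: Iterable[int], params: ModelParams) -> float:
    """Fitness in one generation: product of benefits over present herbivores times fecundity."""
    present = sorted(set(present))
    if any(i < 0 or i >= params.nh for i in present):
        raise IndexError("herbivore index out of range")
    w = fecundity(cost_trait(geno, params), params.c)
    if present:
        a = activities(geno, params)
        for i in present:
            w *= benefit(a[i], params.benefit[i])
    return w


def geometric_mean_fitness(geno: Genotype, params: ModelParams) -> float:
    """Long-run geometric mean fitness over the herbivore presence process.

    ``W~ = prod_i b(a_i)^{p_i} * f(zc)`` — each herbivore contributes its
    benefit weighted by its presence probability.  Independent of the
    phase length g, phase ordering, and autocorrelation.  The long-run
    growth criterion applies to homozygous genotypes (which breed true);
    heterozygous input is accepted but flagged with a warning because the
    quantity has no invasion interpretation there.
    """
    if not geno.is_homozygous:
        warnings.warn(
            "geometric mean fitness evaluated on a heterozygous genotype; "
            "the long-run growth interpretation holds only for homozygotes",
            UserWarning,
            stacklevel=2,
        )
    a = activities(geno, params)
    logw = -params.c * cost_trait(geno, params)
    for i in range(params.nh):
        logw += params.p[i] * np.log(benefit(a[i], params.benefit[i]))
    return float(np.exp(logw))


# ---------------------------------------------------------------------------
# Vectorized population-level machinery (used by the simulator)
# ---------------------------------------------------------------------------

def population_doses(pop: np.ndarray) -> np.ndarray:
    """Allele doses per individual and locus for an (N, L, 2) population array."""
    return pop.sum(axis=2)


def population_fitness(pop: np.ndarray, present: np.ndarray, params: ModelParams) -> np.ndarray:
    """Fitness of every individual in an (N, L, 2) population array.

    ``present`` is a length-nh boolean mask of herbivores active this
    generation.  Returns a length-N array of positive fitnesses.
    """
    dose = population_doses(pop)  # (N, L)
    zc = dose_to_trait(dose, params.dom.dc).sum(axis=1)  # (N,)
    logw = -params.c * zc
    idx = np.flatnonzero(present)
    if idx.size:
        za = dose_to_trait(dose, params.dom.da)  # (N, L)
        act = za @ params.M[:, idx]  # (N, n_present)
        b0 = np.array([params.benefit[i].b0 for i in idx])
        ahalf = np.array([params.benefit[i].ahalf for i in idx])
        s = np.array([params.benefit[i].s for i in idx])
        with np.errstate(over="ignore"):
            b = b0 + (1.0 - b0) / (1.0 + np.exp(-s * (act - ahalf)))
        if np.any(b <= 0):
            raise InvalidBenefitError(
                "benefit function yielded a non-positive value; "
                "escape probabilities must lie in (0, 1]"
            )
        logw += np.log(b).sum(axis=1)
    return np.exp(logw)
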