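"""Analytic invasion analysis for metabolite presence-absence polymorphism.

In a temporally fluctuating environment with nonoverlapping generations
the fate of a rare allele is governed by geometric mean fitness.  For a
monomorphic homozygous resident population, a rare mutant allele at one
locus occurs almost exclusively in heterozygotes, whose numbers grow per
generation by

    lambda_t = 1 - theta + theta * W_m,t / W_r,t

(survival of heterozygous adults plus fitness-weighted reproduction),
where ``W_m,t`` and ``W_r,t`` are heterozygote and resident fitness in
generation t.  The mutant invades iff the geometric mean ``lambda~`` of
``lambda_t`` over the herbivore-presence process exceeds 1.  Polymorphism
is scored as possible when *every* homozygous resident genotype can be
invaded by at least one single-locus mutant, so that no multilocus
genotype can fix.

The geometric mean is computed exactly by enumerating all 2^nh herbivore
subsets with their Bernoulli probabilities (in log space).  Phase length
g never enters: geometric mean fitness is invariant to the ordering and
autocorrelation of environments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .model_core import BenefitParams, ModelParams, benefit, fecundity

__all__ = [
    "InvasionResult",
    "DominanceScan",
    "optimal_homozygote",
    "mutant_growth_rate",
    "polymorphism_possible",
    "simplified_condition",
    "dominance_scan",
]

_MAX_ENUM_NH = 10
_MAX_ENUM_L = 20


@dataclass(frozen=True)
class InvasionResult:
    """Verdict of a single-locus invasion attempt against a resident."""

    resident: np.ndarray  # length-L 0/1 homozygous presence vector
    locus: int
    lambda_tilde: float

    @property
    def invades(self) -> bool:
        """Strict criterion: the mutant invades iff lambda~ > 1 (drift decides ties)."""
        return self.lambda_tilde > 1.0


@dataclass(frozen=True)
class DominanceScan:
    """Polymorphism verdicts over a (da, dc) dominance grid."""

    da_values: np.ndarray
    dc_values: np.ndarray
    polymorphic: np.ndarray  # bool, shape (len(da_values), len(dc_values))

    @property
    def scope_percent(self) -> float:
        """Percentage of grid cells where polymorphism is possible."""
        return 100.0 * float(self.polymorphic.mean())


def _check_guards(params: ModelParams) -> None:
    if params.nh > _MAX_ENUM_NH:
        raise ValueError(f"exact environment enumeration limited to nh <= {_MAX_ENUM_NH}")


def _environments(params: ModelParams):
    """All herbivore subsets with their Bernoulli probabilities.

    Yields (mask, prob) with mask a length-nh boolean array.  Subsets of
    probability zero are skipped.
    """
    _check_guards(params)
    p = params.p
    for bits in product((False, True), repeat=params.nh):
        mask = np.asarray(bits)
        prob = float(np.prod(np.where(mask, p, 1.0 - p)))
        if prob > 0.0:
            yield mask, prob


def _log_fitness_from_traits(za: np.ndarray, zc: float, mask: np.ndarray,
                             params: ModelParams) -> float:
    """log fitness of an individual with activity-trait vector za in environment mask."""
    act = za @ params.M
    logw = -params.c * zc
    for i in np.flatnonzero(mask):
        logw += np.log(benefit(act[i], params.benefit[i]))
    return logw


def _homozygote_traits(presence: np.ndarray):
    za = presence.astype(float)
    return za, float(presence.sum())


def _heterozygote_traits(presence: np.ndarray, locus: int, params: ModelParams):
    """Traits of the resident's one-locus heterozygous mutant."""
    za = presence.astype(float).copy()
    zc_vec = presence.astype(float).copy()
    za[locus] = params.dom.da[locus]
    zc_vec[locus] = params.dom.dc[locus]
    return za, float(zc_vec.sum())


def log_geometric_mean_fitness(presence: np.ndarray, params: ModelParams) -> float:
    """log W~ of a homozygous genotype given as a 0/1 presence vector."""
    za, zc = _homozygote_traits(np.asarray(presence))
    act = za @ params.M
    logw = -params.c * zc
    for i in range(params.nh):
        logw += params.p[i] * np.log(benefit(act[i], params.benefit[i]))
    return float(logw)


def optimal_homozygote(params: ModelParams) -> tuple[np.ndarray, float]:
    """Homozygous genotype maximizing geometric mean fitness.

    Returns ``(presence_vector, W~)``.  When all loci have identical
    effect rows only the presence-allele count matters and enumeration
    collapses to r = 0..L; otherwise all 2^L homozygotes are enumerated
    (guarded to L <= 20).  Ties are broken toward fewer presence alleles.
    """
    _check_guards(params)
    best_logw = -np.inf
    best = None
    for presence in _iter_residents(params):
        logw = log_geometric_mean_fitness(presence, params)
        if logw > best_logw:  # strict: first (fewest alleles) wins ties
            best_logw = logw
            best = presence
    return best, float(np.exp(best_logw))


def _effects_collapse(params: ModelParams) -> bool:
    """True if all loci are exchangeable (identical effect rows and dominance)."""
    M = params.M
    rows_equal = np.all(M == M[0:1, :])
    da, dc = params.dom.da, params.dom.dc
    return bool(rows_equal and np.all(da == da[0]) and np.all(dc == dc[0]))


def _iter_residents(params: ModelParams):
    """Representative homozygous residents (collapsed to counts when exchangeable)."""
    L = params.L
    if _effects_collapse(params):
        for r in range(L + 1):
            presence = np.zeros(L, dtype=np.int8)
            presence[:r] = 1
            yield presence
    else:
        if L > _MAX_ENUM_L:
            raise ValueError(
                f"exhaustive resident enumeration limited to L <= {_MAX_ENUM_L} "
                "for heterogeneous effect matrices"
            )
        order = sorted(range(2 ** L), key=lambda b: (bin(b).count("1"), b))
        for bits in order:
            yield np.array([(bits >> l) & 1 for l in range(L)], dtype=np.int8)


def mutant_growth_rate(resident: np.ndarray, locus: int,
                       params: ModelParams) -> InvasionResult:
    """Geometric-mean growth factor lambda~ of a rare one-locus mutant.

    The mutant is the resident with a heterozygote at ``locus``.  Exact
    over all herbivore subsets:

        log lambda~ = sum_E P(E) * log(1 - theta + theta * W_m(E) / W_r(E))
    """
    resident = np.asarray(resident, dtype=np.int8)
    if not 0 <= locus < params.L:
        raise IndexError(f"locus {locus} out of range [0, {params.L})")
    za_r, zc_r = _homozygote_traits(resident)
    za_m, zc_m = _heterozygote_traits(resident, locus, params)
    log_lam = 0.0
    for mask, prob in _environments(params):
        logw_r = _log_fitness_from_traits(za_r, zc_r, mask, params)
        logw_m = _log_fitness_from_traits(za_m, zc_m, mask, params)
        ratio = np.exp(logw_m - logw_r)
        log_lam += prob * np.log(1.0 - params.theta + params.theta * ratio)
    return InvasionResult(resident=resident, locus=locus,
                          lambda_tilde=float(np.exp(log_lam)))


def _resident_invadable(presence: np.ndarray, params: ModelParams,
                        collapsed: bool) -> bool:
    """Whether some one-locus mutant strictly invades this resident.

    When loci are exchangeable only one representative addition and one
    representative removal mutant need checking.
    """
    L = params.L
    if collapsed:
        r = int(presence.sum())
        loci = []
        if r < L:
            loci.append(int(np.flatnonzero(presence == 0)[0]))  # addition mutant
        if r > 0:
            loci.append(int(np.flatnonzero(presence == 1)[0]))  # removal mutant
    else:
        loci = range(L)
    return any(mutant_growth_rate(presence, l, params).invades for l in loci)


def polymorphism_possible(params: ModelParams) -> bool:
    """Whether every homozygous resident can be invaded by a one-locus mutant."""
    collapsed = _effects_collapse(params)
    return all(_resident_invadable(presence, params, collapsed)
               for presence in _iter_residents(params))


def simplified_condition(r: int, params: ModelParams) -> bool:
    """Closed-form invadability of the resident with r presence loci.

    Valid for theta = 1, a single herbivore, and identical per-locus
    effects m: the resident is invadable iff

        b(m*(r + da))^p * f(r + dc)   >  b(m*r)^p * f(r)      (addition)
     or b(m*(r - 1 + da))^p * f(r - 1 + dc) > b(m*r)^p * f(r) (removal)

    with only the defined mutant checked at r = 0 or r = L.  Serves as
    an independent cross-check of :func:`mutant_growth_rate`.
    """
    if params.theta != 1 or params.nh != 1:
        raise ValueError("simplified condition requires theta=1 and a single herbivore")
    if not _effects_collapse(params):
        raise ValueError("simplified condition requires identical effects and dominance across loci")
    if not 0 <= r <= params.L:
        raise ValueError(f"r must be in [0, {params.L}]")
    m = float(params.M[0, 0])
    da = float(params.dom.da[0])
    dc = float(params.dom.dc[0])
    p1 = float(params.p[0])
    bp: BenefitParams = params.benefit[0]

    def w_tilde(n_full: float, d_act: float, d_cost: float) -> float:
        b = benefit(m * (n_full + d_act), bp)
        return p1 * np.log(b) - params.c * (n_full + d_cost)

    logw_res = w_tilde(r, 0.0, 0.0)
    if r < params.L and w_tilde(r, da, dc) > logw_res:
        return True
    if r > 0 and w_tilde(r - 1, da, dc) > logw_res:
        return True
    return False


def dominance_scan(params: ModelParams, grid_step: float = 0.05) -> DominanceScan:
    """Polymorphism verdicts over a regular (da, dc) grid on [0, 1]^2.

    The same scalar dominance pair is applied to all loci in each cell.
    """
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide [0, 1]")
    values = np.linspace(0.0, 1.0, n + 1)
    poly = np.zeros((n + 1, n + 1), dtype=bool)
    from .model_core import DominanceParams

    for i, da in enumerate(values):
        for j, dc in enumerate(values):
            cell = params.replace(dom=DominanceParams.broadcast(da, dc, params.L))
            poly[i, j] = polymorphism_possible(cell)
    return DominanceScan(da_values=values, dc_values=values, polymorphic=poly)
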