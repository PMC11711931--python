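"""Stochastic individual-based forward simulation.

The population holds N diploid plants as an (N, L, 2) array of 0/1
alleles.  Time runs in discrete plant generations grouped into phases of
g generations; each herbivore is independently present for a whole phase
with probability p_i.  One generation consists of, in order:

1. fitness of all N adults under the phase's herbivore set,
2. F ~ Binomial(N, theta) breeding sites free up,
3. for each site a mother and a father are drawn independently with
   replacement, weights proportional to fitness (soft selection;
   incidental selfing allowed),
4. offspring formed by free recombination — one allele per locus drawn
   uniformly from each parent's two copies,
5. each offspring allele mutates (flips) independently with probability u,
6. F uniformly chosen adults die and the offspring take their sites.

theta = 1 gives a fitness-weighted Wright-Fisher generation; theta < 1
gives overlapping generations.  Parents are drawn from all N adults
alive at selection time; deaths are applied last and are independent of
fitness.  Mutation is germline-only (surviving adults never mutate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import allele_frequencies, diversity_summary
from .model_core import ModelParams, population_fitness

__all__ = [
    "HerbivoreSchedule",
    "PopulationState",
    "RunRecord",
    "draw_schedule",
    "initialize_population",
    "step",
    "run",
    "run_replicates",
    "run_neutral",
]

INIT_MODES = ("all-absent", "random-0.5", "fixed-frequency")


@dataclass(frozen=True)
class HerbivoreSchedule:
    """Per-phase herbivore presence: boolean array (n_phases, nh)."""

    presence: np.ndarray
    g: int

    def present_at(self, generation: int) -> np.ndarray:
        """Boolean herbivore mask for a given generation (phase = gen // g)."""
        return self.presence[generation // self.g]

    @property
    def n_phases(self) -> int:
        return self.presence.shape[0]


@dataclass
class PopulationState:
    members: np.ndarray  # (N, L, 2) int8
    generation: int = 0

    @property
    def N(self) -> int:
        return self.members.shape[0]


@dataclass
class RunRecord:
    """Observables of one simulation run.

    Mean fitness is recorded every generation (it is computed anyway);
    allele frequencies and diversity at the recording cadence plus the
    final generation.
    """

    generations: np.ndarray          # recorded generation indices
    pi: np.ndarray                   # (n_records, L) allele frequencies
    gamma: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mean_fitness: np.ndarray         # per generation, length T
    schedule: HerbivoreSchedule
    final_population: np.ndarray
    seed: int | None = None
    params: ModelParams | None = None

    @property
    def final_summary(self):
        return diversity_summary(self.pi[-1])

    def to_frame(self):
        """Recorded observables as a tidy pandas DataFrame."""
        import pandas as pd

        L = self.pi.shape[1]
        data = {"generation": self.generations, "gamma": self.gamma,
                "alpha": self.alpha, "beta": self.beta}
        for l in range(L):
            data[f"pi_{l + 1}"] = self.pi[:, l]
        return pd.DataFrame(data)


def draw_schedule(params: ModelParams, T: int, rng: np.random.Generator) -> HerbivoreSchedule:
    """Independent Bernoulli(p_i) presence per phase and herbivore for T generations."""
    if T < 1:
        raise ValueError("T must be >= 1")
    n_phases = -(-T // params.g)  # ceil
    presence = rng.random((n_phases, params.nh)) < params.p
    return HerbivoreSchedule(presence=presence, g=params.g)


def initialize_population(params: ModelParams, mode: str = "all-absent",
                          rng: np.random.Generator | None = None,
                          freq: float = 0.5) -> PopulationState:
    """Initial population: ancestrally undefended by default.

    Modes: ``all-absent`` (every allele 0), ``random-0.5`` (each allele
    a fair coin), ``fixed-frequency`` (each allele Bernoulli(freq)).
    """
    shape = (params.N, params.L, 2)
    if mode == "all-absent":
        members = np.zeros(shape, dtype=np.int8)
    elif mode == "random-0.5":
        members = _require_rng(rng).integers(0, 2, size=shape, dtype=np.int8)
    elif mode == "fixed-frequency":
        members = (_require_rng(rng).random(shape) < freq).astype(np.int8)
    else:
        raise ValueError(f"unknown init mode {mode!r}; choose from {INIT_MODES}")
    return PopulationState(members=members, generation=0)


def _require_rng(rng):
    if rng is None:
        raise ValueError("this init mode needs an rng")
    return rng


def step(state: PopulationState, present: np.ndarray, params: ModelParams,
         rng: np.random.Generator) -> float:
    """Advance the population by one generation in place.

    ``present`` is the length-nh boolean herbivore mask for this
    generation.  Returns the adults' mean fitness (recorded observable).
    """
    pop = state.members
    N = state.N
    w = population_fitness(pop, np.asarray(present, dtype=bool), params)
    wsum = w.sum()
    if wsum <= 0 or not np.isfinite(wsum):
        raise RuntimeError("cannot normalize selection weights: total fitness is zero")
    F = N if params.theta == 1.0 else rng.binomial(N, params.theta)
    if F > 0:
        # inverse-CDF sampling of both parents in one draw, weights prop. to fitness
        cdf = np.cumsum(w)
        parents = np.searchsorted(cdf, rng.random(2 * F) * cdf[-1])
        mothers, fathers = parents[:F], parents[F:]
        loci = np.arange(params.L)
        picks = rng.integers(0, 2, size=(2, F, params.L))
        gam_m = pop[mothers[:, None], loci[None, :], picks[0]]
        gam_f = pop[fathers[:, None], loci[None, :], picks[1]]
        offspring = np.stack([gam_m, gam_f], axis=2)
        if params.u > 0:
            flips = rng.random(offspring.shape) < params.u
            offspring = (offspring ^ flips).astype(np.int8)
        if F == N:
            state.members = offspring  # full replacement (Wright-Fisher)
        else:
            dead = rng.permutation(N)[:F]
            pop[dead] = offspring
    state.generation += 1
    return float(w.mean())


def run(params: ModelParams, T: int, seed: int | None = None, *,
        rng: np.random.Generator | None = None,
        init_mode: str = "all-absent", init_freq: float = 0.5,
        record_every: int = 5,
        schedule: HerbivoreSchedule | None = None) -> RunRecord:
    """Run one replicate for T generations and record observables.

    Reproducible: a given seed yields a bit-identical record.  A custom
    ``schedule`` (e.g. with a herbivore that only appears late) overrides
    the default Bernoulli phase draws.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    state = initialize_population(params, init_mode, rng, init_freq)
    if T > 0 and schedule is None:
        schedule = draw_schedule(params, T, rng)
    elif schedule is None:
        schedule = HerbivoreSchedule(np.zeros((1, params.nh), dtype=bool), params.g)

    rec_gens, rec_pi = [], []
    mean_w = np.empty(T)

    def _record():
        pi = allele_frequencies(state.members)
        rec_gens.append(state.generation)
        rec_pi.append(pi)

    _record()
    for t in range(T):
        mean_w[t] = step(state, schedule.present_at(t), params, rng)
        if state.generation % record_every == 0 or state.generation == T:
            _record()

    pi = np.array(rec_pi)
    q = 1.0 - (1.0 - pi) ** 2
    return RunRecord(
        generations=np.array(rec_gens),
        pi=pi,
        gamma=(pi > 0).sum(axis=1),
        alpha=q.sum(axis=1),
        beta=(2.0 * q * (1.0 - q)).sum(axis=1),
        mean_fitness=mean_w,
        schedule=schedule,
        final_population=state.members.copy(),
        seed=seed,
        params=params,
    )


def run_replicates(params: ModelParams, T: int, replicates: int,
                   base_seed: int, **kwargs) -> list[RunRecord]:
    """Independent replicates seeded base_seed + replicate index."""
    return [run(params, T, seed=base_seed + i, **kwargs) for i in range(replicates)]


def run_neutral(params: ModelParams, replicates: int, T: int,
                base_seed: int, *, records: bool = False, **kwargs):
    """Neutral control: all effects and costs zeroed, averaged end-state diversity.

    Returns the (gamma0, alpha0, beta0) reference triple averaged over
    replicates; mutation and drift alone shape the outcome.  With
    ``records=True`` the per-replicate RunRecords are returned instead.
    """
    neutral = params.replace(M=np.zeros((params.L, params.nh)), c=0.0)
    recs = run_replicates(neutral, T, replicates, base_seed, **kwargs)
    if records:
        return recs
    triples = np.array([r.final_summary.as_tuple() for r in recs])
    g0, a0, b0 = triples.mean(axis=0)
    return float(g0), float(a0), float(b0)
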