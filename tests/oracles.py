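"""Independent oracles used by the test suite.

The invasion verdict oracle iterates a deterministic one-locus diploid
recursion under Hardy-Weinberg random mating over a long randomized
herbivore-presence sequence, starting from a rare mutant allele.  It
shares no code with the analytic growth-factor machinery it checks.
"""

import numpy as np

from chemevol import Genotype, ModelParams, fitness


def recursion_env_fitnesses(resident: np.ndarray, locus: int, params: ModelParams):
    """Fitness of resident hom., heterozygote and mutant hom. in each herbivore subset.

    Returns arrays indexed by environment code (bitmask over herbivores).
    """
    resident = np.asarray(resident, dtype=int)
    dose_r = 2 * resident
    dose_h = dose_r.copy()
    dose_h[locus] = 1
    dose_m = dose_r.copy()
    dose_m[locus] = 2 * (1 - resident[locus])
    genos = [Genotype.from_dose(d) for d in (dose_r, dose_h, dose_m)]
    n_env = 2 ** params.nh
    W = np.zeros((3, n_env))
    for e in range(n_env):
        present = [i for i in range(params.nh) if (e >> i) & 1]
        for k, g in enumerate(genos):
            W[k, e] = fitness(g, present, params)
    return W  # rows: resident, heterozygote, mutant homozygote


def recursion_invades(resident: np.ndarray, locus: int, params: ModelParams,
                      rng: np.random.Generator, T: int = 50_000,
                      x0: float = 1e-6) -> bool:
    """Long-run verdict of the deterministic diploid recursion.

    Each generation draws the herbivore subset (per-phase Bernoulli with
    phase length g), computes Hardy-Weinberg genotype frequencies at the
    focal locus (other loci fixed as in the resident), and updates the
    mutant allele frequency by fitness-weighted reproduction among the
    replaced fraction theta of the population:

        x_off = x * (x*W_mm + (1-x)*W_het) / W_bar
        x'    = (1 - theta) * x + theta * x_off

    Invasion is scored as x_T > x_0.
    """
    W = recursion_env_fitnesses(resident, locus, params)
    n_phases = -(-T // params.g)
    present = rng.random((n_phases, params.nh)) < params.p
    codes = (present @ (1 << np.arange(params.nh))).astype(int)
    env_seq = np.repeat(codes, params.g)[:T]
    x = x0
    theta = params.theta
    for e in env_seq:
        w_rr, w_het, w_mm = W[0, e], W[1, e], W[2, e]
        wbar = x * x * w_mm + 2 * x * (1 - x) * w_het + (1 - x) * (1 - x) * w_rr
        x_off = x * (x * w_mm + (1 - x) * w_het) / wbar
        x = (1 - theta) * x + theta * x_off
    return x > x0


def recursion_invades_batch(cases, rng, T: int = 50_000, x0: float = 1e-6):
    """Vectorized recursion verdicts for a batch of single-herbivore cases.

    ``cases`` is a list of (resident, locus, params) with nh=1.  Each case
    gets its own randomized phase sequence.  Returns a boolean array.
    """
    n = len(cases)
    W = np.zeros((n, 3, 2))
    env = np.zeros((n, T), dtype=np.int8)
    theta = np.zeros(n)
    for k, (resident, locus, params) in enumerate(cases):
        assert params.nh == 1
        W[k] = recursion_env_fitnesses(resident, locus, params)
        n_phases = -(-T // params.g)
        codes = (rng.random(n_phases) < params.p[0]).astype(np.int8)
        env[k] = np.repeat(codes, params.g)[:T]
        theta[k] = params.theta
    x = np.full(n, x0)
    idx = np.arange(n)
    for t in range(T):
        e = env[:, t]
        w_rr, w_het, w_mm = W[idx, 0, e], W[idx, 1, e], W[idx, 2, e]
        wbar = x * x * w_mm + 2 * x * (1 - x) * w_het + (1 - x) * (1 - x) * w_rr
        x = (1 - theta) * x + theta * x * (x * w_mm + (1 - x) * w_het) / wbar
    return x > x0


def per_env_log_growth_sd(resident, locus, params) -> float:
    """Standard deviation of per-generation log growth of the rare allele.

    Used to require a detectable signal |log lambda~| before trusting a
    finite-sequence recursion verdict.
    """
    W = recursion_env_fitnesses(resident, locus, params)
    theta = params.theta
    logs, probs = [], []
    for e in range(W.shape[1]):
        present = [(e >> i) & 1 for i in range(params.nh)]
        prob = np.prod([params.p[i] if b else 1 - params.p[i]
                        for i, b in enumerate(present)])
        logs.append(np.log(1 - theta + theta * W[1, e] / W[0, e]))
        probs.append(prob)
    logs, probs = np.array(logs), np.array(probs)
    mean = (probs * logs).sum()
    return float(np.sqrt((probs * (logs - mean) ** 2).sum()))
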