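"""Experiment definitions: effect-size distributions, herbivory presets,
synergy calibration, random per-locus dominance, the herbivore-invasion
(screening) experiment, and the standard figure-style parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DiversitySummary
from .model_core import BenefitParams, DominanceParams, ModelParams
from .simulator import HerbivoreSchedule, run

__all__ = [
    "EffectDistribution",
    "ScreeningResult",
    "HERBIVORY_PRESETS",
    "preset_params",
    "draw_effect_matrix",
    "attract_probability",
    "calibrate_b0",
    "draw_random_dominance",
    "run_screening_experiment",
    "run_screening_sweep",
    "run_figure_sweep",
]


@dataclass(frozen=True)
class EffectDistribution:
    """Discrete distribution of per-locus, per-herbivore metabolite effects.

    ``only-repellent``: protective effects 0.2, 0.4, 0.6, 0.8, 1 with
    probability 0.1 each, neutral (0) with probability 0.5.
    ``repellent+attractive``: same protective part, plus attractive
    effects -0.2 .. -1 with probability 0.02 each, neutral 0.4.
    """

    name: str
    values: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if v.shape != p.shape:
            raise ValueError("values and probs must have the same length")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "probs", p)

    @classmethod
    def only_repellent(cls) -> "EffectDistribution":
        return cls("only-repellent",
                   np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]),
                   np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1]))

    @classmethod
    def repellent_attractive(cls) -> "EffectDistribution":
        return cls("repellent+attractive",
                   np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0,
                             -0.2, -0.4, -0.6, -0.8, -1.0]),
                   np.array([0.4, 0.1, 0.1, 0.1, 0.1, 0.1,
                             0.02, 0.02, 0.02, 0.02, 0.02]))

    @classmethod
    def constant_one(cls) -> "EffectDistribution":
        return cls("constant-1", np.array([1.0]), np.array([1.0]))

    @classmethod
    def by_name(cls, name: str) -> "EffectDistribution":
        table = {"only-repellent": cls.only_repellent,
                 "repellent+attractive": cls.repellent_attractive,
                 "constant-1": cls.constant_one}
        try:
            return table[name]()
        except KeyError:
            raise ValueError(f"unknown effect distribution {name!r}") from None


# The three herbivory regimes compared throughout: fluctuating presence
# with severe herbivory when present; constant presence with the same
# benefit curve; and constant presence with a high baseline escape
# probability (mild herbivory of similar long-run pressure).
HERBIVORY_PRESETS = {
    "fluctuating": dict(p=0.2, b0=0.0),
    "constant-high": dict(p=1.0, b0=0.0),
    "constant-low": dict(p=1.0, b0=0.8),
}


def preset_params(preset: str, base: ModelParams | None = None, **overrides) -> ModelParams:
    """ModelParams for a named herbivory preset, on top of defaults."""
    if preset not in HERBIVORY_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(HERBIVORY_PRESETS)}")
    cfg = HERBIVORY_PRESETS[preset]
    base = ModelParams() if base is None else base
    ben = BenefitParams(b0=cfg["b0"], ahalf=base.benefit[0].ahalf, s=base.benefit[0].s)
    return base.replace(p=cfg["p"], benefit=ben, **overrides)


def draw_effect_matrix(dist: EffectDistribution, L: int, nh: int,
                       rng: np.random.Generator) -> np.ndarray:
    """L x nh i.i.d. draws from an effect-size distribution."""
    idx = rng.choice(len(dist.values), size=(L, nh), p=dist.probs)
    return dist.values[idx]


def attract_probability(dist: EffectDistribution, nh: int) -> float:
    """Probability a locus attracts (negative effect on) at least one of nh herbivores."""
    if nh < 1:
        raise ValueError("nh must be >= 1")
    p_neg = float(dist.probs[dist.values < 0].sum())
    return 1.0 - (1.0 - p_neg) ** nh


def calibrate_b0(ahalf: float, s: float, target: float = 0.01) -> float:
    """Baseline intercept b0 such that the benefit at activity 0 equals ``target``.

    Solves b0 + (1 - b0) * sigma = target with sigma = 1/(1 + exp(s*ahalf)),
    the raw logistic at zero activity.  The result is negative whenever
    sigma > target; that is a legitimate intercept (benefit evaluation
    still guards positivity).
    """
    if not 0 < target < 1:
        raise ValueError("target escape probability must be in (0, 1)")
    sigma = 1.0 / (1.0 + np.exp(s * ahalf))
    if sigma >= 1.0:
        raise ValueError("degenerate benefit function: sigma = 1")
    return float((target - sigma) / (1.0 - sigma))


def draw_random_dominance(L: int, rng: np.random.Generator) -> DominanceParams:
    """Per-locus dominance: 2L independent Uniform(0, 1) draws (da and dc)."""
    return DominanceParams(rng.uniform(0, 1, L), rng.uniform(0, 1, L))


# ---------------------------------------------------------------------------
# Screening-hypothesis experiment: invasion of an additional herbivore
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of one herbivore-invasion run.

    ``pre_diversity`` averages the recorded diversity measures over the
    pre-invasion window; ``post_fitness`` is mean population fitness
    over the post-invasion window.
    """

    pre_diversity: DiversitySummary
    post_fitness: float
    nh_before: int


def run_screening_experiment(params: ModelParams, dist: EffectDistribution,
                             seed: int | np.random.Generator, *,
                             T_invasion: int = 5000, T_post: int = 500,
                             pre_window: int = 95,
                             record_every: int = 5) -> ScreeningResult:
    """Evolve under nh native herbivores, then introduce one more.

    ``params.nh`` native herbivores fluctuate throughout; a new herbivore
    with an independently drawn effect column joins the phase-presence
    process at generation ``T_invasion`` (which must fall on a phase
    boundary) and stays in play until ``T_invasion + T_post``.  Diversity
    is averaged over the last ``pre_window`` generations before invasion,
    fitness over the ``T_post`` generations after.
    """
    if T_invasion % params.g != 0:
        raise ValueError("invasion time must fall on a phase boundary")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nh_all = params.nh + 1
    M = draw_effect_matrix(dist, params.L, nh_all, rng)
    p_all = np.append(params.p, params.p[0])  # invader fluctuates like the natives
    ben_all = tuple(params.benefit) + (params.benefit[0],)
    full = params.replace(nh=nh_all, M=M, p=p_all, benefit=ben_all)

    T = T_invasion + T_post
    n_phases = -(-T // full.g)
    invasion_phase = T_invasion // full.g
    presence = rng.random((n_phases, nh_all)) < full.p
    presence[:invasion_phase, -1] = False  # invader absent before invasion
    schedule = HerbivoreSchedule(presence=presence, g=full.g)

    record = run(full, T, rng=rng, record_every=record_every, schedule=schedule)
    window = (record.generations >= T_invasion - pre_window) & \
             (record.generations <= T_invasion)
    pre = DiversitySummary(
        gamma=float(record.gamma[window].mean()),
        alpha=float(record.alpha[window].mean()),
        beta=float(record.beta[window].mean()),
        pi=record.pi[window].mean(axis=0),
    )
    post_fitness = float(record.mean_fitness[T_invasion:T].mean())
    return ScreeningResult(pre_diversity=pre, post_fitness=post_fitness,
                           nh_before=params.nh)


def run_screening_sweep(dist: EffectDistribution, seed: int, *,
                        nh_values=(1, 2, 5),
                        da_values=(0.0, 0.5, 1.0), dc_values=(0.0, 0.5, 1.0),
                        replicates: int = 5, base: ModelParams | None = None,
                        T_invasion: int = 5000, T_post: int = 500,
                        pre_window: int = 95) -> pd.DataFrame:
    """Screening experiment across herbivore numbers and a dominance grid.

    One row per scenario point, averaging replicates; columns include the
    pre-invasion diversity triple and post-invasion mean fitness.
    """
    base = ModelParams() if base is None else base
    ss = np.random.SeedSequence(seed)
    rows = []
    for nh in nh_values:
        for da in da_values:
            for dc in dc_values:
                params = preset_params(
                    "fluctuating", base, nh=nh,
                    M=np.ones((base.L, nh)),  # placeholder; redrawn per replicate
                    dom=DominanceParams.broadcast(da, dc, base.L),
                )
                results = []
                for _ in range(replicates):
                    rng = np.random.default_rng(ss.spawn(1)[0])
                    results.append(run_screening_experiment(
                        params, dist, rng, T_invasion=T_invasion,
                        T_post=T_post, pre_window=pre_window))
                rows.append({
                    "nh": nh, "da": da, "dc": dc, "replicates": replicates,
                    "pre_gamma": np.mean([r.pre_diversity.gamma for r in results]),
                    "pre_alpha": np.mean([r.pre_diversity.alpha for r in results]),
                    "pre_beta": np.mean([r.pre_diversity.beta for r in results]),
                    "post_fitness": np.mean([r.post_fitness for r in results]),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figure-style sweeps
# ---------------------------------------------------------------------------

# Escape probability at zero activity used to calibrate b0 in the synergy
# sweep: severe herbivory scenarios pin it at 0.01; the mild (constant-low)
# scenario keeps its high baseline escape probability of 0.8.
SYNERGY_TARGETS = {"fluctuating": 0.01, "constant-high": 0.01, "constant-low": 0.8}


def _spawned_rng(ss: np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(ss.spawn(1)[0])


def run_figure_sweep(figure: str, seed: int, *,
                     presets=("fluctuating", "constant-high", "constant-low"),
                     da_values=None, dc_values=None,
                     nh_values=(1, 2, 5), dists=("only-repellent", "repellent+attractive"),
                     ahalf_values=(0.0, 2.0, 4.0, 6.0),
                     replicates: int = 5, T: int = 5000,
                     base: ModelParams | None = None,
                     dominance_mode: str = "grid",
                     record_every: int = 5) -> pd.DataFrame:
    """Long-format results table for one of the standard experiment designs.

    ``fig2``: herbivory preset x dominance grid, one herbivore of unit
    effect — the dominance-reversal experiment.
    ``fig3``: preset x effect distribution x herbivore number x dominance
    grid — the interaction-diversity experiment.
    ``fig4``: preset x half-saturation sweep with b0 calibrated per
    preset x dominance grid — the synergy experiment.

    One row per (scenario point, replicate) with the end-state diversity
    triple; aggregate with pandas as needed.
    """
    base = ModelParams() if base is None else base
    if da_values is None:
        da_values = np.round(np.linspace(0, 1, 5), 3)
    if dc_values is None:
        dc_values = np.round(np.linspace(0, 1, 5), 3)
    ss = np.random.SeedSequence(seed)
    rows = []

    def _simulate(params: ModelParams, meta: dict):
        for rep in range(replicates):
            rec = run(params, T, rng=_spawned_rng(ss), record_every=record_every)
            fin = rec.final_summary
            rows.append({**meta, "replicate": rep, "gamma": fin.gamma,
                         "alpha": fin.alpha, "beta": fin.beta})

    if figure == "fig2":
        for preset in presets:
            for da in da_values:
                for dc in dc_values:
                    params = preset_params(preset, base,
                                           dom=DominanceParams.broadcast(da, dc, base.L))
                    _simulate(params, {"figure": "fig2", "preset": preset,
                                       "da": da, "dc": dc})
    elif figure == "fig3":
        if dominance_mode not in ("grid", "uniform-random"):
            raise ValueError("dominance_mode must be 'grid' or 'uniform-random'")
        grid = ([(da, dc) for da in da_values for dc in dc_values]
                if dominance_mode == "grid" else [(np.nan, np.nan)])
        for preset in presets:
            for dist_name in dists:
                dist = EffectDistribution.by_name(dist_name)
                for nh in nh_values:
                    for da, dc in grid:
                        for rep in range(replicates):
                            rng = _spawned_rng(ss)
                            M = draw_effect_matrix(dist, base.L, nh, rng)
                            dom = (draw_random_dominance(base.L, rng)
                                   if dominance_mode == "uniform-random"
                                   else DominanceParams.broadcast(da, dc, base.L))
                            params = preset_params(preset, base, nh=nh, M=M, dom=dom)
                            rec = run(params, T, rng=rng, record_every=record_every)
                            fin = rec.final_summary
                            rows.append({"figure": "fig3", "preset": preset,
                                         "distribution": dist_name, "nh": nh,
                                         "da": da, "dc": dc, "replicate": rep,
                                         "gamma": fin.gamma, "alpha": fin.alpha,
                                         "beta": fin.beta})
    elif figure == "fig4":
        s = base.benefit[0].s
        for preset in presets:
            target = SYNERGY_TARGETS[preset]
            for ahalf in ahalf_values:
                b0 = calibrate_b0(ahalf, s, target)
                ben = BenefitParams(b0=b0, ahalf=ahalf, s=s)
                for da in da_values:
                    for dc in dc_values:
                        params = preset_params(
                            preset, base,
                            dom=DominanceParams.broadcast(da, dc, base.L))
                        params = params.replace(benefit=ben)
                        _simulate(params, {"figure": "fig4", "preset": preset,
                                           "ahalf": ahalf, "b0": b0,
                                           "da": da, "dc": dc})
    else:
        raise ValueError(f"unknown figure id {figure!r}; choose fig2, fig3 or fig4")

    return pd.DataFrame(rows)
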