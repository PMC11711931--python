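# Methods

## The model

`chemevol` models the evolution of plant chemodiversity as
presence–absence polymorphism at `L` unlinked biallelic loci in a
diploid, randomly mating plant population of constant size `N`.  Each
locus controls production of one defense metabolite; allele 1 means the
metabolite is produced, allele 0 that it is not.  Metabolite `l` has an
effect `m_{li}` on herbivore `i` (positive = repellent, negative =
attractant), collected in the `L × n_h` effect matrix `M`.

**Antiherbivore activity.**  Activity against herbivore `i` is additive
across loci with dominance,

    a_i = Σ_l m_{li} · z_{a,l},   z_{a,l} ∈ {0, d_a(l), 1}

for genotypes 00 / 01 / 11 at locus `l`.  The heterozygote is unordered
(01 ≡ 10); only the allele dose matters.

**Benefit.**  When herbivore `i` is present, an individual escapes it
with probability given by a logistic benefit function

    b(a) = b0 + (1 − b0) / (1 + exp(−s · (a − a_half)))

`b0` is the baseline escape probability for strongly attracting
individuals, `a_half` the half-saturation activity, and `s` the
sensitivity.  Low `a_half` gives diminishing returns of additional
metabolites; high `a_half` makes metabolites synergistic (the joint
benefit exceeds the sum of single-metabolite benefits over most of the
range).  `b(a)` is interpreted as the fraction of fitness remaining
after attack; plants are never killed outright, so the model suits
insect rather than large mammalian herbivory.

**Cost.**  Metabolite production reduces fecundity multiplicatively,
`f(z_c) = exp(−c · z_c)` with cost trait `z_c = Σ_l z_{c,l}`,
`z_{c,l} ∈ {0, d_c(l), 1}`.  The exponential is well approximated by the
linear cost `1 − c·z_c` for moderate costs but can never go negative.
The two dominance coefficients are the model's central objects: `d_a`
scales the heterozygote's benefit, `d_c` its cost, and a *dominance
reversal* (`d_a > 0.5`, `d_c < 0.5`) makes heterozygotes enjoy most of
the protection at little of the cost.

**Fitness.**  All components multiply:
`W_t = Π_{i ∈ H_t} b(a_i) · f(z_c)` with `H_t` the set of herbivores
present in generation `t`.  Herbivore presence is phase-structured: time
is divided into phases of `g` generations and herbivore `i` is present
for a whole phase independently with probability `p_i`.

## Analytic invasion analysis

For a monomorphic homozygous resident, a rare mutant allele at one locus
resides almost exclusively in heterozygotes (random mating), whose
number grows per generation by `λ_t = 1 − θ + θ·W_m,t / W_r,t`, where θ
is the adult death probability (θ = 1: nonoverlapping generations).  The
mutant invades iff the geometric mean `λ̃` over the environment process
exceeds 1; `λ̃` is computed exactly in log space by enumerating all
`2^{n_h}` herbivore subsets with their Bernoulli probabilities (guarded
to `n_h ≤ 10`).  It is independent of phase length `g` and of the
ordering or autocorrelation of environments, a classical property of
geometric-mean-fitness criteria.

*Polymorphism scope.*  Polymorphism is scored possible when **every**
homozygous resident can be invaded by at least one single-locus mutant,
so no multilocus genotype can fix.  Residents are enumerated
exhaustively (`2^L`, guarded to `L ≤ 20`); when all loci are
exchangeable (identical effect rows and dominance), residents collapse
to presence-allele counts `r = 0..L` and only one representative
addition and removal mutant per resident needs checking.  For θ = 1, a
single herbivore and equal effects this reduces to the closed-form
pairwise comparisons of resident and one-step-mutant geometric mean
fitness, which the package implements separately as an independent
cross-check.  Multi-locus-step mutants are deliberately not analyzed
(they rarely arise at small mutation rates); for strongly synergistic
benefit functions this makes the analytic scope conservative relative to
simulations, where several segregating mutations can jointly invade.

*Numerical choices.*  Invasion uses strict `λ̃ > 1`; the neutral case
`λ̃ = 1` (e.g. `d_a = d_c = 0`, a phenotypically silent mutant) is
scored non-invasion, since drift decides it.  Ties in the optimal
homozygote search are broken toward fewer presence alleles, which is
deterministic and biologically conservative.  The dominance scan runs a
21×21 grid by default (step 0.05, a config knob) and reports the
percentage of grid cells where polymorphism is possible.

*A resolution caveat.*  Under the fluctuating preset the analytic
coexistence region extends beyond the dominance-reversal quadrant while
excluding a thin sliver of it just above the diagonal near
`(d_a, d_c) = (0.5, 0.5)` — at step 0.05 that sliver falls between grid
points (all strict-quadrant cells have `d_a − d_c ≥ 0.1`), so exhibiting
the exclusion requires refining the scan locally (step ≤ 0.01).

## Individual-based simulation

The simulator holds the population as an `(N, L, 2)` array of alleles.
Each generation, in order: (1) fitness of all N adults under the phase's
herbivore set; (2) `F ~ Binomial(N, θ)` sites free up; (3) for each site
a mother and father are drawn independently with replacement,
probability ∝ fitness (soft selection; incidental selfing allowed);
(4) offspring formed by free recombination, one allele per locus
uniformly from each parent's two copies; (5) each offspring allele flips
with probability `u` (germline-only mutation); (6) F uniformly chosen
adults die and are replaced.  Parents are drawn from all N adults alive
at selection time, including those subsequently killed, because deaths
come last and are fitness-independent.  θ = 1 is a fitness-weighted
Wright–Fisher generation.

Populations start ancestrally undefended (all-absent) by default; with
`2NLu ≈ 1` new mutations per generation and the standard 5000
generations this reaches stationarity (alternative starts are a config
switch).  Each replicate uses one RNG stream seeded `base_seed +
replicate` (sweeps use spawned seed sequences); a given seed reproduces
a run bit-identically.  Mean fitness is recorded every generation;
allele frequencies and diversity every `record_every` generations
(default 5, which is what makes a 95-generation pre-invasion averaging
window exactly 20 records) plus the final generation.

## Diversity measures

With `π_l` the presence-allele frequency: γ counts loci with `π_l > 0`
(a single copy counts); α = `Σ_l [1 − (1 − π_l)²]` is the expected
number of metabolites per individual under Hardy–Weinberg proportions;
β = `Σ_l 2 q_l (1 − q_l)` with carrier probability
`q_l = 1 − (1 − π_l)²` is the expected number of metabolites possessed
by exactly one of two random individuals.  `empirical_diversity`
recomputes α and β by direct counting on the raw population and serves
as an oracle for the estimator forms (random mating justifies HW).  A
locus is called polymorphic when `0.1 ≤ π_l ≤ 0.9`, bounds inclusive
(boundary atoms have probability ≈ 0).

## Standard experiments

*Herbivory presets* — fluctuating (`p = 0.2, b0 = 0`), constant-high
(`p = 1, b0 = 0`), constant-low (`p = 1, b0 = 0.8`): constant presence
but a high baseline escape probability, giving long-run herbivory
pressure comparable to the fluctuating preset.

*Effect-size distributions* — "only-repellent": protective effects
{0.2, 0.4, 0.6, 0.8, 1} with probability 0.1 each, neutral with 0.5;
"repellent+attractive": same protective part plus attractive effects
−{0.2 .. 1} with probability 0.02 each, neutral 0.4.  Entries are drawn
independently per locus, herbivore and replicate.  The probability that
a locus attracts at least one of `n_h` herbivores is
`1 − 0.9^{n_h}` (0.1, 0.19, 0.41 for 1, 2, 5 herbivores).

*Synergy calibration* — for a sweep over `a_half` the baseline `b0` is
solved so that an individual of zero activity has a fixed escape
probability when the herbivore is present:
`b0 = (target − σ)/(1 − σ)` with `σ = 1/(1 + exp(s·a_half))`.  The
calibrated `b0` is negative whenever `σ > target`; that is a legitimate
intercept, and benefit evaluation raises an error if a strongly
attracting genotype would push the realized benefit to ≤ 0 (impossible
in repellent-only scenarios, where activities are nonnegative).  The
target is 0.01 for the fluctuating and constant-high presets.  For the
constant-low preset the calibration target is taken as 0.8, its
baseline escape probability, preserving that preset's mild-herbivory
character across the sweep; pinning all presets to 0.01 would make
constant-low identical to constant-high.

*Screening (herbivore invasion) experiment* — `n_h` native herbivores
fluctuate for `T_invasion` generations; a new herbivore with an
independently drawn effect column then joins the phase-presence process
(same `p` as the natives) until `T_invasion + T_post`.  Reported are
diversity averaged over the last 95 generations before invasion and
mean population fitness over the `T_post` generations after.

## Test and verification scales

The verification suite checks closed forms at machine precision
(1e-12 for algebraic identities; printed three-decimal constants at
1e-3), and checks the analytic invasion verdict against an independent
deterministic diploid recursion (Hardy–Weinberg genotype frequencies,
fitness-weighted reproduction of the replaced fraction θ, iterated from
allele frequency 1e-6 over 50 000 randomized generations; draws whose
`|log λ̃|` is below six standard errors of the sequence's per-generation
log growth are redrawn as undecidable at that sequence length).

Simulation trend checks run at deliberately reduced scale chosen once:
the polymorphic/non-polymorphic β contrast at `N = 500, T = 1500`,
3 replicates; the synergy sweep at `N = 250, u = 2·10⁻⁴` (halving N
while doubling u keeps the population-scaled mutation input `2NLu` at
its standard value), `T = 1500`, a 5×5 dominance grid; the screening
sweep at `T_invasion = 1000, T_post = 300`; the herbivore-number sweep
at `N = 500, u = 10⁻⁴, T = 2000`, a 5×5 dominance grid and 2
replicates.  The neutral control compares 100 replicates of the standard
model with all effects and costs zeroed against 100 runs of the
dedicated neutral path at `N = 200, T = 800` (Kolmogorov–Smirnov on
end-state α).

What these scaled runs show is that the package reproduces the model's
qualitative structure — where polymorphism is maintained, how diversity
responds to herbivore numbers, synergy and new enemies — not the exact
diversity levels of any full-scale run, which depend on `N`, `T` and
grid resolution.

## Known limitations

- The between-individual diversity (β) response to herbivore number is
  the one expectation the verification suite does not confirm: averaged
  over the dominance plane, β is flat to slightly decreasing in the
  number of herbivores in our runs (the corresponding trend test fails
  by design rather than being weakened), although β does increase with
  herbivore number inside the strong-reversal corner of dominance
  space, and the per-individual (α) and population-total (γ) increases
  are robust.  Averages over the dominance plane are sensitive to grid
  resolution and weighting, so full-plane summaries should be read with
  that in mind.

- The generator emulates the model world exactly as specified — it is
  not a model of any real plant population: no seed bank, no spatial or
  neighborhood (associational) effects, no herbivore population dynamics
  or coevolution, constant N, and a direct genotype→metabolite map with
  no pathway structure.  Conclusions about real chemodiversity therefore
  rest on the model's assumptions, not on these tests.
- The analytic machinery requires enumerable residents; for
  heterogeneous effect matrices it enumerates all `2^L` homozygotes
  (practical to `L ≈ 16–20`) and makes no claim of matching any
  published pattern there.
- Heterozygous-input geometric mean fitness has no invasion
  interpretation (the growth criterion applies to true-breeding
  homozygotes); the function computes it but warns.
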