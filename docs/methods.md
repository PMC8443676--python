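# Methods

`plasmidsim` models the ecology of *parasitic* plasmids — mobile genetic
elements that burden their host and persist only through infectious
transfer — across three population scales, and fits the resulting
plasmid-count distributions to genome collections.  This note records the
models, the numerical choices, and what the synthetic-data generator does
and does not establish.

## 1. Single-plasmid chemostat models

State variables: plasmid-free cells ρ, plasmid-bearing cells ρ_p,
nutrient C, and (transformation only) free plasmids P.  Nutrient is
supplied at rate S (nutrient/time); cells grow at αC (plasmid-free) or
(1−Δ)αC (plasmid-bearing, cost Δ ∈ [0,1)); all cells die at rate δ; at
each division of a carrier the new daughter is plasmid-free with
probability p_ℓ.

**Conjugation** transfers plasmids by cell–cell contact at mass-action
rate γ_c:

    dρ/dt   = αCρ − γ_c ρ ρ_p + p_ℓ(1−Δ)αCρ_p − δρ
    dρ_p/dt = (1−Δ)αCρ_p + γ_c ρ ρ_p − p_ℓ(1−Δ)αCρ_p − δρ_p
    dC/dt   = S − αCρ − (1−Δ)αCρ_p

**Transformation** releases n_eff viable free plasmids per cell death,
which decay at δ_p and infect at γ_t (replace γ_c ρ ρ_p by γ_t ρ P and
add dP/dt = n_eff δ ρ_p − γ_t ρ P − δ_p P).

The plasmid-free equilibrium is ρ* = S/δ, C* = δ/α.  Linearizing there
gives the invasion thresholds

    conjugation:     γ_c ρ* > δ (Δ + p_ℓ(1−Δ))
    transformation:  γ_t ρ* > δ_p (Δ + p_ℓ(1−Δ)) / (n_eff − Δ − p_ℓ(1−Δ))

with equality treated as non-invading.  If n_eff does not exceed the
total replication deficit, the transformative plasmid can never invade
and the solver returns an infinite sentinel.

**Copy number.** With per-copy cost Δ_p, cost scales as Δ = Δ_p·n_p and
random segregation gives p_ℓ = 2^(1−n_p).  The conjugative invasion
barrier δ(Δ_p n_p + 2^(1−n_p)(1−Δ_p n_p)) has an interior minimum:
conjugative parasites are optimized at moderate copy number.  The
optimum is reported over integers n_p ≥ 1 (ties to the smaller value;
plasmid counts are discrete), with the continuous minimizer available as
a diagnostic.  For transformation, n_eff = p_v·n_p makes the invasion
condition monotone in n_p up to the budget, so the optimum is
n_p = 1/Δ_p — the host's growth is driven to zero and the element
behaves like a phage; it requires p_v > Δ_p, else the sentinel.

**Equilibria and phase diagrams.** The plasmid-only state is closed-form
for p_ℓ = 0 (C = δ/((1−Δ)α), ρ_p = S/δ, plus P = n_eff δ ρ_p/δ_p);
interior (coexistence) equilibria are closed-form for conjugation
(ρ_p = S/(δΔ) − δ/γ_c) and reduced to a bracketed scalar root in P for
transformation; finite p_ℓ uses multi-start Newton root-finding seeded
from the p_ℓ = 0 forms and from a long integration endpoint.  An
equilibrium is reported only if it zeroes the right-hand side to 1e-10.
Stability comes from the eigenvalues of hand-derived analytic Jacobians
(cross-checked against central differences in the tests); "stable" means
all real parts < −1e-8, a leading real part within ±1e-8 of zero is
flagged marginal.  Grid labels: `bistable` if plasmid-free and
plasmid-only are both stable, else `coexistence` if a stable interior
state exists, else the unique stable boundary state.  The analytic
stability boundaries behind these labels are numerical reconstructions,
not closed-form expressions.  Phase diagrams default to a linear Δ axis
on (0,1) and a log transfer-rate axis, with p_ℓ = 0 (the case where
segregation loss is negligible relative to the fitness burden).

**Integration.** Classical fixed-step RK4, default step 0.01 time units.
Steady state is declared when max_i |dx_i/dt| / max(max_j |x_j|, 1e-12)
< 1e-9; the normalization is global across components because a
component decaying exponentially to zero has a constant *per-component*
relative derivative and would never converge under a per-component
criterion.  Components dipping below zero by less than 1e-12 are clipped
to zero; larger undershoots raise (step too large).

## 2. Co-infection of m compatible types

Plasmid types from distinct incompatibility groups segregate and
transfer independently.  The cost of carrying k types is multiplicative,
Δ_tot(k) = 1 − (1−Δ)^k, or additive k·Δ clamped at 1 (the clamp keeps
the growth rate nonnegative).  The full model tracks every subset of
types (2^m + 1 equations, capped at m ≤ 12): a dividing class produces
one new cell that retains each parental type independently with
probability 1−p_ℓ (binomial redistribution — the natural generalization
that reduces exactly to the single-plasmid model at m = 1), and a cell
lacking type i gains it at γ_c times the total density of carriers of i
(one type per transfer event).  For identical types at symmetric
abundances this collapses exactly — not approximately — to m + 2
equations over the number of carried types, with promotion rate
γ_c (m−k) x_k D, D = Σ_j x_j j/m; the full/reduced equivalence is the
internal consistency check for the reconstruction, since the subset
system's printed form was not available.

Steady-state type-count distributions start from the plasmid-free state
with a 1e-6·ρ* inoculum per single-type class and integrate to the
steady-state criterion above (error if not reached by t = 1e5).  At low
cost the distribution approaches Binomial(m, p̂) with p̂ the
single-plasmid infected fraction; the exact Poisson-binomial is computed
by iterative convolution.  Mean host fitness E[1−Δ_tot(k)] decreases
strictly with m at fixed relative transfer rate — the single-population
tragedy of the commons.

## 3. Wright–Fisher metapopulation

N demes each carry one population with i unique plasmid types and
fitness w_i = 1 − Δ_tot(i).  Each epoch, all N demes are synchronously
replaced by one multinomial draw of size N with

    p_0 = n_0 w_0 (1−q) / Σ n_j w_j
    p_i = (n_i w_i (1−q) + n_{i−1} w_{i−1} q) / Σ n_j w_j   (i > 0)

where q is the per-epoch probability that a lineage is invaded by one
new compatible type (within-epoch ecology is assumed fast and absorbed
into q).  Epistasis forms: `none` Δ_tot = 1−(1−Δ)^i; `positive`
Δ_tot = Δ for i > 0 (plasmids beyond the first are cost-free);
`negative` Δ_tot = 1−(1−Δ)^(i^1.5); `power` Δ_tot = 1−(1−Δ)^(i^a); or a
custom table.

The infinite-N stationary distribution is the fixed point of the
resampling kernel: with w_0 = 1 and f_0 > 0, the mean fitness is
W̄ = (1−q) and

    f_i = f_{i−1} w_{i−1} q / ((1−q)(1 − w_i)),   i ≥ 1.

This requires a strictly positive cost for every i ≥ 1 and a convergent
tail (for the constant-cost form, q < Δ up to the (1−q)/(1−Δ) factor).
Under positive epistasis consecutive ratios are exactly constant —
an exponential tail; `none` is Poisson-like; `negative` is
sub-Poissonian.  The truncation support auto-extends until the dropped
tail mass is below 1e-15 so that the fixed-point residual of the
returned vector is comfortably below 1e-12 (a looser 1e-10 tail leaves a
truncation artifact of the same order).  A generalized solver accepts
arbitrary cost and invasion functions of i, with
f_i = f_{i−1} w_{i−1} q_{i−1} / (w_0(1−q_0) − w_i(1−q_i)); an
exponential results whenever invasion and cost stay comparable across i,
so invasion epistasis alone can mimic cost epistasis.

**Finite-N caveat.** The recursion is the deterministic infinite-N fixed
point, validated against stochastic simulation in the large-N regime
(time-averaged TV ≈ 0.008 at N = 10,000 and 0.003 at N = 100,000 over
20,000 epochs).  At N ~ 1000 with Δ = 0.01, q = 0.005 the plasmid-free
class is nearly neutral (its selective advantage per epoch is O(Δ−q)),
so the class-0 fraction performs a slow random walk (stationary sd
≈ 0.16) and its extinction — which the model makes absorbing, since
plasmids are never lost — triggers unbounded runaway.  Finite-N time
averages therefore do not converge on the analytic distribution at that
scale, and the corresponding stochastic-agreement check in the
acceptance suite is expected to fail at N = 1000 while passing at
N = 10,000.

Simulation details: one seeded `numpy` generator, consumed by exactly
one multinomial draw per epoch; draws overflowing the i_max cap are
folded into the top class (warned once); invasion at i_max folds back,
conserving mass.

## 4. Fitting histograms

Observed plasmid-count histograms are truncated to bins with ≥ 10
observations (boundary inclusive); observed probabilities keep the
*full* histogram total as denominator, and model probabilities are the
stationary f without renormalization over the retained bins — the two
sides are treated symmetrically, preserving the empirical scale.  The
objective is the sum of squared differences of log probabilities,
minimized by bounded trust-region least squares over log10 Δ and
log10 q (and log10 a for the power form), Δ, q ∈ [1e-6, 0.5],
a ∈ [1e-6, 3], from 10 Latin-hypercube starts (seeded).  The small-a
floor lets the power family numerically reach its constant-cost limit,
so the power fit nests the positive fit; power fits additionally start
from the positive-form solution.  Parameter draws without a convergent
stationary tail receive a large penalty residual.  Histograms store
counts as nonnegative reals so exact expected counts can be fitted
noiselessly; fewer than three retained bins is an error
(under-determined).

In the strong-positive-epistasis regime the objective is nearly flat
along (Δ, q) scalings and only the ratio q/Δ is individually estimable;
this is detected from the Gauss–Newton Hessian (smallest eigenvalue
< 1e-6 of the largest) and flagged on the result.  On synthetic
genome-scale draws (17,725 genomes) the ratio is recovered to within a
few percent; exact expected-count input recovers it to ~1e-14.

## 5. Genome tables and synthetic data

The genome pipeline consumes a flat TSV surrogate for an assembly
summary (columns `assembly_accession`, `replicon_name`, `replicon_role`,
`length_bp`, `genus`).  Completeness requires a chromosome strictly
longer than 0.5 Mb (0.5e6 bp); the plasmid count is the number of
replicons whose role is "plasmid", matched case-insensitively on the
role column only; genus exclusion is case-insensitive exact matching; a
cas-positive genome has at least one profile-HMM hit with E-value
strictly below 1e-30.  No length floor is applied to plasmid replicons.

The generator emulates the statistical structure of such a collection
without any sequence content: per-genome counts are i.i.d. draws from a
chosen stationary distribution (defaults Δ = 9.8e-3, q = 5.4e-3 under
positive epistasis — the regime a genome-wide collection exhibits);
chromosomes are 1–6 Mb, plasmids log-uniform 2–200 kb, an optional
incomplete fraction gets a 100–450 kb chromosome (lengths matter only to
the 0.5 Mb filter); genus labels are drawn from a weighted pool skewed
toward heavily sequenced genera; cas carriage is Bernoulli with a
constant (or count-dependent) probability, true hits get E-values in
[1e-60, 1e-31] and decoys in [1e-29, 1e-5].  Everything is deterministic
per seed, and a JSON sidecar records the ground truth.

What a green round-trip establishes: the parsing, filtering, tallying,
stratification and fitting stages are exact and unbiased on data whose
generating process is known.  What it does not establish: anything about
real genome collections — sampling biases, mislabeled replicons,
assembly chimeras, phylogenetic correlation between genomes (the
generator draws genomes independently) and within-genus structure are
all absent by construction.

## 6. Known limitations

- Deterministic ODEs only: no demographic noise or extinction in the
  chemostat models; copy-number dynamics enter only through the Δ, p_ℓ,
  n_eff scalings.
- Compatible plasmids only; incompatibility-group competition is out of
  scope.
- The Wright–Fisher model has no plasmid-loss move, so the plasmid-free
  class is not renewable in finite populations (see the finite-N caveat).
- Fits report point estimates plus the identifiability flag; no
  uncertainty quantification beyond that.
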