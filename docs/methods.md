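# Methods

This note records the models and estimators the package implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic test-beds do and do not establish.

## The incoherence statistic

Given `K` trials over a common outcome space, each trial is reduced to an
entropy `H_k`, the merged trials to a pooled entropy `H̃`, and the space to a
maximum entropy `Hmax`.  Incoherence is

    I² = Σₖ wₖ (H̃ − H_k)² / (H̃ · Hmax),

with uniform weights `wₖ = 1/K` by default (non-uniform weights are accepted
throughout but are not used by any of the shipped studies).  Design intent,
in brief: the second moment of the entropy gaps over-weights outlier trials;
dividing by `Hmax` makes the measure invariant to the size of the state
space; dividing by `H̃` boosts divergence in ordered (low-entropy) ensembles,
where disagreement between trials is more surprising.  The variants
`T = I·√(H̃/Hmax)` and `L = I·√Hmax` drop one normalization each and are
reported for comparison.

Degenerate conventions (all chosen so that "every trial is the same point
mass" reads as perfect coherence):

* `H̃ = 0` (tolerance 1e−12) ⇒ `I = L = 0`.  This is forced by internal
  consistency: an ensemble of identical minimum-entropy trials must sit at
  the measure's lower bound, and the ordered cellular-automaton rule 0 must
  measure exactly 0.
* `Hmax = 0` (single-state space) ⇒ `I = T = 0`.
* `I` is clamped into `[0, 1]`; floating error alone can exceed 1 by ~1e−16.

Member entropies may exceed the pooled entropy (one uniform trial among many
point masses), so no ordering between `H_k` and `H̃` is assumed anywhere.

Worked anchors used as fixed tests: the pair `{[0.9,0.1,0,0,0],
[0.8,0.2,0,0,0]}` gives `H̃ = 0.6`, `D_JS = 0.014`, `I = 0.107`; the pair
`{[0.2×5], [0.4,0,0.2,0.2,0.2]}` gives `H̃ = 2.2`, `D_JS = 0.125`,
`I = 0.103`; `{[½,½],[1,0]}` gives `I = 0.654`; identity matrices of any
size give `I = 1` exactly.

One nuance: for the max-entropy-vs-min-entropy pair padded to `x` states,
`I` is *near*-invariant, not exactly invariant — the closed form drifts from
0.6539 at `x = 2` to 0.6441 at `x = 10`.  Tests assert a 0.011 band around
0.654 rather than exact equality.

## Entropy estimators

**Discrete.**  Shannon entropy in bits (base-2 logs everywhere), zero terms
contributing zero, `Hmax = log2(n_states)`.  Ensembles require a shared,
consistently ordered state space; the file reader reconciles ragged inputs by
taking the union of observed labels and zero-filling, which is what makes
the pooled (element-wise mean) distribution well defined.

**Continuous.**  An observation set is reduced to a density profile
`g_j = (1/N) Σᵢ exp(−k·|r_j − o_i|)` at `R` reference points evenly spaced
over a fixed range, *including both endpoints* (the estimator's definition
only requires even spacing; endpoint inclusion is this package's convention
and is covered by the brute-force oracle test).  Defaults `R = 100`,
`k = 100`, range `[0, 1]`; inputs are affinely normalized onto the range
using the ensemble-wide min/max so all members share one scale (an
all-identical ensemble maps to 0.5 by convention and measures as perfectly
ordered and coherent).  The *population* variance of the profile is then
mapped onto entropy:

    H = 1 − (Var(G) − V0) / (V1 − V0), clamped into [0, 1], Hmax = 1.

`V0` and `V1` are the calibration anchors: the profile variance of the
maximum-entropy reference (a uniform spread of observations) and of the
minimum-entropy reference (all observations identical).  The package derives
both **from the estimator's own extremal profiles** under the configured
grid, kernel and range: `V0` from the analytic infinite-sample uniform
density `g(r) = (2 − e^{−k(r−lo)} − e^{−k(hi−r)})/(kW)`, and `V1` from a
point mass at the range midpoint.  Self-calibration makes the estimator
exactly self-consistent — a uniform sample measures `H ≈ 1`, a point mass
`H = 0` — and it is what delivers the cross-domain agreement the measure
promises: five point-mass plus five uniform trials measure `I ≈ 0.65`,
matching the discrete `{[½,½],[1,0]}` analogue's 0.654.  Published constants
for this estimator family exist but follow an internal convention that is
not reproducible from the formula alone and is mutually inconsistent with
it (with those constants the estimator saturates at `H = 1` for broad input
families and the cross-domain anchor lands at 0.707 instead of 0.65);
explicit `v0`/`v1` overrides remain available on
`ContinuousEntropyConfig` for anyone wanting a different calibration.

Known consequences of this estimator: point masses anywhere in the range
measure `H = 0` (profiles of boundary or on-grid point masses have variance
at or above `V1` and clamp); small samples from a smooth distribution
measure slightly below 1 due to sampling noise in the profile; and a
continuous "identity matrix" of `x` point-mass trials at distinct levels
only approaches `I = 1` once `x` is large enough for the pooled profile to
smooth out (above ~0.9 from `x = 20`; ensembles of six or fewer trials are
bounded visibly below 1, so sampling with more than six trials is advised).

**Comparators.**  KL, Hellinger, total variation and 1-Wasserstein distances
are computed member-vs-pooled and averaged, mirroring how the Jensen–Shannon
divergence relates members to the pool (the reduction is this package's
choice; the original plots do not state one).  Discrete Wasserstein uses
unit-spaced state indices as coordinates.  The χ² contingency test receives
the probability rows multiplied by 10 and used as (possibly fractional)
weights without rounding, with all-zero state columns dropped; ANOVA and
Kruskal–Wallis act on the raw observation sets.  Degenerate inputs (constant
data, empty tables) yield absent (`None`/`NaN`) p-values rather than errors.

## Baseline cases

Six deterministic discrete constructions (shape sweep between identical and
disjoint pairs, identity matrices, one uniform among `x` point masses,
duplicated pairs, max-vs-min and disjoint state padding) and six stochastic
continuous ones (Gaussian mean- and spread-outliers among 12 i.i.d. trials,
three shrinking uniforms, 20 Gaussians at `x` observations each, a continuous
identity matrix at levels `i/x`, and `x` point-mass plus `x` uniform trials).
Stochastic cases default to `M = 50` repeats with per-repeat seeds
`seed + repeat`, reporting mean ± sd of every measure; continuous trials
default to `N = 1000` observations (the studies leave `N` unstated except
where it is the swept variable; 1000 keeps profile sampling noise well below
the effects being measured).  All three uniforms in the shrinking-width case
share one fixed `N`.

## Erdős–Rényi ensembles

Standard `G(n, p)` plus a systemically randomized variant: one
`r ~ U(0, 1)` per graph, effective edge probability `p(1−q) + rq`.  Trial
streams are `seed + trial_index`; sweep grid points get separate seed blocks.
Degree distributions live on the fixed space `0..n−1` so pooling is well
defined; connectivity is the binary one-hot state (graphs with isolated
nodes count as disconnected).  Study sizes: 50 nodes × 100 trials for degree
sweeps (mean `I ≈ 0.066`, flat across `p ∈ [0.1, 0.9]`, exactly 0 at
`p ∈ {0, 1}`); 100 nodes × 200 trials for the connectivity transition, whose
incoherence peak falls within 0.02 of `ln(100)/100 ≈ 0.046` with roughly
half the graphs connected at the peak.  The noise level behind the published
"markedly higher" modified-model value is unstated, so system noise is
treated qualitatively: at `q = 0.5` incoherence is more than double the
standard model's at matched `p`.

## Cellular automata

All 256 elementary rules, periodic boundaries, row 0 the initial condition.
The stable window keeps rows strictly after the midpoint (`index > T/2`) so
transients are excluded; the full window is available.  Orientations:
`column` (fixed cell through time), `diagonal` / `diagonal_left` (cell index
shifting ±1 per step with wrap — constant along a travelling stripe), and
`diagonal_both` for sweeps (measures averaged over the two directions, since
rule 226's stripes travel either way depending on the initial density).  The
per-sample scalar entropy is the mean over cells of per-cell entropies
(cells are distinguishable, like labeled graph nodes); the pooled entropy
averages the per-cell distributions across samples first.  The alternative
reduction (per-cell incoherences, then mean) is not the default.

Grid sizes behind the published rule snapshots are unprinted; this package
fixes `n = 100` cells, `T = 200` steps, `K = 10` samples, initial density
`p = 0.5` (each cell independently 1 with probability `p`) and ties all its
checks to those defaults.  Under them: rule 0 gives `I = 0` exactly (the
`H̃ = 0` convention), rule 30 gives `I ≈ 0.01`, rule 218 gives `I ≈ 0.53`
column-wise (reported against a ≥ 0.3 acceptance bar since the original
dimensions are unknown), and rule 226's density sweep peaks at `p = 0.5`
(`I ≈ 0.79` under `diagonal_both`) while dominating rules 0 and 30
everywhere.

## Daisyworld

The grid port follows the canonical NetLogo update rules, all constants
exposed as config fields: 29×29 toroidal world; absorbed flux
`l·(1 − albedo)` (daisy albedo if occupied, else surface 0.4); local heating
`72·ln(absorbed) + 80`, or 80 when nothing is absorbed; halfway temperature
relaxation; diffusion of 50% of each cell's temperature split equally among
its 8 neighbors; seeding probability `0.1457·T − 0.0032·T² − 0.6443` clamped
to `[0, 1]` (optimum near 22.5 °C); maximum age 25; default species black
(albedo 0.25) and white (0.75) at 20% of cells each.  A daisy-free world
therefore converges to the closed-form fixed point
`72·ln(l·(1 − 0.4)) + 80`, which the tests verify to < 0.1 °C.

Choices where the port was genuinely open: initial ages are uniform on
`0..max_age−1` so the founding cohort does not die in one synchronized wave;
seeding is processed in a random order each tick (a cell claimed earlier in
the tick blocks later seeders) to avoid scan-order bias; mutated offspring
shift their albedo by `U(−0.05, +0.05)` clamped to `[0, 1]` (the
perturbation's distribution is unstated upstream; uniform with a small scale
is the minimal choice); plague victims are removed before the next
absorption step, so their cells cool from the following tick.

Luminosity sweeps run `K = 20` trials × 500 ticks per luminosity, varying
only initial placement, and measure the final-step temperature sets (841
values per trial, jointly normalized).  With seed 0 over 25 luminosities in
`[0.45, 1.35]`: a dead plateau (`I = 0`) below `l ≈ 0.5`; a sharp bifurcation
peak (`I ≈ 0.50`) near `l ≈ 0.53` where trials split between dead and
black-colonized worlds; a self-regulated black plateau (`I ≈ 0`, mean
temperature pinned near the growth optimum); a second local maximum
(`I ≈ 0.15`) near `l ≈ 0.75` at the black-to-mixed transition; a low mixed
plateau; and rising incoherence again past `l ≈ 1.3` as the world
destabilizes.  The exact tipping luminosities depend on unprinted upstream
parameters, so tests assert this qualitative structure (≥ 2 interior peaks,
plateaus below a third of the peak) rather than exact locations.

## What the synthetic studies do not show

All validation inputs are generated by the package itself; none involve
measured data.  The continuous cases use smooth, unimodal (or uniform)
generators, so they exercise the estimator's variance response but not, for
example, heavy-tailed real-world noise; the simulators establish that
incoherence ranks *known* ordered/complex/chaotic regimes correctly, not
that it detects complexity in arbitrary systems.  Multi-variable outputs are
out of scope: when a system emits several observables, the package measures
each variable separately rather than guessing a joint-entropy aggregation.

## Problem sizes and determinism

Default study sizes (above) were chosen so each published behaviour is
reproduced by a computation of modest size: the full test suite regenerates
every input programmatically, and the acceptance script's targets span the
worked table, the bounds, the continuous consistency anchor (10 trials ×
1000 observations), the degree sweep (900 graphs of 50 nodes) and the
rule-0/30 ensembles (10 automata of 100×200 cells).  All randomness flows
through `numpy.random.default_rng` with explicitly derived sub-seeds, so
identical seeds give bit-identical results.
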