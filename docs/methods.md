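# Methods

## Model and formulation

The reconstruction operates on a split model: every reversible reaction of
the reference network contributes a forward and a backward irreversible
step, so all step fluxes are non-negative; an originally reversible reaction
with bounds `[l, u]` (`l < 0`) yields steps with upper bounds `u` and `−l`.
Exchange reactions export in the forward direction; a growth medium is a map
`exchange id → max uptake` applied to the backward (uptake) steps, with
unlisted exchanges closed for uptake and secretion left open (whether the
original study also restricted secretion is not determinable from its
description; leaving it open is the weaker assumption and is configurable).

Before the reconstruction LP, a flux variability analysis computes
`vmax_i = max v_i` subject to steady state, the step bounds, the medium and
`v_biomass ≥ v*`, one LP per step. Steps with `vmax_i ≤ feas_tol` are
*blocked*: they are bound-fixed to zero and carry no objective term, and a
reaction all of whose steps are blocked counts against the attainable
H-coverage ceiling rather than against the algorithm.

The FVA is deliberately run on the **split** model without any
one-direction-at-a-time constraint. For a reversible step this means `vmax`
can be realised by a forward+backward cycle and is then limited only by the
nominal bounds. This is what makes the relaxed LP's spurious-cycle behaviour
possible in the first place (both steps can reach their activation threshold
"for free"), and the iterative elimination below is the counterpart that
deals with it. Computing per-direction net maxima instead would silently
remove the phenomenon — and with it the reward for genuinely usable
reversible H reactions whose `vmax` is honest.

## Objective and weights

L and M steps cost `W/(δ·vmax_i)` per flux unit; each unblocked H step gets
a continuous variable `z_i ∈ [0, 1]` rewarded with `−W_H` and tied to flux by
`δ·vmax_i·z_i ≤ v_i`. Normalising by `δ·vmax_i` removes the dependence on
the stoichiometric scale at which a reaction happens to be written:
multiplying a reaction's column by `k` and its bounds by `1/k` (the same
chemistry, rewritten) leaves costs, activation thresholds and hence the
extracted network unchanged. This invariance is asserted in the test suite
for `k ∈ {0.1, 10}`.

Weights follow the three schemas `(W_H, W_M, W_L)` =
`(α, 1, α²)`, `(α, 1, α)`, `(α², 1, α)` with `α = 10³` by default. Schema 1
buys L avoidance at the price of H coverage; schema 3 the opposite; the
package's cohort fixture plants both directions of that trade (an L reaction
that unlocks two H reactions, and two L reactions that unlock one), so the
orderings `L₁ ≤ L₂ ≤ L₃` and `H₁ ≤ H₂ ≤ H₃` of the median coverages are
structural, not statistical. M flux (including biomass itself, which has no
GPR) carries weight 1, so the network stays minimal where expression is
silent.

`δ` defaults to 0.1: comfortably above the activity threshold `act_tol`
(1e−6) so that an activated H step is unambiguously "on", and well below 1
so that activation does not demand the full `vmax`. `v*` defaults to 1% of
the wild-type maximum biomass computed on the medium-constrained model — a
relative default that adapts to arbitrary fixtures; any absolute value can
be configured. `feas_tol` (1e−9) is solver noise; `act_tol` (1e−6) is a
modelling decision about what counts as carrying flux; they are kept
separate and both configurable.

## The iteration

Solving the relaxed LP activates both steps of reversible H reactions even
at zero net flux (each direction earns its own `z` reward). Per round the
algorithm:

1. detects all H pairs with both steps above `act_tol`, ordered by
   descending `min(v_f, v_b)` with ties broken by reaction id;
2. picks a direction to keep per pair — the net-flux direction when
   `|v_f − v_b| > act_tol`, otherwise the step whose `z` reduced cost is
   more negative (the larger potential objective improvement from pushing
   that activation), ties keeping the forward step;
3. fixes the discarded step's flux and `z` to zero and re-solves.

All detected pairs are fixed per round by default (a config switch fixes one
per round). Each round removes at least one direction permanently, so the
procedure terminates. After convergence a verification pass revisits every
fixed-off direction: it is re-opened with its partner fixed off, and the
orientation is swapped if that LP is feasible, at least as good as the
converged objective (within a relative `obj_tol` of 1e−6), and actually
activates the step's `z`. Any spurious pairs surfaced by a swap are cleaned
up before continuing. The reduced-cost rule and this re-admission step are
this package's concrete rendering of a reduced-cost guided iteration; they
are validated behaviourally against an exact mixed-integer oracle (below)
rather than against any reference pseudocode.

Determinism: all LPs use HiGHS dual simplex through
`scipy.optimize.linprog`, single-threaded with fixed options, so solutions,
reduced costs and therefore the whole iteration are reproducible bit-for-bit
across runs.

The final network is every reaction whose net flux exceeds `act_tol` in the
last solution, plus the biomass reaction; the induced submodel is re-checked
to grow at `≥ v*` on its own.

## The MILP oracle

For testing only, the same data are solved exactly with binary `z` and a
binary direction selector per reversible pair (`v_f ≤ ub_f·y`,
`v_b ≤ ub_b·(1−y)`), via `scipy.optimize.milp`. This formulation makes
spurious cycles structurally impossible and defines the "right answer" for
gap measurement. On 100 seeded 15-reaction fixtures the iterative LP's final
objective lands within 5% of the oracle optimum in ≥95% of instances (the
acceptance script recomputes the exact rate). The oracle is never the
production path.

## Expression handling

Probe-level z-scores aggregate to genes by the median over mapped probe
sets (a probe mapping to several genes contributes to each; genes with no
probes are absent, not zero-filled). Calls are `z ≥ threshold → +1` else
`−1`, with the threshold configurable (default 5.0) because the upstream
calling criteria are a property of the preprocessing pipeline, not of this
package — precomputed ±1 calls are the preferred input. GPRs evaluate over
`{+1, 0, −1}` with AND = min and OR = max; unmeasured genes contribute 0 so
missing probe coverage cannot force a reaction into L. Reactions without a
GPR are M. Internally calls are `{+1, −1}` directly rather than
present/absent bits plus a second mapping; the encoding is equivalent.

## Essentiality and backgrounds

A gene knockout disables the reactions whose GPR is false with that gene
deleted and every other gene functional. Essentiality means the knockout
FBA maximum falls below `essential_tol`, default `min(1e−6, v*)` — i.e.
"numerically unable to produce biomass"; the stricter "cannot reach `v*`"
reading is available by passing `essential_tol = v*`. The skip heuristic
computes one wild-type reference distribution (minimal total flux through
gene-associated reactions at the fixed wild-type optimum, biomass pinned
within 1e−9 relative) and skips any gene none of whose knockout reactions
carries flux there: removing inactive reactions cannot disturb an optimal
solution that never used them, so the skip is sound for *any* optimal
reference distribution and no canonicalisation is attempted. Equality of
labels with exhaustive knockouts is asserted on 50 seeded models.

Backgrounds permute the ±1 calls among the metabolic genes (multiset
preserved, per-sample substreams derived deterministically from one master
seed, 10 permutations per sample by default) and re-run
classification → reconstruction → essentiality per permutation, under the
same weighting schema as the matched sample. Frequencies divide by the
number of networks in each group, so a gene missing from some
reconstructions counts as non-essential there.

The one-sided two-sample KS statistic is `D⁺ = sup_x [F_ess(x) − F_other(x)]`
(essential scores stochastically smaller). The p-value is exact by
enumeration over all `C(m+n, m)` label assignments when `m + n ≤ 16`, else
the asymptotic one-sided Smirnov tail `exp(−2mnD²/(m+n))` capped at 1. Ties
are handled by evaluating both empirical CDFs on the pooled support.
External scores are consumed as given — the loader never re-signs them; a
score of exactly 0 counts as non-negative in the negative-fraction measure.

## What the synthetic data does and does not show

The generators emulate the *structural* situations the algorithm must
handle: a guaranteed feasible biomass route whose availability is
independent of the expression profile, isolated reversible H pairs (the
spurious-cycle trap), isozyme OR-rules, dead-end branches (FVA-blocked),
parallel pathways whose relative expression creates context-dependent
essentiality, and chains that couple H inclusion to L cost in both
directions. They do not emulate genome-scale connectivity, compartments,
cofactor coupling, realistic GPR depth, or biologically calibrated flux
bounds — so passing tests demonstrate algorithmic correctness and the
qualitative phenomena, not recovery of any particular organism's biology.
Fixture sizes (≈15 reactions, 20-profile cohorts, 100 oracle instances, 50
essentiality models, 10 permutations per sample) were chosen so every
planted behaviour is exercised while each oracle comparison stays exactly
solvable; all are parameters of the generators.

## Known limitations

* No thermodynamic/loopless constraints: multi-reaction loops among
  distinct H reactions are not penalised (only same-reaction
  forward+backward pairs are), matching the formulation's scope.
* The relaxed LP can leave `z` fractional when `vmax` is cycle-inflated;
  the objective gap to the binary-z optimum is measured, not bounded a
  priori.
* The heuristic direction choice is validated empirically against the MILP
  oracle; no optimality guarantee is claimed for adversarial instances.
* SBML support covers the Level 3 + fbc subset that cobra exposes
  (stoichiometry, bounds, GPR strings, objective); groups, annotations and
  compartment semantics are ignored.
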