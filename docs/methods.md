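# Methods

## Model

The network couples M attribute-representation sublayers to one
preference-accumulation layer. All nodes share the piecewise-linear
activation bounded at 0 and 1, and every layer follows the synchronous
recurrence

    X_i(t) = f[ s·X_i(t−1) − l·Σ_{k≠i} X_k(t−1) + Y_i(t) ]

with layer-specific self-feedback `s` and lateral inhibition `l`. Timescale
separation is assumed: attribute sublayers settle to equilibrium
"immediately" relative to attribute sampling, so a decision only ever sees
their stable activations. A decision starts from an all-off network; at
each sampling step one attribute j is drawn iid (uniformly by default,
configurable), the weighted equilibrium `w_j·α_ij` enters the preference
layer, and the first available preference to reach the threshold Q —
crossing is **inclusive** (`≥ Q`), which LEX requires since its attainable
input exactly equals Q — ends the decision. Simultaneous crossings break
uniformly at random. All stochasticity comes from attribute sampling and
tie-breaks; there is no within-node noise, no feedback from preferences to
attribute layers, and no continuous-time variant.

Alternatives are zero-indexed everywhere; unavailable alternatives receive
no input, stay at activation 0, and can never be chosen.

## Equilibrium computation

Sublayer equilibria are computed by synchronous fixed-point iteration from
the all-zero state (matching the decision onset), with tolerance 1e-10 and
an iteration cap of 10,000. Two failure modes are detected and reported
rather than raised: hitting the cap, and period-2 cycles (the state
returning to where it was two steps earlier while still moving by far more
than the tolerance — e.g. `s = 0, l = 1` flip-flops). Unconverged profiles
carry `converged=False`, trigger a log warning, and their final state is
still used downstream; classification labels such cells OTHER. The cycle
test requires the residual to exceed 1e3× the tolerance so that slow
geometric convergence (which also revisits the two-steps-back
neighborhood) is not misflagged.

Within a decision — and across the 10,000 repetitions of a probability
estimate — equilibria are constant, so they are computed once per
(choice set, attribute, s, l) and cached. The studies share a cache across
parameter combinations that differ only in Q.

## Transform classification

With inputs sorted decreasingly and distinct, a converged equilibrium is
classified in this order: IDENTITY (α equals the inputs within 1e-9);
saturated 0/1 patterns aligned with the input order (IDENTIFY_BEST for
top-1, IDENTIFY_K_BEST for top-k with 2 ≤ k ≤ n−1; all-ones is OTHER since
it discriminates nothing); IDENTIFY_WORST (only the input-minimal node at
0, the rest positive — the top node may be saturated at 1, matching the
region-map definition); NORMALIZED (all nodes strictly interior and an
exact least-squares fit of α_i = ω₁·x_i − ω₂·Σ_{k≠i}x_k with residual
below 1e-8). Saturation tolerance is 1e-9: geometric convergence at
tolerance 1e-10 makes saturation numerically exact, so this is not a
sensitive knob. Tied inputs make ordinal regimes undefined: classification
returns OTHER, and the symbolic heuristics return UNDEFINED rather than
breaking ties silently.

For the interior regime the coefficients have the closed form (derived by
solving the linear fixed point for n active nodes; the n = 3 case is the
one usually quoted)

    ω₁ = [1 − l/(1−s+(n−1)l)] / (1−s−l),
    ω₂ = l / [(1−s−l)(1−s+(n−1)l)],

verified against the iterated equilibria to 1e-8. At l = 0 the interior
fit degenerates to ω₂ = 0 (pure rescaling); the classifier accepts it, and
the strictly positive-ω property is checked on l > 0 cells.

Monotonicity caveat: the equilibrium of every node increases with s only
when l = 0. With inhibition active, raising s lifts the top node, whose
stronger inhibition can push a weaker node to 0 (e.g. inputs
(0.353, 0.185, 0.455), l = 0.637: s 0.05 → 0.23 drops node 1 from 0.09 to
0). The input-maximal node is monotone in s in every instance we tested;
the tests assert exactly these two statements.

Closed-form saturation thresholds used as oracles: with all non-top nodes
suppressed, the top node saturates exactly when s ≥ 1 − x₁ (from
α₁ = x₁/(1−s)), and the runner-up stays suppressed at the state (1, 0, …)
exactly when l ≥ x₂.

## Heuristic presets

| preset | s_P | l_P | sublayers | Q | weights |
|--------|-----|-----|-----------|---|---------|
| LEX | 0 | 0 | identify-best (s_A = l_A = 1) | max w_j | proportional |
| CONF / k-CONF | 1 | 0 | identify-best | k·w (w < 1/k) | equal |
| WP | 1 | 0 | identify-best | 0.99 | proportional |
| MCD | 1 | 0 | identify-best | 0.99 | equal |
| EW | 1 | 0 | identity (s_A = l_A = 0) | 0.99 | equal |
| WAD | 1 | 0 | identity | 0.99 | proportional |
| ITW | 1 | 0 | identify-worst (searched) | 0.99 | proportional |
| k-MCD | 1 | 0 | identify-k-best (searched) | 0.99 | equal |

"High Q" defaults to 0.99 and the study weights are 0.03/0.015/0.01
(proportional) and 0.01 (equal). Ordinal presets use s_A = l_A = 1 — the
study values — for every sublayer; when a choice set is supplied the
preset verifies that (1, 1) actually identifies the best alternative and
falls back to a lexicographic grid search (step 0.01) where it does not.
ITW and k-MCD always search, and therefore require the choice set. Note
the ITW preset accumulates the *attenuated* leaky-competitive equilibrium
values of the surviving alternatives, while the symbolic ITW oracle uses
raw values with each attribute's worst excluded — the network and the
oracle can disagree by construction; the tests exercise a case where they
agree and the gap is deliberate, not hidden.

The symbolic oracles are deterministic and return UNDEFINED on any tie
relevant to the rule (never a random break): study accuracies are computed
only over uniquely-predicted sets. CONF has no deterministic oracle (its
outcome depends on the sampling order) and is excluded from the
identification study; instead the CONF preset is validated against the
exact absorption distribution of its finite Markov chain on hit counts,
enumerated by brute force in the tests.

## Monte-Carlo engine

`simulate_decision` is a plain-Python reference implementation of one
decision (optionally recording the preference trajectory and the sampled
attributes). `estimate_choice_probabilities` runs the identical per-step
recurrence in a numba-compiled kernel with early exit at the first
crossing — an implementation of the same dynamics, not an approximation —
and a test checks distributional agreement between the two. Trials that
reach T_max (default 10,000 samples) without a crossing are censored; in
probability estimates they are resolved by a uniform random choice among
available alternatives so probability vectors stay normalized, and the
censoring fraction is reported and logged. Mean decision times include
censored trials at T_max. A single root seed drives every run; the kernel
seed is derived from the caller's generator, so results are reproducible
bit-for-bit under a fixed seed.

## Identification study

100 choice sets, 3 alternatives × 3 attributes, values iid uniform(0, 1)
(clipped away from the boundary by machine epsilon), weights
0.03/0.015/0.01. Each preset is simulated 10,000 times per set; its modal
choice (argmax of empirical frequencies, exact ties scored as mismatch) is
compared with each idealized rule's prediction on the sets where that
prediction is unique. The tally rule (MCD) is undefined when the three
per-attribute winners are all distinct, which for iid uniform values
happens with probability 6/27 — the expected unique-winner fraction is
7/9, checked by a binomial test.

A structural note: with the study's top-heavy weights (w₁ > w₂ + w₃) the
weighted-pros argmax provably coincides with the lexicographic choice on
every tie-free set, and the WP preset's fastest accumulator is always the
best-on-attribute-1 alternative (rate w₁/3 against at most (w₂+w₃)/3), so
the WP and LEX rows of the accuracy matrix coincide asymptotically. The
off-diagonal tests exclude that structurally-degenerate pair.

## Recovery study

Grid: s_A, l_A, Q ∈ {0.1, …, 0.9} (shared across sublayers), s_P = 1,
l_P = 0, weights w₁ = w₂ = 0.01 on 3-alternative × 2-attribute sets, plus
one memoryless ordinal combination (s_P = l_P = 0, s_A = l_A = 1,
Q = w₁) — 9³ + 1 = 730 combinations. Every combination is simulated twice
per set with independent streams (a "data" and a "model" run, 10,000
repetitions each); for each combination's data the mean-squared error —
the mean over (choice set, alternative) cells of squared probability
differences — is computed against every combination's model
probabilities, with explicit differences so that identical probability
vectors tie exactly. Uniqueness is the proportion of combinations that are
the *strict* unique minimizer of their own data's MSE (no numeric
tolerance: exact ties count as non-unique). Curve points share choice sets
(the n-set point uses the first n of the largest batch), which is
statistically equivalent per point and halves the simulation cost.

Uniqueness from only two choice sets is a highly variable statistic — the
two random sets drive everything; across seeds at full scale we observed
counts ranging roughly from 60 to 165 around a mean near 105 — so the
acceptance script reports the mean over five independent two-set
replicates alongside per-replicate values.

## Problem sizes

Defaults used by the test suite: identification at full scale (100 sets,
10,000 reps); recovery at the package's scaled-down defaults (2,000 reps;
2, 10, 25 sets; full 730-combination grid). The acceptance script runs
identification at full scale and the two-set recovery point at 10,000
reps. The full-scale uniqueness curve (up to 200 sets at 10,000 reps) is
a long-running computation exposed through `lcachoice study-recovery`.

## Known limitations

* Synchronous updates admit period-2 cycles for strong inhibition
  (reported, not hidden); an asynchronous or continuous-time variant would
  behave differently near those boundaries and is out of scope.
* Region-map boundaries depend on grid granularity and the update
  schedule; the maps are trusted in region interiors, not at single
  boundary pixels.
* The generator draws attribute values iid uniform — no interattribute
  correlation, no alternative-specific structure — so passing studies
  demonstrate identifiability and mimicry under these idealized
  conditions, not on real choice data.
* Elimination-based heuristics and decision-by-sampling extensions are out
  of scope; lateral inhibition in the preference layer exists in the core
  model (`l_P`) but the studies keep it at 0.
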