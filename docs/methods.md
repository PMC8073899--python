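# Methods

## Model

The simulator iterates a signed weighted directed network ("fuzzy cognitive
map"). Concepts carry an activity in [−1, 1]; 0 is an arbitrary baseline, +1
maximal expression/presence, −1 maximal suppression/absence. Edge weights in
[−1, 1] \ {0} encode influence strength and sign; absence of an edge *is*
weight 0, so networks are stored sparsely and zero weights are unstorable by
design. An edge may instead carry the indeterminate marker `I` for
relationships known to exist but of unknown sign and strength (a neutrosophic
extension of the fuzzy weights).

One synchronous update is

    a_i(t+1) = f( λ·a_i(t) + Σ_j w_ji·a_j(t) ),

with locked concepts reasserted to their clamp value after every step.
Clamping is the single mechanism by which everything external enters the
model: reprogramming protocols (transcription factors and media locked ON at
+1), gene deletion (locked OFF at −1 — complete loss of function; hypomorphs
can be locked at intermediate values), and drug action (targets locked at
action × dose). Unlocked clamp entries set only the initial state; all other
concepts start at baseline 0, optionally plus seeded Gaussian jitter.

### Assumptions

- Continuous activities are kept throughout; states are never thresholded to
  a trinary code.
- Synchronous updates; no update-order effects.
- No self-loops in the network: any self-contribution is the engine's memory
  parameter λ, applied uniformly.
- A single weight per ordered concept pair (no parallel evidence channels).
- The map itself is not learned here; weights are curated or generated
  inputs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| squash `f` | tanh | odd, range (−1,1), f(0)=0; alternative: logistic rescaled to (−1,1) |
| memory λ | 0 | self-contribution in [0,1]; 0 = plain vector–matrix iteration |
| tolerance ε | 1e−4 | max-norm change declaring a fixed point; also the cycle-match tolerance |
| max_iterations | 1000 | iteration cap |
| cycle_window | 50 | how far back recurrence is sought |
| indeterminacy half-range r | 0.25 | `I` weights resolve to Uniform[−r, r]; r=0 drops them |
| initial jitter σ | 0 | sd of seeded jitter on unclamped initial values |
| dead zone δ | 0.05 | \|value\| ≤ δ counts as baseline, never as expressed |
| replicates k | 3 | simulations per condition |
| dose range | [0.65, 0.85] | treatment dose as fraction of maximum; fixed-dose mode uses 0.75, the range's mean |
| positive bias p_pos | 0.658 | positive-prediction probability used by the biased binomial; computable from any concrete network as its positive-edge fraction |

The tanh default preserves the [−1, 1] semantics with a 0 fixed point at
baseline and a maximum slope of 1, so any network whose maximum absolute
column sum is below 1 (with λ=0) is a contraction and provably converges —
a property the test suite checks empirically over random networks.

### Convergence classification

`fixed_point` when the max-norm step change drops below ε; `limit_cycle`
when a state recurs (within ε) at lag ≥ 2 inside the window, in which case
the reported final state is the element-wise mean over one cycle and the
outcome is flagged so a cycle is never mistaken for a fixed point;
`max_iterations` otherwise. Non-finite components abort with an error naming
the iteration. Note that a two-node mutual-inhibition motif cannot oscillate
under tanh with |w| ≤ 1 (the map is non-expansive); sustained cycles need a
summed gain above 1, e.g. two sources each inhibiting two sinks — that
four-node circuit is the package's canonical cycling example.

### Replicates and seeding

A deterministic map makes "triplicate" meaningless, so replicate variability
comes from the two seeded stochastic elements: per-replicate resolution of
indeterminate weights and optional initial jitter. Per-replicate (and
per-treatment, per-dose) seeds are derived from the master seed and indices
via `numpy.random.SeedSequence`, so results are bit-reproducible and adding
treatments or replicates never perturbs earlier ones.

## Statistics

- **Biased binomial chance probability.** For a profile with n_pos expected
  promotions and n_neg expected inhibitions, the probability that all
  directional calls succeed by chance is p_pos^n_pos · (1−p_pos)^n_neg. The
  generalized product (rather than plain p_pos^N) exists because real
  feature profiles mix directions. No multiple-testing correction is applied
  anywhere in the package; the screen logs the number of tests it performed.
- **Exact Mann–Whitney U.** Two-sided p by full enumeration of rank
  assignments (midranks for ties; p = 2·min(P(U≤u), P(U≥u)) capped at 1)
  whenever n_a·n_b ≤ 400 *and* C(n_a+n_b, n_a) ≤ 200,000 — the feasibility
  cap is ours, since pure n_a·n_b ≤ 400 admits infeasible 20×20 enumerations.
  Larger samples use the normal approximation with tie and continuity
  corrections. The exact two-sided minimum for 3-vs-3 groups is 0.1; p-values
  below that for triplicates are arithmetically impossible and this package
  will not produce them.
- **Paired t.** Standard two-tailed paired t on n−1 df; zero-variance
  differences raise a degenerate-test error rather than silently returning 0
  (the screen reports such treatments with p = 1).
- **Cosine similarity / ACD.** CS is clipped to [−1, 1] against rounding
  overshoot, and (anti-)identical vectors short-circuit to exactly ±1 so a
  self-comparison has a distance of exactly 0. ACD = arccos(CS)/π.
- **Shortlist confidence.** `at_least_one_success(p, k) = 1 − (1−p)^k`. At
  p = 0.5, k = 12 this is 0.999756 (it exceeds 0.9999 at p = 0.658).

## Screening design

The comparison vector for CS is the *simulated* placebo profile vector (the
untreated disease steady state over the nine profile factors), not a raw
clamp vector: the placebo treatment is an empty overlay ("all 0s"). Drug
pharmacology is encoded explicitly as per-drug (target, sign) lists —
clamping is the only mechanism the engine exposes. When two drugs in a pair
hit one concept with the same sign the larger magnitude wins; opposite signs
are summed, bounded and logged. Ranking is by ACD descending with lexical
tie-breaks, so permuting the input treatment list cannot change the result.
Triple combinations are excluded by default (max pair size 2), though the
enumeration code is generic.

Dose handling: in sampled mode each treatment × replicate draws its dose
uniformly from [0.65, 0.85] under the screen seed; fixed-dose mode (0.75)
exists for deterministic runs and is what the regression tests use. On the
toy fixture the restorative pair's ACD is not strictly monotone in dose
(0.9666 at 0.65 vs 0.9554 at 0.85, always > 0.9): the mirror is best where
the clamp magnitudes match the placebo profile's magnitudes; the dose-response
check therefore logs, rather than forbids, a mild decrease.

## Synthetic data

`random_network` draws edges uniformly over ordered pairs without self-loops,
with independent indeterminate/positive coin flips and uniform magnitudes.
Its defaults (mean degree 9.334, positive fraction 0.658) reproduce the
summary statistics of the proprietary reference database (4,660 concepts,
43,498 influences), which is not redistributable; the generator emulates its
density and sign balance but **not** its curated biological topology —
passing tests on generated networks validate the machinery (boundedness,
convergence, statistics), not biological predictions.

The MLD fixture is a hand-curated ~20-concept cascade: ARSA deficiency feeds
two branches — sulfatide accumulation (lysosomal → released → astrocyte
activation, peripheral neuropathy) and lysosomal stress (→ microglial
activation) — converging on demyelination → neurodegeneration → dementia and
seizures, with oligodendrocytes and barrier function suppressed. Weights are
saturating (±0.5, ±0.8) so sign conclusions are robust to ε, δ and λ
defaults; the fixture asserts directions only, never magnitudes. The
two-branch topology is deliberate: no single toy drug can mirror the whole
disease profile, so the screen's top hit must be a combination (the
sulfatide-clearance agonist plus the glial calmative), mirroring the
structure of the published screen where all top candidates were drug pairs.
"Restoration" on the fixture means no profile factor remains elevated above
+δ; a strongly ranked treatment in fact pushes factors below baseline, which
is exactly what a near-maximal ACD requires. The shipped 41-entry drug
library reproduces the published library's size and class structure; its
target assignments are illustrative placeholders, not pharmacological claims.

## Numerical and design notes

- Concept order is insertion order and fixes the state-vector layout;
  edge-list serialization sorts by (source, target) so write∘parse is the
  identity.
- Indeterminate resolution iterates edges in sorted order, making it
  independent of construction order.
- The update uses `scipy.sparse` CSR matrices; a 4,660-concept network is
  handled without densifying.
- Degenerate inputs: empty networks simulate to an immediate fixed point;
  r = 0 resolution drops all indeterminate edges; a zero profile vector
  cannot be cosine-compared and flags the record instead of crashing.
- The engine records iterations-to-convergence; specific published iteration
  counts (31 wild-type, 27 disease) depend on the unavailable reference
  network and are not reproduced.

## Known limitations

- Qualitative signs only: steady-state magnitudes are artifacts of curated
  weights and must not be read quantitatively.
- Synchronous deterministic updates cannot represent asynchronous or
  stochastic regulatory timing.
- The fixture is a test harness, not an MLD model of record; the generator
  matches two summary statistics of real curated networks and nothing else
  (no hubs, no motif structure, no degree heterogeneity beyond the binomial).
- Drug encodings assume dose-proportional clamping of named targets; there
  is no pharmacokinetics, toxicity or blood–brain-barrier permeability.
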