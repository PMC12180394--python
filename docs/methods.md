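# Methods

## The unit model

Every inference unit is a discrete active-inference agent over a bounded
state line of `n_states` positions (default 5, indices 0–4), with the
observation alphabet equal to the state alphabet. Its generative model:

* **A** — noisy-identity likelihood: `A[o,s] = 1 − η` on the diagonal and
  `η/(n−1)` off it, with `likelihood_noise η ∈ [0, 1)` (default 0.2).
  η = 0.2 keeps perception mostly veridical while leaving enough sensory
  ambiguity that beliefs, and hence expected free energies, are graded
  rather than degenerate.
* **B** — deterministic transitions for the three policies *up* (s+1),
  *down* (s−1) and *stay*, clamped at the boundaries (no wrap-around: the
  state line has edges, so trajectories cannot alias across them).
* **C** — preference over observations, `C(o) ∝ exp(κ·1[o = target])` with
  sharpness κ (default 4.0, i.e. the preferred observation is `e⁴ ≈ 55`
  times more preferred than any other). A finite κ keeps `C` strictly
  positive so the risk term `KL(q(o)‖C)` is always finite; κ → ∞ recovers
  a one-hot preference.
* **D** — uniform prior.

Per step a unit executes, in this fixed order: (a) sample the observation
from the likelihood column of the niche's true state; (b) tilt the prior
in log space by the external message adjustment; (c) infer the posterior
`σ(log A[o,·] + log prior)` (algebraically exact Bayes); (d) compute
`F = KL(q ‖ Â_o) − log P(o)`; (e) compute `G(π) = ambiguity + risk` for
the three policies from the posterior; (f) act by argmin G; (g) advance
the niche's true state through the chosen (deterministic) transition;
(h) carry `B_π · q` forward as the next prior (the posterior propagated
through the chosen action, which reduces to "posterior becomes prior"
exactly when the transition is applied to both beliefs and world).

`F` is stated against the normalized likelihood column rather than against
the prior-weighted joint; under a uniform prior it equals the negative
evidence lower bound exactly (verified by enumeration in the tests). Under
a non-uniform prior the two differ by the Bayesian-surprise bookkeeping of
the prior; the implementation follows the stated form unconditionally and
the identity tests pin the uniform-prior case.

### Numerical choices

* Floor `ε = 1e−16` inside every logarithm; KL terms use the convention
  `0·log 0 = 0` with the same floor on both arguments. All free energies
  are in nats.
* Policy selection treats G values within `1e−12` of the minimum as exact
  ties, broken toward the lowest policy index (up < down < stay). With a
  noise-free likelihood the three G values are equal in exact arithmetic
  and differ only by floor-level noise (~1e−15); the tolerance makes the
  implementation follow the exact-arithmetic tie rule instead of that
  noise. A consequence worth knowing: a noise-free, indifferent unit
  drifts upward by tie-breaking.
* An optional temperature-softmax action mode (`select_policy(...,
  temperature=τ)`, seeded) exists for stochastic-policy experiments; the
  default everywhere is hard argmin.
* Observations are sampled from the likelihood column (seeded generator);
  `deterministic=True` replaces sampling by the argmax, which makes whole
  runs exactly deterministic — used for symmetry tests.

## Intra-agent coupling

Each agent couples three structurally identical units, Real, Symbolic and
Imaginary, through synchronous message passing: after every step, unit *k*
emits `m_k = w_k · F_k · (q_k − 1/n)` — its posterior deviation from the
uniform belief scaled by its nonnegative precision weight and by its
current prediction error. Messages sum to zero, so a receiving prior stays
a simplex after the softmax. Each unit's log-prior adjustment for the next
step is the **average** of the other units' messages, computed from the
previous step's posteriors and F values so the result is independent of
unit evaluation order; at t = 0 posteriors are uniform and F = 0, so the
first step carries no messages.

Averaging rather than summing the incoming messages is deliberate: it
normalizes the received tilt by the number of senders, and it keeps the
coupling inside the sensitive range of action selection across the whole
0–2 weight span. With summed messages the perturbation response saturates
near w ≈ 1 (action flips are threshold events, and a tilt of ~2–3 nats
already dominates the 0.8/0.05 likelihood log-odds), which flattens the
weight dependence between 1.5 and 2.0; averaged messages yield a cleanly
increasing propagation curve (≈ 0 → 0.35 → 0.45 → 0.57 for w = 0, 1.0,
1.5, 2.0 averaged over 200 seeds). A weight of zero silences an order's
output entirely, and the uncoupled agent is bit-for-bit identical to three
independent units.

## The individual protocol

15 steps. The Symbolic niche starts at state 1 and the Symbolic unit gets
a sharp preference for observation 4; Real and Imaginary niches start at
the center state 2 with uniform (indifferent) preferences. The matched
baseline is the same run with the perturbation removed entirely — Symbolic
initial state reset to 2 and preference uniform — under identical seed
streams, so any trajectory difference is attributable to the perturbation.
The propagation score into an order is the mean absolute true-state
difference between perturbed and baseline runs over the full 15 steps.

## Desire networks

A desirer reads the desired agent's Symbolic niche state through its *own*
Symbolic likelihood (the other is perceived through one's own symbolic
system): it samples an observation from that likelihood column, infers a
posterior under a uniform prior, and installs the floored, renormalized
posterior as its own Symbolic preference, replacing the previous one
entirely (no mixing with an intrinsic preference). Scheduling is
synchronous: per step all desire updates fire from last-step states, then
all agents step. Dyads use mutual edges A↔B with distinct initial Symbolic
states (default 0 and 4); triads use the directed ring A→B→C→A with
defaults 0/2/4; agents are otherwise identical, with internal coupling
weights defaulting to the moderate uniform 1.5. Removing all desire edges
reproduces the solo runs bitwise, because per-(agent, order) random
streams are keyed by (master seed, agent index, stream tag) and a fourth
reserved stream feeds desire observations.

## Metrics

* `sync_index = 1 − mean_t |s_a − s_b| / (n−1)`, on true niche states, by
  default over the final 5 of 15 steps (a steady-state reading; the first
  two-thirds of a run are dominated by the initial transient). MAP-state
  and posterior-expectation variants are provided since figure conventions
  differ.
* `propagation_score = mean_t |s_perturbed − s_baseline|` per order.
* `divergence`: per-step mean absolute state difference across all
  (agent, order) channels between two runs differing only in one initial
  condition, plus its final-window mean.
* A convergence threshold of 0.9 on the sync index is used as the
  conventional reading of "complete" convergence; no empirical calibration
  for it exists, and it enters no pass/fail logic beyond being a reported
  convention.

## What the synthetic setup does and does not show

All inputs are generated programmatically; there is no empirical data.
The simulator demonstrates mechanism-level properties — exact inference,
zero-coupling factorization, monotone perturbation propagation, desire-
driven synchronization, sensitivity of ring dynamics to initial conditions
— at desk scale (15 steps, ≤ 3 agents, 5 states). It does not establish
anything about neural systems or clinical populations, and deliberately
excludes learning of (A, B, C, D), hierarchical or continuous state
spaces, deep (multi-step) policies, preference mixtures, and populations
beyond three agents. Statistical properties (propagation monotonicity,
dyad synchronization gain, triad divergence fraction) are averages over
20-seed replicate batteries and can fluctuate for any single seed.

## Problem sizes

Oracle batteries use 100 random models with 2–6 states; behavioral checks
use the protocols' native scale of 15 steps with 20 replicate seeds —
everything runs in seconds on one core.
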