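# Methods

## Model overview

`micsim` implements a single instrumental controller that blends model-free
and model-based computation. Its state is (i) a tabular cache of action
values Q(s,a) with per-entry uncertainty C(s,a) — C is the variance of the
mean of the Q distribution, not the outcome variance — and (ii) a learned
reward model R̂(s), the mean reward expected at each state. The agent's
internal transition model is assumed correct and deterministic (it is the
maze itself); nothing in the package learns transitions.

A trial is one episode in a depth-2 binary T-maze: start at the stem,
choose twice, terminate in an arm, collect a Gaussian reward draw at every
state entered along the way (negative draws are passed through; nothing is
clipped). Trial indices are 1-based, and schedule change events govern the
named trial and all later ones: "moved after 50 trials" means trial 51 is
the first under the new contingencies.

At each decision-state visit the cycle is:

1. **Meta-choice** (per action, independently): compute
   VoI(a) = C(a)/(|Q(a) − Q(a′)| + ε) from the pre-simulation cached
   values and flag the action for simulation iff VoI(a) > γ. The
   inequality is strict; a VoI exactly at threshold does not simulate
   (ties go to the cheaper option). γ is the entire cost of simulating —
   there is no per-sweep marginal cost.
2. **Mental simulation** for each flagged action: `round(λ·C)` forward
   sweeps (round half-up, floor 0), each a rollout whose first action is
   clamped and whose subsequent actions are uniform random. Sweeps read
   the deterministic means R̂(s); no sampling noise is injected, so all
   sweep-to-sweep variability comes from the random continuation policy
   (and, when truncated, the random bootstrap action). With C > ζ
   (strict) sweeps run to a leaf; otherwise they stop after η transitions
   and, if the stop state is a decision state, add δ^η times a cached Q
   there. The retrieved Q is that of a uniformly random action by
   default; `AgentParams.truncation_bootstrap="best"` switches to the
   greedy read, since the analogous bootstrap from *real* experience uses
   the best action and either reading of the simulated case is defensible.
   The start state's own R̂ is not counted: rewards attach to states
   *entered*, mirroring the real episode bookkeeping.
3. **Fusion and choice**: each flagged action's pseudo-observations are
   fused with its cached value by the conjugate normal-mean update with
   unit observation variance; the fused value is *transient* — it informs
   this choice only. The choice is softmax with inverse temperature β over
   the values in effect, computed with max-subtraction for stability.
4. **Learning** after each executed action: the delta rule updates R̂ of
   the state entered for every entered state, including zero-reward ones —
   this is what lets a stale reward expectation decay after a relocation —
   and the particle filter updates (Q, C) of the executed pair only, using
   the pre-simulation cached value as prior and the bootstrapped
   observation o = r + maxₐ Q(s′, a) (zero bootstrap at a leaf).

## Particle filter

Per update, N = 1000 particles (a smooth posterior at negligible cost for
a 6-entry table; exposed in `AgentParams`): propose Cₙ ~ N(C, κ) with κ
read as a variance and negative draws clipped to 10⁻⁶ so every particle
remains a valid variance; propose Qₙ ~ N(Q, Cₙ); weight by the Gaussian
likelihood of o given Qₙ with unit variance; multinomial resampling
(inverse-CDF on the weight cumsum — distributionally identical to drawing
with probability proportional to weight); report post-resampling means of
both coordinates. If every weight underflows (observation absurdly far
from the prior) the update falls back to uniform weights with a
`RuntimeWarning` rather than dividing by zero.

The C↔Q coupling gives the filter its uncertainty dynamics: confirming
observations select low-spread particles and shrink C; surprising ones
select high-C particles and re-inflate it. That re-inflation is what
re-arms the meta-choice after a contingency change.

With κ clamped near zero the filter reduces to the conjugate normal-mean
update q + (c/(c+1))(o − q); the test suite and the acceptance script both
check this equivalence at N = 10 000 particles over 20 seeds.

## Scenarios and generated data

The five factories are the study conditions themselves, not tunable
fixtures: sim1 {S7: N(5, 0.2)}; sim2 {S2: 2, S4: 1, S7: 5, var 0.2};
sim3 = sim1 with the reward moving to S4 at trial 51 (S7 then pays
exactly 0 — nothing remains there); sim4 = sim1 at variance 1;
sim5 = sim2 at variance 1. All use 100 trials and the default agent
parameters. The number of independent runs averaged per condition is 50
(exposed in `ScenarioConfig`); per-run streams are spawned from the master
seed via `numpy.random.SeedSequence`, so results are bit-reproducible and
runs are mutually independent.

What the generator emulates is the reward statistics of the behavioural
settings: stationary or relocated Gaussian rewards on a known graph. What
it does not emulate: stochastic or unknown transitions, reaction times,
within-trial real-time dynamics, off-line (inter-trial) replay, or any
sensory noise. Passing tests therefore speak to the arbitration and
learning dynamics of the model under its own assumptions, not to fits of
animal data.

## Reported series

The per-trial "figure-style" series track, per run: the at-choice softmax
probability of going left at S1/S2/S3 (the model probability actually used
for the choice — smooth, unlike the 0/1 empirical choice; S2/S3 have a
value only in trials whose path visits them, and cross-run means skip the
missing entries), the end-of-trial cached C and Q for going right at S1
and S3, and the sweep count and mean sweep length for going *right* at S1
(the action whose deliberation the uncertainty/sweep panels conventionally
track). A sweep count of 0 is recorded whenever the meta-choice declined
simulation; in modal-length summaries those trials count as length 0.

## Numerical choices and degenerate inputs

- Zero-variance states return their mean exactly (no RNG draw), so
  unrewarded states pay exactly 0.
- `posterior_q` with no pseudo-observations returns the prior unchanged;
  C = 0 keeps the prior regardless of observations.
- Softmax at β = 0 or equal values returns exactly 0.5; extreme β·ΔQ
  saturates to 0/1 at float precision.
- A leaf passed to `step` or to `decide_meta` raises: these are caller
  bugs, not data conditions.
- `n_sweeps` rounds half-up (`floor(λC + 0.5)`) so the sweep budget is a
  deterministic function of C.

## Known limitations

- The VoI is the stated ratio heuristic, not a decision-theoretic value of
  information; it ignores absolute values and uses a fixed cost.
- Only depth-2 binary trees ship with factories; the data model accepts
  other graphs, but sweep-length conventions (full path = ≤2 transitions)
  are only exercised on the double T-maze.
- The filter is strictly recursive (no smoothing across trials) and runs
  once per executed action; unvisited states and actions are never
  updated, so stale values persist until revisited — by design, as that
  persistence is part of the habitization account.
- Whether the particle count and the pseudo-observation count should share
  a symbol is moot here: they are independent parameters.
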