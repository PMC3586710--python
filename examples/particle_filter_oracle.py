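"""The value-learning particle filter against its closed-form oracle.

When the random walk on the uncertainty C is clamped (kappa -> 0), the
filter reduces to a conjugate normal-mean update with unit observation
variance, whose posterior mean is q + (c/(c+1)) (o - q). The script
checks that the sampled posterior reproduces it, then shows the
uncertainty dynamics that the oracle cannot capture: confirming outcomes
shrink C, surprising ones re-inflate it.
"""

import numpy as np

import micsim as m

params = m.AgentParams(kappa=1e-6, n_particles=10_000)
q, c = 1.0, 1.0
obs = m.LearningObservation(o=q + 2.0)
posts = [m.particle_update(q, c, obs, params, np.random.default_rng(s))[0]
         for s in range(20)]
print(f"clamped-C filter: mean posterior Q = {np.mean(posts):.4f} "
      f"(analytic conjugate value = {q + 1.0})")

params = m.AgentParams()  # kappa = 1: C follows the evidence
match = [m.particle_update(0.0, 2.0, m.LearningObservation(o=0.0), params,
                           np.random.default_rng(s))[1] for s in range(100)]
surprise = [m.particle_update(0.0, 2.0, m.LearningObservation(o=6.0), params,
                              np.random.default_rng(s))[1] for s in range(100)]
print(f"posterior C after a confirming outcome: {np.mean(match):.2f} "
      f"(prior was 2.0)")
print(f"posterior C after a surprising outcome: {np.mean(surprise):.2f}")
print("Confirming evidence favours low-spread particles and shrinks C; a "
      "surprise favours high-C particles — the mechanism that re-triggers "
      "mental simulation after contingencies change.")
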