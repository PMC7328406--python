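# trailmc

Self-avoiding ("trail") MCMC sampling with an externalized memory, and the
trajectory-analysis pipeline for central-place exploration experiments.

## The problem

A central-place forager — an ant scouting the arena around its nest — keeps
covering the same ground, and so does a Metropolis–Hastings (M–H) random
walker sampling a probability distribution.  Social insects solve this with
stigmergy: chemical markers (pheromones or cuticular-hydrocarbon
footprints) left on explored ground let nest-mates steer elsewhere, with no
internal map and no central controller.  `trailmc` implements both sides of
this analogy for researchers in collective behaviour and anyone who needs
to sample sparse discrete distributions cheaply:

- a **sampler** in which the walker deposits a marker on every visited cell
  into an externalized memory *M* and targets **P×P/M** instead of *P*:
  the *P*² factor prioritizes high-probability regions, the *M* divisor
  repels the walker from ground already covered, and since *M* → *P* as
  deposits accumulate, the objective relaxes back to *P* itself.  A
  periodic "cleaning" condition (reset of *M* to its Dirichlet prior) and
  an exponential marker decay e^(−λ)·M are included;
- an **analysis pipeline** that turns tracked exploration trajectories into
  a blurred log-polar target density, measures convergence toward it by
  cross-entropy CE(P, Q) = −Σ P ln Q (nats) as walkers accumulate, builds a
  memoryless **Markov-ant** null by movement-segment resampling, and tests
  treatment contrasts with paired permutation, χ² goodness-of-fit and exact
  multinomial tests;
- a **synthetic cohort generator** (correlated random walks with a
  repulsive footprint field between successive walkers) so every stage is
  testable end to end without animal data.

## Worked example

`examples/cohort_treatment_contrast.py` simulates matched cohorts of
central-place walkers (3 colonies × 6 walkers, 45 min at 0.1 s in a
90 × 90 cm arena): in the **NC** cohort each walker is steered away from
the accumulated footprint field of its predecessors, in the **C** cohort
the field is wiped before every release.  It then builds the pooled
log-polar target, computes cumulative CE curves by release order, and runs
the paired permutation test on orders 2–6:

```
pooled log-polar target: 125 x 177, H = 8.315 nats

mean CE (nats) toward the final target, by walker order:
order:       1        2        3        4        5        6
   NC:  11.855   10.559    9.842    9.743    9.317    9.078
    C:  11.855   11.405   10.958   10.682   10.631   10.495

paired permutation test, orders 2-6: mean(NC) - mean(C) = -1.126 nats,
p = 6.104e-05 (exhaustive, 32768 permutations)
```

Order 1 is identical by construction (the first walker sees a clean arena
in both treatments).  From order 2 on, the footprint-informed NC cohort's
cumulative density approaches the target faster — its CE sits about a nat
below C — and the exhaustive sign-flip test over the 15 (colony, order)
pairs finds the difference decisive.  A lower CE means the colony's pooled
coverage resembles the well-explored arena more closely; the floor is the
target's entropy H.

The other examples: `sparse_target_sampling.py` (trail sampler vs plain
M–H on a sparse gamma target — the trail sampler's running sample ends, on
average, ≈ 0.4 nats closer to the target after 60,000 steps),
`markov_ant_null.py` (the memoryless null converges slowest), and
`exit_side_analysis.py` (exit-side heterogeneity: χ²₃ and exact multinomial
tests against uniform sides).

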