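"""Exit-side heterogeneity: which side of a central square walkers leave by.

Counts the first crossing of a nest-centred square for each trajectory of a
synthetic cohort with a planted upper-left quadrant preference, then tests
the counts against uniformity with a chi-square goodness-of-fit test and an
exact multinomial test (appropriate at small sample sizes).
"""

import trailmc as tm
from trailmc.pipeline import exit_sides

cfg = tm.CohortConfig(n_colonies=6, quadrant_bias=(1, 4, 1, 1), bias_gain=0.25,
                      avoidance_strength=0.0, seed=8)
trajs = tm.simulate_cohort(cfg)
summary = exit_sides(trajs, square_half_width_mm=250.0)
print(f"first-exit sides through the central 50 x 50 cm square "
      f"({len(trajs)} walkers, {summary.n_non_exiting} never left):")
for side, count in summary.counts.items():
    print(f"  {side:>6}: {count}")

counts = summary.as_list()
chi = tm.chi_square_gof(counts)
print(f"\nchi-square GOF vs uniform: X2({chi.df}) = {chi.statistic:.2f}, "
      f"p = {chi.p_value:.4g}")
p_emt = tm.exact_multinomial_test(counts)
print(f"exact multinomial test:    p = {p_emt:.4g}")
print("small p-values: the planted quadrant preference shows up as a "
      "significant exit-side bias.")
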