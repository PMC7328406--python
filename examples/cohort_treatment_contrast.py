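"""The cleaning-treatment contrast on a synthetic exploration cohort.

Simulates matched cohorts of central-place walkers (3 colonies x 6 walkers,
45 min each): in the NC cohort each walker avoids the accumulated footprint
field of its predecessors; in the C cohort the field is wiped before every
release.  The pooled trajectories define the empirical target; cumulative
per-colony densities are compared to it by cross-entropy as walkers
accumulate, and the NC-vs-C difference on walkers 2-6 is assessed with an
exhaustive paired sign-flip permutation test.
"""

import trailmc as tm
from trailmc.pipeline import LogPolarGridSpec, build_target, cumulative_ce_curves

spec = LogPolarGridSpec.coarse(5)  # reduced lattice, same physical blur
nc, c = tm.simulate_treatment_pair(tm.CohortConfig(seed=11))
print(f"simulated {len(nc)} NC and {len(c)} C trajectories "
      f"({nc[0].n_points} points each)")

target = build_target(nc + c, spec)
print(f"pooled log-polar target: {target.n_rows} x {target.n_cols}, "
      f"H = {tm.entropy(target):.3f} nats")

curves = cumulative_ce_curves(nc + c, target, spec)
print("\nmean CE (nats) toward the final target, by walker order:")
print("order:", "  ".join(f"{k:>7d}" for k in range(1, 7)))
for treatment in ("NC", "C"):
    print(f"{treatment:>5}:", "  ".join(f"{v:7.3f}" for v in curves.mean(treatment)))

res = tm.permutation_test(curves.paired_samples("NC", "C"))
print(f"\npaired permutation test, orders 2-6: "
      f"mean(NC) - mean(C) = {res.statistic:+.3f} nats, "
      f"p = {res.p_value:.4g} ({res.scheme}, {res.n_permutations} permutations)")
print("negative statistic + small p: walkers informed by nest-mate "
      "footprints cover the arena significantly faster.")
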