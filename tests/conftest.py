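import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

import trailmc as tm
from trailmc.pipeline import (
    LogPolarGridSpec, build_density, build_target, cartesian_to_logpolar,
    cumulative_ce_curves, periodic_pad, remove_mask_region,
)


@pytest.fixture(scope="session")
def coarse_spec() -> LogPolarGridSpec:
    """Reduced-resolution log-polar lattice (×5 step, same physical blur)."""
    return LogPolarGridSpec.coarse(5)


@pytest.fixture(scope="session")
def cohort_pair():
    """One matched NC/C synthetic cohort pair at the default planted effect."""
    return tm.simulate_treatment_pair(tm.CohortConfig(seed=0))


def _successive_overlaps(trajs, spec):
    """Mean inner product of successive walkers' individual densities."""
    by_colony: dict[str, list] = {}
    for tr in trajs:
        by_colony.setdefault(tr.colony, []).append(tr)
    vals = []
    for ants in by_colony.values():
        ants = sorted(ants, key=lambda a: a.order)
        dens = []
        for a in ants:
            m = remove_mask_region(a)
            th, lr, _ = cartesian_to_logpolar(m.x, m.y, lnr_min=spec.lnr_min,
                                              lnr_max=spec.lnr_max)
            th, lr = periodic_pad(th, lr)
            dens.append(build_density(th, lr, spec).values)
        vals.extend(float((d1 * d2).sum()) for d1, d2 in zip(dens, dens[1:]))
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def treatment_study(coarse_spec):
    """20 seeded NC-vs-C replicates: CE curves, permutation p, overlaps.

    Each replicate simulates matched cohorts (avoidance coupling active in
    NC, markers wiped in C), builds the pooled target, computes cumulative
    CE curves per colony, and tests NC vs C on orders 2-6 by paired
    permutation.  Also records the successive-walker density overlap for
    each treatment.
    """
    out = []
    for seed in range(20):
        nc, c = tm.simulate_treatment_pair(tm.CohortConfig(seed=seed))
        target = build_target(nc + c, coarse_spec)
        curves = cumulative_ce_curves(nc + c, target, coarse_spec)
        res = tm.permutation_test(curves.paired_samples("NC", "C"))
        out.append({
            "seed": seed,
            "entropy": tm.entropy(target),
            "nc_mean": curves.mean("NC"),
            "c_mean": curves.mean("C"),
            "p_value": res.p_value,
            "statistic": res.statistic,
            "overlap_nc": _successive_overlaps(nc, coarse_spec),
            "overlap_c": _successive_overlaps(c, coarse_spec),
        })
    return out


@pytest.fixture(scope="session")
def sparse_study():
    """Sampler three-way comparison on 20 sparse 50x50 targets, T=60,000."""
    spec = tm.ExperimentSpec(name="fig3_sparse", seeds=tuple(range(20)))
    return tm.run_experiment(spec)["summary"]
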