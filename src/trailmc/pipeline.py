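"""From exploration trajectories to log-polar density targets and CE curves.

A cohort of central-place exploration trajectories — one walker at a time
released from a nest at the centre of a square arena, tracked at 0.1 s
resolution — is converted into an empirical target distribution in four
stages:

1. points under the central mask (a square of half-width 75 mm around the
   nest, where walkers linger and edge-follow) are removed;
2. Cartesian (x, y) in mm become log-polar (θ, ln r) about the nest, which
   roughly equalizes visit density across radii before histogramming;
3. the angular axis is padded periodically (each point duplicated 2π away)
   so the subsequent blur sees no artificial edge at θ = ±π;
4. points are counted on a regular (θ, ln r) lattice, blurred with an
   isotropic Gaussian, truncated back to θ ∈ [−π, π], and normalized.

The default lattice is θ step 0.01 over the padded range (1257 nodes) and
ln r step 0.0025 over (4.3, 6.5) (881 nodes), with blur σ = 30 cells —
in physical terms the blur widens from ~6 mm near the nest to ~40 mm at the
arena edge.  Coarser lattices for simulation studies keep the same physical
blur via :meth:`LogPolarGridSpec.coarse`.

Convergence of a treatment toward the full-cohort target is measured by the
cross-entropy of cumulative densities (walkers 1..k pooled per colony)
against the final target; the per-colony curves are averaged per treatment.
A memoryless "Markov ant" null walker is built by concatenating 1 s movement
segments resampled from the pooled cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import GridDistribution, cross_entropy
from .stats import PairedSamples

__all__ = [
    "Trajectory",
    "LogPolarGridSpec",
    "CECurveSet",
    "ExitSummary",
    "remove_mask_region",
    "cartesian_to_logpolar",
    "periodic_pad",
    "build_density",
    "build_target",
    "cumulative_ce_curves",
    "markov_ant_resample",
    "markov_ant_cohort",
    "exit_sides",
    "read_trajectories",
    "write_trajectories",
]

TRAJECTORY_COLUMNS = ["ant_id", "colony", "treatment", "order", "t_s", "x_mm", "y_mm"]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped planar path of one walker in arena coordinates (mm).

    Coordinates are arena-centred (origin at the nest), y increasing upward.
    Raw tracks have constant 0.1 s spacing; derived trajectories (e.g. after
    mask removal) may have gaps but timestamps stay strictly increasing.
    """

    ant_id: str
    colony: str
    treatment: str
    order: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"timestamps of {self.ant_id!r} must be strictly increasing")
        for arr, name in ((t, "t"), (x, "x"), (y, "y")):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        """Nominal duration: one sampling interval per recorded point."""
        if self.n_points < 2:
            return 0.0
        dt = float(np.median(np.diff(self.t)))
        return dt * (self.n_points - 1)

    def path_length_mm(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


@dataclass(frozen=True)
class LogPolarGridSpec:
    """Geometry of the (θ, ln r) histogram lattice.

    θ nodes sit at integer multiples of ``theta_step`` centred on 0; the
    padded axis spans ≈[−2π, 2π] and the truncated axis keeps nodes with
    |θ| ≤ π.  ln r nodes run from ``lnr_min`` to ``lnr_max`` inclusive.
    ``sigma`` is the Gaussian blur width in lattice cells, isotropic.
    """

    theta_step: float = 0.01
    lnr_min: float = 4.3
    lnr_max: float = 6.5
    lnr_step: float = 0.0025
    sigma: float = 30.0
    blur_truncate: float = 4.0

    def __post_init__(self) -> None:
        if min(self.theta_step, self.lnr_step) <= 0 or self.lnr_max <= self.lnr_min:
            raise ValueError("invalid lattice geometry")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def n_theta_half(self) -> int:
        """Number of θ nodes on each side of 0 in the truncated grid."""
        return int(math.floor(math.pi / self.theta_step + 1e-12))

    @property
    def n_theta_padded(self) -> int:
        return 4 * self.n_theta_half + 1

    @property
    def n_theta(self) -> int:
        return 2 * self.n_theta_half + 1

    @property
    def n_lnr(self) -> int:
        return int(round((self.lnr_max - self.lnr_min) / self.lnr_step)) + 1

    @property
    def padded_shape(self) -> tuple[int, int]:
        """(θ nodes, ln r nodes) of the padded histogram lattice."""
        return (self.n_theta_padded, self.n_lnr)

    @property
    def truncated_shape(self) -> tuple[int, int]:
        return (self.n_theta, self.n_lnr)

    @classmethod
    def coarse(cls, factor: int = 5, **overrides) -> "LogPolarGridSpec":
        """A lattice coarsened by ``factor`` with the same physical blur width."""
        overrides.setdefault("sigma", 30.0 / factor)
        return cls(theta_step=0.01 * factor, lnr_step=0.0025 * factor, **overrides)

    def bin_indices(self, theta: np.ndarray, lnr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-node bin indices on the padded lattice."""
        it = np.rint(theta / self.theta_step).astype(np.int64) + 2 * self.n_theta_half
        ir = np.rint((lnr - self.lnr_min) / self.lnr_step).astype(np.int64)
        it = np.clip(it, 0, self.n_theta_padded - 1)
        ir = np.clip(ir, 0, self.n_lnr - 1)
        return it, ir


def remove_mask_region(traj: Trajectory, half_width_mm: float = 75.0) -> Trajectory:
    """Drop points under the central square mask (max-norm < half width).

    Points exactly on the mask boundary are kept (closed outward).
    """
    keep = np.maximum(np.abs(traj.x), np.abs(traj.y)) >= half_width_mm
    return replace(traj, t=traj.t[keep], x=traj.x[keep], y=traj.y[keep])


def cartesian_to_logpolar(x: np.ndarray, y: np.ndarray,
                          center: tuple[float, float] = (0.0, 0.0),
                          lnr_min: float = 4.3, lnr_max: float = 6.5,
                          ) -> tuple[np.ndarray, np.ndarray, int]:
    """Map (x, y) mm to (θ, ln r) about the nest; filter the ln r range.

    θ = atan2(y−cy, x−cx) ∈ (−π, π]; ln r is the natural log of the
    Euclidean radius in mm.  Points with ln r outside the *open* interval
    (lnr_min, lnr_max) — including zero-radius points — are dropped; the
    number dropped is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    dx = x - center[0]
    dy = y - center[1]
    r = np.hypot(dx, dy)
    with np.errstate(divide="ignore"):
        lnr = np.log(r)
    keep = (lnr > lnr_min) & (lnr < lnr_max)
    theta = np.arctan2(dy[keep], dx[keep])
    return theta, lnr[keep], int((~keep).sum())


def periodic_pad(theta: np.ndarray, lnr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate every point 2π away in θ: θ ≤ 0 shifts up, θ > 0 shifts down.

    Doubles the point count, extending (−π, π] to (−2π, 2π] so a blur sees
    no artificial edge at ±π.
    """
    shift = np.where(theta <= 0, theta + 2 * math.pi, theta - 2 * math.pi)
    return np.concatenate([theta, shift]), np.concatenate([lnr, lnr])


def build_density(theta: np.ndarray, lnr: np.ndarray,
                  spec: LogPolarGridSpec) -> GridDistribution:
    """Histogram padded points, blur, truncate to |θ| ≤ π, normalize.

    The blur is an isotropic Gaussian of ``spec.sigma`` lattice cells
    (kernel truncated at ``spec.blur_truncate`` σ, zero-padded boundary —
    the periodic θ padding is what protects the seam).  Mass is conserved
    on the padded lattice; the final normalization makes the truncated grid
    a probability distribution.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("no points to bin; cannot build a density")
    it, ir = spec.bin_indices(theta, np.asarray(lnr, dtype=np.float64))
    counts = np.zeros(spec.padded_shape, dtype=np.float64)
    np.add.at(counts, (it, ir), 1.0)
    if spec.sigma > 0:
        counts = gaussian_filter(counts, sigma=spec.sigma, mode="constant",
                                 truncate=spec.blur_truncate)
    half = spec.n_theta_half
    center = 2 * half
    truncated = counts[center - half: center + half + 1, :]
    return GridDistribution(truncated / truncated.sum())


def _pooled_logpolar(trajs, spec, mask_half_width_mm, center):
    thetas, lnrs = [], []
    for tr in trajs:
        masked = remove_mask_region(tr, mask_half_width_mm)
        th, lr, _ = cartesian_to_logpolar(masked.x, masked.y, center,
                                          spec.lnr_min, spec.lnr_max)
        thetas.append(th)
        lnrs.append(lr)
    return np.concatenate(thetas), np.concatenate(lnrs)


def build_target(trajs: list[Trajectory], spec: LogPolarGridSpec | None = None,
                 mask_half_width_mm: float = 75.0,
                 center: tuple[float, float] = (0.0, 0.0)) -> GridDistribution:
    """Empirical target distribution from a pooled cohort of trajectories.

    Composes mask removal → log-polar transform → periodic padding →
    blurred histogram over the pooled point set.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    spec = spec or LogPolarGridSpec()
    theta, lnr = _pooled_logpolar(trajs, spec, mask_half_width_mm, center)
    theta, lnr = periodic_pad(theta, lnr)
    return build_density(theta, lnr, spec)


@dataclass
class CECurveSet:
    """Cross-entropy convergence curves by walker order.

    ``curves[(treatment, colony)]`` is the CE (nats) of the cumulative
    density of walkers 1..k against the final target, indexed k−1.
    """

    curves: dict[tuple[str, str], np.ndarray]
    n_orders: int

    @property
    def treatments(self) -> list[str]:
        return sorted({t for t, _ in self.curves})

    def colony_matrix(self, treatment: str) -> np.ndarray:
        """(n_colonies, n_orders) CE matrix, colonies sorted by name."""
        keys = sorted(k for k in self.curves if k[0] == treatment)
        if not keys:
            raise KeyError(f"no colonies for treatment {treatment!r}")
        return np.vstack([self.curves[k] for k in keys])

    def mean(self, treatment: str) -> np.ndarray:
        return self.colony_matrix(treatment).mean(axis=0)

    def sem(self, treatment: str) -> np.ndarray:
        m = self.colony_matrix(treatment)
        if m.shape[0] < 2:
            return np.full(m.shape[1], np.nan)
        return m.std(axis=0, ddof=1) / math.sqrt(m.shape[0])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"treatment": t, "colony": col, "order": k + 1, "ce_nats": ce}
            for (t, col), curve in sorted(self.curves.items())
            for k, ce in enumerate(curve)
        ]
        return pd.DataFrame(rows)

    def paired_samples(self, treatment_a: str, treatment_b: str,
                       orders: list[int] | None = None) -> PairedSamples:
        """Pair the two treatments' CE values by (colony rank, order).

        Colonies are paired by sorted position within each treatment (the
        experimental design pairs release days, not colony identity across
        treatments).  Default orders 2..n: the first walker out sees a clean
        arena in both treatments, so it carries no treatment signal.
        """
        orders = orders or list(range(2, self.n_orders + 1))
        ma = self.colony_matrix(treatment_a)
        mb = self.colony_matrix(treatment_b)
        if ma.shape != mb.shape:
            raise ValueError("treatments have different numbers of colonies")
        labels, va, vb = [], [], []
        for ci in range(ma.shape[0]):
            for k in orders:
                labels.append((ci, k))
                va.append(ma[ci, k - 1])
                vb.append(mb[ci, k - 1])
        return PairedSamples(labels, np.array(va), np.array(vb))


def cumulative_ce_curves(trajs: list[Trajectory], final_target: GridDistribution,
                         spec: LogPolarGridSpec | None = None,
                         mask_half_width_mm: float = 75.0,
                         center: tuple[float, float] = (0.0, 0.0),
                         smoothing_epsilon: float = 1e-9) -> CECurveSet:
    """CE convergence of cumulative per-colony densities toward the target.

    For each (treatment, colony) and order k, the walkers of orders 1..k are
    pooled, the density rebuilt with the same lattice, and compared to
    ``final_target`` by cross-entropy.  Each cumulative estimate is mixed
    with a uniform floor of mass ``smoothing_epsilon`` so it is strictly
    positive on the target's support (set 0 to disable).  Gibbs' inequality
    bounds every value below by the target's entropy.
    """
    spec = spec or LogPolarGridSpec()
    if final_target.shape != spec.truncated_shape:
        raise ValueError("final_target shape does not match the lattice spec")
    groups: dict[tuple[str, str], dict[int, list[Trajectory]]] = {}
    for tr in trajs:
        groups.setdefault((tr.treatment, tr.colony), {}).setdefault(tr.order, []).append(tr)
    n_orders = max(o for by_order in groups.values() for o in by_order)

    half = spec.n_theta_half
    ctr = 2 * half
    ncells = final_target.values.size
    curves: dict[tuple[str, str], np.ndarray] = {}
    for key, by_order in sorted(groups.items()):
        missing = [k for k in range(1, n_orders + 1) if k not in by_order]
        if missing:
            raise ValueError(f"treatment/colony {key} is missing orders {missing}")
        cum = np.zeros(spec.padded_shape, dtype=np.float64)
        ces = np.empty(n_orders)
        for k in range(1, n_orders + 1):
            theta, lnr = _pooled_logpolar(by_order[k], spec, mask_half_width_mm, center)
            if theta.size:
                theta, lnr = periodic_pad(theta, lnr)
                it, ir = spec.bin_indices(theta, lnr)
                np.add.at(cum, (it, ir), 1.0)
            if cum.sum() == 0:
                raise ValueError(f"no points for {key} up to order {k}")
            blurred = gaussian_filter(cum, sigma=spec.sigma, mode="constant",
                                      truncate=spec.blur_truncate) if spec.sigma > 0 else cum
            q = blurred[ctr - half: ctr + half + 1, :]
            q = q / q.sum()
            if smoothing_epsilon > 0:
                q = (1.0 - smoothing_epsilon) * q + smoothing_epsilon / ncells
            ces[k - 1] = cross_entropy(final_target, GridDistribution(q))
        curves[key] = ces
    return CECurveSet(curves, n_orders)


def _segment_library(pool: list[Trajectory], segment_s: float, dt_s: float) -> np.ndarray:
    """Non-overlapping runs of segment_s/dt_s consecutive displacement vectors.

    Returns an (n_segments, steps, 2) array of within-segment cumulative
    displacements.
    """
    steps = int(round(segment_s / dt_s))
    segs = []
    for tr in pool:
        d = np.column_stack([np.diff(tr.x), np.diff(tr.y)])
        n_full = len(d) // steps
        if n_full:
            blocks = d[: n_full * steps].reshape(n_full, steps, 2)
            segs.append(np.cumsum(blocks, axis=1))
    if not segs:
        raise ValueError("trajectory pool yields no complete movement segments")
    return np.concatenate(segs, axis=0)


def markov_ant_resample(pool: list[Trajectory], duration_s: float = 2700.0,
                        segment_s: float = 1.0, arena_mm: float = 900.0,
                        seed: int | np.random.Generator = 0, dt_s: float = 0.1,
                        max_retries: int = 10_000,
                        ant_id: str = "markov", colony: str = "markov",
                        treatment: str = "markov", order: int = 1,
                        _library: np.ndarray | None = None) -> Trajectory:
    """A memoryless null walker: concatenated resampled 1 s movement segments.

    Starting from the nest, segments of ``segment_s`` worth of consecutive
    displacement vectors are drawn uniformly from the pooled cohort and
    appended; a candidate segment that would leave the arena is rejected and
    redrawn (up to ``max_retries`` per segment).  The walker has neither
    internal nor externalized memory.
    """
    if not pool and _library is None:
        raise ValueError("empty trajectory pool")
    lib = _library if _library is not None else _segment_library(pool, segment_s, dt_s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = arena_mm / 2.0
    n_segments = int(round(duration_s / segment_s))
    steps = lib.shape[1]
    xs = np.empty(n_segments * steps + 1)
    ys = np.empty(n_segments * steps + 1)
    xs[0] = ys[0] = 0.0
    px = py = 0.0
    n_lib = len(lib)
    for s in range(n_segments):
        for attempt in range(max_retries + 1):
            seg = lib[rng.integers(0, n_lib)]
            cx = px + seg[:, 0]
            cy = py + seg[:, 1]
            if max(np.abs(cx).max(), np.abs(cy).max()) <= half:
                break
        else:
            raise RuntimeError(
                f"no admissible segment from ({px:.0f}, {py:.0f}) after {max_retries} draws")
        lo = 1 + s * steps
        xs[lo: lo + steps] = cx
        ys[lo: lo + steps] = cy
        px, py = cx[-1], cy[-1]
    t = np.arange(len(xs)) * dt_s
    return Trajectory(ant_id, colony, treatment, order, t, xs, ys)


def markov_ant_cohort(pool: list[Trajectory], n_colonies: int = 100,
                      ants_per_colony: int = 6, duration_s: float = 2700.0,
                      segment_s: float = 1.0, arena_mm: float = 900.0,
                      seed: int = 0, dt_s: float = 0.1) -> list[Trajectory]:
    """Colonies of independent Markov-ant null walkers (benchmark cohorts)."""
    lib = _segment_library(pool, segment_s, dt_s)
    rng = np.random.default_rng(seed)
    out = []
    for ci in range(n_colonies):
        colony = f"markov{ci:03d}"
        for order in range(1, ants_per_colony + 1):
            out.append(markov_ant_resample(
                [], duration_s, segment_s, arena_mm, rng, dt_s,
                ant_id=f"{colony}-a{order}", colony=colony,
                treatment="markov", order=order, _library=lib))
    return out


_SIDES = ("right", "left", "top", "bottom")


@dataclass(frozen=True)
class ExitSummary:
    """First-exit sides through a nest-centred square, plus non-exiters."""

    counts: dict[str, int]
    n_non_exiting: int
    sides: list[str | None] = field(default_factory=list)

    def as_list(self, order: tuple[str, ...] = ("top", "bottom", "left", "right")) -> list[int]:
        return [self.counts[s] for s in order]


def exit_sides(trajs: list[Trajectory], square_half_width_mm: float) -> ExitSummary:
    """Which side of a centred square each trajectory first exits.

    The first segment crossing from inside (max-norm ≤ half width) to
    outside is interpolated linearly; the side whose boundary is reached
    first (smallest interpolation parameter) is assigned.  Exact corner hits
    break ties in the order right, left, top, bottom.  Trajectories that
    never leave the square are excluded from the counts and tallied
    separately.
    """
    w = float(square_half_width_mm)
    counts = {s: 0 for s in _SIDES}
    sides: list[str | None] = []
    n_non_exiting = 0
    for tr in trajs:
        outside = np.maximum(np.abs(tr.x), np.abs(tr.y)) > w
        idx = np.flatnonzero(outside)
        if idx.size == 0:
            n_non_exiting += 1
            sides.append(None)
            continue
        i = int(idx[0])
        if i == 0:
            x1, y1 = tr.x[0], tr.y[0]
            side = ("right" if x1 > w else "left") if abs(x1) >= abs(y1) else \
                   ("top" if y1 > w else "bottom")
        else:
            x0, y0 = tr.x[i - 1], tr.y[i - 1]
            x1, y1 = tr.x[i], tr.y[i]
            cands = []
            if x1 > w:
                cands.append(((w - x0) / (x1 - x0), "right"))
            if x1 < -w:
                cands.append(((-w - x0) / (x1 - x0), "left"))
            if y1 > w:
                cands.append(((w - y0) / (y1 - y0), "top"))
            if y1 < -w:
                cands.append(((-w - y0) / (y1 - y0), "bottom"))
            side = min(cands, key=lambda c: c[0])[1]
        counts[side] += 1
        sides.append(side)
    return ExitSummary(counts, n_non_exiting, sides)


def write_trajectories(trajs: list[Trajectory], path) -> None:
    """Write a cohort as CSV: ant_id,colony,treatment,order,t_s,x_mm,y_mm."""
    frames = [
        pd.DataFrame({
            "ant_id": tr.ant_id, "colony": tr.colony, "treatment": tr.treatment,
            "order": tr.order, "t_s": tr.t, "x_mm": tr.x, "y_mm": tr.y,
        })
        for tr in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path, arena_mm: float = 900.0, dt_s: float = 0.1,
                      validate: bool = True) -> list[Trajectory]:
    """Read a trajectory CSV, optionally validating spacing and arena bounds."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file is missing columns {missing}")
    out = []
    for (ant_id, colony), grp in df.groupby(["ant_id", "colony"], sort=False):
        t = grp["t_s"].to_numpy(dtype=np.float64)
        x = grp["x_mm"].to_numpy(dtype=np.float64)
        y = grp["y_mm"].to_numpy(dtype=np.float64)
        if validate:
            if len(t) > 1 and not np.allclose(np.diff(t), dt_s, atol=1e-6):
                raise ValueError(f"{ant_id!r}: timestamps not spaced by {dt_s} s")
            half = arena_mm / 2.0 + 1e-6
            if np.abs(x).max(initial=0) > half or np.abs(y).max(initial=0) > half:
                raise ValueError(f"{ant_id!r}: points outside the {arena_mm} mm arena")
        out.append(Trajectory(str(ant_id), str(colony), str(grp["treatment"].iloc[0]),
                              int(grp["order"].iloc[0]), t, x, y))
    return out
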