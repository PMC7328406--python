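"""Metropolis–Hastings and self-avoiding "trail" MCMC on a periodic 2D lattice.

The trail sampler models an ant that cannot remember where it has been but
marks every cell it visits: an externalized memory *M* starts as a uniform
Dirichlet prior (``alpha`` pseudo-counts per cell) and gains one deposit at
the walker's cell after every step, accepted or not.  Proposals add an
independent uniform draw from {−1, 0, +1} to each coordinate (the Moore
neighbourhood including the current cell), wrapped periodically.  The
acceptance ratio multiplies the classic M–H criterion P(prop)/P(curr) by
(P(prop)/M(prop)) / (P(curr)/M(curr)), so the chain samples from P×P/M:
the squared term prioritizes high-probability regions while the deposits
repel the walker from ground already covered.  As M accumulates where the
walker has been, M → P and the objective relaxes back to P itself.

Renormalization of M is handled lazily — raw weights are used directly,
which is exact because any global scale of M cancels in the ratio.

A "cleaning" condition resets the deposit field to the pure prior at given
step indices, modelling the experimental removal of chemical markers between
successive ants.  An optional exponential decay multiplies the deposit
excess by e^(−λ) each step, modelling pheromone evaporation; the prior floor
never decays, keeping M strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import GridDistribution, cross_entropy

__all__ = [
    "WalkerState",
    "MemoryModel",
    "ChainConfig",
    "ChainTrace",
    "propose",
    "acceptance_ratio",
    "step",
    "run_chain",
    "visit_distribution",
    "transition_matrix",
    "cleaning_schedule",
]

VARIANTS = ("plain_mh", "trail")

# Moore neighbourhood offsets in the fixed order the proposal enumerates them.
_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]


@dataclass(frozen=True)
class WalkerState:
    """Lattice position of the walker (0-based row/column indices)."""

    row: int
    col: int


class MemoryModel:
    """The walker's externalized memory: per-cell prior plus deposits.

    The weight of a cell is ``alpha + deposits[r, c]`` (deposits decayed if
    ``decay_lambda > 0``).  Weights are kept unnormalized; callers needing a
    distribution use :meth:`normalized`.
    """

    def __init__(self, shape: tuple[int, int], alpha: float = 1.0,
                 decay_lambda: float = 0.0, deposits: np.ndarray | None = None):
        if not (alpha > 0):
            raise ValueError("Dirichlet prior alpha must be strictly positive")
        if decay_lambda < 0:
            raise ValueError("decay constant must be nonnegative")
        self.alpha = float(alpha)
        self.decay_lambda = float(decay_lambda)
        if deposits is None:
            self.deposits = np.zeros(shape, dtype=np.float64)
        else:
            d = np.asarray(deposits, dtype=np.float64)
            if d.shape != tuple(shape):
                raise ValueError("deposit field shape mismatch")
            if np.any(d < 0):
                raise ValueError("deposits must be nonnegative")
            self.deposits = d.copy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.deposits.shape

    @property
    def weights(self) -> np.ndarray:
        return self.alpha + self.deposits

    def weight(self, row: int, col: int) -> float:
        return self.alpha + self.deposits[row, col]

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def deposit(self, row: int, col: int, amount: float = 1.0) -> None:
        self.deposits[row, col] += amount

    def decay_step(self) -> None:
        """Apply one step of exponential decay to the deposit excess."""
        if self.decay_lambda > 0:
            self.deposits *= math.exp(-self.decay_lambda)

    def reset(self) -> None:
        """Cleaning: drop all deposits, back to the pure prior."""
        self.deposits[:] = 0.0

    def normalized(self) -> GridDistribution:
        return GridDistribution(self.weights / self.total)

    def copy(self) -> "MemoryModel":
        return MemoryModel(self.shape, self.alpha, self.decay_lambda, self.deposits)


@dataclass(frozen=True)
class ChainConfig:
    """Configuration of one sampler run.

    ``ce_snapshot_interval`` requests periodic cross-entropy measurements of
    the running estimate against the target; ``ce_estimator`` selects the
    estimate: the smoothed visit histogram (``"visits"``, the sample itself)
    or the normalized memory (``"memory"``).
    """

    variant: str = "trail"
    n_steps: int = 60_000
    alpha: float = 1.0
    decay_lambda: float = 0.0
    cleaning_times: tuple[int, ...] = ()
    seed: int = 0
    start: WalkerState | str = "uniform-random"
    ce_snapshot_interval: int | None = None
    ce_estimator: str = "visits"
    ce_smoothing_alpha: float = 1.0
    freeze_memory: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if not (self.alpha > 0):
            raise ValueError("alpha must be strictly positive")
        if self.decay_lambda < 0:
            raise ValueError("decay_lambda must be nonnegative")
        times = tuple(sorted(int(t) for t in self.cleaning_times))
        if any(t < 1 or t > self.n_steps for t in times):
            raise ValueError(f"cleaning times {times} outside [1, n_steps={self.n_steps}]")
        object.__setattr__(self, "cleaning_times", times)
        if self.ce_snapshot_interval is not None and self.ce_snapshot_interval < 1:
            raise ValueError("ce_snapshot_interval must be a positive integer")
        if self.ce_estimator not in ("visits", "memory"):
            raise ValueError("ce_estimator must be 'visits' or 'memory'")


@dataclass
class ChainTrace:
    """Result of one sampler run.

    ``states`` holds the walker's post-decision position after each step as
    an (n_steps, 2) integer array; ``ce_curve`` the (step, CE nats) snapshots
    requested; ``final_memory`` the memory at the end of the run.
    """

    states: np.ndarray
    ce_curve: list[tuple[int, float]]
    final_memory: MemoryModel
    config: ChainConfig

    def __len__(self) -> int:
        return len(self.states)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.final_memory.shape

    def visit_counts(self) -> np.ndarray:
        counts = np.zeros(self.grid_shape, dtype=np.float64)
        if len(self.states):
            np.add.at(counts, (self.states[:, 0], self.states[:, 1]), 1.0)
        return counts


def cleaning_schedule(n_steps: int, n_resets: int = 5) -> tuple[int, ...]:
    """Evenly spaced reset times: resets after each of the first n 'ants'.

    For the benchmark run of 60,000 steps and 5 resets this gives
    (10000, 20000, ..., 50000) — one reset after each ant's 10,000-step bout,
    six ants in total.
    """
    bout = n_steps // (n_resets + 1)
    return tuple(bout * k for k in range(1, n_resets + 1))


def propose(state: WalkerState, rng: np.random.Generator,
            n_rows: int, n_cols: int) -> WalkerState:
    """Propose a Moore-neighbourhood move with periodic wrap.

    Each coordinate gets an independent uniform draw from {−1, 0, +1}; all 9
    outcomes (including staying put) have probability 1/9.
    """
    dr, dc = rng.integers(-1, 2, size=2)
    return WalkerState((state.row + int(dr)) % n_rows, (state.col + int(dc)) % n_cols)


def _ratio(pc: float, pp: float, mc: float, mp: float, trail: bool) -> float:
    """Acceptance ratio with explicit zero-mass handling.

    Both cells zero → 1 (free diffusion on null support); current zero →
    +inf (always escape onto positive support); proposed zero → 0.
    """
    if pc > 0.0 and pp > 0.0:
        if trail:
            return (pp * pp * mc) / (pc * pc * mp)
        return pp / pc
    if pc == 0.0 and pp == 0.0:
        return 1.0
    if pc == 0.0:
        return math.inf
    return 0.0


def acceptance_ratio(p: GridDistribution, m: MemoryModel, current: WalkerState,
                     proposed: WalkerState, variant: str = "trail") -> float:
    """M–H acceptance ratio for the move current → proposed.

    ``plain_mh`` returns P(prop)/P(curr); ``trail`` multiplies in
    (P(prop)/M(prop)) / (P(curr)/M(curr)), targeting P²/M.  Raw memory
    weights are used: the ratio is invariant under any global rescaling of
    M, so lazy normalization is exact.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    pc = float(p.values[current.row, current.col])
    pp = float(p.values[proposed.row, proposed.col])
    mc = m.weight(current.row, current.col)
    mp = m.weight(proposed.row, proposed.col)
    return _ratio(pc, pp, mc, mp, variant == "trail")


def step(p: GridDistribution, m: MemoryModel, state: WalkerState,
         rng: np.random.Generator, variant: str = "trail",
         freeze_memory: bool = False) -> WalkerState:
    """Advance the walker one step, mutating the memory.

    Draw order is fixed: two proposal integers, then one acceptance uniform
    (always consumed).  The move is accepted when ratio > 1 or ratio exceeds
    the uniform draw; one deposit then lands on the post-decision cell —
    even after a rejection — following one decay step if λ > 0.
    """
    cand = propose(state, rng, *m.shape)
    ratio = acceptance_ratio(p, m, state, cand, variant)
    u = rng.random()
    new = cand if (ratio > 1.0 or ratio > u) else state
    if not freeze_memory:
        m.decay_step()
        m.deposit(new.row, new.col)
    return new


def run_chain(p: GridDistribution, config: ChainConfig) -> ChainTrace:
    """Run a full chain: seeded, replayable, with cleaning resets.

    Proposal offsets and acceptance uniforms are pre-drawn from one seeded
    generator and consumed in step order, so a trace is reproducible from
    (target, config) alone.  Cleaning resets happen at the *end* of the
    named steps, after that step's deposit.
    """
    n_rows, n_cols = p.shape
    n = config.n_steps
    rng = np.random.default_rng(config.seed)

    if isinstance(config.start, WalkerState):
        r, c = config.start.row % n_rows, config.start.col % n_cols
    elif config.start == "uniform-random":
        r = int(rng.integers(0, n_rows))
        c = int(rng.integers(0, n_cols))
    else:
        raise ValueError(f"invalid start {config.start!r}")

    memory = MemoryModel((n_rows, n_cols), config.alpha, config.decay_lambda)
    ce_curve: list[tuple[int, float]] = []
    if n == 0:
        return ChainTrace(np.empty((0, 2), dtype=np.int32), ce_curve, memory, config)

    offsets = rng.integers(-1, 2, size=(n, 2))
    uniforms = rng.random(n)

    # Hot loop on plain Python floats/lists; numpy only at the boundaries.
    pv = p.values.tolist()
    dep = [[0.0] * n_cols for _ in range(n_rows)]
    visits = [[0] * n_cols for _ in range(n_rows)]
    states = np.empty((n, 2), dtype=np.int32)
    trail = config.variant == "trail"
    frozen = config.freeze_memory
    alpha = config.alpha
    lam = config.decay_lambda
    decay_mult = math.exp(-lam) if lam > 0 else 1.0
    inv_scale = 1.0  # lazy decay: true deposits = stored * (1/inv_scale)
    scale = 1.0
    clean_set = set(config.cleaning_times)
    snap = config.ce_snapshot_interval
    off_list = offsets.tolist()
    uni_list = uniforms.tolist()

    for t in range(1, n + 1):
        dr, dc = off_list[t - 1]
        nr = (r + dr) % n_rows
        nc = (c + dc) % n_cols
        pc = pv[r][c]
        pp = pv[nr][nc]
        if pc > 0.0 and pp > 0.0:
            if trail:
                mc = alpha + dep[r][c] * scale
                mp = alpha + dep[nr][nc] * scale
                ratio = (pp * pp * mc) / (pc * pc * mp)
            else:
                ratio = pp / pc
            accept = ratio > 1.0 or ratio > uni_list[t - 1]
        elif pc == 0.0 and pp == 0.0:
            accept = 1.0 > uni_list[t - 1]  # ratio == 1: always true for u in [0,1)
        elif pc == 0.0:
            accept = True
        else:
            accept = False
        if accept:
            r, c = nr, nc
        if not frozen:
            if lam > 0:
                scale *= decay_mult
                inv_scale /= decay_mult
                if inv_scale > 1e12:  # fold the lazy scale back in
                    for row in dep:
                        for j in range(n_cols):
                            row[j] *= scale
                    scale = 1.0
                    inv_scale = 1.0
            dep[r][c] += inv_scale
        visits[r][c] += 1
        states[t - 1, 0] = r
        states[t - 1, 1] = c
        if t in clean_set:
            dep = [[0.0] * n_cols for _ in range(n_rows)]
            scale = 1.0
            inv_scale = 1.0
        if snap is not None and t % snap == 0:
            if config.ce_estimator == "visits":
                est = np.asarray(visits, dtype=np.float64) + config.ce_smoothing_alpha
            else:
                est = alpha + np.asarray(dep, dtype=np.float64) * scale
            ce_curve.append((t, cross_entropy(p, GridDistribution(est / est.sum()))))

    memory = MemoryModel((n_rows, n_cols), alpha, lam,
                         np.asarray(dep, dtype=np.float64) * scale)
    return ChainTrace(states, ce_curve, memory, config)


def visit_distribution(trace: ChainTrace, smoothing_alpha: float = 0.0) -> GridDistribution:
    """Normalized visit histogram of a trace, with a Dirichlet pseudocount.

    ``smoothing_alpha > 0`` guarantees strict positivity so the result can
    serve as the estimate in a cross-entropy.
    """
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be nonnegative")
    counts = trace.visit_counts()
    return GridDistribution.from_counts(counts, pseudocount=smoothing_alpha)


def transition_matrix(p: GridDistribution, m: MemoryModel,
                      variant: str = "trail") -> np.ndarray:
    """Single-step transition matrix with the memory held fixed.

    Enumerates the 9 equiprobable proposals from every cell and integrates
    the accept/reject rule analytically (acceptance probability
    min(1, ratio)).  Rows are flat cell indices (row-major); each row sums
    to 1.  Useful for exact small-grid diagnostics: stationary
    distributions, limiting-case equivalences.
    """
    n_rows, n_cols = p.shape
    ncells = n_rows * n_cols
    T = np.zeros((ncells, ncells))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in _OFFSETS:
                nr, nc = (r + dr) % n_rows, (c + dc) % n_cols
                j = nr * n_cols + nc
                ratio = acceptance_ratio(p, m, WalkerState(r, c), WalkerState(nr, nc), variant)
                a = min(1.0, ratio)
                T[i, j] += a / 9.0
                T[i, i] += (1.0 - a) / 9.0
    return T
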