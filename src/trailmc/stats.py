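"""Resampling and categorical tests for treatment comparisons.

Three procedures, written from first principles:

* a paired sign-flip permutation test for comparing two treatments measured
  on the same (colony, order) cells — exhaustive over all 2^n sign patterns
  when feasible, Monte Carlo with the add-one correction otherwise;
* a chi-square goodness-of-fit test for categorical counts against stated
  proportions (e.g. uniform exit sides);
* an exact multinomial goodness-of-fit test by full enumeration, summing the
  probability of every outcome at most as probable as the observed one
  (the point-probability method) — appropriate for small samples where the
  chi-square approximation is poor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSamples",
    "PermutationResult",
    "ChiSquareResult",
    "permutation_test",
    "chi_square_gof",
    "exact_multinomial_test",
]

_TIE_REL_TOL = 1e-12


@dataclass(frozen=True)
class PairedSamples:
    """Two measurements per experimental cell, aligned by label."""

    labels: list
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=np.float64)
        b = np.asarray(self.values_b, dtype=np.float64)
        labels = list(self.labels)
        if not (len(labels) == len(a) == len(b)):
            raise ValueError("labels, values_a and values_b must have equal length")
        if len(set(map(tuple, map(np.atleast_1d, labels)))) != len(labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int
    scheme: str  # "exhaustive" | "monte-carlo"
    alternative: str


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) ±1 matrix."""
    bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
    return 2.0 * bits - 1.0


def permutation_test(samples: PairedSamples, n_perm: int | str = "auto",
                     seed: int | None = None,
                     alternative: str = "two-sided") -> PermutationResult:
    """Paired sign-flip permutation test on the mean within-pair difference.

    The statistic is mean(a) − mean(b).  Under the null the treatment labels
    within each pair are exchangeable, so the null distribution is built by
    independently flipping the sign of each pair's difference.  With
    ``n_perm="auto"`` (or ``"exhaustive"``) all 2^n patterns are enumerated
    when 2^n ≤ 2^20; otherwise ``n_perm`` Monte Carlo draws are used with
    the add-one correction p = (1 + #extreme) / (1 + n_perm), which never
    reports p below 1/(n_perm + 1).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = samples.differences
    t_obs = float(d.mean())

    exhaustive = n_perm in ("auto", "exhaustive")
    if exhaustive and 2 ** n > 2 ** 20:
        if n_perm == "exhaustive":
            raise ValueError(f"exhaustive enumeration infeasible for n={n} pairs")
        exhaustive = False
        n_perm = 10_000

    if exhaustive:
        t_null = _sign_matrix(n) @ d / n
        n_used = 2 ** n
        add_one = 0
        scheme = "exhaustive"
    else:
        n_perm = int(n_perm)
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        t_null = signs @ d / n
        n_used = n_perm
        add_one = 1
        scheme = "monte-carlo"

    tol = _TIE_REL_TOL * max(1.0, abs(t_obs))
    if alternative == "two-sided":
        extreme = np.abs(t_null) >= abs(t_obs) - tol
    elif alternative == "greater":
        extreme = t_null >= t_obs - tol
    else:
        extreme = t_null <= t_obs + tol
    p = (add_one + int(extreme.sum())) / (add_one + n_used)
    return PermutationResult(t_obs, float(p), n_used, scheme, alternative)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_gof(counts, expected_props=None) -> ChiSquareResult:
    """Chi-square goodness of fit: Σ (O−E)²/E against stated proportions.

    ``expected_props`` defaults to uniform; all proportions must be
    positive and sum to 1.  df = k − 1; the p-value is the upper tail of
    the chi-square distribution.
    """
    obs = np.asarray(counts, dtype=np.float64)
    if obs.ndim != 1 or len(obs) < 2 or np.any(obs < 0):
        raise ValueError("counts must be a 1D list of nonnegative integers, k >= 2")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    k = len(obs)
    if expected_props is None:
        props = np.full(k, 1.0 / k)
    else:
        props = np.asarray(expected_props, dtype=np.float64)
        if len(props) != k or np.any(props <= 0):
            raise ValueError("expected proportions must be positive, one per category")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("expected proportions must sum to 1")
    expected = total * props
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    return ChiSquareResult(stat, df, float(sps.chi2.sf(stat, df)))


def _compositions(n: int, k: int):
    """Yield all k-part compositions of n (weak, ordered)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def exact_multinomial_test(counts, probs=None, budget: int = 10 ** 6) -> float:
    """Exact multinomial goodness-of-fit p-value by full enumeration.

    p is the total probability of all outcome vectors whose multinomial
    probability is at most that of the observed vector (point-probability
    ordering).  Enumeration of the C(N+k−1, k−1) compositions beyond
    ``budget`` raises, suggesting the chi-square approximation instead.
    """
    obs = [int(c) for c in counts]
    if any(c < 0 for c in obs):
        raise ValueError("counts must be nonnegative")
    n = sum(obs)
    if n < 1:
        raise ValueError("need at least one observation")
    k = len(obs)
    if k < 2:
        raise ValueError("need at least two categories")
    if probs is None:
        p_vec = np.full(k, 1.0 / k)
    else:
        p_vec = np.asarray(probs, dtype=np.float64)
        if len(p_vec) != k or np.any(p_vec < 0) or abs(p_vec.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be nonnegative and sum to 1")
    n_outcomes = math.comb(n + k - 1, k - 1)
    if n_outcomes > budget:
        raise ValueError(
            f"{n_outcomes} outcomes exceed the enumeration budget ({budget}); "
            "use chi_square_gof for large samples")

    log_p = np.where(p_vec > 0, np.log(np.where(p_vec > 0, p_vec, 1.0)), -np.inf)
    lg_n = math.lgamma(n + 1)

    def log_pmf(vec) -> float:
        s = lg_n
        for c, lp in zip(vec, log_p):
            if c:
                if lp == -np.inf:
                    return -np.inf
                s += c * lp - math.lgamma(c + 1)
        return s

    lp_obs = log_pmf(obs)
    thresh = lp_obs + math.log1p(_TIE_REL_TOL) if lp_obs > -np.inf else -np.inf
    total = 0.0
    for vec in _compositions(n, k):
        lp = log_pmf(vec)
        if lp <= thresh:
            total += math.exp(lp)
    return min(1.0, total)
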