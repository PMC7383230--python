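"""Power and sample-size design for detecting an increased fraction of
signature-expressing cells with Fisher's exact test.

Exact unconditional power: with n cells per group and true expressing
proportions p0 (control) and p1 (alternative), the observed table
(k0, k1) has probability Binom(k0; n, p0) * Binom(k1; n, p1); the power
is the total probability of tables whose Fisher exact p-value is <=
alpha. Several p-value conventions are exposed:

* ``two-sided`` (default): probability-mass method — the sum of
  hypergeometric outcomes no more probable than the observed table (the
  common convention, and the one used by scipy / R ``fisher.test``);
* ``doubling``: twice the smaller one-sided tail, capped at 1;
* ``one-sided``: upper tail of k1;

each optionally as a mid-p variant (half weight on the observed
outcome). Exact tests have saw-toothed power in n, so the sample-size
search returns the smallest n from which power stays above target over a
run of consecutive values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CONVENTIONS = ("two-sided", "doubling", "one-sided")


@dataclass(frozen=True)
class PowerSpec:
    p0: float
    p1: float
    alpha: float = 0.00032
    power_target: float = 0.8

    def __post_init__(self):
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError("power_target must lie in (0, 1)")


@dataclass
class SampleSizeResult:
    n_per_group: int
    achieved_power: float


def fisher_two_sided_p(k0: int, k1: int, n: int, convention: str = "two-sided",
                       mid_p: bool = False) -> float:
    """Fisher exact p-value for the 2x2 table (k0 of n) vs (k1 of n)."""
    t = k0 + k1
    kmin, kmax = max(0, t - n), min(t, n)
    supp = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(supp, 2 * n, t, n)
    obs = pmf[k1 - kmin]
    if convention == "two-sided":
        p = pmf[pmf <= obs * (1 + 1e-7)].sum()
    elif convention == "one-sided":
        p = pmf[supp >= k1].sum()
    elif convention == "doubling":
        lo = pmf[supp <= k1].sum()
        hi = pmf[supp >= k1].sum()
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        raise ValueError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    if mid_p:
        p -= 0.5 * obs
    return float(min(p, 1.0))


def fisher_power(spec: PowerSpec, n: int, convention: str = "two-sided",
                 mid_p: bool = False, tail_eps: float = 1e-13) -> float:
    """Exact power of the Fisher test at n cells per group.

    Enumerates all (k0, k1) outcomes with non-negligible binomial
    probability (outcome pairs below ``tail_eps`` are dropped; the
    truncated mass is below ~1e-9 at screen-relevant n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b0 = stats.binom.pmf(np.arange(n + 1), n, spec.p0)
    b1 = stats.binom.pmf(np.arange(n + 1), n, spec.p1)
    k0s = np.flatnonzero(b0 > tail_eps)
    k1s = np.flatnonzero(b1 > tail_eps)

    # group outcomes by the conditioning margin t = k0 + k1 so each
    # hypergeometric vector is computed once
    pairs: dict = {}
    for k0 in k0s:
        for k1 in k1s:
            pairs.setdefault(k0 + k1, []).append((int(k0), int(k1)))
    power = 0.0
    for t, klist in pairs.items():
        kmin, kmax = max(0, t - n), min(t, n)
        supp = np.arange(kmin, kmax + 1)
        pmf = stats.hypergeom.pmf(supp, 2 * n, t, n)
        asc = np.sort(pmf)
        cum = np.cumsum(asc)
        upper = np.cumsum(pmf[::-1])[::-1]  # upper tail sums
        lower = np.cumsum(pmf)
        for k0, k1 in klist:
            i = k1 - kmin
            obs = pmf[i]
            if convention == "two-sided":
                j = np.searchsorted(asc, obs * (1 + 1e-7), side="right")
                p = cum[j - 1] if j > 0 else 0.0
            elif convention == "one-sided":
                p = upper[i]
            elif convention == "doubling":
                p = min(1.0, 2.0 * min(lower[i], upper[i]))
            else:
                raise ValueError(f"unknown convention {convention!r}")
            if mid_p:
                p -= 0.5 * obs
            if p <= spec.alpha:
                power += b0[k0] * b1[k1]
    return float(power)


def min_sample_size(spec: PowerSpec, convention: str = "two-sided", mid_p: bool = False,
                    stability_window: int = 5, n_max: int = 20000) -> SampleSizeResult:
    """Smallest cells-per-group n achieving the target power.

    Because exact-test power is saw-toothed in n, the accepted n is the
    smallest value from which power remains >= target over the next
    ``stability_window`` consecutive sample sizes.
    """
    if spec.p0 == spec.p1:
        raise ValueError("p0 == p1: no finite sample size achieves the target power")

    cache: dict = {}

    def pw(n: int) -> float:
        if n not in cache:
            cache[n] = fisher_power(spec, n, convention=convention, mid_p=mid_p)
        return cache[n]

    def stable(n: int) -> bool:
        return all(pw(n + i) >= spec.power_target for i in range(stability_window + 1))

    hi = 16
    while not stable(hi):
        hi *= 2
        if hi > n_max:
            raise ValueError(f"no stable sample size below {n_max}")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if stable(mid):
            hi = mid
        else:
            lo = mid
    # guard against non-monotone wobble just below the bisection answer
    n = hi
    while n - 1 >= 1 and stable(n - 1):
        n -= 1
    return SampleSizeResult(n_per_group=n, achieved_power=pw(n))


def power_curve(spec: PowerSpec, n_values, convention: str = "two-sided",
                mid_p: bool = False):
    """Power at each n in ``n_values`` as a list of (n, power)."""
    return [(int(n), fisher_power(spec, int(n), convention=convention, mid_p=mid_p))
            for n in n_values]
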