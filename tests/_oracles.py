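"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths (and edlib): plain
dynamic-programming Levenshtein, exhaustive whitelist search, direct
step-up BH, and full-outcome Fisher power enumeration via scipy.
"""

import numpy as np
from scipy import stats


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def dp_levenshtein_block(query: str, targets):
    """Edit distance of one query against many targets at once: the same
    textbook DP recurrence, with the target axis vectorised in numpy."""
    tmat = np.array([list(t) for t in targets])  # T x L
    T, L = tmat.shape
    prev = np.broadcast_to(np.arange(L + 1), (T, L + 1)).copy()
    for i, qc in enumerate(query, start=1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        cost = (tmat != qc).astype(int)
        for j in range(1, L + 1):
            cur[:, j] = np.minimum(
                np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1),
                prev[:, j - 1] + cost[:, j - 1],
            )
        prev = cur
    return prev[:, L]


def brute_force_match(sequence: str, library, max_edits: int = 2,
                      max_context_edits: int = 4):
    """Exhaustive re-implementation of the two-tier read matching rule.

    Returns (guide_id or None, tier or None)."""
    if len(sequence) < 43:
        return None, None
    proto = sequence[23:43]
    protos = library.guides.set_index("guide_id")["protospacer"]
    for gid, p in protos.items():
        if p == proto:
            return gid, "exact"
    dvec = dp_levenshtein_block(proto, protos.to_numpy())
    dists = dict(zip(protos.index, (int(d) for d in dvec)))
    dmin = min(dists.values())
    if dmin > max_edits:
        return None, None
    nearest = [gid for gid, d in dists.items() if d == dmin]
    if len(nearest) != 1:
        return None, None
    if len(sequence) < 66:
        return None, None
    up_ok = dp_levenshtein(sequence[:23], library.upstream_context) <= max_context_edits
    down_ok = dp_levenshtein(sequence[43:66], library.downstream_context) <= max_context_edits
    if up_ok and down_ok:
        return nearest[0], "corrected"
    return None, None


def brute_force_cell_call(guide_counts: dict) -> str:
    """Direct evaluation of the per-cell confidence rule."""
    n = sum(guide_counts.values())
    if n == 0:
        return "none"
    k = max(guide_counts.values())
    if k / n > 0.9 and np.sqrt(0.9 * 0.1 / n) <= 0.1:
        return "unique"
    supported = sum(1 for c in guide_counts.values() if c >= 2)
    if supported == 2:
        return "two"
    if supported >= 3:
        return "multiple"
    return "none"


def brute_force_bh(pvalues):
    """Step-up BH evaluated directly from the definition."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return np.minimum(q, 1.0)


def brute_force_fisher_power(p0: float, p1: float, alpha: float, n: int) -> float:
    """Exact power by enumerating every (k0, k1) outcome and calling
    scipy's Fisher exact test (two-sided)."""
    power = 0.0
    for k0 in range(n + 1):
        w0 = stats.binom.pmf(k0, n, p0)
        if w0 == 0:
            continue
        for k1 in range(n + 1):
            w1 = stats.binom.pmf(k1, n, p1)
            if w1 == 0:
                continue
            _, p = stats.fisher_exact([[k1, n - k1], [k0, n - k0]], alternative="two-sided")
            if p <= alpha:
                power += w0 * w1
    return power
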