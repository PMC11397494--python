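"""Small exact-test utilities shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency

__all__ = ["fisher_exact_2x3", "odds_ratio_2x2"]


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x3(table, max_exact_total: int = 2000) -> float:
    """Two-sided exact test of independence for a 2x3 table.

    Enumerates all tables with the observed margins and sums the multivariate
    hypergeometric probabilities not exceeding the observed one.  Above
    ``max_exact_total`` entries the chi-square test of independence is used
    instead (the enumeration grows quadratically in the smaller row margin).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3) or np.any(t < 0):
        raise ValueError("need a non-negative 2x3 table")
    n = int(t.sum())
    if n == 0:
        return 1.0
    r1 = int(t[0].sum())
    c = t.sum(axis=0)
    if r1 == 0 or r1 == n or np.count_nonzero(c) <= 1:
        return 1.0
    if n > max_exact_total:
        return float(chi2_contingency(t[:, c > 0])[1])
    denom = _log_comb(n, r1)

    def logp(a: int, b: int) -> float:
        d = r1 - a - b
        return (
            _log_comb(c[0], a) + _log_comb(c[1], b) + _log_comb(c[2], d) - denom
        )

    obs = logp(int(t[0, 0]), int(t[0, 1]))
    total = 0.0
    for a in range(max(0, r1 - c[1] - c[2]), min(r1, c[0]) + 1):
        bmax = min(r1 - a, c[1])
        bmin = max(0, r1 - a - c[2])
        for b in range(bmin, bmax + 1):
            lp = logp(a, b)
            if lp <= obs + 1e-9:
                total += np.exp(lp)
    return float(min(total, 1.0))


def odds_ratio_2x2(table, haldane: bool = True) -> float:
    """Sample odds ratio; Haldane-Anscombe +0.5 on all cells if any margin is 0."""
    t = np.asarray(table, dtype=float)
    if haldane and (np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0) or np.any(t == 0)):
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
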