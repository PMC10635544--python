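"""Independent, deliberately naive reference implementations.

These share no code with the package: hypergeometric probabilities come
from exact integer binomial coefficients, and the nested LOOCV is a
plain-loop transcription of the procedure's definition.  They exist so
the fast vectorized implementations can be checked against something
that is obviously correct on small inputs.
"""

from fractions import Fraction
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Fisher's exact test by full enumeration
# ---------------------------------------------------------------------------


def fisher_enumeration(k: int, n: int, K: int, N: int, sided: str = "greater") -> float:
    """Exact rational hypergeometric p by enumerating every table with the
    observed margins."""
    lo, hi = max(0, n + K - N), min(n, K)
    total = comb(N, n)
    pmf = {x: Fraction(comb(K, x) * comb(N - K, n - x), total) for x in range(lo, hi + 1)}
    if sided == "greater":
        p = sum(pr for x, pr in pmf.items() if x >= k)
    elif sided == "two_sided":
        observed = pmf[k]
        p = sum(pr for pr in pmf.values() if pr <= observed)
    else:
        raise ValueError(sided)
    return float(min(p, Fraction(1)))


def chisq_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Textbook 2x2 Pearson statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    N = a + b + c + d
    return N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------
# nested LOOCV by plain loops
# ---------------------------------------------------------------------------


def _rank(scores: dict[str, float], target: str) -> float:
    s = scores[target]
    greater = sum(v > s for v in scores.values())
    ties = sum(v == s for v in scores.values())
    return greater + (ties + 1) / 2


def _scores_at_tau(W, ids, scoring_seeds, pool, tau):
    index = {g: i for i, g in enumerate(ids)}
    out = {}
    for g in pool:
        out[g] = sum(
            1 for s in scoring_seeds if s != g and W[index[g], index[s]] >= tau
        )
    return out


def naive_inner(W, ids, training, grid, rank_cap=200.0):
    traces = {}
    for held in training:
        scoring = [s for s in training if s != held]
        pool = [g for g in ids if g not in scoring]
        traces[held] = [
            _rank(_scores_at_tau(W, ids, scoring, pool, tau), held) for tau in grid
        ]
    qualifying = [g for g, tr in traces.items() if all(r > rank_cap for r in tr)]
    outlier = None
    if qualifying:
        best = max(max(traces[g]) for g in qualifying)
        outlier = sorted(g for g in qualifying if max(traces[g]) == best)[0]
    used = [g for g in traces if g != outlier]
    means = [np.mean([traces[g][t] for g in used]) for t in range(len(grid))]
    optimal_tau = grid[int(np.argmin(means))]
    return traces, float(optimal_tau), outlier


def naive_outer(W, ids, seeds, grid, rank_cap=200.0):
    folds = []
    for test in seeds:
        training = [s for s in seeds if s != test]
        _, tau, outlier = naive_inner(W, ids, training, grid, rank_cap)
        pool = [g for g in ids if g not in training]
        scores = _scores_at_tau(W, ids, training, pool, tau)
        folds.append((test, tau, _rank(scores, test), outlier))
    median_rank = float(np.median([f[2] for f in folds]))
    return folds, median_rank
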