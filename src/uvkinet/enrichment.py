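"""Gene-set overrepresentation arithmetic.

All quantities derive from the 2x2 contingency table of a selection of
size n drawn from a background universe of size N, against a gene set
with K members in the background, k of them in the selection:

    fold enrichment = (k/n) / (K/N)
    Fisher exact p  = hypergeometric tail (one-sided "greater") or the
                      point-probability two-sided sum
    chi-square      = Pearson 1-df test on [[k, n-k], [K-k, N-n-K+k]]

Folds are computed in exact rational arithmetic and rounded only for
display (2 d.p. for folds, 1 d.p. for percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection
from .deg import bh_adjust


def _contingency(k: int, n: int, K: int, N: int) -> np.ndarray:
    table = np.array([[k, n - k], [K - k, N - n - K + k]])
    if (table < 0).any():
        raise ValueError(f"invalid counts (k={k}, n={n}, K={K}, N={N}): negative cell")
    return table


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N), computed as an exact rational then converted."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    return float(Fraction(k, n) / Fraction(K, N))


def display_fold(fold: float) -> float:
    """Fold rounded to 2 decimal places, the conventional display precision."""
    return round(fold, 2)


def display_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded to 1 decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def fisher_exact(k: int, n: int, K: int, N: int, sided: str = "greater") -> float:
    """Fisher's exact test on the selection-vs-background table.

    ``sided`` is "greater" (overrepresentation tail) or "two_sided"
    (point-probability method: the sum of all outcomes no more probable
    than the observed one).
    """
    table = _contingency(k, n, K, N)
    if sided == "greater":
        alternative = "greater"
    elif sided in ("two_sided", "two_sided_by_point_probability"):
        alternative = "two-sided"
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = stats.fisher_exact(table, alternative=alternative).pvalue
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def chi_square(k: int, n: int, K: int, N: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the 2x2 table; Yates optional."""
    table = _contingency(k, n, K, N)
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError("chi-square undefined: an expected cell is 0")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EnrichmentResult:
    table: pd.DataFrame  # one row per gene set, sorted by fisher_p


def enrich(selection: list[str], background: list[str],
           gene_sets: GeneSetCollection, sided: str = "greater",
           chi_correction: bool = False) -> EnrichmentResult:
    """Overrepresentation of each gene set in ``selection`` vs ``background``.

    Set memberships are intersected with the background before counting,
    so N is always |background| and K the set's in-universe size.  A
    selection gene absent from the background is an error (it would
    silently distort the universe).  Sets with no background member are
    flagged ``not_represented`` and excluded from the BH adjustment.
    """
    bg = set(background)
    sel = set(selection)
    stray = sel - bg
    if stray:
        raise ValueError(f"selection gene not in background: {sorted(stray)[0]!r}")
    n, N = len(sel), len(bg)

    rows = []
    for s in gene_sets:
        members = set(s.members) & bg
        K = len(members)
        k = len(members & sel)
        if K == 0:
            rows.append(dict(set_name=s.name, k=0, n=n, K=0, N=N,
                             fold=np.nan, fisher_p=np.nan, chisq_stat=np.nan,
                             chisq_p=np.nan, not_represented=True))
            continue
        fold = fold_enrichment(k, n, K, N)
        fp = fisher_exact(k, n, K, N, sided=sided)
        try:
            cstat, cp = chi_square(k, n, K, N, correction=chi_correction)
        except ValueError:
            cstat, cp = np.nan, np.nan
        rows.append(dict(set_name=s.name, k=k, n=n, K=K, N=N, fold=fold,
                         fisher_p=fp, chisq_stat=cstat, chisq_p=cp,
                         not_represented=False))
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    tested = ~df["not_represented"]
    if tested.any():
        df.loc[tested, "q"] = bh_adjust(df.loc[tested, "fisher_p"].to_numpy())
    df = df.sort_values(["fisher_p", "set_name"], na_position="last").reset_index(drop=True)
    return EnrichmentResult(df)
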