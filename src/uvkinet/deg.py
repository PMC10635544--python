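"""Differential-expression cascade for the UV time course.

Order is fixed: (1) low-intensity filter, (2) intrinsic-drift exclusion
against the week-1 vs week-8 controls, (3) per-week fold change vs the
week-1 control with Welch testing and Benjamini-Hochberg FDR, (4) the
two-fold / q <= 0.05 rule with direction assignment.  Counts are monotone
non-increasing along the cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, FormatError, VALID_WEEKS

DIRECTIONS = ("up", "down", "excluded_drift", "excluded_low_intensity", "not_significant")


def low_intensity_filter(matrix: ExpressionMatrix, fraction: float = 0.20) -> list[str]:
    """Retain genes detectably expressed somewhere.

    A gene is dropped only when its intensity is below the ``fraction``
    quantile of the pooled intensity distribution in *every* sample.
    Returns the retained gene ids (input order).
    """
    if matrix.n_genes == 0:
        raise FormatError("empty expression matrix")
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    vals = matrix.data.to_numpy()
    cutoff = np.quantile(vals, fraction)
    below_everywhere = (vals < cutoff).all(axis=1)
    return [g for g, drop in zip(matrix.gene_ids, below_everywhere) if not drop]


def control_drift_genes(matrix: ExpressionMatrix, fold: float = 1.5) -> list[str]:
    """Genes whose week-8 control mean moved >= ``fold`` vs week-1 control.

    These reflect intrinsic (chronological) aging rather than UV and are
    excluded so UV-attributed changes are not confounded.  Requires
    control samples at both weeks 1 and 8.
    """
    if not matrix.design.has_control_week8():
        raise FormatError("drift filter requires control samples at week 8")
    m1 = matrix.group_mean("control", 1).to_numpy()
    m8 = matrix.group_mean("control", 8).to_numpy()
    nonpos = (m1 <= 0) | (m8 <= 0)
    if nonpos.any():
        gene = np.asarray(matrix.gene_ids)[nonpos][0]
        raise FormatError(f"non-positive control mean for gene {gene!r}")
    ratio = np.maximum(m8 / m1, m1 / m8)
    return [g for g, r in zip(matrix.gene_ids, ratio) if r >= fold]


def fold_change_profiles(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log2 fold change of the UV group mean at each week vs the
    week-1 control mean.  Rows: genes; columns: weeks {1,2,4,6,8}."""
    ref = matrix.group_mean("control", 1)
    if (ref <= 0).any():
        gene = ref.index[ref <= 0][0]
        raise FormatError(f"non-positive week-1 control mean for gene {gene!r}")
    cols = {}
    for w in VALID_WEEKS:
        mw = matrix.group_mean("uv", w)
        if (mw <= 0).any():
            gene = mw.index[mw <= 0][0]
            raise FormatError(f"non-positive uv week-{w} mean for gene {gene!r}")
        cols[w] = np.log2(mw / ref)
    return pd.DataFrame(cols, index=matrix.data.index)


def per_week_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Welch two-sample t-test on log2 intensities, UV(week w) vs
    control(week 1), two-sided.  Degenerate groups (zero variance on both
    sides with equal means) get p = 1 by convention; p is clipped into
    (0, 1] so downstream -log transforms stay finite."""
    tiny = np.finfo(float).tiny
    ctrl = np.log2(matrix.data[matrix.design.samples("control", 1)].to_numpy())
    out = {}
    for w in VALID_WEEKS:
        uv = np.log2(matrix.data[matrix.design.samples("uv", w)].to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-identical groups trip a scipy precision warning; the
            # degenerate cases are resolved explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(uv, ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # both groups constant: equal means -> no evidence, p = 1
        degenerate = np.isnan(p)
        equal = np.isclose(uv.mean(axis=1), ctrl.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = tiny
        out[w] = np.clip(p, tiny, 1.0)
    return pd.DataFrame(out, index=matrix.data.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEGTable:
    """Per-gene cascade outcome: log2fc and q per week, direction label."""

    table: pd.DataFrame  # index gene_id; log2fc_w*, p_w*, q_w*, max_abs_log2fc, direction

    def genes(self, direction: str) -> list[str]:
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        return list(self.table.index[self.table["direction"] == direction])

    @property
    def up_genes(self) -> list[str]:
        return self.genes("up")

    @property
    def down_genes(self) -> list[str]:
        return self.genes("down")

    def counts(self) -> dict[str, int]:
        return {d: int((self.table["direction"] == d).sum()) for d in DIRECTIONS}

    def profiles(self, direction: str | None = None) -> pd.DataFrame:
        """log2 fold-change profiles (weeks as integer columns), optionally
        restricted to one direction."""
        cols = [f"log2fc_w{w}" for w in VALID_WEEKS]
        t = self.table if direction is None else self.table.loc[self.genes(direction)]
        out = t[cols].copy()
        out.columns = list(VALID_WEEKS)
        return out

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @staticmethod
    def from_tsv(path) -> "DEGTable":
        return DEGTable(pd.read_csv(path, sep="\t", index_col="gene_id"))


def select_degs(profiles: pd.DataFrame, q: pd.DataFrame, p: pd.DataFrame,
                drift_excluded: list[str], low_excluded: list[str],
                fc_threshold: float = 1.0, q_threshold: float = 0.05) -> DEGTable:
    """Apply the two-fold / FDR rule and label every gene.

    A gene is a DEG iff it survives both exclusions and some week shows
    |log2fc| >= ``fc_threshold`` with q <= ``q_threshold``.  Direction is
    the sign at the qualifying week of largest |log2fc|; a tie between a
    positive and a negative qualifying week of equal magnitude resolves
    to "down".
    """
    if not profiles.index.equals(q.index):
        raise ValueError("profiles and q-values must be aligned on gene ids")
    weeks = list(profiles.columns)
    fc = profiles.to_numpy()
    qv = q.to_numpy()
    drift_set, low_set = set(drift_excluded), set(low_excluded)

    rows = []
    for gi, gene in enumerate(profiles.index):
        if gene in low_set:
            direction = "excluded_low_intensity"
        elif gene in drift_set:
            direction = "excluded_drift"
        else:
            ok = (np.abs(fc[gi]) >= fc_threshold) & (qv[gi] <= q_threshold)
            if not ok.any():
                direction = "not_significant"
            else:
                mags = np.where(ok, np.abs(fc[gi]), -np.inf)
                best = mags.max()
                best_weeks = np.flatnonzero(mags == best)
                signs = np.sign(fc[gi, best_weeks])
                direction = "down" if (signs < 0).any() else "up"
        rows.append(direction)

    data = {}
    for wi, w in enumerate(weeks):
        data[f"log2fc_w{w}"] = fc[:, wi]
    for wi, w in enumerate(weeks):
        data[f"p_w{w}"] = p.to_numpy()[:, wi]
    for wi, w in enumerate(weeks):
        data[f"q_w{w}"] = qv[:, wi]
    data["max_abs_log2fc"] = np.abs(fc).max(axis=1)
    data["direction"] = rows
    return DEGTable(pd.DataFrame(data, index=profiles.index))


def run_deg_pipeline(matrix: ExpressionMatrix,
                     fc_threshold: float = 1.0, q_threshold: float = 0.05,
                     drift_fold: float = 1.5, low_intensity_q: float = 0.20,
                     pooled_fdr: bool = False) -> DEGTable:
    """Full cascade on one matrix.

    ``pooled_fdr`` switches BH from within-week (default) to pooled
    across all gene-week p-values.
    """
    retained = set(low_intensity_filter(matrix, low_intensity_q))
    low_excluded = [g for g in matrix.gene_ids if g not in retained]
    drift_excluded = control_drift_genes(matrix, drift_fold) if \
        matrix.design.has_control_week8() else []

    profiles = fold_change_profiles(matrix)
    p = per_week_test(matrix)
    if pooled_fdr:
        qflat = bh_adjust(p.to_numpy().ravel())
        q = pd.DataFrame(qflat.reshape(p.shape), index=p.index, columns=p.columns)
    else:
        q = pd.DataFrame(np.column_stack([bh_adjust(p[c].to_numpy()) for c in p.columns]),
                         index=p.index, columns=p.columns)
    return select_degs(profiles, q, p, drift_excluded, low_excluded,
                       fc_threshold=fc_threshold, q_threshold=q_threshold)
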