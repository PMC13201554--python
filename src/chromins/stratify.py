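"""Per-cell insulin-signaling stratification and prevalence statistics.

Each cell receives an insulin-signaling-mediator (ISM) score: the mean
of normalised log-scale expression over the four-gene panel INSR,
IGF1R, IRS1, IRS2 (genes absent from the matrix are dropped with a
warning).  Cells are classified high/low by comparing the score with a
mean threshold, either the global mean over all cells (default) or the
cell's own cluster mean.  The global scope is the default because with
a per-cluster mean split every cluster with roughly symmetric,
unimodal scores lands near 50% high, which cannot produce contrasts
between cluster groups; both scopes are available.

High-ISM prevalence is compared between two cluster groups
("aggressive" vs "other" by default, configurable) in a 2x2 table with
a Pearson chi-square test (no continuity correction, df=1).  Group-wise
differences of SES or single-gene expression are tested by
Wilcoxon-Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

DEFAULT_ISM_GENES = ("INSR", "IGF1R", "IRS1", "IRS2")
#: Default cluster -> group mapping for RA synovial-tissue T cells.
DEFAULT_AGGRESSIVE_CLUSTERS = ("Tph", "proliferating", "Vdelta2")


def ism_score(
    expr: pd.DataFrame, ism_genes: Sequence[str] = DEFAULT_ISM_GENES
) -> pd.Series:
    """Per-cell mean normalised log-expression of the ISM gene panel."""
    present = [g for g in ism_genes if g in expr.index]
    if not present:
        raise ValueError(f"none of the ISM genes {tuple(ism_genes)} present")
    if len(present) < len(ism_genes):
        missing = sorted(set(ism_genes) - set(present))
        warnings.warn(f"ISM genes absent and dropped: {missing}")
    scores = expr.loc[present].astype(float).mean(axis=0)
    scores.name = "ism_score"
    return scores


def classify_high_low(
    scores: pd.Series,
    scope: str = "global",
    clusters: pd.Series | None = None,
) -> pd.Series:
    """Label each cell ``high``/``low`` by a mean-score threshold.

    ``scope="global"`` thresholds at the mean score over all cells;
    ``scope="per-cluster"`` at the cell's own cluster mean (``clusters``
    required; singleton clusters are labelled low with a warning).
    Ties at the threshold are labelled low.
    """
    if len(scores) < 2:
        raise ValueError("classify_high_low requires >= 2 cells")
    if scope == "global":
        thresh = pd.Series(scores.mean(), index=scores.index)
    elif scope == "per-cluster":
        if clusters is None:
            raise ValueError("per-cluster scope requires cluster labels")
        clusters = clusters.loc[scores.index]
        sizes = clusters.value_counts()
        singletons = set(sizes.index[sizes == 1])
        if singletons:
            warnings.warn(
                f"singleton clusters labelled low: {sorted(singletons)}"
            )
        means = scores.groupby(clusters).transform("mean")
        thresh = means.where(~clusters.isin(singletons), np.inf)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    labels = np.where(scores > thresh, "high", "low")
    return pd.Series(labels, index=scores.index, name="ism_class")


@dataclass
class PrevalenceResult:
    """2x2 high/low x group counts with per-group prevalences (%)."""

    table: pd.DataFrame  # rows: high/low, columns: group labels
    prevalence: pd.Series  # % high per group

    @property
    def n_cells(self) -> int:
        return int(self.table.to_numpy().sum())


def prevalence_table(
    labels: pd.Series, groups: pd.Series
) -> PrevalenceResult:
    """Count high/low cells per group and report prevalence percentages.

    ``labels`` holds ``high``/``low`` per cell and ``groups`` the cluster
    group per cell, aligned on the same index.
    """
    if not labels.index.equals(groups.index):
        groups = groups.loc[labels.index]
    group_levels = sorted(groups.unique())
    if len(group_levels) < 2:
        raise ValueError("prevalence_table requires >= 2 groups")
    counts = pd.crosstab(labels, groups).reindex(
        index=["high", "low"], columns=group_levels, fill_value=0
    )
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a group has zero cells")
    prev = 100.0 * counts.loc["high"] / totals
    prev.name = "prevalence_pct"
    return PrevalenceResult(table=counts, prevalence=prev)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chisq_test(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    ``statistic = sum (O - E)^2 / E`` over the four cells with expected
    counts from the margins; df = 1; upper-tail p.  Zero margins raise.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chisq_test expects a 2x2 table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chisq_test: zero margin")
    expected = np.outer(row, col) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    return ChiSquareResult(stat, 1, float(stats.chi2.sf(stat, df=1)))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p: float
    paired: bool
    n: int


def groupwise_wilcoxon(
    values: pd.Series | Sequence[float],
    labels: pd.Series | Sequence[str],
    paired: bool = False,
) -> WilcoxonResult:
    """Two-group Wilcoxon test of ``values`` split by ``labels``.

    Unpaired: Wilcoxon-Mann-Whitney rank-sum with midrank ties (exact
    permutation distribution for small tie-free samples, otherwise
    tie-corrected normal approximation).  Paired: Wilcoxon signed-rank
    on within-pair differences, pairs matched by order within each
    group; all-zero differences give p = 1 with a warning.  Two-sided.
    """
    vals = pd.Series(np.asarray(values, dtype=float))
    labs = pd.Series(np.asarray(labels, dtype=object))
    if len(vals) != len(labs):
        raise ValueError("values and labels must align")
    levels = sorted(pd.unique(labs))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = vals[labs == levels[0]].to_numpy()
    b = vals[labs == levels[1]].to_numpy()
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        if len(a) < 5:
            raise ValueError("paired test requires >= 5 pairs")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return WilcoxonResult(0.0, 1.0, True, len(a))
        stat, p = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
        return WilcoxonResult(float(stat), float(p), True, len(a))
    if min(len(a), len(b)) < 3:
        raise ValueError("unpaired test requires >= 3 per group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (not ties and len(a) + len(b) <= 30) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), False,
                          len(a) + len(b))


def map_groups(
    clusters: pd.Series,
    aggressive: Sequence[str] = DEFAULT_AGGRESSIVE_CLUSTERS,
    aggressive_label: str = "aggressive",
    other_label: str = "other",
) -> pd.Series:
    """Total cluster -> group mapping: clusters in ``aggressive`` map to
    the aggressive label, every other cluster to the other label."""
    groups = np.where(clusters.isin(set(aggressive)), aggressive_label,
                      other_label)
    return pd.Series(groups, index=clusters.index, name="group")


class ISMStratifier(BaseEstimator):
    """Estimator bundling ISM scoring, classification and prevalence.

    Parameters
    ----------
    ism_genes : gene panel averaged into the per-cell score.
    scope : {"global", "per-cluster"} — mean-threshold scope.
    aggressive_clusters : clusters forming the "aggressive" group when
        the metadata carries no explicit ``group`` column.

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_, labels_ : per-cell ISM score and high/low label.
    prevalence_ : :class:`PrevalenceResult` over the two groups.
    chi2_ : :class:`ChiSquareResult` for the 2x2 table.
    """

    def __init__(
        self,
        ism_genes: Sequence[str] = DEFAULT_ISM_GENES,
        scope: str = "global",
        aggressive_clusters: Sequence[str] = DEFAULT_AGGRESSIVE_CLUSTERS,
    ) -> None:
        self.ism_genes = ism_genes
        self.scope = scope
        self.aggressive_clusters = aggressive_clusters

    def fit(self, expr: pd.DataFrame, cell_meta: pd.DataFrame) -> "ISMStratifier":
        """``expr``: genes x cells normalised log expression; ``cell_meta``:
        indexed by cell id with a ``cluster`` column and optionally a
        precomputed ``group`` column."""
        meta = cell_meta.loc[expr.columns]
        scores = ism_score(expr, self.ism_genes)
        labels = classify_high_low(
            scores, scope=self.scope, clusters=meta["cluster"]
        )
        if "group" in meta:
            groups = meta["group"]
        else:
            groups = map_groups(meta["cluster"], self.aggressive_clusters)
        prev = prevalence_table(labels, groups)
        self.scores_ = scores
        self.labels_ = labels
        self.groups_ = groups
        self.prevalence_ = prev
        self.chi2_ = chisq_test(prev.table)
        return self
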