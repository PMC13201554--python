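"""Gene-set summary scores, mean-split labels, correlations and ORA.

The standardized expression sum (SES) of a gene set in a unit (sample or
cell) is the sum over member genes of the gene's z-scored expression
across units (sample standard deviation, ddof 1).  Member genes absent
from the matrix or with zero variance are dropped, and the number of
genes actually used is reported per set so that a mean-scaled variant is
recoverable.  SES is cohort-relative: scores over the full unit
collection sum to ~0 per set, and restricting to a unit subset
re-centres the scores.

Expression is expected on a normalised log scale.  Two standard schemes
are provided: bulk counts are divided by median-of-ratios size factors
and transformed log2(x+1); single-cell counts are scaled per cell to the
median total depth and transformed log2(x+1).

Enrichment of a discrete gene list against GO-derived sets is assessed
with a hypergeometric over-representation test (upper tail), BH-adjusted
across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .diffexpr import bh_adjust, size_factors


@dataclass(frozen=True)
class GeneSet:
    """A flat, named gene set (e.g. one GO term's annotated genes)."""

    name: str
    source: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description/source, members...).

    Duplicate members within a line are collapsed with a warning; a line
    with fewer than three fields is a parse error; an empty file yields
    an empty collection.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line with < 3 fields")
            name, source = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            dup = False
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dup = True
                    continue
                seen.add(g)
                members.append(g)
            if dup:
                warnings.warn(f"{path}:{lineno}: duplicate members collapsed")
            sets.append(GeneSet(name, source, tuple(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Normalisation


def normalize_bulk(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Size-factor-scaled log2(x+1) expression for bulk counts."""
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts.div(factors.loc[counts.columns], axis=1) + 1.0)


def normalize_sc(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell median-depth-scaled log2(x+1) expression for single cells."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts cannot be normalised")
    scaled = counts.div(totals, axis=1) * float(np.median(totals))
    return np.log2(scaled + 1.0)


# ---------------------------------------------------------------------------
# SES


def ses(expr: pd.DataFrame, gene_set: GeneSet) -> tuple[pd.Series, int]:
    """SES of one gene set: per-unit sum of member-gene z-scores.

    Parameters
    ----------
    expr : genes x units DataFrame of normalised log-scale expression.
    gene_set : the set to score.

    Returns
    -------
    (scores, n_genes_used) — scores indexed by unit (all-NaN when no
    member gene is usable), and the number of member genes that entered
    the sum (present in the matrix with nonzero variance).
    """
    if expr.shape[1] < 2:
        raise ValueError("ses requires >= 2 units")
    present = [g for g in gene_set.members if g in expr.index]
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    sub = sub.loc[usable]
    n_used = int(usable.sum())
    if n_used == 0:
        warnings.warn(f"gene set {gene_set.name!r}: no usable member gene")
        return pd.Series(np.nan, index=expr.columns, name=gene_set.name), 0
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[usable], axis=0)
    scores = z.sum(axis=0)
    scores.name = gene_set.name
    return scores, n_used


class SESScorer(BaseEstimator, TransformerMixin):
    """Transformer computing SES for a collection of gene sets.

    ``transform`` maps a genes x units expression matrix (normalised,
    log scale) to a units x sets score table.  ``n_genes_used_`` records
    how many member genes entered each set's sum.
    """

    def __init__(self, gene_sets: Sequence[GeneSet] = ()) -> None:
        self.gene_sets = gene_sets

    def fit(self, expr: pd.DataFrame, y=None) -> "SESScorer":
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, pd.Series] = {}
        used: dict[str, int] = {}
        for gs in self.gene_sets:
            scores, n_used = ses(expr, gs)
            cols[gs.name] = scores
            used[gs.name] = n_used
        self.n_genes_used_ = pd.Series(used, name="n_genes_used", dtype=int)
        return pd.DataFrame(cols, index=expr.columns)


def ses_table(expr: pd.DataFrame, gene_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Units x sets SES table (thin wrapper over :class:`SESScorer`)."""
    return SESScorer(gene_sets).fit(expr).transform(expr)


def split_by_gene_mean(expr: pd.DataFrame, gene_id: str) -> pd.Series:
    """Label each unit ``hi``/``lo`` by the gene's mean expression across
    units; ties at the mean go to ``lo``.  Used for the BIRC5 high/low
    split of bulk cohorts."""
    if gene_id not in expr.index:
        raise KeyError(f"gene {gene_id!r} absent from expression matrix")
    vals = expr.loc[gene_id].astype(float)
    labels = np.where(vals > vals.mean(), "hi", "lo")
    return pd.Series(labels, index=expr.columns, name=f"{gene_id}_split")


# ---------------------------------------------------------------------------
# Correlation and ratios


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation: Pearson on midranks, two-sided p by the
    t approximation.  Constant input is flagged as undefined."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = xa.size
    if n < 4:
        raise ValueError("spearman requires >= 4 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("spearman: constant vector, rho undefined")
        return CorrelationResult(np.nan, np.nan, n)
    rho, p = stats.spearmanr(xa, ya)
    return CorrelationResult(float(rho), float(p), n)


def correlation_matrix(
    table: pd.DataFrame, other: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pairwise Spearman rho and p between columns of ``table`` (and
    ``other`` when given), tidy long format: var_a, var_b, rho, p, n."""
    right = table if other is None else other
    rows = []
    for a in table.columns:
        for b in right.columns:
            pair = pd.concat([table[a], right[b]], axis=1).dropna()
            res = spearman(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"var_a": a, "var_b": b, "rho": res.rho,
                         "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def expression_ratio(
    expr: pd.DataFrame,
    numerator_gene: str,
    denominator_gene: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-unit expression ratio ``(num + c) / (den + c)`` on normalised
    (linear-scale) expression, e.g. the INSR : IGF1R receptor ratio."""
    for g in (numerator_gene, denominator_gene):
        if g not in expr.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    num = expr.loc[numerator_gene].astype(float) + pseudocount
    den = expr.loc[denominator_gene].astype(float) + pseudocount
    ratio = num / den
    ratio.name = f"{numerator_gene}:{denominator_gene}"
    return ratio


# ---------------------------------------------------------------------------
# Over-representation


def ora(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Each set is intersected with the universe before testing; the
    upper-tail p is the probability of drawing >= k set members in
    ``|query|`` draws without replacement from ``|universe|``; BH is
    applied across sets.
    """
    uni = set(universe)
    q = set(query)
    if not uni or not q:
        raise ValueError("ora: query and universe must be non-empty")
    if not q <= uni:
        raise ValueError("ora: query must be a subset of the universe")
    M, n_draw = len(uni), len(q)
    rows = []
    for gs in sets:
        members = set(gs.members) & uni
        k = len(members & q)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_draw)) if K else np.nan
        rows.append({"set": gs.name, "source": gs.source, "n_set": K,
                     "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
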