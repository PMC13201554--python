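"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's algorithmic paths:
interval components are built by per-base union-find, annotation by a
double loop over (region, element) pairs, BH by direct enumeration of
the step-up definition, and the hypergeometric tail by ``math.comb``.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from chromins.intervals import GenomicInterval, PeakSet


# ---------------------------------------------------------------------------
# Per-base interval oracle


def per_base_components(intervals):
    """Union-find over intervals where every base unions all intervals
    covering it; returns a list of sets of interval indices."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_base: dict[tuple[str, int], list[int]] = {}
    for idx, iv in enumerate(intervals):
        for b in range(iv.start, iv.end):
            by_base.setdefault((iv.chrom, b), []).append(idx)
    for covering in by_base.values():
        for other in covering[1:]:
            union(covering[0], other)
    groups: dict[int, set[int]] = {}
    for idx in range(len(intervals)):
        groups.setdefault(find(idx), set()).add(idx)
    return list(groups.values())


def oracle_merge_spans(peaks: PeakSet) -> set[tuple[str, int, int]]:
    """Expected merge_overlapping output spans via the per-base oracle."""
    ivs = list(peaks)
    spans = set()
    for comp in per_base_components(ivs):
        members = [ivs[i] for i in comp]
        spans.add(
            (members[0].chrom, min(m.start for m in members),
             max(m.end for m in members))
        )
    return spans


def oracle_codeposition_spans(a: PeakSet, b: PeakSet) -> set[tuple[str, int, int]]:
    """Expected codeposition spans: per-base components over the pooled
    peaks keeping only components containing both sides."""
    ivs = list(a) + list(b)
    sides = ["a"] * len(a) + ["b"] * len(b)
    spans = set()
    for comp in per_base_components(ivs):
        if {sides[i] for i in comp} == {"a", "b"}:
            members = [ivs[i] for i in comp]
            spans.add(
                (members[0].chrom, min(m.start for m in members),
                 max(m.end for m in members))
            )
    return spans


def random_intervals(rng, n, genome_len=10_000, chroms=("chr1",),
                     len_min=5, len_max=400, mark="x"):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(len_min, len_max + 1))
        start = int(rng.integers(0, genome_len - length))
        out.append(GenomicInterval(chrom, start, start + length, mark=mark))
    return out


# ---------------------------------------------------------------------------
# Statistics oracles


def oracle_bh(pvals):
    """Step-up BH from its definition: padj_i = min over j with
    p_(j) >= p_i of p_(j) * m / rank(j), capped at 1."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        adj[i] = min(best, 1.0)
    return adj


def oracle_spearman_rho(x, y):
    """Rank (midranks for ties) then plain Pearson."""
    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def oracle_hypergeom_upper_tail(k, M, K, n):
    """P(X >= k) for X ~ Hypergeom(M, K, n) by direct enumeration."""
    total = math.comb(M, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(M - K, n - j)
    return acc / total


def oracle_permutation_ranksum_p(a, b):
    """Exhaustive two-sided permutation p for the rank-sum statistic:
    fraction of label assignments whose rank-sum deviates from its mean
    at least as much as observed."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n1 = len(a)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    sv = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    mean_s = n1 * (len(pooled) + 1) / 2.0
    s_obs = ranks[:n1].sum()
    dev_obs = abs(s_obs - mean_s)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean_s) >= dev_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Common fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def fixture_dir():
    from pathlib import Path

    d = Path(__file__).resolve().parent.parent / "fixtures"
    assert d.exists(), "shipped fixture bundle missing"
    return d
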