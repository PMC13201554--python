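"""Seeded synthetic-data generators with ground-truth bookkeeping.

Every input the pipeline consumes can be generated here: two ChIP peak
sets with a controllable co-deposited fraction, a regulatory-element
map with connected-gene lists, NB-distributed bulk count matrices with
planted insulin-responsive genes (paired-stimulation and plasma-insulin
covariate designs), and clustered single-cell counts with planted
per-group high-ISM prevalences.  Each generator records the planted
truth so recovery tests can compare pipeline output against it exactly.

Design notes
------------
* All randomness flows through one ``numpy.random.Generator`` seeded per
  call; identical (config, seed) pairs give identical outputs.
* Peaks belonging to distinct truth components are placed with at least
  one base of separation, so the co-deposition truth is recoverable
  exactly by construction.
* The region -> element -> gene truth is computed by a plain double loop
  over (region, element) pairs with direct coordinate arithmetic — an
  oracle independent of the indexed query path in :mod:`.annotate`.
* Single-cell ISM genes are simulated highly expressed with
  near-Poisson dispersion so that the four-gene mean score is cleanly
  bimodal at the configured shift; this makes prevalence recovery a
  test of the stratification bookkeeping rather than of robustness to
  droplet-level sparsity (which is deliberately not emulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, RegulatoryElement, promoter_interval
from .intervals import GenomicInterval, PeakSet
from .setscore import GeneSet
from .stratify import DEFAULT_ISM_GENES

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PeakSimConfig:
    """Two-mark peak simulation."""

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_peaks_a: int = 500
    n_peaks_b: int = 500
    mark_a: str = "survivin"
    mark_b: str = "H3K27ac"
    peak_len_min: int = 200
    peak_len_max: int = 1000
    co_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_fraction <= 1.0:
            raise ValueError("co_fraction must lie in [0, 1]")
        if min(self.n_peaks_a, self.n_peaks_b) < 0:
            raise ValueError("peak counts must be non-negative")
        if not 1 <= self.peak_len_min <= self.peak_len_max:
            raise ValueError("invalid peak length range")


@dataclass
class RegMapSimConfig:
    """Gene tiling and enhancer placement."""

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 150
    gene_len: int = 3000
    gene_spacing: int = 25_000
    n_enhancers: int = 120
    enhancer_len: int = 1500
    genes_per_enhancer_max: int = 3
    promoter_len: int = 2000
    #: fraction of truth co-deposited regions placed inside enhancers
    region_in_enhancer_fraction: float = 0.4


@dataclass
class BulkSimConfig:
    """Bulk RNA-seq counts with planted responsive genes."""

    n_genes: int = 2000
    n_samples: int = 12  # paired: donors = n_samples // 2
    design: str = "paired"  # "paired" | "covariate"
    responsive_fraction: float = 0.1
    log2fc: float = 1.0
    slope_log2: float = 0.08  # log2 change per covariate unit
    dispersion: float = 0.05
    mean_log: float = math.log(200.0)
    mean_sd: float = 1.0
    size_factor_sd: float = 0.15
    donor_effect_sd_log2: float = 0.15
    insulin_log_mean: float = math.log(10.0)
    insulin_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.design not in ("paired", "covariate"):
            raise ValueError("design must be 'paired' or 'covariate'")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if self.design == "paired" and self.n_samples % 2:
            raise ValueError("paired design needs an even sample count")


@dataclass
class ScSimConfig:
    """Clustered single-cell counts with planted high-ISM prevalences."""

    n_cells: int = 5000
    cluster_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "Tph": 0.12, "proliferating": 0.10, "Vdelta2": 0.08,
            "Treg": 0.20, "naive": 0.30, "CD8": 0.20,
        }
    )
    group_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "Tph": "aggressive", "proliferating": "aggressive",
            "Vdelta2": "aggressive", "Treg": "other", "naive": "other",
            "CD8": "other",
        }
    )
    #: planted fraction of true high-ISM cells per cluster group
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"aggressive": 0.133, "other": 0.067}
    )
    ism_genes: Sequence[str] = DEFAULT_ISM_GENES
    ism_mean: float = 600.0
    ism_dispersion: float = 0.003
    ism_shift_log2: float = 2.0
    #: optional per-cluster multiplier on baseline ISM means (used to
    #: emulate cluster-level signalling differences without planted cells)
    cluster_ism_scale: Mapping[str, float] | None = None
    n_background_genes: int = 300
    bg_mean_log: float = math.log(150.0)
    bg_mean_sd: float = 0.5
    bg_dispersion: float = 0.1
    n_markers_per_cluster: int = 3
    marker_mean: float = 100.0
    marker_fc: float = 4.0
    #: response genes down-shifted in true-high cells (the lower
    #: BIRC5/IFNG/TNF expression seen at high insulin signaling)
    response_genes: Sequence[str] = ("BIRC5", "IFNG", "TNF")
    response_mean: float = 80.0
    response_down_fc: float = 0.5
    depth_sd: float = 0.25
    tissue: str = "ST"

    def __post_init__(self) -> None:
        tot = sum(self.cluster_props.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        for g, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{g}] must lie in [0, 1]")
        missing = set(self.cluster_props) - set(self.group_map)
        if missing:
            raise ValueError(f"group_map not total, missing {sorted(missing)}")


def rast_sc_config(**overrides) -> ScSimConfig:
    """Synthetic twin of the RA synovial-tissue contrast: aggressive
    clusters (Tph/proliferating/Vdelta2, 30% of cells) planted at 13.3%
    high-ISM prevalence vs 6.7% elsewhere."""
    cfg = dict(prevalence={"aggressive": 0.133, "other": 0.067}, tissue="ST")
    cfg.update(overrides)
    return ScSimConfig(**cfg)


def t2d_sc_config(**overrides) -> ScSimConfig:
    """Synthetic twin of the T2D peripheral-blood contrast: metabolically
    active clusters (IL7R+ and proliferating, 40% of cells) planted at
    13% high-ISM prevalence vs 4% elsewhere."""
    cfg = dict(
        cluster_props={
            "IL7R_1": 0.20, "IL7R_2": 0.10, "proliferating": 0.10,
            "naive": 0.25, "GNLY": 0.15, "CD161": 0.10, "Vdelta2": 0.10,
        },
        group_map={
            "IL7R_1": "active", "IL7R_2": "active", "proliferating": "active",
            "naive": "other", "GNLY": "other", "CD161": "other",
            "Vdelta2": "other",
        },
        prevalence={"active": 0.13, "other": 0.04},
        tissue="PB",
    )
    cfg.update(overrides)
    return ScSimConfig(**cfg)


# ---------------------------------------------------------------------------
# Placement helpers


class _Occupancy:
    """Per-chromosome occupied-interval index with a 1 bp guard gap."""

    def __init__(self) -> None:
        from intervaltree import IntervalTree

        self._trees: dict[str, "IntervalTree"] = {}
        self._IntervalTree = IntervalTree

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is None or not tree.overlap(start - 1, end + 1)

    def add(self, chrom: str, start: int, end: int) -> None:
        self._trees.setdefault(chrom, self._IntervalTree())[start:end] = True


def _sample_position(
    rng: np.random.Generator, chrom_sizes: Mapping[str, int], length: int
) -> tuple[str, int]:
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    c = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
    limit = chrom_sizes[c] - length
    if limit <= 0:
        raise ValueError(f"chromosome {c} too small for length {length}")
    return c, int(rng.integers(0, limit))


# ---------------------------------------------------------------------------
# Peaks


def gen_peaks(
    cfg: PeakSimConfig,
    seed: int,
    enhancers: Sequence[RegulatoryElement] | None = None,
    in_enhancer_fraction: float = 0.0,
    occupancy: _Occupancy | None = None,
) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Simulate two peak sets with a planted co-deposited fraction.

    ``co_fraction`` of ``min(n_peaks_a, n_peaks_b)`` truth regions each
    receive one peak per mark overlapping by >= 1 bp; all remaining
    peaks are placed by rejection sampling with >= 1 bp separation from
    every other component, so ``codeposition_regions`` recovers exactly
    the truth spans.  When ``enhancers`` are supplied, a fraction of the
    truth regions is placed fully inside a randomly chosen enhancer.

    Returns ``(peaks_a, peaks_b, truth_regions)``; truth regions carry
    mark ``"region"`` and score 2 (member peaks).
    """
    rng = np.random.default_rng(seed)
    occ = occupancy if occupancy is not None else _Occupancy()
    n_co = round(cfg.co_fraction * min(cfg.n_peaks_a, cfg.n_peaks_b))
    n_in_enh = (
        round(in_enhancer_fraction * n_co) if enhancers else 0
    )
    peaks_a: list[GenomicInterval] = []
    peaks_b: list[GenomicInterval] = []
    regions: list[GenomicInterval] = []

    def _draw_len(cap: int | None = None) -> int:
        hi = cfg.peak_len_max if cap is None else min(cfg.peak_len_max, cap)
        lo = min(cfg.peak_len_min, hi)
        return int(rng.integers(lo, hi + 1))

    max_tries = 2000
    for i in range(n_co):
        in_enh = i < n_in_enh
        placed = False
        for _ in range(max_tries):
            inside = (
                enhancers[int(rng.integers(len(enhancers)))] if in_enh else None
            )
            if inside is not None:
                cap = max(2, (len(inside.interval) - 1) // 2)
                la, lb = _draw_len(cap), _draw_len(cap)
            else:
                la, lb = _draw_len(), _draw_len()
            ov = int(rng.integers(1, min(la, lb) + 1))
            span = la + lb - ov
            if inside is not None:
                iv = inside.interval
                if span > len(iv):
                    continue
                chrom = iv.chrom
                s = int(rng.integers(iv.start, iv.end - span + 1))
            else:
                chrom, s = _sample_position(rng, cfg.chrom_sizes, span)
            if not occ.is_free(chrom, s, s + span):
                continue
            occ.add(chrom, s, s + span)
            peaks_a.append(GenomicInterval(chrom, s, s + la, mark=cfg.mark_a))
            peaks_b.append(
                GenomicInterval(chrom, s + span - lb, s + span, mark=cfg.mark_b)
            )
            regions.append(
                GenomicInterval(chrom, s, s + span, mark="region", score=2.0)
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                "genome too small to place co-deposited truth regions"
            )

    for mark, n_total, bucket in (
        (cfg.mark_a, cfg.n_peaks_a, peaks_a),
        (cfg.mark_b, cfg.n_peaks_b, peaks_b),
    ):
        for _ in range(n_total - n_co):
            placed = False
            for _ in range(max_tries):
                length = _draw_len()
                chrom, s = _sample_position(rng, cfg.chrom_sizes, length)
                if not occ.is_free(chrom, s, s + length):
                    continue
                occ.add(chrom, s, s + length)
                bucket.append(GenomicInterval(chrom, s, s + length, mark=mark))
                placed = True
                break
            if not placed:
                raise ValueError("genome too small to place singleton peaks")

    return (
        PeakSet(peaks_a, source=cfg.mark_a),
        PeakSet(peaks_b, source=cfg.mark_b),
        PeakSet(regions, source="truth"),
    )


# ---------------------------------------------------------------------------
# Regulatory map


def gen_regmap(
    cfg: RegMapSimConfig, seed: int
) -> tuple[list[RegulatoryElement], list[GeneModel]]:
    """Tile genes with alternating strands and place enhancers in the
    intergenic gaps with known connected-gene lists.

    Genes occupy ``[k * spacing + promoter_len, k * spacing +
    promoter_len + gene_len)`` slots so that promoters never collide;
    enhancers are placed between gene feature blocks by rejection
    sampling.  An empty enhancer config yields gene-only maps.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(cfg.chrom_sizes)
    genes: list[GeneModel] = []
    per_chrom = math.ceil(cfg.n_genes / len(chroms))
    block = cfg.promoter_len + cfg.gene_len + cfg.promoter_len
    i = 0
    for chrom in chroms:
        capacity = (cfg.chrom_sizes[chrom] - block) // cfg.gene_spacing
        if per_chrom > capacity:
            raise ValueError("gene tiling exceeds chromosome size")
        for k in range(per_chrom):
            if i >= cfg.n_genes:
                break
            start = k * cfg.gene_spacing + cfg.promoter_len
            strand = "+" if i % 2 == 0 else "-"
            genes.append(
                GeneModel(f"G{i + 1:04d}", chrom, start, start + cfg.gene_len, strand)
            )
            i += 1

    occ = _Occupancy()
    for g in genes:
        lo = g.start - cfg.promoter_len if g.strand == "+" else g.start
        hi = g.end if g.strand == "+" else g.end + cfg.promoter_len
        occ.add(g.chrom, max(0, lo), hi)

    elements: list[RegulatoryElement] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for j in range(cfg.n_enhancers):
        placed = False
        for _ in range(2000):
            chrom, s = _sample_position(rng, cfg.chrom_sizes, cfg.enhancer_len)
            if not occ.is_free(chrom, s, s + cfg.enhancer_len):
                continue
            occ.add(chrom, s, s + cfg.enhancer_len)
            cands = by_chrom.get(chrom, [])
            if not cands:
                continue
            order = sorted(cands, key=lambda g: abs(g.start - s))
            k = int(rng.integers(1, cfg.genes_per_enhancer_max + 1))
            connected = tuple(g.gene_id for g in order[:k])
            elements.append(
                RegulatoryElement(
                    f"E{j + 1:04d}",
                    GenomicInterval(chrom, s, s + cfg.enhancer_len,
                                    mark="enhancer"),
                    connected,
                    kind="enhancer",
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError("genome too small to place enhancers")
    return elements, genes


def truth_connections(
    regions: PeakSet,
    enhancers: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    promoter_len: int = 2000,
) -> tuple[dict[tuple[str, int, int], set[str]], pd.DataFrame]:
    """Ground-truth region -> element hits and per-gene element counts by
    brute-force coordinate arithmetic (independent of :mod:`.annotate`).

    Returns ``(region_hits, gene_table)`` where ``gene_table`` has
    columns gene_id / n_elements / element_ids, matching
    :func:`chromins.annotate.assign_regions` output.
    """
    features: list[tuple[str, int, int, str, tuple[str, ...]]] = []
    for el in enhancers:
        iv = el.interval
        features.append((iv.chrom, iv.start, iv.end, el.element_id,
                         el.connected_genes))
    for g in genes:
        features.append((g.chrom, g.start, g.end, f"body::{g.gene_id}",
                         (g.gene_id,)))
        prom = promoter_interval(g, promoter_len)
        if prom is not None:
            features.append((prom.chrom, prom.start, prom.end,
                             f"prom::{g.gene_id}", (g.gene_id,)))

    region_hits: dict[tuple[str, int, int], set[str]] = {}
    gene_elements: dict[str, set[str]] = {}
    for region in regions:
        key = (region.chrom, region.start, region.end)
        hits: set[str] = set()
        for chrom, fs, fe, fid, connected in features:
            if chrom == region.chrom and min(fe, region.end) - max(fs, region.start) >= 1:
                hits.add(fid)
                for gid in connected:
                    gene_elements.setdefault(gid, set()).add(fid)
        region_hits[key] = hits
    rows = [
        {"gene_id": gid, "n_elements": len(els),
         "element_ids": ",".join(sorted(els))}
        for gid, els in sorted(gene_elements.items())
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "n_elements", "element_ids"])
    return region_hits, table


def gen_genomic(
    peak_cfg: PeakSimConfig, regmap_cfg: RegMapSimConfig, seed: int
) -> dict:
    """Orchestrate regmap + peaks with shared occupancy and full truth.

    Returns a dict with keys ``peaks_a``, ``peaks_b``, ``regions``
    (truth co-deposition spans), ``enhancers``, ``genes``,
    ``region_hits`` and ``gene_table`` (annotation truth).
    """
    elements, genes = gen_regmap(regmap_cfg, seed)
    occ = _Occupancy()  # peaks may overlap gene features, only peak-peak
    peaks_a, peaks_b, regions = gen_peaks(
        peak_cfg,
        seed + 1,
        enhancers=elements if elements else None,
        in_enhancer_fraction=regmap_cfg.region_in_enhancer_fraction,
        occupancy=occ,
    )
    region_hits, gene_table = truth_connections(
        regions, elements, genes, regmap_cfg.promoter_len
    )
    return {
        "peaks_a": peaks_a,
        "peaks_b": peaks_b,
        "regions": regions,
        "enhancers": elements,
        "genes": genes,
        "region_hits": region_hits,
        "gene_table": gene_table,
    }


# ---------------------------------------------------------------------------
# Count sampling


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray | float
) -> np.ndarray:
    """NB(mean, dispersion) counts; dispersion 0 gives the Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        n = 1.0 / phi[~pois]
        p = n / (n + mean[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out


# ---------------------------------------------------------------------------
# Bulk


def gen_bulk(
    cfg: BulkSimConfig, seed: int,
    responsive_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a bulk count matrix with planted responsive genes.

    Paired design: ``n_samples // 2`` donors, each with a control and an
    insulin-stimulated sample; planted genes change by ``±log2fc`` in
    the stimulated condition; gene-by-donor baseline wobble of sd
    ``donor_effect_sd_log2`` log2 units.  Covariate design: per-sample
    plasma insulin drawn log-normal; planted genes follow a
    ``±slope_log2`` log2-per-unit trend around the mean insulin level.

    Returns ``(counts, meta, truth)`` where truth has one row per gene
    with columns ``responsive`` (bool) and ``effect_log2`` (the planted
    log2FC or slope; 0 for null genes).

    ``responsive_genes`` overrides the random choice of planted genes;
    the stimulation and regression arms of one study share a single
    insulin-responsive program, so paired fixtures plant the same set
    in both (see :func:`gen_bulk_pair`).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    base_mean = rng.lognormal(cfg.mean_log, cfg.mean_sd, size=cfg.n_genes)

    responsive = np.zeros(cfg.n_genes, dtype=bool)
    if responsive_genes is not None:
        wanted = set(responsive_genes)
        unknown = wanted - set(gene_ids)
        if unknown:
            raise ValueError(f"unknown responsive genes: {sorted(unknown)[:5]}")
        responsive[[i for i, g in enumerate(gene_ids) if g in wanted]] = True
    else:
        n_resp = round(cfg.responsive_fraction * cfg.n_genes)
        resp_idx = rng.choice(cfg.n_genes, size=n_resp, replace=False)
        responsive[resp_idx] = True
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)

    sf = rng.lognormal(0.0, cfg.size_factor_sd, size=cfg.n_samples)

    if cfg.design == "paired":
        n_donors = cfg.n_samples // 2
        donors = [f"D{d + 1:02d}" for d in range(n_donors)]
        units = [f"{d}_{g}" for d in donors for g in ("ctrl", "insulin")]
        group = ["ctrl", "insulin"] * n_donors
        donor_col = [d for d in donors for _ in range(2)]
        effect = np.where(responsive, signs * cfg.log2fc, 0.0)
        donor_fx = rng.normal(
            0.0, cfg.donor_effect_sd_log2, size=(cfg.n_genes, n_donors)
        )
        log2_mu = np.log2(base_mean)[:, None] + np.repeat(donor_fx, 2, axis=1)
        treated = np.array([g == "insulin" for g in group], dtype=float)
        log2_mu = log2_mu + np.outer(effect, treated)
        meta = pd.DataFrame(
            {"group": group, "donor": donor_col}, index=units
        )
    else:
        units = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
        insulin = rng.lognormal(
            cfg.insulin_log_mean, cfg.insulin_log_sd, size=cfg.n_samples
        )
        effect = np.where(responsive, signs * cfg.slope_log2, 0.0)
        centered = insulin - insulin.mean()
        log2_mu = np.log2(base_mean)[:, None] + np.outer(effect, centered)
        meta = pd.DataFrame({"insulin": insulin}, index=units)

    mu = (2.0 ** log2_mu) * sf[None, :]
    counts = pd.DataFrame(
        _nb_draw(rng, mu, cfg.dispersion), index=gene_ids, columns=units
    )
    meta.index.name = "unit"
    truth = pd.DataFrame(
        {"responsive": responsive, "effect_log2": effect}, index=gene_ids
    )
    truth.index.name = "gene_id"
    return counts, meta, truth


def gen_bulk_pair(
    stim_cfg: BulkSimConfig, reg_cfg: BulkSimConfig, seed: int
) -> dict:
    """Generate the two bulk arms of one study sharing a single planted
    insulin-responsive gene program.

    The responsive set is drawn once (``stim_cfg.responsive_fraction``
    of the shared gene universe) and planted in both the
    paired-stimulation and the covariate-regression dataset, mirroring
    a cohort whose insulin-responsive genes both react to stimulation
    in vitro and track plasma insulin.  Returns a dict with keys
    ``stim_counts``, ``stim_meta``, ``stim_truth``, ``reg_counts``,
    ``reg_meta``, ``reg_truth`` and ``responsive_genes``.
    """
    if stim_cfg.n_genes != reg_cfg.n_genes:
        raise ValueError("both arms must share one gene universe")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(stim_cfg.n_genes)]
    n_resp = round(stim_cfg.responsive_fraction * stim_cfg.n_genes)
    resp = sorted(rng.choice(gene_ids, size=n_resp, replace=False))
    sc, sm, st = gen_bulk(stim_cfg, seed + 1, responsive_genes=resp)
    rc, rm, rt = gen_bulk(reg_cfg, seed + 2, responsive_genes=resp)
    return {
        "stim_counts": sc, "stim_meta": sm, "stim_truth": st,
        "reg_counts": rc, "reg_meta": rm, "reg_truth": rt,
        "responsive_genes": set(resp),
    }


def gen_bulk_gene_sets(
    truth: pd.DataFrame, seed: int, n_sets: int = 6, set_size: int = 40,
    enriched_fraction: float = 0.5,
) -> list[GeneSet]:
    """GO-like gene sets over a bulk universe: the first set is enriched
    in planted responsive genes (``enriched_fraction`` of its members),
    the rest are uniform draws."""
    rng = np.random.default_rng(seed)
    universe = np.array(truth.index)
    resp = np.array(truth.index[truth["responsive"]])
    nonresp = np.array(truth.index[~truth["responsive"]])
    sets: list[GeneSet] = []
    k = min(round(enriched_fraction * set_size), len(resp))
    members = np.concatenate([
        rng.choice(resp, size=k, replace=False),
        rng.choice(nonresp, size=set_size - k, replace=False),
    ])
    sets.append(GeneSet("planted_enriched", "SYN:0001", tuple(sorted(members))))
    for j in range(1, n_sets):
        members = rng.choice(universe, size=set_size, replace=False)
        sets.append(
            GeneSet(f"random_{j}", f"SYN:{j + 1:04d}", tuple(sorted(members)))
        )
    return sets


# ---------------------------------------------------------------------------
# Single cell


def gen_sc(
    cfg: ScSimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate clustered single-cell counts with planted high-ISM cells.

    Cells are assigned clusters by the configured proportions; within
    each cluster group a ``prevalence[group]`` fraction of cells is true
    high-ISM, with every ISM gene's mean shifted up by
    ``ism_shift_log2`` log2 units.  Per-cluster marker genes (x
    ``marker_fc`` in their own cluster) and the response genes
    (down-shifted in aggressive-group true-high cells) add structure;
    per-cell depth factors are log-normal.

    Returns ``(counts, cell_meta, truth)``; ``cell_meta`` has columns
    cluster / group / tissue / donor, ``truth`` a boolean
    ``true_high`` per cell.
    """
    rng = np.random.default_rng(seed)
    clusters_list = sorted(cfg.cluster_props)
    props = np.array([cfg.cluster_props[c] for c in clusters_list])
    cluster_ix = rng.choice(len(clusters_list), size=cfg.n_cells, p=props)
    clusters = np.array(clusters_list, dtype=object)[cluster_ix]
    groups = np.array([cfg.group_map[c] for c in clusters], dtype=object)

    true_high = np.zeros(cfg.n_cells, dtype=bool)
    for g, prev in cfg.prevalence.items():
        sel = groups == g
        n_exp = prev * sel.sum()
        if 0 < n_exp < 5:
            import warnings

            warnings.warn(
                f"group {g!r}: expected high-ISM cells < 5 ({n_exp:.1f})"
            )
        true_high[sel] = rng.random(sel.sum()) < prev

    gene_ids: list[str] = list(cfg.ism_genes)
    ism_n = len(gene_ids)
    marker_ids = {
        c: [f"MK_{c}_{j + 1}" for j in range(cfg.n_markers_per_cluster)]
        for c in clusters_list
    }
    for c in clusters_list:
        gene_ids.extend(marker_ids[c])
    gene_ids.extend(cfg.response_genes)
    bg_ids = [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]
    gene_ids.extend(bg_ids)
    n_genes = len(gene_ids)

    mean = np.empty((n_genes, cfg.n_cells))
    disp = np.empty(n_genes)
    row = 0
    ism_scale = np.ones(cfg.n_cells)
    if cfg.cluster_ism_scale:
        for c, s in cfg.cluster_ism_scale.items():
            ism_scale[clusters == c] = s
    shift = 2.0 ** cfg.ism_shift_log2
    for _ in range(ism_n):
        mean[row] = cfg.ism_mean * ism_scale * np.where(true_high, shift, 1.0)
        disp[row] = cfg.ism_dispersion
        row += 1
    for c in clusters_list:
        in_c = clusters == c
        for _ in marker_ids[c]:
            mean[row] = cfg.marker_mean * np.where(in_c, cfg.marker_fc, 1.0)
            disp[row] = cfg.bg_dispersion
            row += 1
    down = true_high
    for _ in cfg.response_genes:
        mean[row] = cfg.response_mean * np.where(down, cfg.response_down_fc, 1.0)
        disp[row] = cfg.bg_dispersion
        row += 1
    bg_means = rng.lognormal(cfg.bg_mean_log, cfg.bg_mean_sd,
                             size=cfg.n_background_genes)
    for m in bg_means:
        mean[row] = m
        disp[row] = cfg.bg_dispersion
        row += 1

    depth = rng.lognormal(0.0, cfg.depth_sd, size=cfg.n_cells)
    mean *= depth[None, :]
    counts = pd.DataFrame(
        _nb_draw(rng, mean, disp[:, None]),
        index=gene_ids,
        columns=[f"cell{i + 1:05d}" for i in range(cfg.n_cells)],
    )
    donors = np.array([f"P{1 + (i % 5):02d}" for i in range(cfg.n_cells)])
    cell_meta = pd.DataFrame(
        {
            "cluster": clusters,
            "group": groups,
            "tissue": cfg.tissue,
            "donor": donors,
        },
        index=counts.columns,
    )
    cell_meta.index.name = "cell"
    truth = pd.DataFrame({"true_high": true_high}, index=counts.columns)
    truth.index.name = "cell"
    return counts, cell_meta, truth


def gen_sc_gene_sets(cfg: ScSimConfig, seed: int) -> list[GeneSet]:
    """Gene sets over the single-cell universe for SES scoring: one
    metabolic-like background set per pathway name plus the ISM panel."""
    rng = np.random.default_rng(seed)
    bg_ids = np.array([f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)])
    names = ["glycolysis_like", "oxphos_like", "ppp_like", "tca_like"]
    sets = []
    size = max(5, cfg.n_background_genes // 8)
    for j, name in enumerate(names):
        members = rng.choice(bg_ids, size=size, replace=False)
        sets.append(GeneSet(name, f"SYN:SC{j + 1:03d}", tuple(sorted(members))))
    sets.append(GeneSet("insulin_signaling", "SYN:ISM",
                        tuple(cfg.ism_genes)))
    return sets
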