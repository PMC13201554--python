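"""Connect co-deposited chromatin regions to genes via regulatory elements.

A regulatory map pools three element kinds, each carrying a list of
connected gene identifiers:

* ``enhancer`` — rows of a GeneHancer-style flat export (BED4 plus a
  final comma-separated connected-gene column),
* ``gene_body`` — one element per gene model, connected to itself,
* ``promoter`` — a fixed-length window immediately upstream of the TSS
  (strand-aware, clipped at the chromosome origin), connected to its gene.

A query region "hits" an element when their intersection is at least one
base (half-open coordinates); every hit contributes the element's
connected genes.  No connection-score filtering is applied: the entire
connected-gene list of a hit element is retrieved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, PeakSet

ELEMENT_KINDS = ("enhancer", "gene_body", "promoter")


@dataclass(frozen=True)
class GeneModel:
    """A gene body ``chrom:[start, end)`` with strand; the TSS is ``start``
    on "+" and ``end`` on "-"."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class RegulatoryElement:
    element_id: str
    interval: GenomicInterval
    connected_genes: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if not self.connected_genes:
            raise ValueError(f"{self.element_id}: connected_genes must be non-empty")
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"{self.element_id}: unknown kind {self.kind!r}")


class RegMap:
    """An integrated list of regulatory elements indexed for interval query."""

    def __init__(self, elements: Iterable[RegulatoryElement]) -> None:
        self.elements: tuple[RegulatoryElement, ...] = tuple(elements)
        ids = [e.element_id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element ids in RegMap")
        self._trees: dict[str, IntervalTree] = {}
        for el in self.elements:
            tree = self._trees.setdefault(el.interval.chrom, IntervalTree())
            tree[el.interval.start:el.interval.end] = el

    def __len__(self) -> int:
        return len(self.elements)

    def query(self, chrom: str, start: int, end: int) -> list[RegulatoryElement]:
        """Elements intersecting ``chrom:[start, end)`` by >= 1 base."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(start, end)]
        return sorted(hits, key=lambda e: (e.interval.start, e.element_id))


@dataclass
class RegionAssignment:
    """Result of overlapping regions with a regulatory map.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per connected gene: ``gene_id``, ``n_elements`` (distinct
        co-deposition-bearing elements) and ``element_ids``
        (comma-joined).  Every listed gene has count >= 1.
    region_hits : dict
        Per region ``(chrom, start, end)``: sorted list of hit element ids.
    n_regions, n_enhancer_hit : int
        Total regions queried and regions hitting >= 1 enhancer-kind
        element.
    enhancer_fraction : float
        ``n_enhancer_hit / n_regions`` — the "within cis-RE" fraction.
    """

    table: pd.DataFrame
    region_hits: dict[tuple[str, int, int], list[str]]
    n_regions: int
    n_enhancer_hit: int

    @property
    def enhancer_fraction(self) -> float:
        return self.n_enhancer_hit / self.n_regions if self.n_regions else 0.0

    @property
    def connected_genes(self) -> set[str]:
        return set(self.table["gene_id"])


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED6-subset TSV:
    ``chrom  start  end  gene_id  score  strand`` (score ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene ids")
    return genes


def read_re_table(path: str | Path) -> list[RegulatoryElement]:
    """Read a regulatory-element map from a BED4+genes TSV:
    ``chrom  start  end  element_id  connected_genes`` where the last
    column is a comma-separated gene-id list.  Records with an empty
    gene list are rejected with a warning."""
    elements: list[RegulatoryElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, start, end, element_id, genes_col = fields[:5]
            genes = tuple(g for g in genes_col.split(",") if g)
            if not genes:
                warnings.warn(f"{path}:{lineno}: RE with empty gene list rejected")
                continue
            elements.append(
                RegulatoryElement(
                    element_id,
                    GenomicInterval(chrom, int(start), int(end), mark="enhancer"),
                    genes,
                    kind="enhancer",
                )
            )
    return elements


def write_re_table(elements: Sequence[RegulatoryElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            fh.write(
                "\t".join(
                    [
                        el.interval.chrom,
                        str(el.interval.start),
                        str(el.interval.end),
                        el.element_id,
                        ",".join(el.connected_genes),
                    ]
                )
                + "\n"
            )


def promoter_interval(
    gene: GeneModel, promoter_len: int = 2000
) -> GenomicInterval | None:
    """The ``promoter_len`` bases immediately upstream of the TSS:
    ``[start - L, start)`` on "+", ``[end, end + L)`` on "-", clipped at
    the chromosome origin.  Returns None when entirely clipped away."""
    if gene.strand == "+":
        start, end = max(0, gene.start - promoter_len), gene.start
    else:
        start, end = gene.end, gene.end + promoter_len
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, mark="promoter")


def build_regmap(
    re_elements: Iterable[RegulatoryElement],
    genes: Sequence[GeneModel],
    promoter_len: int = 2000,
) -> RegMap:
    """Combine enhancer REs with per-gene body and upstream-promoter
    elements into one integrated :class:`RegMap`.

    Every gene contributes a ``gene_body`` element (connected to itself)
    and, unless clipped away, a ``promoter`` element of ``promoter_len``
    bases upstream of its TSS.
    """
    if promoter_len < 1:
        raise ValueError("promoter_len must be positive")
    elements: list[RegulatoryElement] = list(re_elements)
    for gene in genes:
        elements.append(
            RegulatoryElement(
                f"body::{gene.gene_id}",
                GenomicInterval(gene.chrom, gene.start, gene.end, mark="gene_body"),
                (gene.gene_id,),
                kind="gene_body",
            )
        )
        prom = promoter_interval(gene, promoter_len)
        if prom is None:
            warnings.warn(
                f"promoter of {gene.gene_id} entirely clipped away; dropped"
            )
            continue
        elements.append(
            RegulatoryElement(
                f"prom::{gene.gene_id}", prom, (gene.gene_id,), kind="promoter"
            )
        )
    return RegMap(elements)


def assign_regions(regions: PeakSet, regmap: RegMap) -> RegionAssignment:
    """Overlap regions with the regulatory map and retrieve connected genes.

    A region hits an element iff their intersection is >= 1 bp; each hit
    contributes the element's full connected-gene list; elements are
    deduplicated per gene.  Also reports how many regions hit at least
    one enhancer-kind element (the "within cis-RE" count/fraction).
    """
    if len(regmap) == 0:
        raise ValueError("assign_regions: empty RegMap")
    gene_elements: dict[str, set[str]] = {}
    region_hits: dict[tuple[str, int, int], list[str]] = {}
    n_enh = 0
    for region in regions:
        hits = regmap.query(region.chrom, region.start, region.end)
        region_hits[(region.chrom, region.start, region.end)] = [
            e.element_id for e in hits
        ]
        if any(e.kind == "enhancer" for e in hits):
            n_enh += 1
        for el in hits:
            for g in el.connected_genes:
                gene_elements.setdefault(g, set()).add(el.element_id)
    rows = [
        {
            "gene_id": g,
            "n_elements": len(els),
            "element_ids": ",".join(sorted(els)),
        }
        for g, els in sorted(gene_elements.items())
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "n_elements", "element_ids"])
    return RegionAssignment(
        table=table,
        region_hits=region_hits,
        n_regions=len(regions),
        n_enhancer_hit=n_enh,
    )


def fraction_connected(query: Iterable[str], connected: Iterable[str]) -> float:
    """Fraction of ``query`` genes present in ``connected``:
    ``|query ∩ connected| / |query|``."""
    qs = set(query)
    if not qs:
        raise ValueError("fraction_connected: empty query gene set")
    return len(qs & set(connected)) / len(qs)
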