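"""Pipeline stages tying the analysis arms together.

Three arms compose the library stages on files declared in a single
YAML configuration:

* ``codeposition`` — read two peak BEDs, derive co-deposition regions,
  overlap them with the integrated regulatory map, retrieve connected
  genes and per-pathway connection fractions;
* ``insulin`` — size factors, NB Wald fits for the paired stimulation
  contrast and the plasma-insulin regression, the insulin-responsive
  union with Venn counts, and hypergeometric over-representation of the
  union against the configured gene sets;
* ``stratify`` — single-cell normalisation, SES per gene set, ISM
  scoring, high/low classification, group prevalence with chi-square,
  and Wilcoxon comparisons of SES and selected genes between high and
  low ISM cells.

Every analysis choice (thresholds, scopes, gene lists) lives in the
configuration; outputs are TSV files written with a fixed float format
so reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    assign_regions,
    build_regmap,
    fraction_connected,
    read_gene_models,
    read_re_table,
    write_re_table,
)
from .diffexpr import (
    insulin_responsive,
    nb_fit,
    read_counts_mtx,
    read_counts_tsv,
    read_sample_meta,
    write_counts_mtx,
    write_counts_tsv,
)
from .intervals import codeposition_regions, read_bed, write_bed
from .setscore import (
    normalize_sc,
    ora,
    read_gmt,
    ses_table,
    write_gmt,
)
from .stratify import ISMStratifier, groupwise_wilcoxon
from .synthetic import (
    BulkSimConfig,
    PeakSimConfig,
    RegMapSimConfig,
    ScSimConfig,
    gen_bulk_gene_sets,
    gen_bulk_pair,
    gen_genomic,
    gen_sc,
    gen_sc_gene_sets,
    rast_sc_config,
)

log = logging.getLogger("chromins")

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


class PipelineConfig:
    """Declarative pipeline configuration (YAML mapping).

    Top-level keys: ``seed`` (int), ``outdir`` (path), ``inputs``
    (mapping of input-file paths) and ``params`` (stage parameters).
    Unknown parameter keys raise, so typos fail fast.
    """

    _PARAM_DEFAULTS: dict[str, Any] = {
        "promoter_len": 2000,
        "alpha": 0.05,
        "scope": "global",
        "ism_genes": ["INSR", "IGF1R", "IRS1", "IRS2"],
        "aggressive_clusters": ["Tph", "proliferating", "Vdelta2"],
        "wilcoxon_genes": ["BIRC5", "IFNG", "TNF"],
        "treatment": None,
    }

    def __init__(self, mapping: Mapping[str, Any], base_dir: Path | None = None):
        self.seed = int(mapping.get("seed", 0))
        base = Path(base_dir) if base_dir is not None else Path(".")
        self.outdir = base / str(mapping.get("outdir", "results"))
        raw_inputs = mapping.get("inputs", {}) or {}
        self.inputs = {k: base / str(v) for k, v in raw_inputs.items()}
        params = dict(self._PARAM_DEFAULTS)
        unknown = set(mapping.get("params", {}) or {}) - set(params)
        if unknown:
            raise ValueError(f"unknown config params: {sorted(unknown)}")
        params.update(mapping.get("params", {}) or {})
        self.params = params

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls(mapping, base_dir=path.parent)

    def input_path(self, key: str) -> Path:
        try:
            path = self.inputs[key]
        except KeyError:
            raise PipelineError(f"config: missing input {key!r}") from None
        if not path.exists():
            raise PipelineError(f"config: input file not found: {path}")
        return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index,
              index_label=index_label)


def _stage(name: str):
    def deco(fn):
        def wrapper(cfg: PipelineConfig, *a, **kw):
            try:
                cfg.outdir.mkdir(parents=True, exist_ok=True)
                log.info("stage %s: start (seed=%d, version=%s)", name,
                         cfg.seed, __version__)
                for k, v in sorted(cfg.params.items()):
                    log.debug("stage %s: param %s = %r", name, k, v)
                out = fn(cfg, *a, **kw)
                log.info("stage %s: done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:  # surface stage name on any failure
                raise PipelineError(f"stage {name}: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("codeposition")
def run_codeposition(cfg: PipelineConfig) -> dict[str, Any]:
    """Co-deposition regions, connected genes, per-set connection fractions."""
    peaks_a = read_bed(cfg.input_path("peaks_a"))
    peaks_b = read_bed(cfg.input_path("peaks_b"))
    regions = codeposition_regions(peaks_a, peaks_b)
    log.info("codeposition: %d + %d peaks -> %d regions",
             len(peaks_a), len(peaks_b), len(regions))

    re_elements = read_re_table(cfg.input_path("re_map"))
    genes = read_gene_models(cfg.input_path("gene_models"))
    regmap = build_regmap(re_elements, genes,
                          promoter_len=int(cfg.params["promoter_len"]))
    assignment = assign_regions(regions, regmap)
    log.info("codeposition: %d/%d regions within cis-RE (%.1f%%), "
             "%d connected genes", assignment.n_enhancer_hit,
             assignment.n_regions, 100 * assignment.enhancer_fraction,
             len(assignment.connected_genes))

    write_bed(regions, cfg.outdir / "codeposition_regions.bed")
    _write_tsv(assignment.table, cfg.outdir / "gene_connections.tsv")

    frac_rows = []
    if "genome_gene_sets" in cfg.inputs:
        connected = assignment.connected_genes
        for gs in read_gmt(cfg.input_path("genome_gene_sets")):
            frac_rows.append({
                "set": gs.name,
                "n_set": len(gs.members),
                "fraction_connected": fraction_connected(gs.members, connected),
            })
    frac = pd.DataFrame(frac_rows,
                        columns=["set", "n_set", "fraction_connected"])
    _write_tsv(frac, cfg.outdir / "connection_fractions.tsv")

    summary = pd.DataFrame([{
        "n_peaks_a": len(peaks_a), "n_peaks_b": len(peaks_b),
        "n_regions": assignment.n_regions,
        "n_enhancer_hit": assignment.n_enhancer_hit,
        "enhancer_fraction": assignment.enhancer_fraction,
        "n_connected_genes": len(assignment.connected_genes),
    }])
    _write_tsv(summary, cfg.outdir / "codeposition_summary.tsv")
    return {"regions": regions, "assignment": assignment,
            "fractions": frac}


@_stage("insulin")
def run_insulin(cfg: PipelineConfig) -> dict[str, Any]:
    """DE on both arms, insulin-responsive union, Venn counts, ORA."""
    stim_counts = read_counts_tsv(cfg.input_path("stim_counts"))
    stim_meta = read_sample_meta(cfg.input_path("stim_meta"))
    reg_counts = read_counts_tsv(cfg.input_path("reg_counts"))
    reg_meta = read_sample_meta(cfg.input_path("reg_meta"))
    if "insulin" not in reg_meta.columns:
        raise PipelineError(
            "insulin: covariate design requires an 'insulin' metadata column"
        )
    treatment = cfg.params.get("treatment")
    stim = nb_fit(stim_counts, stim_meta, design="paired-contrast",
                  treatment=treatment)
    reg = nb_fit(reg_counts, reg_meta, design="covariate",
                 covariate_name="insulin")
    alpha = float(cfg.params["alpha"])
    resp = insulin_responsive(stim, reg, alpha=alpha)
    log.info("insulin: stim %d, reg %d, union %d responsive genes",
             resp.n_stim, resp.n_reg, resp.n_union)

    _write_tsv(stim, cfg.outdir / "stim_de.tsv", index=True,
               index_label="gene_id")
    _write_tsv(reg, cfg.outdir / "reg_de.tsv", index=True,
               index_label="gene_id")
    (cfg.outdir / "responsive_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(resp.genes))
    )
    venn = pd.DataFrame([resp.venn_counts()])
    _write_tsv(venn, cfg.outdir / "venn_counts.tsv")

    ora_df = pd.DataFrame(
        columns=["set", "source", "n_set", "overlap", "p", "padj"]
    )
    if "bulk_gene_sets" in cfg.inputs and resp.genes:
        sets = read_gmt(cfg.input_path("bulk_gene_sets"))
        universe = set(stim.index) | set(reg.index)
        ora_df = ora(resp.genes & universe, sets, universe)
    _write_tsv(ora_df, cfg.outdir / "ora.tsv")
    return {"stim": stim, "reg": reg, "responsive": resp, "ora": ora_df}


@_stage("stratify")
def run_stratify(cfg: PipelineConfig) -> dict[str, Any]:
    """SES, ISM stratification, prevalence/chi-square, Wilcoxon tables."""
    counts = read_counts_mtx(
        cfg.input_path("sc_counts_mtx"),
        cfg.input_path("sc_genes"),
        cfg.input_path("sc_cells"),
    )
    meta = read_sample_meta(cfg.input_path("cell_meta"))
    expr = normalize_sc(counts)
    gene_sets = read_gmt(cfg.input_path("sc_gene_sets"))

    ses_df = ses_table(expr, gene_sets)
    strat = ISMStratifier(
        ism_genes=tuple(cfg.params["ism_genes"]),
        scope=str(cfg.params["scope"]),
        aggressive_clusters=tuple(cfg.params["aggressive_clusters"]),
    ).fit(expr, meta)
    prev = strat.prevalence_
    log.info("stratify: prevalences %s; chi2=%.3f p=%.3g",
             {g: round(v, 2) for g, v in prev.prevalence.items()},
             strat.chi2_.statistic, strat.chi2_.p)

    out = pd.DataFrame({
        "ism_score": strat.scores_,
        "ism_class": strat.labels_,
        "cluster": meta.loc[strat.scores_.index, "cluster"],
        "group": strat.groups_,
    })
    _write_tsv(out, cfg.outdir / "ism_stratification.tsv", index=True,
               index_label="cell")
    _write_tsv(ses_df, cfg.outdir / "ses.tsv", index=True, index_label="cell")
    _write_tsv(prev.table, cfg.outdir / "prevalence_counts.tsv", index=True,
               index_label="ism_class")
    prev_df = prev.prevalence.rename_axis("group").reset_index()
    prev_df["n_total"] = prev.table.sum(axis=0).loc[prev_df["group"]].values
    _write_tsv(prev_df, cfg.outdir / "prevalence.tsv")
    chi_df = pd.DataFrame([dataclasses.asdict(strat.chi2_)])
    _write_tsv(chi_df, cfg.outdir / "chisquare.tsv")

    # Wilcoxon: SES per set and selected genes, high vs low ISM cells
    wil_rows = []
    labels = strat.labels_
    for col in ses_df.columns:
        res = groupwise_wilcoxon(ses_df[col], labels.loc[ses_df.index])
        wil_rows.append({"variable": f"SES:{col}", "statistic": res.statistic,
                         "p": res.p, "n": res.n})
    for g in cfg.params["wilcoxon_genes"]:
        if g in expr.index:
            res = groupwise_wilcoxon(expr.loc[g], labels)
            wil_rows.append({"variable": f"gene:{g}",
                             "statistic": res.statistic, "p": res.p,
                             "n": res.n})
    wil = pd.DataFrame(wil_rows, columns=["variable", "statistic", "p", "n"])
    _write_tsv(wil, cfg.outdir / "wilcoxon.tsv")
    return {"ses": ses_df, "stratifier": strat, "wilcoxon": wil,
            "prevalence": prev}


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the three analysis arms in sequence on one configuration."""
    out = {}
    out["codeposition"] = run_codeposition(cfg)
    out["insulin"] = run_insulin(cfg)
    out["stratify"] = run_stratify(cfg)
    return out


# ---------------------------------------------------------------------------
# Simulation bundle


def simulate_bundle(
    outdir: str | Path,
    seed: int,
    peak_cfg: PeakSimConfig | None = None,
    regmap_cfg: RegMapSimConfig | None = None,
    stim_cfg: BulkSimConfig | None = None,
    reg_cfg: BulkSimConfig | None = None,
    sc_cfg: ScSimConfig | None = None,
) -> Path:
    """Emit a complete synthetic input bundle plus truth tables and a
    ready-to-run ``config.yaml``; returns the config path.

    Truth files land under ``<outdir>/truth/`` so recovery tests can
    compare pipeline output with the planted structure.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    peak_cfg = peak_cfg or PeakSimConfig()
    regmap_cfg = regmap_cfg or RegMapSimConfig()
    stim_cfg = stim_cfg or BulkSimConfig(design="paired")
    reg_cfg = reg_cfg or BulkSimConfig(design="covariate", n_samples=24)
    sc_cfg = sc_cfg or rast_sc_config()

    gen = gen_genomic(peak_cfg, regmap_cfg, seed)
    write_bed(gen["peaks_a"], outdir / "peaks_survivin.bed")
    write_bed(gen["peaks_b"], outdir / "peaks_h3k27ac.bed")
    write_re_table(gen["enhancers"], outdir / "re_map.tsv")
    with open(outdir / "gene_models.tsv", "w") as fh:
        for g in gen["genes"]:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    write_bed(gen["regions"], outdir / "truth" / "codeposition_regions.bed")
    _write_tsv(gen["gene_table"], outdir / "truth" / "gene_connections.tsv")

    # genome gene sets for connection fractions
    rng = np.random.default_rng(seed + 10)
    gene_ids = np.array([g.gene_id for g in gen["genes"]])
    from .setscore import GeneSet

    genome_sets = []
    for j, name in enumerate(
        ["glycolysis_like", "oxphos_like", "ppp_like", "tca_like"]
    ):
        members = rng.choice(gene_ids, size=max(5, len(gene_ids) // 8),
                             replace=False)
        genome_sets.append(
            GeneSet(name, f"SYN:GN{j + 1:03d}", tuple(sorted(members)))
        )
    write_gmt(genome_sets, outdir / "genome_genesets.gmt")

    pair = gen_bulk_pair(stim_cfg, reg_cfg, seed + 20)
    write_counts_tsv(pair["stim_counts"], outdir / "stim_counts.tsv")
    _write_tsv(pair["stim_meta"], outdir / "stim_meta.tsv", index=True,
               index_label="unit")
    write_counts_tsv(pair["reg_counts"], outdir / "reg_counts.tsv")
    _write_tsv(pair["reg_meta"], outdir / "reg_meta.tsv", index=True,
               index_label="unit")
    _write_tsv(pair["stim_truth"], outdir / "truth" / "bulk_truth.tsv",
               index=True, index_label="gene_id")
    bulk_sets = gen_bulk_gene_sets(pair["stim_truth"], seed + 21)
    write_gmt(bulk_sets, outdir / "bulk_genesets.gmt")

    counts, cell_meta, sc_truth = gen_sc(sc_cfg, seed + 30)
    write_counts_mtx(counts, outdir / "sc_counts.mtx",
                     outdir / "sc_genes.txt", outdir / "sc_cells.txt")
    _write_tsv(cell_meta, outdir / "cell_meta.tsv", index=True,
               index_label="cell")
    _write_tsv(sc_truth, outdir / "truth" / "sc_truth.tsv", index=True,
               index_label="cell")
    write_gmt(gen_sc_gene_sets(sc_cfg, seed + 31), outdir / "sc_genesets.gmt")

    config = {
        "seed": seed,
        "outdir": "results",
        "inputs": {
            "peaks_a": "peaks_survivin.bed",
            "peaks_b": "peaks_h3k27ac.bed",
            "re_map": "re_map.tsv",
            "gene_models": "gene_models.tsv",
            "genome_gene_sets": "genome_genesets.gmt",
            "stim_counts": "stim_counts.tsv",
            "stim_meta": "stim_meta.tsv",
            "reg_counts": "reg_counts.tsv",
            "reg_meta": "reg_meta.tsv",
            "bulk_gene_sets": "bulk_genesets.gmt",
            "sc_counts_mtx": "sc_counts.mtx",
            "sc_genes": "sc_genes.txt",
            "sc_cells": "sc_cells.txt",
            "cell_meta": "cell_meta.tsv",
            "sc_gene_sets": "sc_genesets.gmt",
        },
        "params": {
            "promoter_len": regmap_cfg.promoter_len,
            "alpha": 0.05,
            "scope": "global",
            "ism_genes": list(sc_cfg.ism_genes),
            "aggressive_clusters": sorted(
                c for c, g in sc_cfg.group_map.items()
                if g in ("aggressive", "active")
            ),
            "wilcoxon_genes": list(sc_cfg.response_genes),
        },
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
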