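"""End-to-end workflow: preprocess -> DE -> classify -> network -> link ->
enrich -> predict -> report, over plain-text inter-stage files.

Stage outputs are written in a fixed order with fixed float formatting, so
a rerun with identical inputs and config is byte-identical. The manifest
records a hash of the resolved config and the row count of every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as clin
from .annotation import GeneIndex, classify_all, read_bed6, read_gtf_genes
from .diffexpr import DECriteria, cluster_order, run_de, volcano_table
from .enrichment import directional_enrichment, read_gmt
from .linking import link_targets
from .matrix import ExpressionMatrix
from .network import build_network, node_table, to_graphml
from .predict import (annotate_by_adjacency, annotate_by_network,
                      pathway_gene_lnc_table, summary_report, write_report)
from .preprocess import FilterPolicy, filter_by_flags, quantile_normalize

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Input paths and thresholds for a full pipeline run."""

    matrix: str = "expression.tsv"
    flags: str = "flags.tsv"
    samples: str = "samples.tsv"
    probes: str = "probes.tsv"
    gtf: str = "genes.gtf"
    lnc_bed: str = "lnc_loci.bed"
    enhancer_bed: str = "enhancers.bed"
    gmt: str = "gene_sets.gmt"
    clinical: str | None = "clinical.tsv"
    ct: str | None = "ct.csv"
    fc: float = 2.0
    p: float = 0.05
    fdr: float = 0.05
    r_threshold: float = 0.998
    window: int = 300_000
    bidirectional_window: int = 1000
    alpha: float = 0.05
    min_r: float = 0.0
    min_flagged_samples: int = 6
    t_variant: str = "pooled"
    filter_order: str = "normalize_then_filter"   # or "filter_then_normalize"
    restrict_to_de: bool = True

    def __post_init__(self) -> None:
        for name in ("fc", "p", "fdr", "r_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window <= 0 or self.bidirectional_window <= 0:
            raise ValueError("windows must be positive")
        if self.filter_order not in ("normalize_then_filter",
                                     "filter_then_normalize"):
            raise ValueError(f"unknown filter_order {self.filter_order!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig, indir, outdir) -> dict:
    """Run every stage on the input bundle; returns the summary report."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        log.info("stage: %s", name)

    # -- preprocess --------------------------------------------------------
    try:
        stage("preprocess")
        m = ExpressionMatrix.from_tsv(
            indir / config.matrix, indir / config.samples, indir / config.flags
        )
        policy = FilterPolicy(min_flagged_samples=config.min_flagged_samples)
        if config.filter_order == "normalize_then_filter":
            m = filter_by_flags(quantile_normalize(m), policy)
        else:
            m = quantile_normalize(filter_by_flags(m, policy))
        m.to_tsv(outdir / "normalized.tsv")
        counts["preprocess"] = len(m.probe_ids)
    except Exception as e:                         # noqa: BLE001
        raise StageError("preprocess", e) from e

    # -- differential expression ------------------------------------------
    try:
        stage("de")
        probes = pd.read_csv(indir / config.probes, sep="\t")
        criteria = DECriteria(fc=config.fc, p=config.p, fdr=config.fdr,
                              variant=config.t_variant)
        de = run_de(m, probes, criteria)
        _write(de, outdir / "de_results.tsv")
        _write(volcano_table(de), outdir / "volcano.tsv")
        sig = de[de["significant"]]
        if len(sig) >= 3:
            rows, cols = cluster_order(m.values.loc[sig["probe_id"]])
            _write(pd.DataFrame({"kind": ["row"] * len(rows) + ["col"] * len(cols),
                                 "id": rows + cols}),
                   outdir / "cluster_order.tsv")
        counts["de"] = int(sig.shape[0])
    except Exception as e:                         # noqa: BLE001
        raise StageError("de", e) from e

    # -- classification ----------------------------------------------------
    try:
        stage("classify")
        genes = read_gtf_genes(indir / config.gtf)
        index = GeneIndex(genes)
        loci = read_bed6(indir / config.lnc_bed)
        enh_path = indir / config.enhancer_bed
        enhancers = read_bed6(enh_path) if enh_path.exists() else []
        sig_lnc = set(sig.loc[sig["probe_type"] == "lncRNA", "probe_id"])
        de_loci = [l for l in loci if l.name in sig_lnc] if config.restrict_to_de else loci
        classifications = classify_all(de_loci, index, enhancers,
                                       config.bidirectional_window)
        _write(classifications, outdir / "classification.tsv")
        counts["classify"] = len(classifications)
    except Exception as e:                         # noqa: BLE001
        raise StageError("classify", e) from e

    # -- co-expression network --------------------------------------------
    try:
        stage("network")
        sig_mrna = list(sig.loc[sig["probe_type"] == "mRNA", "probe_id"])
        edges = build_network(m, sorted(sig_lnc), sig_mrna, config.r_threshold)
        _write(edges.assign(r=edges["r"].round(4)), outdir / "edges.tsv")
        _write(node_table(edges), outdir / "nodes.tsv")
        to_graphml(edges, outdir / "network.graphml")
        counts["network"] = len(edges)
    except Exception as e:                         # noqa: BLE001
        raise StageError("network", e) from e

    # -- target linking ----------------------------------------------------
    try:
        stage("link")
        symbol_of_gene = {g.gene_id: g.symbol for g in index.genes}
        probe_of_symbol = {
            r.symbol: r.probe_id
            for r in probes[probes["probe_type"] == "mRNA"].itertuples()
        }
        gene_probe_of = {
            gid: probe_of_symbol[sym]
            for gid, sym in symbol_of_gene.items() if sym in probe_of_symbol
        }
        restrict = None
        if config.restrict_to_de:
            de_symbols = set(sig.loc[sig["probe_type"] == "mRNA", "symbol"])
            restrict = {g for g, s in symbol_of_gene.items() if s in de_symbols}
        links = link_targets(classifications, de_loci, index, m, gene_probe_of,
                             config.window, config.min_r, restrict)
        _write(links, outdir / "links.tsv")
        counts["link"] = len(links)
    except Exception as e:                         # noqa: BLE001
        raise StageError("link", e) from e

    # -- enrichment --------------------------------------------------------
    try:
        stage("enrich")
        if not (indir / config.gmt).exists():
            raise FileNotFoundError(f"gene-set file not found: {config.gmt}")
        sets = read_gmt(indir / config.gmt)
        universe = set(
            probes.loc[probes["probe_type"] == "mRNA", "symbol"]
        ) & set(m.probe_ids.map(
            dict(zip(probes["probe_id"], probes["symbol"]))))
        de_mrna = de[de["probe_type"] == "mRNA"]
        enrich = directional_enrichment(de_mrna, sets, universe, config.alpha)
        for direction, table in enrich.items():
            _write(table, outdir / f"enrichment_{direction}.tsv")
        counts["enrich"] = int(sum(t["significant"].sum() for t in enrich.values()))
    except Exception as e:                         # noqa: BLE001
        raise StageError("enrich", e) from e

    # -- function prediction ----------------------------------------------
    try:
        stage("predict")
        symbol_of = dict(zip(probes["probe_id"], probes["symbol"]))
        subtype_of = dict(zip(classifications["lnc_id"],
                              classifications["subtype"]))
        net_records = annotate_by_network(edges, enrich, sets, symbol_of,
                                          subtype_of)
        de_dir_of = dict(zip(de_mrna.loc[de_mrna["significant"], "symbol"],
                             de_mrna.loc[de_mrna["significant"], "direction"]))
        adj_records = annotate_by_adjacency(
            links, de_dir_of, sets, universe, subtype_of, symbol_of_gene,
            config.alpha,
        )
        records = pd.concat([net_records, adj_records], ignore_index=True)
        _write(records, outdir / "function_records.tsv")
        _write(pathway_gene_lnc_table(records), outdir / "pathway_tables.tsv")
        counts["predict"] = len(records)
    except Exception as e:                         # noqa: BLE001
        raise StageError("predict", e) from e

    # -- report ------------------------------------------------------------
    try:
        stage("report")
        report = summary_report(records, classifications, de, edges)
        report["config_hash"] = config.config_hash()
        report["stage_counts"] = counts
        write_report(report, outdir / "report.json", outdir / "report.txt")
        manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                    "stage_counts": counts}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as e:                         # noqa: BLE001
        raise StageError("report", e) from e
    return report


def run_clinical_stats(config: RunConfig, indir, outdir) -> dict:
    """Survival, demographics chi-square inputs and ddCt summaries."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}
    if config.clinical and (indir / config.clinical).exists():
        records = clin.read_clinical_tsv(indir / config.clinical)
        chi2, p = clin.logrank(records)
        out["logrank"] = {"chi_square": chi2, "p": p}
        curves = []
        for group in sorted(records["group"].unique()):
            c = clin.km_curve(records, group)
            c.insert(0, "group", group)
            curves.append(c)
        _write(pd.concat(curves, ignore_index=True), outdir / "km_curves.tsv")
    if config.ct and (indir / config.ct).exists():
        ct = clin.read_ct_csv(indir / config.ct)
        per_sample = clin.ddct(ct)
        _write(per_sample, outdir / "ddct_per_sample.tsv")
        summary = clin.ddct_group_summary(per_sample)
        _write(summary, outdir / "ddct_summary.tsv")
        out["ddct"] = {
            f"{r.target_gene}:{r.group}": r.mean_rel_expr
            for r in summary.itertuples()
        }
    with open(outdir / "clinical_stats.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
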