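"""Route-based lncRNA -> candidate target gene linking.

Three genomic routes, chosen by functional subtype:

- ``adjacent``      (lincRNA): coding genes within a gap distance of
                    300 kb on either side (overlap counts as distance 0);
- ``enhancer``      (enhancer-like lncRNA): the adjacency rule plus a
                    positive expression-correlation filter (r > min_r,
                    default 0);
- ``sense_partner`` (antisense lncRNA): the overlapped sense coding
                    gene(s) from the positional classification.

Distance is the gap between closest interval ends, symmetric in the two
intervals, with <= window inclusive.
"""

from __future__ import annotations

import logging

import pandas as pd

from .annotation import ANTISENSE_CLASSES, GeneIndex, GenomicInterval, PositionalClass
from .matrix import ExpressionMatrix
from .network import pearson_r

log = logging.getLogger(__name__)

LINK_COLUMNS = ["lnc_id", "gene_id", "route", "distance", "r"]


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap between closest ends; 0 if overlapping; None on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def adjacent_genes(
    lnc: GenomicInterval,
    genes: GeneIndex,
    window: int = 300_000,
) -> list[tuple[str, int]]:
    """(gene_id, distance) for genes within ``window`` bp, sorted by distance."""
    out = []
    for g in genes.on_chrom(lnc.chrom):
        d = gap_distance(lnc, g.interval)
        if d is not None and d <= window:
            out.append((g.gene_id, d))
    return sorted(out, key=lambda t: (t[1], t[0]))


def enhancer_targets(
    lnc_id: str,
    adjacent: list[tuple[str, int]],
    expr: ExpressionMatrix,
    gene_probe_of: dict[str, str],
    min_r: float = 0.0,
) -> pd.DataFrame:
    """Adjacent genes whose expression correlates positively with the lncRNA.

    ``gene_probe_of`` maps gene ids to their expression probe ids. Genes
    without an expression row are skipped with a warning. Keeps genes with
    pearson r strictly greater than ``min_r``.
    """
    if lnc_id not in expr.probe_ids:
        raise ValueError(f"no expression row for lncRNA {lnc_id}")
    x = expr.values.loc[lnc_id]
    rows = []
    for gene_id, dist in adjacent:
        probe = gene_probe_of.get(gene_id)
        if probe is None or probe not in expr.probe_ids:
            log.warning("gene %s has no expression row; skipped", gene_id)
            continue
        try:
            r = pearson_r(x, expr.values.loc[probe])
        except ValueError:
            log.warning("gene %s has zero variance; skipped", gene_id)
            continue
        if r > min_r:
            rows.append({"lnc_id": lnc_id, "gene_id": gene_id,
                         "route": "enhancer", "distance": dist, "r": r})
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def sense_partner(
    lnc_id: str,
    positional_class: PositionalClass | str,
    partner_gene_ids: list[str],
) -> pd.DataFrame:
    """One sense_partner link per overlapped coding gene of an antisense lncRNA."""
    cls = PositionalClass(positional_class)
    if cls not in ANTISENSE_CLASSES:
        raise ValueError(
            f"sense_partner applies to antisense lncRNAs, not {cls.value}"
        )
    rows = [
        {"lnc_id": lnc_id, "gene_id": g, "route": "sense_partner",
         "distance": 0, "r": float("nan")}
        for g in partner_gene_ids
    ]
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def link_targets(
    classifications: pd.DataFrame,
    loci: list[GenomicInterval],
    genes: GeneIndex,
    expr: ExpressionMatrix,
    gene_probe_of: dict[str, str],
    window: int = 300_000,
    min_r: float = 0.0,
    restrict_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Route-dispatching target links for every classified lncRNA.

    ``restrict_genes`` optionally limits targets to a gene-id set (e.g.
    differentially expressed genes present on the array).
    """
    locus_of = {l.name: l for l in loci}
    frames = []
    for row in classifications.itertuples():
        lnc = locus_of.get(row.lnc_id)
        partners = [g for g in str(row.partner_gene_ids).split(",") if g]
        if row.subtype == "antisense":
            frames.append(sense_partner(row.lnc_id, row.positional_class, partners))
        elif row.subtype in ("lincRNA", "enhancer_like"):
            if lnc is None:
                log.warning("no locus for %s; skipped", row.lnc_id)
                continue
            adj = adjacent_genes(lnc, genes, window)
            if row.subtype == "enhancer_like":
                frames.append(
                    enhancer_targets(row.lnc_id, adj, expr, gene_probe_of, min_r)
                )
            else:
                frames.append(pd.DataFrame(
                    [{"lnc_id": row.lnc_id, "gene_id": g, "route": "adjacent",
                      "distance": d, "r": float("nan")} for g, d in adj],
                    columns=LINK_COLUMNS,
                ))
        # subtype "other" (sense-overlapping / bidirectional) has no route
    frames = [f for f in frames if len(f)]
    links = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame(columns=LINK_COLUMNS)
    )
    if restrict_genes is not None and len(links):
        links = links[links["gene_id"].isin(restrict_genes)].reset_index(drop=True)
    return links
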