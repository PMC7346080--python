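"""Guilt-by-association function prediction.

A lncRNA inherits the significant pathways of the coding genes it is tied
to, through one of two integration routes:

- network route: for each significant pathway, collect its member mRNAs
  present in the co-expression network; every lncRNA partnered to such an
  mRNA receives that pathway (route ``coexpression``);
- genomic route: enrichment is run on the union of linked genes per
  functional subtype and DE direction, and each lncRNA inherits only the
  significant pathways its own linked genes belong to (routes
  ``adjacent`` / ``enhancer`` / ``sense_partner``).

Every reported (lncRNA, pathway) pair carries the explicit supporting
chain lncRNA -> gene -> pathway.
"""

from __future__ import annotations

import json
import logging

import pandas as pd

from .enrichment import GeneSet, enrich_gene_list

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "lnc_id", "subtype", "route", "set_id", "pathway_name",
    "direction", "supporting_genes",
]


def annotate_by_network(
    edges: pd.DataFrame,
    enrichment: dict[str, pd.DataFrame],
    sets: list[GeneSet],
    symbol_of: dict[str, str],
    subtype_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign significant pathways to lncRNAs through network mRNA partners.

    ``symbol_of`` maps mRNA probe ids to gene symbols; ``subtype_of``
    optionally maps lnc ids to functional subtypes for the report.
    """
    set_genes = {s.set_id: s.genes for s in sets}
    rows = []
    for direction, table in enrichment.items():
        for path in table[table["significant"]].itertuples():
            members = set_genes.get(path.set_id, frozenset())
            in_net = edges[
                edges["mrna_id"].map(lambda p: symbol_of.get(p) in members)
            ] if len(edges) else edges
            if len(in_net) == 0:
                continue
            for lnc_id, sub in in_net.groupby("lnc_id"):
                genes = sorted({symbol_of[m] for m in sub["mrna_id"]})
                rows.append({
                    "lnc_id": lnc_id,
                    "subtype": (subtype_of or {}).get(lnc_id, ""),
                    "route": "coexpression",
                    "set_id": path.set_id,
                    "pathway_name": path.name,
                    "direction": direction,
                    "supporting_genes": ",".join(genes),
                })
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return out.sort_values(["lnc_id", "set_id", "direction"],
                           kind="stable").reset_index(drop=True)


def annotate_by_adjacency(
    links: pd.DataFrame,
    de_direction_of: dict[str, str],
    sets: list[GeneSet],
    universe: set[str],
    subtype_of: dict[str, str],
    symbol_of_gene: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign pathways to lncRNAs through their genomically linked genes.

    Enrichment runs on the union of linked gene symbols per (subtype,
    direction); each lncRNA then inherits only the significant pathways of
    its own linked genes. ``de_direction_of`` maps gene symbols to their DE
    direction, ``symbol_of_gene`` maps gene ids to symbols.
    """
    if len(links) == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    links = links.copy()
    links["symbol"] = links["gene_id"].map(symbol_of_gene)
    links["lnc_subtype"] = links["lnc_id"].map(subtype_of)
    links["gene_direction"] = links["symbol"].map(de_direction_of)
    links = links.dropna(subset=["symbol", "gene_direction"])

    set_genes = {s.set_id: s.genes for s in sets}
    rows = []
    for (subtype, direction), grp in links.groupby(["lnc_subtype", "gene_direction"]):
        union = set(grp["symbol"]) & set(universe)
        if not union:
            continue
        table = enrich_gene_list(union, sets, universe, direction, alpha)
        for path in table[table["significant"]].itertuples():
            members = set_genes[path.set_id]
            hit = grp[grp["symbol"].isin(members)]
            for lnc_id, sub in hit.groupby("lnc_id"):
                supp = sorted(
                    f"{s}:{route}" for s, route in
                    zip(sub["symbol"], sub["route"])
                )
                rows.append({
                    "lnc_id": lnc_id,
                    "subtype": subtype,
                    "route": sub["route"].iloc[0],
                    "set_id": path.set_id,
                    "pathway_name": path.name,
                    "direction": direction,
                    "supporting_genes": ",".join(supp),
                })
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return out.sort_values(["lnc_id", "set_id", "direction"],
                           kind="stable").reset_index(drop=True)


def pathway_gene_lnc_table(records: pd.DataFrame) -> pd.DataFrame:
    """Pathway / gene / 'GENE <-> lnc1, lnc2, ...' presentation table."""
    rows = []
    expanded = []
    for rec in records.itertuples():
        for entry in rec.supporting_genes.split(","):
            gene = entry.split(":")[0]
            expanded.append((rec.set_id, rec.pathway_name, gene, rec.lnc_id))
    df = pd.DataFrame(expanded, columns=["set_id", "pathway_name", "gene", "lnc_id"])
    for (set_id, name, gene), grp in df.groupby(["set_id", "pathway_name", "gene"]):
        lncs = ", ".join(sorted(grp["lnc_id"].unique()))
        rows.append({"set_id": set_id, "pathway_name": name, "gene": gene,
                     "mrna_lncrna": f"{gene} <-> {lncs}"})
    return pd.DataFrame(rows, columns=["set_id", "pathway_name", "gene",
                                       "mrna_lncrna"])


def summary_report(
    records: pd.DataFrame,
    classifications: pd.DataFrame,
    de: pd.DataFrame,
    edges: pd.DataFrame,
) -> dict:
    """Machine-readable run summary with headline counts."""
    sig = de[de["significant"]]
    by_type = sig.groupby("probe_type").size().to_dict() if len(sig) else {}
    by_dir = {
        ptype: sig[sig["probe_type"] == ptype]
        .groupby("direction").size().to_dict()
        for ptype in sorted(by_type)
    }
    report = {
        "n_probes_tested": int(len(de)),
        "n_significant": {k: int(v) for k, v in sorted(by_type.items())},
        "n_significant_by_direction": {
            k: {d: int(c) for d, c in sorted(v.items())} for k, v in by_dir.items()
        },
        "n_classified": int(len(classifications)),
        "class_counts": {
            k: int(v) for k, v in sorted(
                classifications["positional_class"].value_counts().items()
            )
        } if len(classifications) else {},
        "subtype_counts": {
            k: int(v) for k, v in sorted(
                classifications["subtype"].value_counts().items()
            )
        } if len(classifications) else {},
        "n_network_edges": int(len(edges)),
        "n_network_lncrnas": int(edges["lnc_id"].nunique()) if len(edges) else 0,
        "n_network_mrnas": int(edges["mrna_id"].nunique()) if len(edges) else 0,
        "n_function_records": int(len(records)),
        "n_lncrnas_with_predictions": int(records["lnc_id"].nunique())
        if len(records) else 0,
        "pathways_with_predictions": sorted(records["set_id"].unique())
        if len(records) else [],
    }
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`summary_report`."""
    lines = ["lncforge run summary", "===================="]
    lines.append(f"probes tested:            {report['n_probes_tested']}")
    for k, v in report["n_significant"].items():
        dirs = report["n_significant_by_direction"].get(k, {})
        updown = ", ".join(f"{d}={c}" for d, c in dirs.items())
        lines.append(f"significant {k}:   {v} ({updown})")
    lines.append(f"classified lncRNA loci:   {report['n_classified']}")
    for k, v in report["class_counts"].items():
        lines.append(f"  class {k}: {v}")
    for k, v in report["subtype_counts"].items():
        lines.append(f"  subtype {k}: {v}")
    lines.append(f"network edges:            {report['n_network_edges']}")
    lines.append(f"network lncRNAs/mRNAs:    {report['n_network_lncrnas']}"
                 f"/{report['n_network_mrnas']}")
    lines.append(f"function records:         {report['n_function_records']}")
    lines.append(f"lncRNAs with predictions: {report['n_lncrnas_with_predictions']}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, json_path, text_path) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(text_path, "w") as fh:
        fh.write(format_report(report))
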