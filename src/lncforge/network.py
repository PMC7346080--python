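"""Thresholded Pearson co-expression network between DE lncRNAs and DE mRNAs.

For every (lncRNA, mRNA) pair of differentially expressed probes the
product-moment correlation across all samples is computed; pairs with
r strictly above the threshold (default 0.998) or strictly below its
negative become edges of a bipartite network.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["lnc_id", "mrna_id", "r", "n_samples"]


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def build_network(
    m: ExpressionMatrix,
    lnc_ids,
    mrna_ids,
    threshold: float = 0.998,
) -> pd.DataFrame:
    """All (lncRNA, mRNA) edges with |r| strictly above ``threshold``.

    Zero-variance probes are skipped with a warning. Empty input sets give
    an empty edge table, not an error.
    """
    lnc_ids = [p for p in lnc_ids if p in m.probe_ids]
    mrna_ids = [p for p in mrna_ids if p in m.probe_ids]
    if not lnc_ids or not mrna_ids:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    n = len(m.sample_ids)
    L = m.values.loc[lnc_ids].to_numpy(dtype=float)
    R = m.values.loc[mrna_ids].to_numpy(dtype=float)

    def _standardize(a: np.ndarray, ids: list[str]):
        sd = a.std(axis=1, ddof=1)
        ok = sd > 0
        for pid in np.asarray(ids)[~ok]:
            log.warning("probe %s has zero variance; skipped", pid)
        z = (a[ok] - a[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        return z, [i for i, keep in zip(ids, ok) if keep]

    Zl, lnc_kept = _standardize(L, lnc_ids)
    Zr, mrna_kept = _standardize(R, mrna_ids)
    if not lnc_kept or not mrna_kept:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    corr = (Zl @ Zr.T) / (n - 1)
    corr = np.clip(corr, -1.0, 1.0)
    ii, jj = np.nonzero(np.abs(corr) > threshold)
    edges = pd.DataFrame(
        {
            "lnc_id": [lnc_kept[i] for i in ii],
            "mrna_id": [mrna_kept[j] for j in jj],
            "r": corr[ii, jj],
            "n_samples": n,
        },
        columns=EDGE_COLUMNS,
    )
    return edges.sort_values(["lnc_id", "mrna_id"], kind="stable").reset_index(drop=True)


def node_table(edges: pd.DataFrame) -> pd.DataFrame:
    """Node table (id, type, degree) for the bipartite network."""
    lnc = edges["lnc_id"].value_counts()
    mrna = edges["mrna_id"].value_counts()
    rows = [
        {"node_id": nid, "node_type": "lncRNA", "degree": int(d)}
        for nid, d in sorted(lnc.items())
    ] + [
        {"node_id": nid, "node_type": "mRNA", "degree": int(d)}
        for nid, d in sorted(mrna.items())
    ]
    return pd.DataFrame(rows, columns=["node_id", "node_type", "degree"])


def edges_for_pathway_genes(
    edges: pd.DataFrame,
    gene_set: set[str],
    symbol_of: dict[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Sub-network of edges whose mRNA maps into ``gene_set``.

    ``symbol_of`` maps mRNA probe ids to gene symbols. Returns the edge
    subset and the induced, deduplicated lncRNA list.
    """
    keep = edges["mrna_id"].map(lambda p: symbol_of.get(p) in gene_set)
    sub = edges[keep.to_numpy(dtype=bool)] if len(edges) else edges
    lncs = sorted(sub["lnc_id"].unique()) if len(sub) else []
    return sub.reset_index(drop=True), lncs


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Export the bipartite network for external viewers."""
    g = nx.Graph()
    for row in edges.itertuples():
        g.add_node(row.lnc_id, node_type="lncRNA")
        g.add_node(row.mrna_id, node_type="mRNA")
        g.add_edge(row.lnc_id, row.mrna_id, r=float(row.r))
    nx.write_graphml(g, path)
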