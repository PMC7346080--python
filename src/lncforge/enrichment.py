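"""Gene-set (KEGG-style pathway) enrichment by two-sided Fisher's exact test.

The 2x2 table for a gene list against a set within a universe is

    [[in-set & in-list,   in-set & not-list],
     [not-set & in-list,  not-set & not-list]]

with the two-sided p summing all fixed-margin tables whose point
probability does not exceed the observed one. Enrichment score = -log10 p.
Significance is called at raw p < 0.05; no correction across pathways by
default (BH available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_id", "name", "n_overlap", "n_list", "n_set", "n_universe",
    "p", "enrichment_score", "direction", "significant", "overlap_genes",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read GMT (set id, description, genes...) one set per line."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def fisher_enrichment(
    gene_list: set[str],
    gs: GeneSet,
    universe: set[str],
    direction: str = "up",
    alpha: float = 0.05,
) -> dict:
    """Two-sided Fisher's exact test of ``gene_list`` against one gene set.

    The set is intersected with the universe before testing; the list must
    be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = set(gene_list) - set(universe)
    if stray:
        raise ValueError(f"gene list not within universe: {sorted(stray)[:5]}")
    set_in_universe = set(gs.genes) & set(universe)
    overlap = set(gene_list) & set_in_universe
    a = len(overlap)
    b = len(set_in_universe) - a
    c = len(gene_list) - a
    d = len(universe) - len(set_in_universe) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p = float(p)
    return {
        "set_id": gs.set_id,
        "name": gs.name,
        "n_overlap": a,
        "n_list": len(gene_list),
        "n_set": len(set_in_universe),
        "n_universe": len(universe),
        "p": p,
        "enrichment_score": float(-np.log10(p)) if p > 0 else float("inf"),
        "direction": direction,
        "significant": p < alpha,
        "overlap_genes": ",".join(sorted(overlap)),
    }


def enrich_gene_list(
    gene_list: set[str],
    sets: list[GeneSet],
    universe: set[str],
    direction: str = "up",
    alpha: float = 0.05,
    correct: bool = False,
) -> pd.DataFrame:
    """Enrichment of one gene list against all sets, ranked by score."""
    rows = [fisher_enrichment(gene_list, s, universe, direction, alpha) for s in sets]
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if correct and len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
    out = out.sort_values(
        ["enrichment_score", "set_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


def directional_enrichment(
    de: pd.DataFrame,
    sets: list[GeneSet],
    universe: set[str],
    alpha: float = 0.05,
    correct: bool = False,
) -> dict[str, pd.DataFrame]:
    """Separate enrichment of up- and down-regulated significant genes.

    ``de`` is a differential-expression table with ``symbol``,
    ``direction`` and ``significant`` columns; gene symbols are
    deduplicated per direction. Returns {"up": table, "down": table},
    each sorted by enrichment score descending.
    """
    out: dict[str, pd.DataFrame] = {}
    sig = de[de["significant"]]
    for direction in ("up", "down"):
        genes = set(sig.loc[sig["direction"] == direction, "symbol"]) & set(universe)
        if not genes:
            log.info("no significant %s-regulated genes; empty enrichment", direction)
            out[direction] = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
            continue
        out[direction] = enrich_gene_list(
            genes, sets, universe, direction, alpha, correct
        )
    return out
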