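"""Two-group differential expression.

Fold change on the linear scale from log2 group means, a two-tailed
Student's t-test (pooled variance by default, Welch by flag), and
Benjamini-Hochberg step-up q-values. A probe is called significant when
fold change >= 2, p < 0.05 and q < 0.05 simultaneously. BH is applied
within the lncRNA and mRNA probe families separately by default, since the
two families are analysed as parallel experiments; a joint mode exists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .matrix import GROUP1, GROUP2, ExpressionMatrix

log = logging.getLogger(__name__)

DE_COLUMNS = [
    "probe_id", "symbol", "probe_type", "mean_g1", "mean_g2",
    "log2fc", "fold_change", "direction", "p", "q", "significant",
]


@dataclass(frozen=True)
class DECriteria:
    """Significance thresholds: FC >= fc, p < p, q < fdr (all must hold)."""

    fc: float = 2.0
    p: float = 0.05
    fdr: float = 0.05
    variant: str = "pooled"          # or "welch"
    fdr_scope: str = "per_family"    # or "joint"

    def __post_init__(self) -> None:
        if self.fc < 1 or not (0 < self.p <= 1) or not (0 < self.fdr <= 1):
            raise ValueError("invalid DE criteria")
        if self.variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test variant {self.variant!r}")
        if self.fdr_scope not in ("per_family", "joint"):
            raise ValueError(f"unknown fdr scope {self.fdr_scope!r}")


def student_t(values_g1, values_g2, variant: str = "pooled"):
    """Two-sided two-sample t-test; returns (t, df, p).

    Zero variance in both groups is degenerate: equal means give p = 1,
    unequal means give p = 0 (logged as degenerate).
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        log.warning("zero variance in both groups with unequal means; p set to 0")
        return np.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def summary_t(mean1, sd1, n1, mean2, sd2, n2, variant: str = "pooled"):
    """Two-sided t-test from group summaries (mean, SD, n); returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or not np.isfinite([mean1, mean2, sd1, sd2]).all():
        raise ValueError("invalid summary statistics")
    if sd1 == 0 and sd2 == 0:
        df = float(n1 + n2 - 2)
        return (0.0, df, 1.0) if mean1 == mean2 else (np.inf, df, 0.0)
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(p)


def fold_change(mean_g1: float, mean_g2: float):
    """Linear fold change and direction from two log2 group means.

    fold_change = 2**|mean_g2 - mean_g1| (>= 1). Direction is ``up`` when
    the comparison-group mean exceeds the baseline (group1) mean, ``down``
    otherwise; an exact tie is reported as ``up`` with a warning.
    """
    if not np.isfinite([mean_g1, mean_g2]).all():
        raise ValueError("means must be finite")
    d = mean_g2 - mean_g1
    if d == 0:
        warnings.warn("equal group means: fold change 1, direction tie -> 'up'")
        return 1.0, "up"
    return float(2.0 ** abs(d)), ("up" if d > 0 else "down")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    m: ExpressionMatrix,
    probe_annotation: pd.DataFrame,
    criteria: DECriteria | None = None,
) -> pd.DataFrame:
    """Per-probe differential expression table for a filtered, normalized matrix.

    ``probe_annotation`` must carry ``probe_id``, ``probe_type``
    (``lncRNA``/``mRNA``) and ``symbol`` columns. Returns one row per probe
    in matrix order with the columns of :data:`DE_COLUMNS`.
    """
    criteria = criteria or DECriteria()
    ann = probe_annotation.set_index("probe_id")
    unknown = m.probe_ids.difference(ann.index)
    if len(unknown):
        raise ValueError(f"probes missing annotation: {list(unknown[:5])}")
    g1 = m.samples_in(GROUP1)
    g2 = m.samples_in(GROUP2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")

    x = m.values[g1].to_numpy(dtype=float)
    y = m.values[g2].to_numpy(dtype=float)
    mean1, mean2 = x.mean(axis=1), y.mean(axis=1)
    log2fc = mean2 - mean1
    fc = 2.0 ** np.abs(log2fc)
    direction = np.where(log2fc < 0, "down", "up")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            x, y, axis=1, equal_var=(criteria.variant == "pooled")
        )
        p = np.asarray(res.pvalue, dtype=float)
    degen = (x.var(axis=1, ddof=1) == 0) & (y.var(axis=1, ddof=1) == 0)
    if degen.any():
        p = p.copy()
        p[degen & (mean1 == mean2)] = 1.0
        p[degen & (mean1 != mean2)] = 0.0
        log.warning("%d probes with zero variance in both groups", int(degen.sum()))

    out = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "symbol": ann.loc[m.probe_ids, "symbol"].to_numpy(),
            "probe_type": ann.loc[m.probe_ids, "probe_type"].to_numpy(),
            "mean_g1": mean1,
            "mean_g2": mean2,
            "log2fc": log2fc,
            "fold_change": fc,
            "direction": direction,
        }
    ).reset_index(drop=True)
    out["p"] = p
    out["q"] = np.nan
    if criteria.fdr_scope == "joint":
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        for _, idx in out.groupby("probe_type").groups.items():
            out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["significant"] = (
        (out["fold_change"] >= criteria.fc)
        & (out["p"] < criteria.p)
        & (out["q"] < criteria.fdr)
    )
    return out[DE_COLUMNS]


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change vs -log10 p, for volcano plots."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(de["p"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"probe_id": de["probe_id"], "log2fc": de["log2fc"],
         "neg_log10_p": neglog, "significant": de["significant"]}
    )


def cluster_order(values: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Average-linkage hierarchical clustering order on 1 - Pearson distance.

    Returns (row order, column order) of probe and sample ids for heatmap
    export. Presentation support only.
    """
    def _order(mat: np.ndarray, labels) -> list[str]:
        if mat.shape[0] < 3:
            return list(labels)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        link = hierarchy.average(squareform(dist, checks=False))
        leaves = hierarchy.leaves_list(link)
        return [labels[i] for i in leaves]

    v = values.to_numpy(dtype=float)
    rows = _order(v, list(values.index))
    cols = _order(v.T, list(values.columns))
    return rows, cols
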