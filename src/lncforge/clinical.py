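"""Cohort statistics and qPCR relative quantification.

Kaplan-Meier product-limit survival curves and the two-sided log-rank
test compare the two patient groups; Pearson's chi-square (no continuity
correction) compares sex proportions; the 2^-ddCt method converts qPCR
cycle thresholds into relative expression against a reference gene
(GAPDH) and a reference group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .matrix import GROUP1

log = logging.getLogger(__name__)


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "time", "event", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def km_curve(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Product-limit survival estimate S(t) for one group.

    Returns a step-function table (time, n_at_risk, survival) with one row
    per distinct event time; S changes only at event times.
    """
    sub = records[records["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no records in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    return pd.DataFrame({
        "time": ev.index.to_numpy(dtype=float),
        "n_at_risk": ev["at_risk"].to_numpy(dtype=int),
        "survival": kmf.survival_function_at_times(ev.index).to_numpy(dtype=float),
    })


def logrank(records: pd.DataFrame) -> tuple[float, float]:
    """Two-sided log-rank test between the two groups: (chi_square, p)."""
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    if records["event"].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    a = records[records["group"] == groups[0]]
    b = records[records["group"] == groups[1]]
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "group", "target_gene", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def ddct(records: pd.DataFrame, reference_group: str = GROUP1) -> pd.DataFrame:
    """Per-sample 2^-ddCt relative expression.

    dCt = ct_target - ct_reference per sample; ddCt subtracts the mean dCt
    of the reference group for that target gene; relative expression is
    2^-ddCt (1.0 at the reference-group mean). Samples missing a reference
    Ct are dropped with a warning.
    """
    rec = records.copy()
    missing = rec["ct_reference"].isna() | rec["ct_target"].isna()
    if missing.any():
        log.warning("dropping %d samples without complete Ct values",
                    int(missing.sum()))
        rec = rec[~missing]
    rec["dct"] = rec["ct_target"] - rec["ct_reference"]
    out = []
    for gene, grp in rec.groupby("target_gene"):
        ref = grp.loc[grp["group"] == reference_group, "dct"]
        if len(ref) == 0:
            raise ValueError(f"no reference-group samples for {gene}")
        base = ref.mean()
        g = grp.copy()
        g["ddct"] = g["dct"] - base
        g["rel_expr"] = 2.0 ** (-g["ddct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


def ddct_group_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group mean and standard error of relative expression per target gene."""
    rows = []
    for (gene, group), grp in per_sample.groupby(["target_gene", "group"]):
        vals = grp["rel_expr"].to_numpy(dtype=float)
        rows.append({
            "target_gene": gene, "group": group, "n": len(vals),
            "mean_rel_expr": float(vals.mean()),
            "se_rel_expr": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else float("nan"),
        })
    return pd.DataFrame(rows)
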