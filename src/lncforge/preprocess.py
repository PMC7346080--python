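"""Detection-flag filtering and quantile normalization.

Probes are kept when they are flagged Present or Marginal in at least
``min_flagged_samples`` samples (default 6, mirroring a 6-vs-6 two-group
design where a probe must be detected in at least half the arrays).
Quantile normalization forces every sample onto a common reference
distribution: the reference value at rank k is the across-sample mean of
each sample's k-th smallest intensity; ties within a sample receive the
mean of the reference values at their tied ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import VALID_FLAGS, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterPolicy:
    """Detection-call retention rule."""

    min_flagged_samples: int = 6
    acceptable_flags: frozenset[str] = field(
        default=frozenset({"Present", "Marginal"})
    )

    def __post_init__(self) -> None:
        if self.min_flagged_samples <= 0:
            raise ValueError("min_flagged_samples must be positive")
        bad = set(self.acceptable_flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags in policy: {sorted(bad)}")


def filter_by_flags(m: ExpressionMatrix, policy: FilterPolicy | None = None) -> ExpressionMatrix:
    """Retain probes with >= ``min_flagged_samples`` acceptable detection flags.

    Row order is preserved. An empty result is allowed (logged, not raised).
    """
    policy = policy or FilterPolicy()
    if m.flags is None:
        raise ValueError("matrix has no detection flags to filter on")
    if policy.min_flagged_samples > len(m.sample_ids):
        raise ValueError(
            f"min_flagged_samples={policy.min_flagged_samples} exceeds "
            f"sample count {len(m.sample_ids)}"
        )
    ok = m.flags.isin(policy.acceptable_flags).sum(axis=1) >= policy.min_flagged_samples
    kept = m.probe_ids[ok.to_numpy()]
    if len(kept) == 0:
        log.warning("flag filter removed every probe")
    return m.subset(kept)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so all samples share one distribution.

    Each column's sorted values become the across-column mean of sorted
    values; within-column rank order is preserved and tied entries receive
    the mean of the reference values over their tied ranks.
    """
    v = m.values.to_numpy(dtype=float)
    if v.shape[0] < 1 or v.shape[1] < 2:
        raise ValueError("need at least 1 probe and 2 samples")
    if not np.isfinite(v).all():
        raise ValueError("missing or non-finite values; imputation is out of scope")
    ref = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the reference over tied ranks
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, groups=m.groups, flags=m.flags)
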