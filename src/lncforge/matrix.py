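"""Probe-by-sample expression container with detection flags and group labels.

The matrix holds log2 intensities. Detection flags take the values
``Present``, ``Marginal`` or ``Absent`` (one flag per probe and sample), the
per-sample group label is ``group1`` (baseline, e.g. no dural penetration)
or ``group2`` (comparison group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_FLAGS = frozenset({"Present", "Marginal", "Absent"})
GROUP1 = "group1"
GROUP2 = "group2"


@dataclass
class ExpressionMatrix:
    """Log2 intensities (probes x samples) plus flags and group labels.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = probe ids, columns = sample ids.
    groups
        Series mapping sample id -> group label (``group1``/``group2``).
    flags
        Optional DataFrame of detection flags with the same shape as
        ``values``. ``None`` means flags are unavailable (e.g. after
        normalization they are no longer needed).
    """

    values: pd.DataFrame
    groups: pd.Series
    flags: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dup[:5]}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.reindex(self.values.columns)
        bad = set(self.groups.unique()) - {GROUP1, GROUP2}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("values and flags must share shape")
            self.flags = self.flags.reindex(
                index=self.values.index, columns=self.values.columns
            )
            bad_flags = set(np.unique(self.flags.to_numpy())) - VALID_FLAGS
            if bad_flags:
                raise ValueError(f"unknown detection flags: {sorted(bad_flags)}")

    # -- convenience -------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset(self, probe_ids) -> "ExpressionMatrix":
        """Row subset preserving order of ``probe_ids``."""
        values = self.values.loc[probe_ids]
        flags = self.flags.loc[probe_ids] if self.flags is not None else None
        return ExpressionMatrix(values=values, groups=self.groups, flags=flags)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, matrix_path, flags_path=None, samples_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id",
                           float_format="%.10g")
        if flags_path is not None and self.flags is not None:
            self.flags.to_csv(flags_path, sep="\t", index_label="probe_id")
        if samples_path is not None:
            self.groups.rename("group").to_csv(
                samples_path, sep="\t", index_label="sample_id"
            )

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, flags_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
        groups = pd.read_csv(samples_path, sep="\t", index_col="sample_id")["group"]
        flags = None
        if flags_path is not None and Path(flags_path).exists():
            flags = pd.read_csv(flags_path, sep="\t", index_col="probe_id")
        return cls(values=values, groups=groups, flags=flags)
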