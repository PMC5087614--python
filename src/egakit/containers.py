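"""In-memory containers shared across the pipeline: the spike-in tag matrix
and the sample sheet describing the FACS-sorted overexpression wells."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: row-id prefix that flags spike-in rows in count matrices (overridable)
SPIKE_PREFIX = "SPIKE_"

GFP_POSITIVE = "positive"
GFP_NEGATIVE = "negative"


class NormalizationError(ValueError):
    """Raised when spike-in normalization is impossible (e.g. a zero spike total)."""


class DesignError(ValueError):
    """Raised when a comparison design cannot be built from the sample sheet."""


@dataclass
class SpikeTagMatrix:
    """Non-negative integer tag counts: TFE rows + spike-in rows x sample columns.

    ``counts`` is a pandas DataFrame indexed by row id with sample-id columns.
    Rows whose id starts with ``spike_prefix`` are exogenous spike-ins of known
    concentration, used to estimate per-sample sequencing depth independently
    of endogenous expression.
    """

    counts: pd.DataFrame
    spike_prefix: str = SPIKE_PREFIX

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate row ids")
        if self.spike_mask.sum() < 1:
            raise ValueError(f"no spike-in rows (prefix {self.spike_prefix!r})")

    @property
    def spike_mask(self) -> np.ndarray:
        return np.asarray(self.counts.index.str.startswith(self.spike_prefix))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tfe_ids(self) -> list[str]:
        return list(self.counts.index[~self.spike_mask])

    def spike_totals(self) -> pd.Series:
        """Per-sample total spike-in tags (the depth proxy)."""
        return self.counts.loc[self.spike_mask].sum(axis=0)

    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[~self.spike_mask]

    def subset_samples(self, sample_ids) -> "SpikeTagMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return SpikeTagMatrix(self.counts[list(sample_ids)].copy(), self.spike_prefix)


@dataclass
class SampleSheet:
    """Sample metadata: one row per well of an STRT library.

    Columns: sample_id, construct, gfp_status (positive/negative), replicate,
    cells_per_well.  Exactly one construct is the fluorescent control
    (the mCherry-only transfection in the emulated design).
    """

    table: pd.DataFrame
    fluorescent_control: str = "mCherry"
    _required: tuple = field(
        default=("sample_id", "construct", "gfp_status", "replicate", "cells_per_well"),
        repr=False,
    )

    def __post_init__(self) -> None:
        missing = [c for c in self._required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sheet")
        bad = set(self.table["gfp_status"]) - {GFP_POSITIVE, GFP_NEGATIVE}
        if bad:
            raise ValueError(f"invalid gfp_status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def constructs(self) -> list[str]:
        return sorted(self.table["construct"].unique())

    def select(self, construct: str | None = None, gfp: str | None = None) -> list[str]:
        """Sample ids matching a construct and/or GFP status filter."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if construct is not None:
            mask &= t["construct"] == construct
        if gfp is not None:
            mask &= t["gfp_status"] == gfp
        return list(t.loc[mask, "sample_id"])

    def validate_against(self, matrix: SpikeTagMatrix) -> None:
        if set(self.sample_ids) != set(matrix.samples):
            raise ValueError("sample sheet ids do not match count-matrix columns")
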