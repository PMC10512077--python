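"""Core in-memory containers for segmented spatial-profiling data.

The unit of observation is the ROI (region of interest): a segmented patch of
one arterial layer from one patient, whose transcripts are barcoded and
counted together. Counts are deduplicated (unique-molecule) target counts;
negative probes carry no genomic target and measure background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STATUSES = ("GCA", "control")
REQUIRED_META_COLUMNS = ("patient", "status", "layer", "sex")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class CountMatrix:
    """ROI-by-target deduplicated counts with per-target negative-probe flags.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = targets, columns = ROIs.
    is_negprobe
        Boolean Series indexed like ``counts.index``; True for negative
        control probes.
    """

    counts: pd.DataFrame
    is_negprobe: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate target ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate ROI ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("counts must be finite")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        self.is_negprobe = self.is_negprobe.reindex(self.counts.index)
        if self.is_negprobe.isna().any():
            raise ValidationError("is_negprobe must cover every target")
        self.is_negprobe = self.is_negprobe.astype(bool)
        if not self.is_negprobe.any():
            raise ValidationError("at least one negative probe is required")

    @property
    def targets(self) -> pd.Index:
        return self.counts.index

    @property
    def rois(self) -> pd.Index:
        return self.counts.columns

    @property
    def gene_counts(self) -> pd.DataFrame:
        """Counts restricted to non-negprobe (gene) targets."""
        return self.counts.loc[~self.is_negprobe]

    @property
    def negprobe_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.is_negprobe]

    def subset(self, targets=None, rois=None) -> "CountMatrix":
        counts = self.counts
        if targets is not None:
            counts = counts.loc[list(targets)]
        if rois is not None:
            counts = counts[list(rois)]
        return CountMatrix(counts, self.is_negprobe.loc[counts.index])


def validate_roi_meta(meta: pd.DataFrame, rois=None) -> pd.DataFrame:
    """Validate per-ROI annotations (patient, status, layer, sex).

    Index must be ROI ids; ``raw_reads`` is an optional column used by the
    raw-read QC gate.
    """
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"ROI metadata missing columns: {missing}")
    if meta.index.duplicated().any():
        raise ValidationError("duplicate ROI ids in metadata")
    bad = set(meta["status"]) - set(VALID_STATUSES)
    if bad:
        raise ValidationError(f"unknown status values: {sorted(bad)}")
    if rois is not None:
        absent = [r for r in rois if r not in meta.index]
        if absent:
            raise ValidationError(f"ROIs without metadata: {absent[:5]}")
    return meta
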