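"""Segment-level QC, negative-probe limit of quantification, target filtering.

Each ROI's limit of quantification (LOQ) is derived from its negative probes:

    LOQ = geomean(NegProbe) * geoSD(NegProbe)^2

with the geometric SD computed from the sample (n-1) standard deviation of
natural-log counts. ROIs are excluded when their upper-quartile deduplicated
count falls below ``q3_min`` (default 2), when fewer than ``frac_min``
(default 1%) of their genes exceed the LOQ, or — when raw read totals are
supplied — when raw reads fall below ``raw_reads_min``. Targets are then
retained only if they exceed the LOQ in at least ``min_roi_frac`` (default
10%) of the retained ROIs; negative probes are always dropped from the
retained gene list.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

REASON_LOW_Q3 = "low_q3"
REASON_LOW_DETECTION = "low_detection"
REASON_LOW_RAW_READS = "low_raw_reads"


def compute_loq(matrix: CountMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-ROI LOQ table: columns neg_geomean, neg_geosd, loq.

    Geometric statistics are taken over natural logs of negative-probe counts
    plus ``pseudocount``; every shifted count must be strictly positive.
    """
    neg = matrix.negprobe_counts
    if neg.shape[0] < 2:
        raise ValueError("compute_loq needs at least 2 negative probes per ROI")
    shifted = neg.to_numpy(dtype=float) + pseudocount
    if (shifted <= 0).any():
        raise ValueError(
            "negative-probe count + pseudocount must be > 0 for geometric stats; "
            "raise the pseudocount")
    logs = np.log(shifted)
    geomean = np.exp(logs.mean(axis=0))
    geosd = np.exp(logs.std(axis=0, ddof=1))
    loq = geomean * geosd**2
    return pd.DataFrame(
        {"neg_geomean": geomean, "neg_geosd": geosd, "loq": loq}, index=matrix.rois
    )


def segment_qc(
    matrix: CountMatrix,
    loq: pd.DataFrame,
    q3_min: float = 2.0,
    frac_min: float = 0.01,
    raw_reads_min: float = 1e6,
    raw_reads: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-ROI QC report; an ROI is excluded iff at least one gate fails.

    Q3 and the detection fraction are computed over non-negprobe targets;
    "above LOQ" is strict (>). The raw-read gate applies only when raw read
    totals are supplied. Boundary semantics follow the stated thresholds:
    exclusion is strict <, so an ROI at exactly 1% detection is retained.
    """
    missing = [r for r in matrix.rois if r not in loq.index]
    if missing:
        raise ValueError(f"LOQ missing for ROIs: {missing[:5]}")
    genes = matrix.gene_counts
    q3 = genes.quantile(0.75, axis=0, interpolation="linear")
    above = genes.gt(loq.loc[matrix.rois, "loq"], axis=1)
    frac_above = above.mean(axis=0)

    report = pd.DataFrame(
        {"q3_dedup": q3, "frac_above_loq": frac_above}, index=matrix.rois
    )
    reasons: List[List[str]] = [[] for _ in matrix.rois]
    for i, roi in enumerate(matrix.rois):
        if q3[roi] < q3_min:
            reasons[i].append(REASON_LOW_Q3)
        if frac_above[roi] < frac_min:
            reasons[i].append(REASON_LOW_DETECTION)
        if raw_reads is not None and roi in raw_reads.index and raw_reads[roi] < raw_reads_min:
            reasons[i].append(REASON_LOW_RAW_READS)
    if raw_reads is not None:
        report["raw_reads"] = raw_reads.reindex(matrix.rois)
    report["excluded"] = [len(r) > 0 for r in reasons]
    report["exclusion_reasons"] = [";".join(r) for r in reasons]
    return report


def retained_rois(qc_report: pd.DataFrame) -> List[str]:
    return list(qc_report.index[~qc_report["excluded"]])


def filter_targets(
    matrix: CountMatrix,
    loq: pd.DataFrame,
    qc_report: pd.DataFrame,
    min_roi_frac: float = 0.10,
) -> List[str]:
    """Gene targets above LOQ in at least ``min_roi_frac`` of retained ROIs.

    Fractions use the QC-retained ROIs only; retention is >= (``at least``);
    negative probes never appear in the retained list.
    """
    rois = retained_rois(qc_report)
    if not rois:
        raise ValueError("no ROIs retained by QC; cannot filter targets")
    genes = matrix.gene_counts[rois]
    above = genes.gt(loq.loc[rois, "loq"], axis=1)
    frac = above.sum(axis=1) / len(rois)
    return list(frac.index[frac >= min_roi_frac])


def apply_qc(
    matrix: CountMatrix,
    loq: pd.DataFrame,
    qc_report: pd.DataFrame,
    targets: Sequence[str],
) -> CountMatrix:
    """Submatrix of retained targets x retained ROIs (negprobes kept apart).

    The returned matrix keeps the negative probes so that LOQ statistics can
    be recomputed downstream if needed.
    """
    keep = list(targets) + list(matrix.targets[matrix.is_negprobe])
    return matrix.subset(targets=keep, rois=retained_rois(qc_report))
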