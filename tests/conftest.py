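import numpy as np
import pandas as pd
import pytest

from arteryscope import CohortConfig, CountMatrix, apply_qc, compute_loq, filter_targets
from arteryscope import generate_cohort, q3_normalize, segment_qc

SMALL_DE_SPEC = {
    "intima": [(30, 2.0)],
    "media": [(20, 2.0)],
    "adventitia": [(5, 2.0)],
    "PVAT": [(1, 2.0)],
}


def make_matrix(gene_counts: dict, negprobe_counts: dict, rois=None) -> CountMatrix:
    """Hand-built CountMatrix from {target: [counts per ROI]} dicts."""
    data = {**gene_counts, **negprobe_counts}
    n_rois = len(next(iter(data.values())))
    rois = rois or [f"ROI{i+1}" for i in range(n_rois)]
    counts = pd.DataFrame.from_dict(data, orient="index", columns=rois)
    flags = pd.Series(
        {t: t in negprobe_counts for t in counts.index}, index=counts.index
    )
    return CountMatrix(counts, flags)


def qc_and_normalize(matrix, meta, loq_pseudocount=1.0):
    """Run the standard QC -> filter -> Q3 chain, returning (normalized, meta)."""
    loq = compute_loq(matrix, pseudocount=loq_pseudocount)
    report = segment_qc(matrix, loq)
    targets = filter_targets(matrix, loq, report)
    filtered = apply_qc(matrix, loq, report, targets)
    normalized, _ = q3_normalize(filtered.gene_counts)
    return normalized, meta.loc[list(normalized.columns)]


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-size synthetic cohort with a graded DE burden (seeded)."""
    cfg = CohortConfig(n_targets=300, n_neg_probes=20, de_spec=SMALL_DE_SPEC, seed=1)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230906)
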