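"""LOQ computation, segment QC gates and target filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arteryscope import compute_loq, filter_targets, segment_qc
from arteryscope.qc import REASON_LOW_DETECTION, REASON_LOW_Q3, REASON_LOW_RAW_READS

from conftest import make_matrix


def loq_log_oracle(x: np.ndarray) -> float:
    """Independent log-domain evaluation: exp(mean(ln x) + 2 sd(ln x))."""
    logs = np.log(x)
    return float(np.exp(logs.mean() + 2.0 * logs.std(ddof=1)))


def test_loq_equal_negprobes_gives_geosd_one():
    m = make_matrix({"G1": [5, 5]}, {"N1": [10, 10], "N2": [10, 10], "N3": [10, 10]})
    loq = compute_loq(m, pseudocount=0.0)
    assert loq["neg_geomean"].tolist() == pytest.approx([10, 10])
    assert loq["neg_geosd"].tolist() == pytest.approx([1, 1])
    assert loq["loq"].tolist() == pytest.approx([10, 10])


def test_loq_worked_case_1_4_16():
    """negprobes {1,4,16}: geomean 4, geoSD 4, LOQ 4*4^2 = 64."""
    m = make_matrix({"G1": [5]}, {"N1": [1], "N2": [4], "N3": [16]})
    loq = compute_loq(m, pseudocount=0.0)
    assert loq.loc["ROI1", "neg_geomean"] == pytest.approx(4.0)
    assert loq.loc["ROI1", "neg_geosd"] == pytest.approx(4.0)
    assert loq.loc["ROI1", "loq"] == pytest.approx(64.0)
    assert loq.loc["ROI1", "loq"] == pytest.approx(loq_log_oracle(np.array([1.0, 4, 16])))


def test_loq_zero_count_without_pseudocount_errors():
    m = make_matrix({"G1": [5]}, {"N1": [0], "N2": [4]})
    with pytest.raises(ValueError, match="pseudocount"):
        compute_loq(m, pseudocount=0.0)
    loq = compute_loq(m, pseudocount=1.0)  # shifted counts {1,5} are fine
    assert loq.loc["ROI1", "loq"] > 0


def test_loq_needs_two_negprobes():
    m = make_matrix({"G1": [5]}, {"N1": [4]})
    with pytest.raises(ValueError, match="negative probes"):
        compute_loq(m)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(min_value=0.5, max_value=1e4), min_size=2, max_size=30),
    st.floats(min_value=0.25, max_value=8.0),
)
def test_loq_log_domain_oracle_and_scale_equivariance(values, c):
    x = np.asarray(values)
    m = make_matrix({"G1": [1.0]}, {f"N{i}": [v] for i, v in enumerate(x)})
    loq = compute_loq(m, pseudocount=0.0)["loq"].iloc[0]
    assert loq == pytest.approx(loq_log_oracle(x), rel=1e-9)
    # scaling every negprobe by c scales the LOQ by c
    m2 = make_matrix({"G1": [1.0]}, {f"N{i}": [v * c] for i, v in enumerate(x)})
    loq2 = compute_loq(m2, pseudocount=0.0)["loq"].iloc[0]
    assert loq2 == pytest.approx(c * loq, rel=1e-9)


def test_loq_geomean_monotone_in_any_count():
    base = np.array([4.0, 8.0, 16.0])
    m1 = make_matrix({"G1": [1.0]}, {f"N{i}": [v] for i, v in enumerate(base)})
    g1 = compute_loq(m1, pseudocount=0.0)["neg_geomean"].iloc[0]
    bumped = base.copy()
    bumped[2] = 32.0
    m2 = make_matrix({"G1": [1.0]}, {f"N{i}": [v] for i, v in enumerate(bumped)})
    g2 = compute_loq(m2, pseudocount=0.0)["neg_geomean"].iloc[0]
    assert g2 > g1


def _qc_fixture(gene_rows, negprobe_value=10):
    """Matrix whose negprobes are constant, so LOQ = negprobe_value exactly."""
    negs = {f"N{i}": [negprobe_value] * len(next(iter(gene_rows.values())))
            for i in range(3)}
    return make_matrix(gene_rows, negs)


def test_roi_with_all_ones_excluded_for_low_q3():
    m = _qc_fixture({f"G{i}": [1, 50] for i in range(20)})
    loq = compute_loq(m)
    report = segment_qc(m, loq)
    assert bool(report.loc["ROI1", "excluded"])
    assert REASON_LOW_Q3 in report.loc["ROI1", "exclusion_reasons"]
    assert not report.loc["ROI2", "excluded"]


def test_roi_with_zero_detection_excluded():
    genes = {f"G{i:04d}": [5, 50] for i in range(1000)}  # 5 < LOQ=10 everywhere
    m = _qc_fixture(genes)
    report = segment_qc(m, compute_loq(m))
    assert report.loc["ROI1", "frac_above_loq"] == 0.0
    assert REASON_LOW_DETECTION in report.loc["ROI1", "exclusion_reasons"]


def test_detection_fraction_exactly_one_percent_is_retained():
    """Exclusion is strict <, so 10 of 1000 genes above LOQ (=1%) passes."""
    genes = {f"G{i:04d}": [11 if i < 10 else 5, 50] for i in range(1000)}
    m = _qc_fixture(genes)
    report = segment_qc(m, compute_loq(m))
    assert report.loc["ROI1", "frac_above_loq"] == pytest.approx(0.01)
    assert not report.loc["ROI1", "excluded"]


def test_raw_reads_gate_only_when_supplied():
    m = _qc_fixture({f"G{i}": [50, 50] for i in range(20)})
    loq = compute_loq(m)
    assert not segment_qc(m, loq)["excluded"].any()
    raw = pd.Series({"ROI1": 5e5, "ROI2": 2e6})
    report = segment_qc(m, loq, raw_reads=raw)
    assert bool(report.loc["ROI1", "excluded"])
    assert REASON_LOW_RAW_READS in report.loc["ROI1", "exclusion_reasons"]
    assert not report.loc["ROI2", "excluded"]


def _detection_matrix(n_rois, n_above):
    """One gene above LOQ (=10) in n_above of n_rois ROIs, plus an anchor gene."""
    target = [20 if i < n_above else 5 for i in range(n_rois)]
    anchor = [20] * n_rois  # keeps every ROI's Q3 and detection healthy
    genes = {"GTEST": target}
    for j in range(8):
        genes[f"GA{j}"] = anchor
    return _qc_fixture(genes)


@pytest.mark.parametrize("n_above,kept", [(6, True), (5, False)])
def test_target_filter_boundary_at_ten_percent_of_59_rois(n_above, kept):
    """6/59 = 10.17% >= 10% retained; 5/59 = 8.47% dropped."""
    m = _detection_matrix(59, n_above)
    loq = compute_loq(m)
    report = segment_qc(m, loq)
    assert not report["excluded"].any()
    retained = filter_targets(m, loq, report, min_roi_frac=0.10)
    assert ("GTEST" in retained) is kept
    assert "GA0" in retained


def test_target_above_loq_everywhere_is_retained_and_negprobes_never():
    m = _detection_matrix(10, 10)
    loq = compute_loq(m)
    report = segment_qc(m, loq)
    retained = filter_targets(m, loq, report)
    assert "GTEST" in retained
    assert not any(t.startswith("N") for t in retained)


def test_filter_errors_when_no_roi_retained():
    genes = {f"G{i:03d}": [1] for i in range(100)}
    m = _qc_fixture(genes)
    loq = compute_loq(m)
    report = segment_qc(m, loq)
    assert report["excluded"].all()
    with pytest.raises(ValueError, match="no ROIs retained"):
        filter_targets(m, loq, report)


def test_qc_idempotent_on_retained_submatrix(small_cohort):
    from arteryscope import apply_qc

    matrix, _, _ = small_cohort
    loq = compute_loq(matrix, pseudocount=1.0)
    report = segment_qc(matrix, loq)
    targets = filter_targets(matrix, loq, report)
    filtered = apply_qc(matrix, loq, report, targets)

    loq2 = compute_loq(filtered, pseudocount=1.0)
    report2 = segment_qc(filtered, loq2)
    assert not report2["excluded"].any()
    targets2 = filter_targets(filtered, loq2, report2)
    assert set(targets2) == set(targets)


def test_background_targets_filtered_at_higher_rate(small_cohort):
    matrix, _, truth = small_cohort
    loq = compute_loq(matrix, pseudocount=1.0)
    report = segment_qc(matrix, loq)
    retained = set(filter_targets(matrix, loq, report))
    bg = set(truth.loc[truth["is_background_only"], "target"])
    expressed = set(truth["target"]) - bg
    bg_drop = len(bg - retained) / len(bg)
    expr_drop = len(expressed - retained) / len(expressed)
    assert bg_drop > expr_drop
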